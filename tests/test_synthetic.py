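import numpy as np
import pandas as pd
import pytest

from sexdim import synthetic as syn
from sexdim.synthetic import (
    CohortSpec,
    ConfigurationError,
    EffectSpec,
    GroundTruth,
    generate_cohort,
    generate_counts,
    generate_gene_sets,
    generate_lr_pairs,
    generate_prior_network,
    generate_proteomics,
    study_cohort_spec,
)


class TestCohort:
    def test_study_scale_totals(self):
        subjects = generate_cohort(study_cohort_spec(), seed=0)
        assert len(subjects) == 306
        assert (subjects["group"] == "control").sum() == 146

    def test_all_zero_sizes_gives_empty_table(self):
        spec = CohortSpec(group_sizes={g: (0, 0) for g in syn.GROUPS})
        assert len(generate_cohort(spec, seed=1)) == 0

    def test_small_cohort_rules(self):
        spec = CohortSpec(group_sizes={"control": (2, 2), "late_ad": (1, 1)})
        subjects = generate_cohort(spec, seed=7)
        assert len(subjects) == 6
        assert (subjects["sex"] == "M").sum() == 3
        ad = subjects[subjects["condition"] == "AD"]
        assert set(ad["braak"]) <= {5.0, 6.0}
        assert (ad["mmse"] < 20).all()
        hc = subjects[subjects["condition"] == "HC"]
        assert hc["braak"].isna().all()
        assert hc["mmse"].between(20, 30).all()

    def test_determinism(self):
        spec = study_cohort_spec()
        a = generate_cohort(spec, seed=5)
        b = generate_cohort(spec, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_overlapping_braak_ranges_rejected(self):
        spec = CohortSpec(
            group_sizes={"early_ad": (1, 1), "late_ad": (1, 1)},
            braak_ranges={"control": (), "early_ad": (0, 1, 2),
                          "late_ad": (2, 5, 6), "intermediate_ad": (3, 4)},
        )
        with pytest.raises(ConfigurationError, match="overlap"):
            generate_cohort(spec, seed=0)


class TestEffectSpec:
    @pytest.mark.parametrize(
        "category,dm,df,ok",
        [
            ("neutral", 1, 1, True),
            ("neutral", 1, -1, False),
            ("male_specific", 1, 0, True),
            ("male_specific", 1, 1, False),
            ("female_specific", 0, -1, True),
            ("dimorphic", 1, -1, True),
            ("dimorphic", 1, 1, False),
            ("dimorphic", 0, 0, False),
        ],
    )
    def test_direction_invariants(self, category, dm, df, ok):
        if ok:
            EffectSpec("g", "ct", category, 0.5, dm, df)
        else:
            with pytest.raises(ConfigurationError):
                EffectSpec("g", "ct", category, 0.5, dm, df)

    def test_ground_truth_round_trips(self, tmp_path):
        truth = GroundTruth(
            effects=[EffectSpec("g1", "ct", "male_specific", 0.5, 1, 0)],
            planted_sets={"S": ["g1"]},
            planted_edges=[{"source": "a", "target": "b", "sign": "+"}],
        )
        truth.to_json(tmp_path / "t.json")
        back = GroundTruth.from_json(tmp_path / "t.json")
        assert back == truth


class TestCounts:
    def _cohort(self, n=10):
        spec = CohortSpec(group_sizes={"control": (n, n), "late_ad": (n, n)})
        return generate_cohort(spec, seed=0)

    def test_planted_logfc_recovered_in_target_sex_only(self):
        subjects = self._cohort(10)
        genes = [f"g{i}" for i in range(20)]
        effects = [EffectSpec("g0", "ct", "male_specific", 0.5, 1, 0)]
        cm, meta, _ = generate_counts(
            subjects, 60, genes, ["ct"], effects, dispersion=0.0, seed=2,
            size_factor_sigma=0.0,
        )
        row = np.asarray(cm.counts[0].todense()).ravel()
        for sex, expected in (("M", 0.5), ("F", 0.0)):
            ad = ((meta["sex"] == sex) & (meta["condition"] == "AD")).to_numpy()
            hc = ((meta["sex"] == sex) & (meta["condition"] == "HC")).to_numpy()
            assert min(ad.sum(), hc.sum()) >= 500
            lfc = np.log(row[ad].mean() / row[hc].mean())
            assert lfc == pytest.approx(expected, abs=0.12)

    def test_null_genes_have_indistinguishable_groups(self):
        from scipy.stats import mannwhitneyu

        subjects = self._cohort(6)
        genes = [f"g{i}" for i in range(40)]
        cm, meta, _ = generate_counts(subjects, 30, genes, ["ct"], [],
                                      dispersion=0.0, seed=3)
        ad = (meta["condition"] == "AD").to_numpy()
        ps = []
        for i in range(40):
            row = np.asarray(cm.counts[i].todense()).ravel()
            if row.sum() == 0:
                continue
            ps.append(mannwhitneyu(row[ad], row[~ad]).pvalue)
        assert np.mean(np.asarray(ps) < 0.05) < 0.15

    def test_same_seed_bit_identical(self):
        subjects = self._cohort(3)
        genes = [f"g{i}" for i in range(10)]
        a = generate_counts(subjects, 10, genes, ["ct"], [], seed=9)
        b = generate_counts(subjects, 10, genes, ["ct"], [], seed=9)
        assert (a[0].counts != b[0].counts).nnz == 0
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_moment_recovery_within_5pct(self):
        # fixed-seed stratum means converge to the planted means
        subjects = self._cohort(10)
        genes = ["g0"]
        cm, meta, _ = generate_counts(
            subjects, 60, genes, ["ct"], [], dispersion=0.0, seed=4,
            size_factor_sigma=0.0, baseline_log_range=(np.log(2.0), np.log(2.0)),
        )
        row = np.asarray(cm.counts[0].todense()).ravel()
        assert abs(row.mean() - 2.0) / 2.0 < 0.05

    def test_unknown_planted_gene_named_in_error(self):
        subjects = self._cohort(2)
        effects = [EffectSpec("missing", "ct", "neutral", 0.5, 1, 1)]
        with pytest.raises(ConfigurationError, match="missing"):
            generate_counts(subjects, 5, ["g0"], ["ct"], effects, seed=0)


class TestGeneSets:
    def test_single_planted_set_only(self):
        coll = generate_gene_sets(["a", "b", "c", "d", "e", "f", "g", "h", "i", "j"],
                                  n_sets=1, planted={"P": list("abcdefghij")}, seed=0)
        assert len(coll) == 1 and coll.sets["P"] == list("abcdefghij")

    def test_seed_fixed_identical_bytes(self, tmp_path):
        from sexdim.io import write_gmt

        genes = [f"g{i}" for i in range(60)]
        for name in ("a.gmt", "b.gmt"):
            write_gmt(generate_gene_sets(genes, 5, seed=11), tmp_path / name)
        assert (tmp_path / "a.gmt").read_bytes() == (tmp_path / "b.gmt").read_bytes()

    def test_planted_gene_outside_universe_rejected(self):
        with pytest.raises(ConfigurationError, match="outside"):
            generate_gene_sets(["a"], 1, planted={"P": ["zzz"]}, seed=0)

    def test_too_few_sets_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_gene_sets(["a", "b"], 0, planted={"P": ["a"]}, seed=0)


class TestPriorNetwork:
    GENES = [f"g{i}" for i in range(30)]

    def test_unknown_fraction_extremes(self):
        none = generate_prior_network(self.GENES, 50, 0.0, seed=1)
        assert (none["sign"] != "unknown").all()
        full = generate_prior_network(self.GENES, 50, 1.0, seed=1)
        assert (full["sign"] == "unknown").all()

    def test_planted_edges_included_with_admissible_annotations(self):
        chain = pd.DataFrame({"source": ["g0", "g1"], "target": ["g1", "g2"],
                              "sign": ["+", "+"]})
        net = generate_prior_network(self.GENES, 20, 0.5, planted_consistent=chain,
                                     seed=2)
        merged = net.merge(chain, on=["source", "target", "sign"])
        assert len(merged) == 2
        head = net.head(2)
        assert set(head["mechanism"]) <= set(syn.ALLOWED_MECHANISMS)
        assert (head["tissue"] == "brain").all()

    def test_requesting_fewer_edges_than_planted_rejected(self):
        chain = pd.DataFrame({"source": ["g0"], "target": ["g1"], "sign": ["+"]})
        with pytest.raises(ConfigurationError):
            generate_prior_network(self.GENES, 0, 0.0, planted_consistent=chain, seed=0)


class TestProteomics:
    def _cohort(self):
        spec = CohortSpec(group_sizes={"control": (30, 30), "late_ad": (30, 30)})
        return generate_cohort(spec, seed=0)

    def test_shared_effect_appears_in_target_sex(self):
        subjects = self._cohort()
        eff = [EffectSpec("p0", "ct", "male_specific", 1.0, 1, 0)]
        ab, meta = generate_proteomics(subjects, ["p0", "p1"], eff,
                                       noise_sd=0.2, seed=3, age_slope=0.0)
        merged = meta.assign(v=ab.loc["p0", meta["subject_id"]].to_numpy())
        for sex, expected in (("M", 1.0), ("F", 0.0)):
            sub = merged[merged["sex"] == sex]
            diff = (sub.loc[sub["condition"] == "AD", "v"].mean()
                    - sub.loc[sub["condition"] == "HC", "v"].mean())
            assert diff == pytest.approx(expected, abs=0.25)

    def test_noiseless_difference_exact(self):
        subjects = self._cohort()
        eff = [EffectSpec("p0", "ct", "neutral", 0.7, 1, 1)]
        ab, meta = generate_proteomics(subjects, ["p0"], eff, noise_sd=0.0,
                                       seed=0, age_slope=0.0)
        merged = meta.assign(v=ab.loc["p0", meta["subject_id"]].to_numpy())
        diff = (merged.loc[merged["condition"] == "AD", "v"].mean()
                - merged.loc[merged["condition"] == "HC", "v"].mean())
        assert diff == pytest.approx(0.7, abs=1e-12)

    def test_deterministic_and_negative_noise_rejected(self):
        subjects = self._cohort()
        a, _ = generate_proteomics(subjects, ["p0"], [], noise_sd=0.5, seed=4)
        b, _ = generate_proteomics(subjects, ["p0"], [], noise_sd=0.5, seed=4)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ConfigurationError):
            generate_proteomics(subjects, ["p0"], [], noise_sd=-1, seed=0)


class TestLrPairs:
    def test_empty_and_closure_and_uniqueness(self):
        genes = ["a", "b", "c"]
        assert len(generate_lr_pairs(genes, 0, seed=0)) == 0
        pairs = generate_lr_pairs(genes, 6, seed=1)
        assert len(pairs) == 6
        assert len(pairs.drop_duplicates()) == 6
        assert (pairs["ligand"] != pairs["receptor"]).all()
        assert set(pairs["ligand"]) | set(pairs["receptor"]) <= set(genes)
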