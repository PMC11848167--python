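"""Synthetic cohort / count / network / proteomics generators with planted effects.

The generators emulate the structure of a sex-stratified AD case-control
single-cell study: four Braak-staged subject groups with sex-stratified sizes,
per-cell-type baseline expression with per-cell size factors, planted
sex-neutral / sex-specific / sex-dimorphic AD effects of known log fold
change, a partially signed prior regulatory network, ligand-receptor pairs,
and a proteomics table sharing a subset of the planted effects. Every
generator is a pure function of its arguments and the seed, and the planted
structure is recorded in a serializable :class:`GroundTruth` registry so
downstream stages can be scored by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, GeneSetCollection

GROUPS = ("control", "early_ad", "intermediate_ad", "late_ad")

#: Sex-stratified group sizes of the study cohort (n_male, n_female).
STUDY_GROUP_SIZES: Mapping[str, tuple[int, int]] = {
    "control": (72, 74),
    "early_ad": (14, 5),
    "intermediate_ad": (37, 22),
    "late_ad": (28, 54),
}

#: Braak stages admissible per group (stages I..VI encoded 1..6; controls NA).
DEFAULT_BRAAK_RANGES: Mapping[str, tuple[int, ...]] = {
    "control": (),
    "early_ad": (0, 1, 2),
    "intermediate_ad": (3, 4),
    "late_ad": (5, 6),
}

CATEGORIES = ("neutral", "male_specific", "female_specific", "dimorphic")


class ConfigurationError(ValueError):
    """A generator spec violates its invariants."""


@dataclass
class CohortSpec:
    """Cohort layout: group sizes, Braak ranges, age distribution, MMSE rule.

    Patients draw integer MMSE below 20 and controls in [20, 30]; AD groups
    draw a Braak stage uniformly from their admissible range while controls
    carry no stage.
    """

    group_sizes: Mapping[str, tuple[int, int]]
    braak_ranges: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BRAAK_RANGES)
    )
    age_mean: float = 85.0
    age_sd: float = 7.0

    def validate(self) -> None:
        for group, (n_m, n_f) in self.group_sizes.items():
            if group not in GROUPS:
                raise ConfigurationError(f"unknown group {group!r}")
            if n_m < 0 or n_f < 0:
                raise ConfigurationError(f"negative size for group {group!r}")
        seen: set[int] = set()
        for group, stages in self.braak_ranges.items():
            if group == "control":
                if stages:
                    raise ConfigurationError("controls must have no Braak range")
                continue
            bad = [s for s in stages if not 0 <= s <= 6]
            if bad:
                raise ConfigurationError(f"Braak stages out of range: {bad}")
            if seen & set(stages):
                raise ConfigurationError("Braak ranges overlap across AD groups")
            seen |= set(stages)


def study_cohort_spec() -> CohortSpec:
    """The cohort at the sizes of the study it emulates (306 subjects)."""
    return CohortSpec(group_sizes=dict(STUDY_GROUP_SIZES))


def generate_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Draw one subject row per cohort slot; deterministic in (spec, seed)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for group in GROUPS:
        if group not in spec.group_sizes:
            continue
        n_m, n_f = spec.group_sizes[group]
        condition = "HC" if group == "control" else "AD"
        stages = spec.braak_ranges.get(group, ())
        if condition == "AD" and not stages:
            raise ConfigurationError(f"AD group {group!r} has empty Braak range")
        for sex, n in (("M", n_m), ("F", n_f)):
            for i in range(n):
                braak = float(rng.choice(stages)) if stages else np.nan
                age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 60, 105))
                if condition == "AD":
                    mmse = int(rng.integers(5, 20))
                else:
                    mmse = int(rng.integers(20, 31))
                rows.append(
                    {
                        "subject_id": f"{group}_{sex}{i:03d}",
                        "group": group,
                        "condition": condition,
                        "sex": sex,
                        "braak": braak,
                        "age": round(age, 1),
                        "mmse": mmse,
                    }
                )
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "condition", "sex", "braak", "age", "mmse"]
    )


@dataclass
class EffectSpec:
    """A planted AD effect for one gene in one cell type.

    ``delta_logfc`` is on the natural-log scale; the AD-cell mean of sex *s*
    is multiplied by exp(direction_s * delta_logfc).
    """

    gene: str
    cell_type: str
    category: str
    delta_logfc: float
    direction_male: int
    direction_female: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigurationError(f"unknown category {self.category!r}")
        dm, df = self.direction_male, self.direction_female
        ok = {
            "neutral": dm == df != 0,
            "male_specific": dm != 0 and df == 0,
            "female_specific": df != 0 and dm == 0,
            "dimorphic": dm == -df != 0,
        }[self.category]
        if not ok:
            raise ConfigurationError(
                f"directions ({dm}, {df}) inconsistent with category {self.category!r}"
            )


def make_effects(
    genes_per_category: Mapping[str, Sequence[str]],
    cell_type: str,
    delta_logfc: float,
) -> list[EffectSpec]:
    """Convenience: build EffectSpecs with canonical directions per category."""
    directions = {
        "neutral": (1, 1),
        "male_specific": (1, 0),
        "female_specific": (0, 1),
        "dimorphic": (1, -1),
    }
    out = []
    for category, genes in genes_per_category.items():
        dm, df = directions[category]
        for g in genes:
            out.append(EffectSpec(g, cell_type, category, delta_logfc, dm, df))
    return out


@dataclass
class GroundTruth:
    """Registry of everything planted, for parameter-recovery scoring."""

    effects: list[EffectSpec] = field(default_factory=list)
    planted_sets: dict[str, list[str]] = field(default_factory=dict)
    planted_edges: list[dict] = field(default_factory=list)
    protein_effects: list[EffectSpec] = field(default_factory=list)

    def effect_by_gene(self) -> dict[str, EffectSpec]:
        return {e.gene: e for e in self.effects}

    def to_json(self, path) -> None:
        payload = {
            "effects": [asdict(e) for e in self.effects],
            "planted_sets": self.planted_sets,
            "planted_edges": self.planted_edges,
            "protein_effects": [asdict(e) for e in self.protein_effects],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            effects=[EffectSpec(**e) for e in payload["effects"]],
            planted_sets=payload["planted_sets"],
            planted_edges=payload["planted_edges"],
            protein_effects=[EffectSpec(**e) for e in payload["protein_effects"]],
        )


def generate_counts(
    subjects: pd.DataFrame,
    cells_per_subject: int,
    genes: Sequence[str],
    cell_types: Sequence[str],
    effects: Sequence[EffectSpec] = (),
    dispersion: float = 0.0,
    seed: int = 0,
    size_factor_sigma: float = 0.3,
    baseline_log_range: tuple[float, float] = (np.log(0.05), np.log(5.0)),
    planted_baseline_log_range: tuple[float, float] = (np.log(0.5), np.log(2.0)),
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw a gene x cell count matrix with planted AD effects.

    Counts are negative-binomial (Poisson when ``dispersion`` is 0) around a
    gene x cell-type baseline mean scaled by a lognormal per-cell size factor.
    For a planted gene in its target cell type the AD-cell mean of sex *s* is
    multiplied by exp(direction_s * delta_logfc). Baselines for planted genes
    are drawn from a moderate-expression band so the effect concerns a gene a
    cell actually expresses; background baselines span a wide log-uniform
    range, which also exercises expression-fraction filters.

    Returns the matrix, the aligned per-cell metadata, and the GroundTruth.
    """
    if dispersion < 0:
        raise ConfigurationError("dispersion must be >= 0")
    gene_list = list(genes)
    gene_pos = {g: i for i, g in enumerate(gene_list)}
    for e in effects:
        if e.gene not in gene_pos:
            raise ConfigurationError(f"planted gene {e.gene!r} absent from gene list")
        if e.cell_type not in cell_types:
            raise ConfigurationError(f"planted cell type {e.cell_type!r} unknown")
    rng = np.random.default_rng(seed)

    n_genes = len(gene_list)
    lo, hi = baseline_log_range
    baselines = {
        ct: np.exp(rng.uniform(lo, hi, size=n_genes)) for ct in cell_types
    }
    plo, phi = planted_baseline_log_range
    for e in effects:
        baselines[e.cell_type][gene_pos[e.gene]] = np.exp(rng.uniform(plo, phi))

    # log-mean multipliers per (cell_type, sex, condition), planted genes only
    effect_mult: dict[tuple[str, str], np.ndarray] = {}
    for ct in cell_types:
        for sex in ("M", "F"):
            effect_mult[(ct, sex)] = np.ones(n_genes)
    for e in effects:
        effect_mult[(e.cell_type, "M")][gene_pos[e.gene]] = np.exp(
            e.direction_male * e.delta_logfc
        )
        effect_mult[(e.cell_type, "F")][gene_pos[e.gene]] = np.exp(
            e.direction_female * e.delta_logfc
        )

    n_cells = len(subjects) * cells_per_subject
    meta_cols = ["cell_id", "subject_id", "cell_type", "condition", "sex",
                 "braak", "age", "mmse"]
    if n_cells == 0:
        meta = pd.DataFrame(columns=meta_cols)
        cm = CountMatrix(gene_list, [], sp.csr_matrix((n_genes, 0), dtype=np.int64))
        return cm, meta, GroundTruth(effects=list(effects))

    ct_idx = rng.integers(len(cell_types), size=n_cells)
    size_factors = np.exp(rng.normal(0.0, size_factor_sigma, size=n_cells))
    subj_rep = subjects.loc[subjects.index.repeat(cells_per_subject)].reset_index(drop=True)
    within = np.tile(np.arange(cells_per_subject), len(subjects))
    meta = pd.DataFrame(
        {
            "cell_id": [f"{s}_c{k:04d}" for s, k in zip(subj_rep["subject_id"], within)],
            "subject_id": subj_rep["subject_id"],
            "cell_type": [cell_types[i] for i in ct_idx],
            "condition": subj_rep["condition"],
            "sex": subj_rep["sex"],
            "braak": subj_rep["braak"],
            "age": subj_rep["age"],
            "mmse": subj_rep["mmse"],
        },
        columns=meta_cols,
    )

    dense = np.zeros((n_genes, n_cells), dtype=np.int64)
    is_ad = (subj_rep["condition"] == "AD").to_numpy()
    sex_arr = subj_rep["sex"].to_numpy()
    # sample block-wise per (cell type, sex, condition) stratum
    for ci, ct in enumerate(cell_types):
        for sex in ("M", "F"):
            for ad in (False, True):
                mask = (ct_idx == ci) & (sex_arr == sex) & (is_ad == ad)
                idx = np.flatnonzero(mask)
                if idx.size == 0:
                    continue
                mean_vec = baselines[ct] * (effect_mult[(ct, sex)] if ad else 1.0)
                mu = mean_vec[:, None] * size_factors[idx][None, :]
                if dispersion == 0:
                    block = rng.poisson(mu)
                else:
                    shape = 1.0 / dispersion
                    block = rng.poisson(rng.gamma(shape, mu / shape))
                dense[:, idx] = block
    counts_mat = sp.csr_matrix(dense)
    cm = CountMatrix(gene_list, meta["cell_id"].tolist() if len(meta) else [], counts_mat)
    truth = GroundTruth(effects=list(effects))
    return cm, meta, truth


def generate_gene_sets(
    genes: Sequence[str],
    n_sets: int,
    planted: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
    set_size_range: tuple[int, int] = (10, 50),
) -> GeneSetCollection:
    """Random background gene sets plus planted sets with fixed membership."""
    planted = dict(planted or {})
    universe = list(genes)
    for name, members in planted.items():
        missing = [m for m in members if m not in set(universe)]
        if missing:
            raise ConfigurationError(
                f"planted set {name!r} contains genes outside the universe: {missing}"
            )
    if n_sets < len(planted):
        raise ConfigurationError(
            f"n_sets={n_sets} smaller than number of planted sets ({len(planted)})"
        )
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for name, members in planted.items():
        sets[name] = list(members)
        descriptions[name] = "planted"
    n_random = n_sets - len(planted)
    lo, hi = set_size_range
    for i in range(n_random):
        size = int(rng.integers(lo, min(hi, len(universe)) + 1))
        members = list(rng.choice(universe, size=size, replace=False))
        name = f"RANDOM_SET_{i:03d}"
        sets[name] = members
        descriptions[name] = "background"
    return GeneSetCollection(sets, descriptions)


ALLOWED_MECHANISMS = (
    "binding",
    "transcription regulation",
    "influence on expression",
    "co-regulation of transcription",
    "regulation",
)
DECOY_MECHANISMS = ("phosphorylation", "cleavage", "transport")


def generate_prior_network(
    genes: Sequence[str],
    n_edges: int,
    frac_unknown_sign: float,
    planted_consistent: pd.DataFrame | None = None,
    seed: int = 0,
    frac_decoy_mechanism: float = 0.2,
    frac_other_tissue: float = 0.1,
) -> pd.DataFrame:
    """Random candidate edge table; planted edges are included verbatim.

    ``planted_consistent`` rows (source, target, sign) are emitted first with
    an admissible mechanism and brain tissue so they survive downstream
    filtering. The requested fraction of the *random* edges carries sign
    ``unknown``; decoy mechanisms and non-brain tissues are mixed into the
    random remainder only.
    """
    if not 0 <= frac_unknown_sign <= 1:
        raise ConfigurationError("frac_unknown_sign must be in [0, 1]")
    n_planted = 0 if planted_consistent is None else len(planted_consistent)
    if n_edges < n_planted:
        raise ConfigurationError(
            f"n_edges={n_edges} smaller than planted edge count ({n_planted})"
        )
    rng = np.random.default_rng(seed)
    gene_arr = np.asarray(list(genes))
    rows = []
    seen_pairs: set[tuple[str, str]] = set()
    if planted_consistent is not None:
        for edge in planted_consistent.itertuples(index=False):
            rows.append(
                {
                    "source": edge.source,
                    "target": edge.target,
                    "sign": edge.sign,
                    "mechanism": ALLOWED_MECHANISMS[len(rows) % len(ALLOWED_MECHANISMS)],
                    "tissue": "brain",
                }
            )
            seen_pairs.add((edge.source, edge.target))
    while len(rows) < n_edges:
        s, t = rng.choice(gene_arr, size=2, replace=False)
        if (s, t) in seen_pairs:
            continue
        seen_pairs.add((s, t))
        if rng.random() < frac_unknown_sign:
            sign = "unknown"
        else:
            sign = "+" if rng.random() < 0.5 else "-"
        if rng.random() < frac_decoy_mechanism:
            mechanism = DECOY_MECHANISMS[int(rng.integers(len(DECOY_MECHANISMS)))]
        else:
            mechanism = ALLOWED_MECHANISMS[int(rng.integers(len(ALLOWED_MECHANISMS)))]
        tissue = "liver" if rng.random() < frac_other_tissue else "brain"
        rows.append(
            {"source": s, "target": t, "sign": sign, "mechanism": mechanism, "tissue": tissue}
        )
    return pd.DataFrame(rows, columns=["source", "target", "sign", "mechanism", "tissue"])


def generate_proteomics(
    subjects: pd.DataFrame,
    proteins: Sequence[str],
    shared_effects: Sequence[EffectSpec] = (),
    noise_sd: float = 0.5,
    seed: int = 0,
    age_slope: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gaussian protein abundances encoding the shared planted effects.

    Returns (protein x sample abundance table, sample metadata). Each
    abundance is base + direction_sex * delta * [AD] + age_slope * (age -
    cohort mean age) + N(0, noise_sd); the age term keeps the age covariate
    non-trivial in the downstream regression.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    protein_list = list(proteins)
    pos = {p: i for i, p in enumerate(protein_list)}
    for e in shared_effects:
        if e.gene not in pos:
            raise ConfigurationError(f"planted protein {e.gene!r} absent from protein list")
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 1.0, size=len(protein_list))
    age_center = float(subjects["age"].mean()) if len(subjects) else 0.0
    data = np.empty((len(protein_list), len(subjects)))
    for j, subj in enumerate(subjects.itertuples(index=False)):
        mu = base + age_slope * (subj.age - age_center)
        if subj.condition == "AD":
            for e in shared_effects:
                direction = e.direction_male if subj.sex == "M" else e.direction_female
                mu[pos[e.gene]] += direction * e.delta_logfc
        noise = rng.normal(0.0, noise_sd, size=len(protein_list)) if noise_sd > 0 else 0.0
        data[:, j] = mu + noise
    abundance = pd.DataFrame(data, index=protein_list, columns=subjects["subject_id"].tolist())
    abundance.index.name = "protein"
    sample_meta = subjects[["subject_id", "condition", "sex", "age"]].copy()
    return abundance, sample_meta


def generate_lr_pairs(genes: Sequence[str], n_pairs: int, seed: int = 0) -> pd.DataFrame:
    """Unique (ligand, receptor) pairs over the gene universe; ligand != receptor."""
    gene_list = list(genes)
    if n_pairs > len(gene_list) * (len(gene_list) - 1):
        raise ConfigurationError("n_pairs exceeds the number of ordered gene pairs")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    while len(pairs) < n_pairs:
        lig, rec = rng.choice(gene_list, size=2, replace=False)
        if (lig, rec) not in seen:
            seen.add((lig, rec))
            pairs.append((lig, rec))
    return pd.DataFrame(pairs, columns=["ligand", "receptor"])
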