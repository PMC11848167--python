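"""Run every analysis stage in order."""

import runpy
import sys
from pathlib import Path

HERE = Path(__file__).parent

STAGES = [
    "01_simulate_data.py",
    "02_differential_expression.py",
    "03_sex_patterns.py",
    "04_enrichment.py",
    "05_communication.py",
    "06_regulatory_networks.py",
    "07_proteomics_validation.py",
    "08_covariate_correlations.py",
]

if __name__ == "__main__":
    for stage in STAGES:
        print(f"\n== {stage} ==")
        sys.argv = [stage]
        runpy.run_path(str(HERE / stage), run_name="__main__")
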