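"""Shared configuration for the numbered analysis drivers.

All drivers operate on one results directory so they can be run in order:

    python analysis/01_simulate_cohort.py
    python analysis/02_group_ica.py
    python analysis/03_hrf_betas.py
    python analysis/04_effective_connectivity.py
    python analysis/05_group_statistics.py

The cohort is desk-scale (10/8/6 subjects per group) on the default
24 x 24 x 12 grid; pass --seed / --out to any driver to change the run.
"""

import argparse

from olfnet.pipeline import PipelineConfig


def driver_config(description: str) -> PipelineConfig:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=str, default="results/analysis")
    args = ap.parse_args()
    cfg = PipelineConfig(
        out_dir=args.out,
        seed=args.seed,
        sizes={"CN": 10, "MCI": 8, "AD": 6},
    )
    cfg.validate()
    return cfg
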