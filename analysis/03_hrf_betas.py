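"""Estimate network HRFs and single-trial beta amplitudes.

FIR deconvolution of each subject's ON/DMN time course over the odor
stimulation events; the CN group HRFs establish the ON/DMN anti-phase
relation, and the CN group ON HRF is the single response shape used to fit
per-trial betas in every group.  DMN suppression appears as negative beta.
"""

import json
import os

import pandas as pd

from common import driver_config
from olfnet.pipeline import stage_betas, stage_hrf


def main():
    cfg = driver_config(__doc__)
    stage_hrf(cfg)
    stage_betas(cfg)
    hdir = os.path.join(cfg.out_dir, "derivatives", "hrf_beta")
    with open(os.path.join(hdir, "phase.json")) as fh:
        phase = json.load(fh)
    print(f"CN ON vs DMN HRF correlation: {phase['correlation']:.3f} "
          f"(anti-phase: {phase['antiphase']})")
    summary = pd.read_csv(os.path.join(hdir, "condition_summary.csv"))
    subjects = pd.read_csv(
        os.path.join(cfg.out_dir, "raw", "participants.tsv"), sep="\t"
    )
    merged = summary.merge(subjects[["subject_id", "group"]], on="subject_id")
    print("mean condition betas by group and network:")
    print(merged.groupby(["network", "group"])
          [["odor_visual", "visual_only", "difference"]].mean().round(3))


if __name__ == "__main__":
    main()
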