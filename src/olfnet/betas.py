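"""Single-trial beta amplitudes and condition contrasts.

Each trial gets one regressor: the estimated group event-response curve
placed at the trial onset.  All trial regressors plus polynomial drift are
fit jointly by least squares, giving one amplitude (beta) per trial per
network time course.  DMN suppression appears as negative beta.  Condition
summaries (per-subject condition means and the odor-minus-visual
difference) feed the group statistics.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .hrf import HRFEstimate, drift_matrix
from .paradigm import ODOR_VISUAL, VISUAL_ONLY, ParadigmDesign


def trial_regressors(design: ParadigmDesign, hrf: HRFEstimate) -> np.ndarray:
    """One column per trial: the event-response curve at the trial onset.

    The FIR curve estimated from the 6-s stimulation events already embeds
    the stimulus duration, so it is placed directly at each onset rather
    than re-convolved with a boxcar.
    """
    T = design.n_volumes
    curve = hrf.values
    X = np.zeros((T, len(design.events)))
    for j, e in enumerate(design.events):
        start = int(round(e.onset / design.tr))
        stop = min(start + curve.size, T)
        X[start:stop, j] = curve[: stop - start]
    return X


def single_trial_betas(
    timecourse: np.ndarray,
    design: ParadigmDesign,
    hrf: HRFEstimate,
    subject_id: Optional[str] = None,
    network: Optional[str] = None,
    drift_order: int = 2,
) -> pd.DataFrame:
    """Joint least-squares single-trial amplitudes for one time course."""
    y = np.asarray(timecourse, dtype=float)
    if y.size != design.n_volumes:
        raise ValueError("time course length must equal n_volumes")
    Xt = trial_regressors(design, hrf)
    X = np.column_stack([Xt, drift_matrix(design.n_volumes, drift_order)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear trial regressors; design is rank-deficient")
    coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
    betas = coefs[: Xt.shape[1]]
    rows = []
    for j, e in enumerate(design.events):
        rows.append(
            {
                "subject_id": subject_id,
                "network": network,
                "trial": j,
                "condition": e.condition,
                "intensity": e.intensity,
                "onset": e.onset,
                "beta": betas[j],
            }
        )
    return pd.DataFrame(rows)


def condition_summary(betas: pd.DataFrame) -> pd.DataFrame:
    """Per-subject condition-mean betas and the odor-minus-visual difference.

    Groups by subject (and network when present).  A subject missing one of
    the two conditions gets NaN for that mean and an undefined (NaN)
    difference; such rows are flagged in the ``complete`` column.
    """
    keys = [k for k in ("subject_id", "network") if k in betas.columns
            and betas[k].notna().any()]
    if not keys:
        betas = betas.assign(subject_id="subject")
        keys = ["subject_id"]
    pivot = (
        betas.groupby(keys + ["condition"])["beta"].mean().unstack("condition")
    )
    for cond in (ODOR_VISUAL, VISUAL_ONLY):
        if cond not in pivot.columns:
            pivot[cond] = np.nan
    pivot = pivot[[ODOR_VISUAL, VISUAL_ONLY]]
    pivot["difference"] = pivot[ODOR_VISUAL] - pivot[VISUAL_ONLY]
    pivot["complete"] = pivot[[ODOR_VISUAL, VISUAL_ONLY]].notna().all(axis=1)
    return pivot.reset_index()
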