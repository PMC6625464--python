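"""Network HRF estimation by FIR deconvolution.

The hemodynamic response of each network to the 6-s odor stimulus is
estimated by least-squares FIR deconvolution of its IC time course over
lags 0..window at TR resolution, pooling all odor stimulation events, with
low-order polynomial drift columns.  The CN group HRF (lag-wise mean of the
unit-peak CN estimates) is the only response shape used downstream for beta
estimation in every group.  In CN the ON and DMN responses are expected to
be in anti-phase (correlation near -1 across lags).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .paradigm import ODOR_VISUAL, ParadigmDesign


@dataclass
class HRFEstimate:
    """Deconvolved event response on the lag grid, unit-peak-normalized."""

    network: Optional[str]
    lags: np.ndarray          # seconds, spacing = TR
    values: np.ndarray        # peak magnitude 1, sign preserved
    peak_latency: float       # seconds
    scale: float              # magnitude divided out at the peak
    degenerate: bool = False


@dataclass
class PhaseRelation:
    correlation: float
    antiphase: bool
    degenerate: bool = False


def drift_matrix(n: int, order: int) -> np.ndarray:
    """Legendre polynomial drift columns of degree 0..order."""
    x = np.linspace(-1.0, 1.0, n)
    return np.polynomial.legendre.legvander(x, order)


def fir_design(
    design: ParadigmDesign, window: float, condition: str = ODOR_VISUAL
) -> np.ndarray:
    """FIR indicator columns, one per lag 0..window at TR resolution."""
    n_lags = int(round(window / design.tr)) + 1
    onsets = design.onset_volumes(condition)
    if onsets.size == 0:
        raise ValueError(f"no {condition!r} events in design")
    X = np.zeros((design.n_volumes, n_lags))
    for lag in range(n_lags):
        idx = onsets + lag
        idx = idx[idx < design.n_volumes]
        X[idx, lag] = 1.0
    return X


def estimate_fir_hrf(
    timecourse: np.ndarray,
    design: ParadigmDesign,
    window: float = 20.0,
    condition: str = ODOR_VISUAL,
    drift_order: int = 2,
    network: Optional[str] = None,
) -> HRFEstimate:
    """Least-squares FIR deconvolution of one network time course.

    Pools all ``condition`` events (defaults to the odor stimulation
    trials, whose 36-s cycle keeps the 20-s FIR window free of overlap).
    The returned curve is normalized to unit peak magnitude with the scale
    stored; sign is preserved so a suppressed network keeps its negative
    response.
    """
    y = np.asarray(timecourse, dtype=float)
    if y.size != design.n_volumes:
        raise ValueError("time course length must equal n_volumes")
    F = fir_design(design, window, condition)
    X = np.column_stack([F, drift_matrix(design.n_volumes, drift_order)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient FIR design: event lags overlap; reduce the "
            "window or check inter-trial spacing"
        )
    coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
    curve = coefs[: F.shape[1]]
    peak = int(np.argmax(np.abs(curve)))
    scale = float(np.abs(curve[peak]))
    values = curve / scale if scale > 0 else curve.copy()
    lags = np.arange(F.shape[1]) * design.tr
    return HRFEstimate(
        network=network,
        lags=lags,
        values=values,
        peak_latency=float(lags[peak]),
        scale=scale,
        degenerate=scale == 0,
    )


def group_hrf(estimates: Sequence[HRFEstimate]) -> HRFEstimate:
    """Lag-wise mean of normalized estimates (the CN group response).

    This pooled curve is the single response shape used for beta estimation
    in all groups.  A near-zero mean curve (mutually cancelling inputs) is
    flagged degenerate.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one estimate")
    lags = estimates[0].lags
    for e in estimates[1:]:
        if e.lags.shape != lags.shape or not np.allclose(e.lags, lags):
            raise ValueError("estimates are on different lag grids")
    mean = np.mean([e.values for e in estimates], axis=0)
    peak = int(np.argmax(np.abs(mean)))
    scale = float(np.abs(mean[peak]))
    degenerate = scale < 0.1
    if degenerate:
        warnings.warn("group HRF is near zero; estimates cancel")
    return HRFEstimate(
        network=estimates[0].network,
        lags=lags.copy(),
        values=mean,
        peak_latency=float(lags[peak]),
        scale=scale,
        degenerate=degenerate,
    )


def phase_relation(
    on: HRFEstimate, dmn: HRFEstimate, threshold: float = -0.5
) -> PhaseRelation:
    """Pearson correlation of the two response curves across lags.

    ``antiphase`` is True when the correlation is below ``threshold``
    (default -0.5, i.e. the curves move in opposition).  Constant curves
    leave the correlation undefined and are flagged.
    """
    if on.lags.shape != dmn.lags.shape or not np.allclose(on.lags, dmn.lags):
        raise ValueError("estimates are on different lag grids")
    a, b = on.values, dmn.values
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant HRF curve; phase relation undefined")
        return PhaseRelation(correlation=float("nan"), antiphase=False, degenerate=True)
    r = float(np.corrcoef(a, b)[0, 1])
    return PhaseRelation(correlation=r, antiphase=r < threshold)
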