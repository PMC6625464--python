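"""Generative model for 4-D BOLD runs.

Each subject's run is built from two network "neural" time series (ON, DMN)
driven by the task through a canonical double-gamma HRF and coupled through
a small linear system with contemporaneous (A), lag-1 (Phi), exogenous
(Gamma) and optional bilinear (task x node) terms - the same model family
the effective-connectivity stage estimates.  The DMN drive is negative
(task suppression) and the ON equation receives the subject's planted
DMN->ON coefficient.  Disease stages degrade the signal two ways: smaller
amplitudes, and a temporal-randomization weight w that mixes the
task-locked series with smoothed noise (w=0 in CN, largest in AD).

Voxel signal = sum over networks of template weight x network series, plus
white noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gamma as gamma_dist

from .cohort import CohortSpec
from .paradigm import ODOR_VISUAL, VISUAL_ONLY, ParadigmDesign
from .templates import NetworkTemplate

CONDITIONS = (ODOR_VISUAL, VISUAL_ONLY)


@dataclass
class BOLDRun:
    """One 4-D run (x, y, z, t) with its brain mask and TR."""

    data: np.ndarray
    mask: np.ndarray
    tr: float

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial grid")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in data")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def voxel_matrix(self) -> np.ndarray:
        """In-mask data as a (voxels x time) matrix."""
        return self.data[self.mask]


def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Double-gamma HRF sampled at TR: peak at 5 s, undershoot at 15 s.

    Returned with unit peak.
    """
    t = np.arange(0, duration + tr / 2, tr)
    h = gamma_dist.pdf(t, a=6, scale=1.0) - gamma_dist.pdf(t, a=16, scale=1.0) / 6.0
    return h / h.max()


def condition_indicator(design: ParadigmDesign, condition: str) -> np.ndarray:
    """Boxcar (0/1) of the condition on the volume grid."""
    box = np.zeros(design.n_volumes)
    for e in design.events_of(condition):
        start = int(round(e.onset / design.tr))
        stop = start + max(1, int(round(e.duration / design.tr)))
        box[start:min(stop, design.n_volumes)] = 1.0
    return box


def convolved_regressors(
    design: ParadigmDesign,
    hrf: Optional[np.ndarray] = None,
    normalize_peak: bool = True,
) -> np.ndarray:
    """HRF-convolved condition indicators, one column per condition.

    Column order follows :data:`CONDITIONS`.  With ``hrf=None`` the
    canonical double-gamma HRF is used.
    """
    if hrf is None:
        hrf = canonical_hrf(design.tr)
    cols = []
    for cond in CONDITIONS:
        box = condition_indicator(design, cond)
        conv = np.convolve(box, hrf)[: design.n_volumes]
        if normalize_peak and np.abs(conv).max() > 0:
            conv = conv / np.abs(conv).max()
        cols.append(conv)
    return np.column_stack(cols)


def spectral_radius(A: np.ndarray, Phi: np.ndarray) -> float:
    """Spectral radius of the lag-1 system after solving out A."""
    n = A.shape[0]
    M = np.linalg.solve(np.eye(n) - A, Phi)
    return float(np.abs(np.linalg.eigvals(M)).max())


def simulate_eusem_series(
    u: np.ndarray,
    A: np.ndarray,
    Phi: np.ndarray,
    Gamma: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    Tmod: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Simulate node series from the structural time-series model.

    eta(t) = A eta(t) + Phi eta(t-1) + Gamma u(t) + sum_k T[:,:,k] u_k(t) eta(t)
             + zeta(t),   zeta ~ N(0, noise_sd^2)

    ``u`` is (T x n_inputs); A, Phi are (n x n); Gamma (n x n_inputs);
    Tmod, if given, (n x n x n_inputs) with zero diagonal per input.
    Rejects non-finite parameters and unstable systems (spectral radius of
    the implied lag-1 transition >= 1).
    """
    for name, arr in [("u", u), ("A", A), ("Phi", Phi), ("Gamma", Gamma)]:
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in {name}")
    if not np.isfinite(noise_sd) or noise_sd < 0:
        raise ValueError("noise_sd must be finite and non-negative")
    n = A.shape[0]
    if np.any(np.diag(A) != 0):
        raise ValueError("contemporaneous self-loops are not allowed")
    if spectral_radius(A, Phi) >= 1:
        raise ValueError("unstable system: spectral radius >= 1")
    T = u.shape[0]
    eta = np.zeros((T, n))
    zeta = rng.normal(0.0, noise_sd, size=(T, n))
    eye = np.eye(n)
    if Tmod is None:
        M = np.linalg.inv(eye - A)
        drive = u @ Gamma.T + zeta
        for t in range(1, T):
            eta[t] = M @ (Phi @ eta[t - 1] + drive[t])
    else:
        if not np.all(np.isfinite(Tmod)):
            raise ValueError("non-finite values in Tmod")
        for t in range(1, T):
            A_t = A + np.tensordot(Tmod, u[t], axes=([2], [0]))
            rhs = Phi @ eta[t - 1] + Gamma @ u[t] + zeta[t]
            eta[t] = np.linalg.solve(eye - A_t, rhs)
    return eta


def simulate_network_series(
    subject: "pd.Series",
    design: ParadigmDesign,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Draw the (ON, DMN) series for one subject row of the cohort table.

    Returns ``eta`` (T x 2, after temporal randomization), the task-locked
    ``eta_clean``, and the task inputs ``u`` (T x 2, odor then visual).
    """
    pars = spec.network[subject["group"]]
    pars.validate()
    u = convolved_regressors(design)
    Gamma = np.array(
        [[pars.on_amp_odor, pars.on_amp_visual],
         [pars.dmn_amp, pars.dmn_amp]]
    )
    ec = float(subject["ec_planted"])
    A = np.array([[0.0, ec], [0.0, 0.0]])
    Phi = np.eye(2) * spec.phi_self
    eta_clean = simulate_eusem_series(u, A, Phi, Gamma, spec.zeta_sd, rng)
    w = pars.rand_w
    eta = eta_clean.copy()
    if w > 0:
        for i in range(2):
            s = gaussian_filter1d(rng.standard_normal(len(eta)), sigma=2.0)
            sd = eta_clean[:, i].std()
            if s.std() > 0:
                s = s / s.std() * (sd if sd > 0 else 1.0)
            eta[:, i] = (1 - w) * eta_clean[:, i] + w * s
    return {"eta": eta, "eta_clean": eta_clean, "u": u}


def simulate_subject_bold(
    subject: "pd.Series",
    design: ParadigmDesign,
    templates: Tuple[NetworkTemplate, NetworkTemplate],
    spec: CohortSpec,
    seed: Optional[int] = None,
    return_planted: bool = False,
):
    """Simulate one subject's 4-D run.

    ``templates`` is the (ON, DMN) pair; the voxel signal is the sum of the
    two template maps times their network series plus white noise with the
    group's noise SD.  With ``return_planted=True`` also returns the planted
    series dictionary from :func:`simulate_network_series`.
    """
    on_t, dmn_t = templates
    if on_t.map.shape != dmn_t.map.shape:
        raise ValueError("templates must share the voxel grid")
    rng = np.random.default_rng(seed)
    planted = simulate_network_series(subject, design, spec, rng)
    eta = planted["eta"]  # (T, 2)
    maps = np.stack([on_t.map, dmn_t.map])  # (2, x, y, z)
    pars = spec.network[subject["group"]]
    data = np.einsum("nxyz,tn->xyzt", maps, eta)
    data += rng.normal(0.0, pars.noise_sd, size=data.shape)
    mask = np.ones(on_t.map.shape, dtype=bool)
    run = BOLDRun(data=data, mask=mask, tr=design.tr)
    if return_planted:
        return run, planted
    return run
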