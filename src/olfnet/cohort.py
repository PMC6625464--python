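"""Synthetic cohort generation.

Draws CN / MCI / AD participant tables whose behavioral scores follow the
study cohort's group means and SDs (truncated normal within each
instrument's range), together with the group-graded network parameters used
by the BOLD simulator: task-response amplitudes (positive for the olfactory
network, negative for the suppressed default mode network), temporal
randomization weights, ROI volumes, QC metrics, and a planted DMN->ON
effective-connectivity (EC) value.

Within the MCI group, the planted EC is generated jointly with UPSIT so
that their correlation equals the requested target *inside the UPSIT > 20
subpopulation* - the subgroup in which the EC-UPSIT association is
analysed.  Calibrating on the full group would leave the post-filter
correlation attenuated by range restriction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .stats import classify_olfaction

GROUPS = ("CN", "MCI", "AD")

# (mean, sd) per group, from the study cohort's demographics table.
DEFAULT_SCORES: Dict[str, Dict[str, Tuple[float, float]]] = {
    "age":        {"CN": (70.40, 10.00), "MCI": (72.80, 9.40),  "AD": (73.70, 12.50)},
    "gds":        {"CN": (2.94, 2.79),   "MCI": (6.61, 3.75),   "AD": (11.67, 6.53)},
    "cvlt2":      {"CN": (63.97, 13.63), "MCI": (47.32, 13.35), "AD": (21.17, 13.22)},
    "mmse":       {"CN": (28.29, 1.64),  "MCI": (26.63, 1.67),  "AD": (19.25, 5.66)},
    "drs2":       {"CN": (141.16, 2.38), "MCI": (134.21, 7.79), "AD": (106.75, 28.15)},
    "drs_memory": {"CN": (24.26, 0.77),  "MCI": (21.21, 2.04),  "AD": (11.67, 6.23)},
    "upsit":      {"CN": (33.42, 4.19),  "MCI": (25.58, 7.69),  "AD": (11.58, 5.42)},
    # ROI volumes (mm^3) and QC metrics: group-graded, plausible magnitudes.
    "hippocampus_volume": {"CN": (7500, 800), "MCI": (6600, 900), "AD": (6100, 1000)},
    "poc_volume":         {"CN": (4200, 450), "MCI": (3700, 500), "AD": (3450, 550)},
    "task_accuracy":      {"CN": (95, 4),     "MCI": (90, 7),     "AD": (85, 10)},
    "max_motion":         {"CN": (1.0, 0.7),  "MCI": (1.2, 0.8),  "AD": (1.5, 1.0)},
}

# instrument / physical ranges used as truncation bounds
DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "age": (40, 100),
    "gds": (0, 30),
    "cvlt2": (0, 80),
    "mmse": (0, 30),
    "drs2": (0, 144),
    "drs_memory": (0, 25),
    "upsit": (0, 40),
    "hippocampus_volume": (3000, 11000),
    "poc_volume": (1500, 6500),
    "task_accuracy": (0, 100),
    "max_motion": (0, 6),
}

DEFAULT_P_MALE = {"CN": 16 / 31, "MCI": 9 / 19, "AD": 4 / 12}


@dataclass(frozen=True)
class GroupNetworkParams:
    """Per-group generative parameters for the two-network BOLD model."""

    on_amp_odor: float       # ON task amplitude, odor+visual trials
    on_amp_visual: float     # ON task amplitude, visual-only trials
    dmn_amp: float           # DMN amplitude (negative = suppression)
    noise_sd: float          # white voxel noise SD
    rand_w: float            # temporal randomization weight in [0, 1]
    ec_mean: float           # planted DMN->ON contemporaneous coefficient
    ec_sd: float

    def validate(self) -> None:
        vals = [self.on_amp_odor, self.on_amp_visual, self.dmn_amp,
                self.noise_sd, self.rand_w, self.ec_mean, self.ec_sd]
        if not all(np.isfinite(vals)):
            raise ValueError("non-finite network parameter")
        if self.noise_sd < 0 or self.ec_sd < 0:
            raise ValueError("SDs must be non-negative")
        if not 0 <= self.rand_w <= 1:
            raise ValueError("randomization weight must be in [0, 1]")


DEFAULT_NETWORK: Dict[str, GroupNetworkParams] = {
    # ON odor response graded CN > MCI ~ AD; visual response lowest in MCI so
    # the odor-vs-visual difference stays positive in CN and MCI but vanishes
    # in AD.  DMN amplitude is negative (task suppression), weakening with
    # disease.  CN time courses are fully task-locked (w=0); AD's are mostly
    # randomized.
    "CN":  GroupNetworkParams(1.00, 0.60, -0.80, 0.6, 0.00, 0.30, 0.08),
    "MCI": GroupNetworkParams(0.55, 0.10, -0.50, 0.6, 0.25, 0.25, 0.10),
    "AD":  GroupNetworkParams(0.50, 0.50, -0.40, 0.6, 0.60, 0.12, 0.10),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one simulated cohort."""

    sizes: Dict[str, int] = field(
        default_factory=lambda: {"CN": 31, "MCI": 19, "AD": 12}
    )
    scores: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SCORES.items()}
    )
    ranges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    p_male: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_P_MALE))
    network: Dict[str, GroupNetworkParams] = field(
        default_factory=lambda: dict(DEFAULT_NETWORK)
    )
    ec_upsit_r: float = 0.639   # EC-UPSIT coupling target within MCI, UPSIT > 20
    phi_self: float = 0.3       # lag-1 self-coupling of each network series
    zeta_sd: float = 0.15       # innovation SD of the network series
    seed: Optional[int] = None

    def validate(self) -> None:
        for g, n in self.sizes.items():
            if g not in GROUPS or n < 0:
                raise ValueError(f"bad group size {g}={n}")
        for score, per_group in self.scores.items():
            for g, (m, s) in per_group.items():
                if s < 0:
                    raise ValueError(f"negative SD for {score}/{g}")
            if score not in self.ranges:
                raise ValueError(f"no range for score {score!r}")
        for g, p in self.network.items():
            p.validate()
        if not -1 <= self.ec_upsit_r <= 1:
            raise ValueError("ec_upsit_r must be in [-1, 1]")

    def with_sizes(self, cn: int, mci: int, ad: int) -> "CohortSpec":
        return replace(self, sizes={"CN": cn, "MCI": mci, "AD": ad})


def _trunc(mean, sd, lo, hi, size, rng):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def truncated_mean(mean, sd, lo, hi) -> float:
    """Expected value of the truncated-normal score distribution."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.mean(a, b, loc=mean, scale=sd))


def _mci_upsit_ec(n, spec: CohortSpec, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Jointly draw (UPSIT, planted EC) for the MCI group.

    EC is linear in UPSIT plus independent noise, with the slope chosen so
    that corr(EC, UPSIT) equals ``spec.ec_upsit_r`` within the UPSIT > 20
    subpopulation of the truncated score distribution.
    """
    m, s = spec.scores["upsit"]["MCI"]
    lo, hi = spec.ranges["upsit"]
    pars = spec.network["MCI"]
    upsit = _trunc(m, s, lo, hi, n, rng)
    rho = spec.ec_upsit_r
    if rho == 0 or s == 0:
        ec = rng.normal(pars.ec_mean, pars.ec_sd, size=n)
        return upsit, ec
    # moments of the analysed (UPSIT > 20) subpopulation
    lo_f = max(lo, 20.0)
    a, b = (lo_f - m) / s, (hi - m) / s
    mu_f = truncnorm.mean(a, b, loc=m, scale=s)
    sd_f = truncnorm.std(a, b, loc=m, scale=s)
    slope = rho * pars.ec_sd / sd_f
    noise_sd = pars.ec_sd * np.sqrt(1 - rho**2)
    ec = pars.ec_mean + slope * (upsit - mu_f) + rng.normal(0, noise_sd, size=n)
    return upsit, ec


def simulate_cohort(spec: CohortSpec, seed: Optional[int] = None) -> pd.DataFrame:
    """Draw one participant table; identical spec + seed give identical tables."""
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    frames = []
    for g in GROUPS:
        n = spec.sizes.get(g, 0)
        rows = {"group": [g] * n}
        for score in spec.scores:
            if g == "MCI" and score == "upsit":
                continue  # drawn jointly with EC below
            m, s = spec.scores[score][g]
            lo, hi = spec.ranges[score]
            rows[score] = _trunc(m, s, lo, hi, n, rng)
        if g == "MCI":
            upsit, ec = _mci_upsit_ec(n, spec, rng)
            rows["upsit"] = upsit
            rows["ec_planted"] = ec
        else:
            pars = spec.network[g]
            rows["ec_planted"] = rng.normal(pars.ec_mean, pars.ec_sd, size=n)
        rows["sex"] = np.where(rng.random(n) < spec.p_male[g], "M", "F")
        frames.append(pd.DataFrame(rows))
        if n == 0:
            continue
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "subject_id", [f"sub-{i + 1:03d}" for i in range(len(df))])
    df["olfactory_class"] = [classify_olfaction(u) for u in df["upsit"]]
    return df


def apply_inclusion_filter(subjects: pd.DataFrame):
    """Retain subjects with task accuracy >= 75% and maximum motion < 3 mm.

    Returns ``(retained, exclusion_log)``; the log lists one entry per
    excluded subject with the reason.  Missing QC values exclude the subject.
    """
    for col in ("task_accuracy", "max_motion"):
        if col not in subjects.columns:
            raise KeyError(f"missing QC column {col!r}")
    keep = np.ones(len(subjects), dtype=bool)
    log = []
    for i, row in enumerate(subjects.itertuples(index=False)):
        acc, mot = row.task_accuracy, row.max_motion
        sid = row.subject_id
        if pd.isna(acc) or pd.isna(mot):
            keep[i] = False
            log.append({"subject_id": sid, "reason": "missing QC"})
        elif acc < 75:
            keep[i] = False
            log.append({"subject_id": sid, "reason": f"accuracy {acc:.1f} < 75"})
        elif mot >= 3:
            keep[i] = False
            log.append({"subject_id": sid, "reason": f"motion {mot:.2f} >= 3 mm"})
    return subjects[keep].reset_index(drop=True), log
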