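"""Effective connectivity via the extended unified SEM (euSEM).

A two-node structural time-series model of the ON and DMN network time
courses.  For node i:

    eta_i(t) = sum_{j!=i} A_ij eta_j(t)            (contemporaneous)
             + sum_j     Phi_ij eta_j(t-1)          (lag-1, incl. self)
             + sum_k     Gamma_ik u_k(t)            (exogenous task input)
             + sum_{j!=i,k} T_ijk u_k(t) eta_j(t)   (bilinear modulation)
             + zeta_i(t)

estimated per equation by least squares over t = 2..T.  The group-level
structure is found by a forward search: at each step the absent candidate
path that is significant (p < alpha) in the largest fraction of subjects is
admitted, provided that fraction reaches the majority criterion; admitted
paths whose significance fraction drops below the majority on refit are
pruned.  The headline quantity is the contemporaneous DMN->ON coefficient,
residualized on age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bold import convolved_regressors
from .hrf import HRFEstimate
from .paradigm import ODOR_VISUAL, VISUAL_ONLY, ParadigmDesign

NODES = ("ON", "DMN")
INPUTS = (ODOR_VISUAL, VISUAL_ONLY)

DMN_TO_ON = "A:ON<-DMN"


def candidate_paths(
    nodes: Sequence[str] = NODES, inputs: Sequence[str] = INPUTS
) -> Tuple[str, ...]:
    """The full admissible candidate set, in canonical (sorted) order."""
    paths = []
    for i in nodes:
        for j in nodes:
            if i != j:
                paths.append(f"A:{i}<-{j}")
            paths.append(f"Phi:{i}<-{j}")
        for k in inputs:
            paths.append(f"Gamma:{i}<-{k}")
        for j in nodes:
            if i == j:
                continue
            for k in inputs:
                paths.append(f"T:{i}<-{j}*{k}")
    return tuple(sorted(paths))


def _parse(path: str):
    kind, rest = path.split(":", 1)
    target, src = rest.split("<-")
    if kind == "T":
        source, inp = src.split("*")
        return kind, target, source, inp
    return kind, target, src, None


@dataclass(frozen=True)
class ECStructure:
    """A set of admitted paths over the candidate grammar."""

    paths: Tuple[str, ...] = ()
    nodes: Tuple[str, ...] = NODES
    inputs: Tuple[str, ...] = INPUTS

    def __post_init__(self):
        allowed = set(candidate_paths(self.nodes, self.inputs))
        for p in self.paths:
            if p not in allowed:
                raise ValueError(f"inadmissible path {p!r}")
        object.__setattr__(self, "paths", tuple(sorted(set(self.paths))))

    def targeting(self, node: str) -> Tuple[str, ...]:
        return tuple(p for p in self.paths if _parse(p)[1] == node)

    def with_path(self, path: str) -> "ECStructure":
        return ECStructure(self.paths + (path,), self.nodes, self.inputs)

    def without_path(self, path: str) -> "ECStructure":
        return ECStructure(
            tuple(p for p in self.paths if p != path), self.nodes, self.inputs
        )

    def __contains__(self, path: str) -> bool:
        return path in self.paths


@dataclass
class ECFit:
    """Per-subject euSEM estimates: one row per admitted path."""

    table: pd.DataFrame           # path, coef, se, t, p
    residual_variance: Dict[str, float]
    n_used: int
    subject_id: Optional[str] = None

    def coef(self, path: str) -> float:
        row = self.table[self.table["path"] == path]
        if row.empty:
            raise LookupError(f"path {path!r} not in fit")
        return float(row["coef"].iloc[0])


@dataclass
class GroupECResult:
    structure: ECStructure
    fits: List[ECFit]
    search_log: List[dict] = field(default_factory=list)


def _node_regressors(
    eta: np.ndarray, u: np.ndarray, node: str, paths: Sequence[str],
    nodes: Sequence[str], inputs: Sequence[str],
):
    """Design columns for one node equation at t = 2..T."""
    ni = {n: i for i, n in enumerate(nodes)}
    ki = {k: i for i, k in enumerate(inputs)}
    cols = []
    for p in paths:
        kind, target, source, inp = _parse(p)
        assert target == node
        if kind == "A":
            cols.append(eta[1:, ni[source]])
        elif kind == "Phi":
            cols.append(eta[:-1, ni[source]])
        elif kind == "Gamma":
            cols.append(u[1:, ki[source]])
        else:  # bilinear
            cols.append(u[1:, ki[inp]] * eta[1:, ni[source]])
    y = eta[1:, ni[node]]
    X = np.column_stack([np.ones(y.size)] + cols) if cols else np.ones((y.size, 1))
    return X, y


def _fit_node(eta, u, node, paths, nodes, inputs, cond_threshold=1e8):
    X, y = _node_regressors(eta, u, node, paths, nodes, inputs)
    if X.shape[1] > 1 and np.linalg.cond(X) > cond_threshold:
        raise ValueError(f"collinear regressors in {node} equation")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = y.size - X.shape[1]
    sigma2 = float(resid @ resid / dof) if dof > 0 else np.nan
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)
    return beta, se, tvals, pvals, sigma2


def fit_subject(
    eta: np.ndarray,
    u: np.ndarray,
    structure: ECStructure,
    subject_id: Optional[str] = None,
) -> ECFit:
    """Estimate all admitted paths for one subject by per-equation OLS."""
    eta = np.asarray(eta, float)
    u = np.asarray(u, float)
    if eta.shape[0] != u.shape[0]:
        raise ValueError("eta and u must share the time axis")
    rows = []
    resid_var = {}
    for node in structure.nodes:
        paths = structure.targeting(node)
        beta, se, tvals, pvals, sigma2 = _fit_node(
            eta, u, node, paths, structure.nodes, structure.inputs
        )
        resid_var[node] = sigma2
        for i, p in enumerate(paths):
            rows.append(
                {"path": p, "coef": beta[i + 1], "se": se[i + 1],
                 "t": tvals[i + 1], "p": pvals[i + 1]}
            )
    table = pd.DataFrame(rows, columns=["path", "coef", "se", "t", "p"])
    return ECFit(
        table=table, residual_variance=resid_var,
        n_used=eta.shape[0] - 1, subject_id=subject_id,
    )


def fit_cohort(etas, us, structure, subject_ids=None) -> List[ECFit]:
    ids = subject_ids if subject_ids is not None else [None] * len(etas)
    return [fit_subject(e, u, structure, s) for e, u, s in zip(etas, us, ids)]


def _candidate_stats(etas, us, structure, candidate):
    """Per-subject (p, |t|) of ``candidate`` added alone to the structure."""
    _, target, _, _ = _parse(candidate)
    trial = structure.with_path(candidate)
    paths = trial.targeting(target)
    pos = paths.index(candidate)
    ps = np.empty(len(etas))
    ts = np.empty(len(etas))
    for s, (eta, u) in enumerate(zip(etas, us)):
        try:
            _, _, tvals, pvals, _ = _fit_node(
                eta, u, target, paths, trial.nodes, trial.inputs
            )
            ps[s] = pvals[pos + 1]
            ts[s] = abs(tvals[pos + 1])
        except ValueError:
            ps[s] = 1.0  # collinear addition never counts as significant
            ts[s] = 0.0
    return ps, ts


def _would_close_cycle(structure: ECStructure, candidate: str) -> bool:
    """True if adding a contemporaneous path creates a directed A cycle."""
    kind, target, source, _ = _parse(candidate)
    if kind != "A":
        return False
    edges = {(_parse(p)[1], _parse(p)[2]) for p in structure.paths
             if p.startswith("A:")}
    edges.add((target, source))
    # DFS over the contemporaneous graph (target <- source)
    graph: Dict[str, list] = {}
    for tgt, src in edges:
        graph.setdefault(src, []).append(tgt)

    def reaches(node, goal, seen):
        if node == goal:
            return True
        seen.add(node)
        return any(reaches(n, goal, seen) for n in graph.get(node, [])
                   if n not in seen)

    return any(reaches(tgt, src, set()) for tgt, src in edges)


def group_search(
    etas: Sequence[np.ndarray],
    us: Sequence[np.ndarray],
    candidates: Optional[Sequence[str]] = None,
    alpha: float = 0.01,
    majority: float = 0.75,
    subject_ids: Optional[Sequence[str]] = None,
    acyclic: bool = True,
    start_with_ar: bool = True,
) -> GroupECResult:
    """Group-level forward search for the shared causal structure.

    At each step, every absent candidate is tested by single-addition t
    test in every subject; the candidate significant (p < alpha) in the
    largest fraction of subjects is admitted if that fraction reaches
    ``majority``.  Ties in the fraction break toward the larger median |t|
    across subjects, then lexicographic path order.  With ``acyclic`` (the
    default) candidates that would close a directed cycle among the
    contemporaneous paths are inadmissible - the standard recursiveness
    condition that keeps the simultaneous equations identified.  After the
    search stops, admitted paths whose refit significance fraction falls
    below the majority are pruned.  An empty structure is a valid outcome.

    ``start_with_ar`` frees the lag-1 self-paths from the outset (the GIMME
    convention): testing contemporaneous directions without the
    autoregressive terms controlled makes the two directions nearly
    indistinguishable.  Unsupported self-paths are removed by the prune
    step like any other path.
    """
    if len(etas) < 2:
        raise ValueError("need at least 2 subjects")
    if not 0 < alpha < 1 or not 0 < majority <= 1:
        raise ValueError("alpha in (0,1) and majority in (0,1] required")
    if candidates is None:
        candidates = candidate_paths()
    candidates = tuple(sorted(candidates))
    structure = ECStructure()
    log: List[dict] = []
    if start_with_ar:
        for node in structure.nodes:
            ar = f"Phi:{node}<-{node}"
            if ar in candidates:
                structure = structure.with_path(ar)
                log.append({"action": "init", "path": ar,
                            "note": "autoregressive self-path freed at start"})
    while True:
        absent = [
            c for c in candidates
            if c not in structure
            and not (acyclic and _would_close_cycle(structure, c))
        ]
        if not absent:
            break
        scores = {}
        for c in absent:
            ps, ts = _candidate_stats(etas, us, structure, c)
            scores[c] = (float(np.mean(ps < alpha)), float(np.median(ts)))
        best = max(f for f, _ in scores.values())
        if best < majority:
            break
        tied = [c for c, (f, _) in scores.items() if f == best]
        chosen = min(tied, key=lambda c: (-scores[c][1], c))
        structure = structure.with_path(chosen)
        log.append({"action": "add", "path": chosen, "fraction": best,
                    "median_abs_t": scores[chosen][1]})
    # prune paths that lost significance in the joint refit
    while structure.paths:
        fits = fit_cohort(etas, us, structure)
        fracs = {
            p: float(np.mean([f.table.set_index("path").loc[p, "p"] < alpha
                              for f in fits]))
            for p in structure.paths
        }
        worst_frac = min(fracs.values())
        if worst_frac >= majority:
            break
        victim = min(p for p, f in fracs.items() if f == worst_frac)
        structure = structure.without_path(victim)
        log.append({"action": "prune", "path": victim, "fraction": worst_frac})
    fits = fit_cohort(etas, us, structure, subject_ids)
    return GroupECResult(structure=structure, fits=fits, search_log=log)


def extract_dmn_to_on(
    fits: Sequence[ECFit], structure: ECStructure, path: str = DMN_TO_ON
) -> np.ndarray:
    """Per-subject DMN->ON coefficients, in the order of ``fits``."""
    if path not in structure:
        raise LookupError(
            f"path {path!r} absent from the selected structure "
            f"{structure.paths}; check the search log"
        )
    return np.array([f.coef(path) for f in fits])


def age_correct(ec: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Residualize EC on age (intercept included); output mean is zero."""
    ec = np.asarray(ec, float)
    ages = np.asarray(ages, float)
    if ec.size != ages.size or ec.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(ages) == 0:
        warnings.warn("constant age vector; returning mean-centered EC")
        return ec - ec.mean()
    X = np.column_stack([np.ones(ec.size), ages])
    beta, *_ = np.linalg.lstsq(X, ec, rcond=None)
    return ec - X @ beta


def build_task_regressors(
    design: ParadigmDesign, hrf: Optional[HRFEstimate] = None
) -> np.ndarray:
    """Convolved task inputs u(t), one column per condition (odor, visual)."""
    kernel = hrf.values if hrf is not None else None
    return convolved_regressors(design, hrf=kernel)
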