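"""Group independent component analysis (gICA).

Two-level reduction and decomposition of temporally concatenated
multi-subject BOLD: per-subject temporal PCA, group PCA with whitening,
FastICA with random restarts, ICASSO-style agglomerative clustering of
restart components into stable group maps, template matching to pick the
olfactory and default-mode networks, and dual-regression back-reconstruction
of subject-specific time courses and maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .bold import BOLDRun
from .templates import DMN, ON, NetworkTemplate


@dataclass
class GICAConfig:
    n_subject_pcs: int = 40
    n_group_pcs: int = 50
    n_ics: int = 20
    n_restarts: int = 10
    fun: str = "logcosh"          # FastICA contrast nonlinearity
    tol: float = 1e-6
    max_iter: int = 1000
    linkage_method: str = "average"
    match_floor: float = 0.3      # minimum |r| for a template match
    seed: int = 0

    def validate(self) -> None:
        if self.n_ics > self.n_group_pcs:
            raise ValueError("n_ics must not exceed n_group_pcs")
        if self.n_restarts < 1:
            raise ValueError("need at least one restart")
        if not 0 < self.tol < 1:
            raise ValueError("tol must be in (0, 1)")


@dataclass
class Decomposition:
    """One FastICA restart: spatial maps and the orthonormal unmixing."""

    maps: np.ndarray        # (n_ics, voxels)
    unmixing: np.ndarray    # (n_ics, n_ics)
    converged: bool
    n_iter: int
    seed: int


@dataclass
class ComponentSet:
    """Clustered group components with stability indices."""

    maps: np.ndarray                 # (n_ics, voxels), rows L2-normalized
    stability: np.ndarray            # (n_ics,), in [0, 1]
    assignments: np.ndarray          # cluster label per restart-component
    mixing: Optional[np.ndarray] = None  # (subjects*time, n_ics)

    @property
    def n_ics(self) -> int:
        return self.maps.shape[0]


@dataclass
class NetworkPair:
    """ON/DMN selection out of a ComponentSet."""

    on_index: int
    dmn_index: int
    match_scores: Dict[str, float]
    matched: Dict[str, bool]
    maps: Dict[str, np.ndarray]      # sign-oriented, keyed ON / DMN
    signs: Dict[str, float] = field(default_factory=dict)
    timecourses: Optional[Dict[str, np.ndarray]] = None  # per network: (subjects, time)


# ---------------------------------------------------------------------------
# reduction
# ---------------------------------------------------------------------------

def _as_time_by_voxels(run) -> np.ndarray:
    if isinstance(run, BOLDRun):
        return run.voxel_matrix().T
    return np.asarray(run, dtype=float)


def center_and_reduce_subject(run, k: int, whiten: bool = False):
    """Voxelwise mean-centering plus temporal PCA to ``k`` components.

    Accepts a :class:`BOLDRun` or a (time x voxels) matrix.  Returns the
    reduced (k x voxels) matrix and a projection dict (temporal basis,
    singular values, voxel means) for back-reconstruction.
    """
    X = _as_time_by_voxels(run)
    t, v = X.shape
    if k > t:
        raise ValueError(f"k={k} exceeds {t} time points")
    means = X.mean(axis=0)
    Xc = X - means
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(t, v) * np.finfo(float).eps)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds data rank {rank}")
    reduced = s[:k, None] * Vt[:k]          # == U_k^T Xc
    if whiten:
        reduced = Vt[:k] * np.sqrt(v)
    projection = {"basis": U[:, :k], "singular_values": s[:k], "voxel_means": means,
                  "all_singular_values": s}
    return reduced, projection


def concat_and_group_reduce(reduced_subjects: Sequence[np.ndarray], K: int):
    """Concatenate reduced subjects and PCA-whiten to ``K`` group dimensions.

    All subjects must share the voxel grid.  The output Z (K x voxels) has
    identity spatial covariance: Z Z^T / voxels = I.
    """
    shapes = [r.shape[1] for r in reduced_subjects]
    if len(set(shapes)) > 1:
        bad = [i for i, s in enumerate(shapes) if s != shapes[0]]
        raise ValueError(f"mismatched voxel grids for subjects {bad}")
    G = np.vstack(reduced_subjects)
    n, v = G.shape
    if K > min(n, v):
        raise ValueError(f"K={K} exceeds concatenated dimension {min(n, v)}")
    C = G @ G.T / v
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[K - 1] <= 0:
        raise ValueError(f"K={K} exceeds rank of concatenated data")
    E, D = evecs[:, :K], evals[:K]
    Z = (E / np.sqrt(D)).T @ G
    projection = {"eigvecs": E, "eigvals": D, "all_eigvals": evals}
    return Z, projection


# ---------------------------------------------------------------------------
# ICA with restarts
# ---------------------------------------------------------------------------

def run_fastica(Z: np.ndarray, config: GICAConfig) -> List[Decomposition]:
    """FastICA (symmetric fixed point, logcosh contrast) once per restart.

    ``Z`` is the whitened group matrix (components ordered by variance);
    the top ``n_ics`` rows are decomposed.  Restarts that do not converge
    within ``max_iter`` are flagged, not dropped.
    """
    config.validate()
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite values in whitened input")
    X = Z[: config.n_ics].T  # (voxels, n_ics)
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_restarts)
    decomps = []
    for restart_seed in seeds:
        # n_components is implied by the column count of X (whiten=False)
        ica = FastICA(
            algorithm="parallel",
            whiten=False,
            fun="logcosh" if config.fun == "logcosh" else config.fun,
            tol=config.tol,
            max_iter=config.max_iter,
            random_state=int(restart_seed % (2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            sources = ica.fit_transform(X)  # (voxels, n_ics)
        decomps.append(
            Decomposition(
                maps=sources.T,
                unmixing=ica.components_,
                converged=ica.n_iter_ < config.max_iter,
                n_iter=int(ica.n_iter_),
                seed=int(restart_seed),
            )
        )
    return decomps


def _row_corr(M: np.ndarray) -> np.ndarray:
    Mc = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Mc, axis=1)
    norms[norms == 0] = 1.0
    Mn = Mc / norms[:, None]
    return np.clip(Mn @ Mn.T, -1.0, 1.0)


def cluster_restarts(
    decomps: Sequence[Decomposition],
    n_ics: Optional[int] = None,
    linkage_method: str = "average",
) -> ComponentSet:
    """Cluster restart components into stable group components.

    Agglomerative clustering (default average linkage) on the dissimilarity
    1 - |spatial correlation| over all converged restart-components, one
    cluster per final component.  The representative map is the sign-aligned
    cluster mean (L2-normalized); the stability index is the mean
    within-cluster |r| minus the mean between-cluster |r|, clipped to [0, 1].
    Components are ordered by decreasing stability.
    """
    if n_ics is None:
        n_ics = decomps[0].maps.shape[0]
    if len(decomps) < 2:
        raise ValueError("need at least 2 restarts for stability clustering")
    # Nonconvergent restarts are flagged upstream but still clustered: with a
    # large Gaussian noise subspace the fixed point never settles globally
    # even when the signal components have, and the stability index exposes
    # any restart-to-restart inconsistency.
    if sum(d.maps.shape[0] for d in decomps) < n_ics:
        raise ValueError("fewer pooled restart components than requested components")
    M = np.vstack([d.maps for d in decomps])
    corr = _row_corr(M)
    dissim = np.clip(1.0 - np.abs(corr), 0.0, None)
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    link = linkage(squareform(dissim, checks=False), method=linkage_method)
    labels = fcluster(link, t=n_ics, criterion="maxclust")
    if len(np.unique(labels)) != n_ics:
        raise ValueError(
            f"clustering produced {len(np.unique(labels))} clusters, "
            f"expected {n_ics}"
        )
    abs_corr = np.abs(corr)
    maps, stability = [], []
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        within = (
            abs_corr[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)].mean()
            if len(idx) > 1 else 1.0
        )
        rest = np.nonzero(labels != lab)[0]
        between = abs_corr[np.ix_(idx, rest)].mean() if rest.size else 0.0
        stability.append(np.clip(within - between, 0.0, 1.0))
        anchor = M[idx[0]]
        signs = np.sign(M[idx] @ anchor)
        signs[signs == 0] = 1.0
        centroid = (signs[:, None] * M[idx]).mean(axis=0)
        nrm = np.linalg.norm(centroid)
        maps.append(centroid / nrm if nrm > 0 else centroid)
    maps = np.asarray(maps)
    stability = np.asarray(stability)
    order = np.argsort(-stability, kind="stable")
    relabel = {int(lab): int(np.where(order == i)[0][0])
               for i, lab in enumerate(np.unique(labels))}
    return ComponentSet(
        maps=maps[order],
        stability=stability[order],
        assignments=np.array([relabel[int(l)] for l in labels]),
    )


# ---------------------------------------------------------------------------
# network selection and back-reconstruction
# ---------------------------------------------------------------------------

def select_networks(
    components: ComponentSet,
    templates: Tuple[NetworkTemplate, NetworkTemplate],
    mask: np.ndarray,
    floor: float = 0.3,
) -> NetworkPair:
    """Pick the ON and DMN components by spatial template correlation.

    Maps are sign-oriented so the template correlation is positive.  Ties in
    |r| break toward the higher stability index.  A best match below
    ``floor`` raises a warning and is marked unmatched.
    """
    on_t, dmn_t = templates
    if on_t.map.shape != dmn_t.map.shape or on_t.map.shape != mask.shape:
        raise ValueError("templates and mask must share the grid")
    tvecs = {ON: on_t.map[mask].astype(float), DMN: dmn_t.map[mask].astype(float)}
    n = components.n_ics
    scores = {}
    for label, tv in tvecs.items():
        tc = tv - tv.mean()
        tn = np.linalg.norm(tc)
        rs = np.empty(n)
        for i in range(n):
            mc = components.maps[i] - components.maps[i].mean()
            denom = np.linalg.norm(mc) * tn
            rs[i] = (mc @ tc) / denom if denom > 0 else 0.0
        scores[label] = rs

    taken: Dict[str, int] = {}
    # assign greedily by best |r|, keeping the two selections distinct
    for label in sorted(tvecs, key=lambda l: -np.abs(scores[l]).max()):
        rs = np.abs(scores[label]).copy()
        for other_idx in taken.values():
            rs[other_idx] = -np.inf
        best = rs.max()
        cand = np.nonzero(rs == best)[0]
        idx = int(cand[np.argmax(components.stability[cand])])
        taken[label] = idx

    matched, oriented, match_scores, signs = {}, {}, {}, {}
    for label, idx in taken.items():
        r = scores[label][idx]
        sign = 1.0 if r >= 0 else -1.0
        oriented[label] = sign * components.maps[idx]
        match_scores[label] = float(abs(r))
        signs[label] = sign
        ok = abs(r) >= floor
        matched[label] = bool(ok)
        if not ok:
            warnings.warn(
                f"best {label} template match |r|={abs(r):.3f} below floor "
                f"{floor}; component marked unmatched"
            )
    return NetworkPair(
        on_index=taken[ON],
        dmn_index=taken[DMN],
        match_scores=match_scores,
        matched=matched,
        maps=oriented,
        signs=signs,
    )


def back_reconstruct(components: ComponentSet, run: BOLDRun,
                     maps: Optional[np.ndarray] = None):
    """Dual regression of one run on the group maps.

    Stage 1 regresses the (voxel-centered) run on the group spatial maps to
    get subject time courses; stage 2 regresses the run on those time
    courses to get subject maps.  Time courses are returned unit-variance
    with the scale stored.
    """
    A = (components.maps if maps is None else maps).T  # (voxels, n)
    M = run.voxel_matrix().astype(float)               # (voxels, time)
    M = M - M.mean(axis=1, keepdims=True)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient stage-1 design (collinear group maps)")
    tc, *_ = np.linalg.lstsq(A, M, rcond=None)         # (n, time)
    smaps, *_ = np.linalg.lstsq(tc.T, M.T, rcond=None)  # (n, voxels)
    scale = tc.std(axis=1, ddof=0)
    safe = np.where(scale > 0, scale, 1.0)
    return {"timecourses": (tc / safe[:, None]).T,      # (time, n), unit variance
            "subject_maps": smaps,
            "scale": scale}


def fit_gica(
    runs: Sequence[BOLDRun],
    config: GICAConfig,
    templates: Optional[Tuple[NetworkTemplate, NetworkTemplate]] = None,
):
    """Full gICA stage over a list of runs.

    Returns ``(components, pair, subject_tcs)`` where ``subject_tcs`` is a
    list of (time x n_ics) unit-variance time-course arrays, and ``pair``
    is the template-matched ON/DMN selection (None when no templates are
    given).  Group mixing time courses are stored on the ComponentSet.
    """
    config.validate()
    n_t = min(r.n_volumes for r in runs)
    k = min(config.n_subject_pcs, n_t)
    reduced = [center_and_reduce_subject(r, k)[0] for r in runs]
    K = min(config.n_group_pcs, len(runs) * k)
    Z, _ = concat_and_group_reduce(reduced, K)
    decomps = run_fastica(Z, config)
    components = cluster_restarts(decomps, config.n_ics, config.linkage_method)
    recons = [back_reconstruct(components, r) for r in runs]
    components.mixing = np.vstack([r["timecourses"] for r in recons])
    pair = None
    if templates is not None:
        pair = select_networks(components, templates, runs[0].mask, config.match_floor)
        on_tc = np.asarray(
            [r["timecourses"][:, pair.on_index] * pair.signs[ON] for r in recons]
        )
        dmn_tc = np.asarray(
            [r["timecourses"][:, pair.dmn_index] * pair.signs[DMN] for r in recons]
        )
        pair.timecourses = {ON: on_tc, DMN: dmn_tc}
    return components, pair, [r["timecourses"] for r in recons]
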