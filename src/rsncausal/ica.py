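"""Temporal-concatenation group spatial ICA.

Pipeline: estimate the latent dimensionality from the covariance
eigenspectrum (minimum description length), concatenate subjects along
time and reduce with a single-stage PCA, unmix with symmetric fixed-point
FastICA in the spatial domain, then back-reconstruct per-subject component
maps and time courses by dual regression.  Component maps are z-scored so
voxel intensities read as standardized contribution strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .synthetic import SubjectDataset


@dataclass
class ReductionOperators:
    """PCA reduction bookkeeping sufficient to reconstruct subject blocks."""

    group_basis: np.ndarray  # (n_voxels, k) orthonormal spatial basis
    column_means: np.ndarray  # (n_voxels,) voxel means over concatenated time
    per_subject_rows: list[tuple[int, int]]  # [start, stop) row ranges
    eigenvalues_retained: np.ndarray
    eigenvalues_discarded: np.ndarray

    @property
    def k(self) -> int:
        return self.group_basis.shape[1]

    @property
    def explained_variance_fraction(self) -> float:
        tot = self.eigenvalues_retained.sum() + self.eigenvalues_discarded.sum()
        return float(self.eigenvalues_retained.sum() / tot) if tot > 0 else 1.0


@dataclass
class ICAResult:
    """Group decomposition and (after back-reconstruction) subject fields."""

    n_components: int
    group_maps: np.ndarray  # (k, n_voxels), z-scored
    group_timecourses: np.ndarray  # (concat_time, k)
    unmixing: np.ndarray  # (k, k): reduced @ unmixing -> time courses
    convergence: dict = field(default_factory=dict)
    subject_maps: list[np.ndarray] | None = None  # each (k, n_voxels), z-scored
    subject_timecourses: list[np.ndarray] | None = None  # each (time, k)


def estimate_ndim_mdl(data: np.ndarray) -> int:
    """Estimate the number of latent components by the Wax-Kailath MDL rule.

    The smaller matrix dimension is treated as the variable dimension p and
    the larger as the sample count N (for time x voxel data with more voxels
    than time points this is the spatial-ICA orientation: time points are
    the mixed variables, voxels the samples).  Returns the k in [0, p-1]
    minimizing

        MDL(k) = -N (p-k) ln(gm_k / am_k) + k (2p - k) ln(N) / 2

    where gm_k and am_k are the geometric and arithmetic means of the
    smallest p-k covariance eigenvalues.  Candidates are restricted to the
    numerical rank of the covariance.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("data must be 2-D with at least 2 rows and 2 columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("data contains non-finite values")
    if X.shape[0] <= X.shape[1]:
        p_side = X - X.mean(axis=0)  # variables along rows after transpose
        gram = p_side @ p_side.T
        N = X.shape[1]
    else:
        Xc = X - X.mean(axis=0)
        gram = Xc.T @ Xc
        N = X.shape[0]
    ev = np.linalg.eigvalsh(gram / N)[::-1]
    ev = np.clip(ev, 0.0, None)
    rank = int(np.sum(ev > ev[0] * 1e-12)) if ev[0] > 0 else 0
    ev = ev[:rank]
    p = len(ev)
    if p < 2:
        return 0
    scores = mdl_scores(ev, N)
    return int(np.argmin(scores))


def mdl_scores(eigenvalues: np.ndarray, n_samples: int) -> np.ndarray:
    """MDL score for each candidate dimensionality k = 0..p-1."""
    ev = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    p = len(ev)
    scores = np.empty(p)
    log_ev = np.log(ev)
    for k in range(p):
        tail = ev[k:]
        am = tail.mean()
        gm_log = log_ev[k:].mean()
        ll = -n_samples * (p - k) * (gm_log - np.log(am))
        pen = 0.5 * k * (2 * p - k) * np.log(n_samples)
        scores[k] = ll + pen
    return scores


def concat_and_reduce(
    subjects: list[SubjectDataset] | list[np.ndarray],
    k: int,
    normalize_variance: bool = False,
) -> tuple[np.ndarray, ReductionOperators]:
    """Stack subjects along time and reduce to k spatial principal directions.

    Voxel columns are centered across the concatenated time dimension
    (optionally variance-normalized); the top-k right singular vectors form
    the spatial basis.  Returns the (concat_time, k) score matrix and the
    operators needed for back-reconstruction.
    """
    mats = [s.data if isinstance(s, SubjectDataset) else np.asarray(s, float) for s in subjects]
    V = mats[0].shape[1]
    if any(m.shape[1] != V for m in mats):
        raise ValueError("all subjects must share the voxel grid")
    rows = []
    start = 0
    for m in mats:
        rows.append((start, start + m.shape[0]))
        start += m.shape[0]
    X = np.vstack(mats)
    col_means = X.mean(axis=0)
    Xc = X - col_means
    if normalize_variance:
        sd = Xc.std(axis=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    if k > V:
        raise ValueError("k cannot exceed the voxel count")

    T = Xc.shape[0]
    if T <= V:
        gram = Xc @ Xc.T
        evals, evecs = linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
    else:
        gram = Xc.T @ Xc
        evals, evecs = linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    rank = int(np.sum(evals > (evals[0] * 1e-10 if evals[0] > 0 else 0)))
    if k > rank:
        raise ValueError(f"k={k} exceeds numerical rank {rank}")
    sing = np.sqrt(evals[:k])
    if T <= V:
        U = evecs[:, :k]
        basis = (Xc.T @ U) / sing  # (V, k) orthonormal
        reduced = U * sing
    else:
        basis = evecs[:, :k]
        reduced = Xc @ basis
    ops = ReductionOperators(
        group_basis=basis,
        column_means=col_means,
        per_subject_rows=rows,
        eigenvalues_retained=evals[:k] / max(T - 1, 1),
        eigenvalues_discarded=evals[k:rank] / max(T - 1, 1),
    )
    return reduced, ops


def _sym_orth(W: np.ndarray) -> np.ndarray:
    """Symmetric decorrelation W <- (W W^T)^(-1/2) W."""
    evals, evecs = linalg.eigh(W @ W.T)
    evals = np.clip(evals, 1e-12, None)
    return (evecs * (1.0 / np.sqrt(evals))) @ evecs.T @ W


def fastica_decompose(
    reduced: np.ndarray,
    ops: ReductionOperators,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ICAResult:
    """Symmetric fixed-point FastICA (tanh contrast) on the spatial maps.

    The reduced data's spatial basis rows are centered over voxels and
    whitened; the fixed-point update

        W <- E[g(WZ) Z^T] - diag(E[g'(WZ)]) W,   g = tanh

    with symmetric decorrelation runs until the maximum rowwise
    |1 - |diag(W_new W_old^T)|| drops below ``tol``.  Sources are the
    spatial maps (z-scored); group time courses are obtained by regressing
    the reduced data onto the maps.  Non-convergence sets a flag instead of
    raising.  Deterministic for a fixed seed.
    """
    reduced = np.asarray(reduced, dtype=float)
    k = reduced.shape[1]
    B = ops.group_basis  # (V, k)
    D = B.T.copy()  # (k, V): spatial representation, voxels as samples
    Vn = D.shape[1]
    row_means = D.mean(axis=1, keepdims=True)
    D = D - row_means
    cov = D @ D.T / Vn
    evals, evecs = linalg.eigh(cov)
    evals = np.clip(evals, 1e-15, None)
    K = (evecs * (1.0 / np.sqrt(evals))) @ evecs.T  # whitening (k, k)
    Z = K @ D

    rng = np.random.default_rng(seed)
    W = _sym_orth(rng.standard_normal((k, k)))
    converged = False
    delta = np.inf
    for it in range(1, max_iter + 1):
        WZ = W @ Z
        G = np.tanh(WZ)
        g_prime = 1.0 - G**2
        W_new = (G @ Z.T) / Vn - np.diag(g_prime.mean(axis=1)) @ W
        W_new = _sym_orth(W_new)
        delta = float(np.max(np.abs(1.0 - np.abs(np.diag(W_new @ W.T)))))
        W = W_new
        if delta < tol:
            converged = True
            break
    S = W @ Z  # (k, V) independent spatial maps, unit variance over voxels
    # resolve the sign ambiguity: orient each map so its skewness is
    # positive (network maps are sparse with heavy positive tails)
    Sc = S - S.mean(axis=1, keepdims=True)
    skew = (Sc**3).mean(axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    S = S * flip[:, None]
    W = W * flip[:, None]
    maps = zscore_maps(S)
    # time courses: regress reduced-space data onto the maps
    # X_c ~ TC @ maps_raw, with X_c = reduced @ B^T
    A = maps @ maps.T  # (k, k)
    G_un = linalg.solve(A, maps @ B).T  # (k, k): reduced @ G_un = TC
    timecourses = reduced @ G_un
    return ICAResult(
        n_components=k,
        group_maps=maps,
        group_timecourses=timecourses,
        unmixing=G_un,
        convergence={"n_iter": it, "delta": delta, "converged": converged},
    )


def back_reconstruct(
    ica: ICAResult,
    ops: ReductionOperators,
    subjects: list[SubjectDataset] | list[np.ndarray],
) -> ICAResult:
    """Fill per-subject maps and time courses by GICA back-reconstruction.

    Subject time courses: the subject's block of the reduced data projected
    through the group unmixing.  Subject maps: the subject's centered data
    regressed onto those time courses (dual-regression form), then z-scored.
    """
    maps_out: list[np.ndarray] = []
    tcs_out: list[np.ndarray] = []
    for idx, s in enumerate(subjects):
        X = s.data if isinstance(s, SubjectDataset) else np.asarray(s, float)
        sid = s.subject_id if isinstance(s, SubjectDataset) else f"subject{idx}"
        Xc = X - ops.column_means
        reduced_s = Xc @ ops.group_basis
        tc = reduced_s @ ica.unmixing  # (time, k)
        gram = tc.T @ tc
        cond = np.linalg.cond(gram)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"singular time-course cross-product for {sid}"
            )
        m = linalg.solve(gram, tc.T @ Xc)  # (k, V)
        maps_out.append(zscore_maps(m))
        tcs_out.append(tc)
    ica.subject_maps = maps_out
    ica.subject_timecourses = tcs_out
    return ica


def zscore_maps(maps: np.ndarray) -> np.ndarray:
    """Standardize each component map to zero mean, unit SD across voxels."""
    maps = np.asarray(maps, dtype=float)
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = np.where(sd.ravel() == 0)[0]
        raise ValueError(f"zero-variance component map(s): {bad.tolist()}")
    return (maps - mu) / sd
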