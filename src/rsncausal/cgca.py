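"""Conditional Granger causality between network time courses.

For networks X (source), Y (target) and the conditioning set Z (the
remaining networks), the conditional influence term is

    F_{X -> Y | Z} = ln( var(e_restricted) / var(e_full) )

where the restricted model is a vector autoregression over {Y} u Z and the
full model adds X's past, both of the same order and fit by ordinary least
squares on the identical effective sample.  Because the restricted target
equation is nested in the full one, F >= 0 always; conditioning on Z
removes influence mediated through the other networks, which is what
distinguishes conditional from pairwise Granger causality.

Model order is chosen by the Schwarz criterion; the observed F values are
normalized against a circular-shift surrogate null that preserves each
series' autocorrelation while destroying cross-coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .utils import fdr_bh


@dataclass
class VARFit:
    """Least-squares vector autoregression fit."""

    order: int
    coefficients: np.ndarray  # (order, d, d): coefficients[l][i, j] = lag l+1, j -> i
    residual_cov: np.ndarray  # (d, d)
    n_effective: int
    sc: float  # Schwarz criterion value


@dataclass
class GCMatrix:
    """All 12 ordered-pair conditional influences for one subject."""

    names: tuple[str, ...]
    F: np.ndarray  # (d, d), F[i, j] = influence j -> i; diagonal NaN
    z: np.ndarray | None  # surrogate-normalized scores, same layout
    order: int

    def to_frame(self, subject_id: str | None = None) -> pd.DataFrame:
        rows = []
        d = len(self.names)
        for i in range(d):
            for j in range(d):
                if i == j:
                    continue
                row = {
                    "source": self.names[j],
                    "target": self.names[i],
                    "F": self.F[i, j],
                    "order": self.order,
                }
                if self.z is not None:
                    row["z"] = self.z[i, j]
                if subject_id is not None:
                    row = {"subject_id": subject_id, **row}
                rows.append(row)
        return pd.DataFrame(rows)


def _lag_design(ts: np.ndarray, order: int, presample: int) -> tuple[np.ndarray, np.ndarray]:
    """Response rows t = presample..T-1 and stacked lag regressors."""
    T, d = ts.shape
    Y = ts[presample:]
    X = np.hstack([ts[presample - lag: T - lag] for lag in range(1, order + 1)])
    return Y, X


def fit_var(ts: np.ndarray, order: int, presample: int | None = None) -> VARFit:
    """Ordinary least squares VAR(order) fit on centered columns.

    ``presample`` rows (default: the order) are reserved so fits of
    different orders can share an identical effective sample.  The residual
    covariance uses the effective sample size as divisor, and

        SC = ln det(residual_cov) + ln(n_eff)/n_eff * order * d^2.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("ts must be (time, d)")
    T, d = ts.shape
    if order < 1:
        raise ValueError("order must be >= 1")
    if presample is None:
        presample = order
    if presample < order:
        raise ValueError("presample must be >= order")
    if T - presample <= d * order + 1:
        raise ValueError("series too short for the requested order")
    Y, X = _lag_design(ts, order, presample)
    if np.linalg.cond(X) > 1e10:
        raise np.linalg.LinAlgError(
            "ill-conditioned lag design; use a shorter order or longer series"
        )
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    n_eff = Y.shape[0]
    resid_cov = resid.T @ resid / n_eff
    sign, logdet = np.linalg.slogdet(resid_cov)
    if sign <= 0:
        logdet = -np.inf
    sc = logdet + (np.log(n_eff) / n_eff) * order * d * d
    # coef rows are [lag1 vars..., lag2 vars...] mapping to all d targets
    A = np.stack(
        [coef[lag * d: (lag + 1) * d].T for lag in range(order)], axis=0
    )
    return VARFit(order=order, coefficients=A, residual_cov=resid_cov,
                  n_effective=n_eff, sc=sc)


def select_order_sc(ts: np.ndarray, max_order: int = 5) -> int:
    """Schwarz-criterion model order, orders 1..max_order on a common sample.

    The first ``max_order`` points are reserved as presample for every fit
    so the criterion values are comparable; ties break to the smaller
    order.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    scs = []
    for m in range(1, max_order + 1):
        scs.append(fit_var(ts, m, presample=max_order).sc)
    scs = np.asarray(scs)
    return int(np.argmin(scs)) + 1  # argmin returns the first (smallest) on ties


def _target_residual_variance(
    ts: np.ndarray, cols: list[int], target: int, order: int, presample: int
) -> float:
    """Residual variance of the target equation in a VAR over ``cols``."""
    sub = ts[:, cols]
    Y, X = _lag_design(sub, order, presample)
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    t_pos = cols.index(target)
    return float(resid[:, t_pos] @ resid[:, t_pos] / Y.shape[0])


def conditional_gc(
    ts: np.ndarray,
    source: int | list[int],
    target: int,
    cond: list[int] | tuple[int, ...] = (),
    order: int = 1,
) -> float:
    """Conditional influence F_{source -> target | cond}.

    Both the restricted VAR over {target} u cond and the full VAR adding
    the source are fit on the identical effective sample (presample =
    order), so the nested residual variances guarantee F >= 0; tiny
    negative round-off is clamped to zero.
    """
    src = [source] if np.isscalar(source) else list(source)
    cnd = list(cond)
    sets = src + [target] + cnd
    if len(set(sets)) != len(sets):
        raise ValueError("source, target and cond must be disjoint")
    ts = np.asarray(ts, dtype=float)
    restricted_cols = [target] + cnd
    full_cols = [target] + cnd + src
    var_r = _target_residual_variance(ts, restricted_cols, target, order, order)
    var_f = _target_residual_variance(ts, full_cols, target, order, order)
    F = np.log(var_r / var_f)
    if F < -1e-12:
        raise AssertionError(f"negative influence {F}: nested-model invariant broken")
    return max(F, 0.0)


def gc_all_pairs(
    network_ts: np.ndarray,
    order: int = 1,
    names: tuple[str, ...] = ("DAN", "VAN", "AfN", "VN"),
) -> GCMatrix:
    """All ordered-pair conditional influences among the network time courses.

    Each pair (source, target) is conditioned on the remaining networks.
    """
    ts = np.asarray(network_ts, dtype=float)
    d = ts.shape[1]
    if d != len(names):
        raise ValueError("names must match the number of columns")
    ts = ts - ts.mean(axis=0)
    F = np.full((d, d), np.nan)
    for i in range(d):  # target
        for j in range(d):  # source
            if i == j:
                continue
            cond = [c for c in range(d) if c not in (i, j)]
            F[i, j] = conditional_gc(ts, j, i, cond, order)
    return GCMatrix(names=tuple(names), F=F, z=None, order=order)


def gc_normalize(
    F_obs: float,
    ts: np.ndarray,
    source: int,
    target: int,
    cond: list[int] | tuple[int, ...],
    order: int = 1,
    n_surrogates: int = 99,
    seed: int = 0,
) -> float:
    """Normalize an influence value against a circular-shift surrogate null.

    The source series is circularly shifted by uniform random offsets of at
    least order+1 samples, F recomputed each time, and the observed value
    standardized: z = (F - mean(F_null)) / sd(F_null).  Deterministic for a
    fixed seed.
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates")
    ts = np.asarray(ts, dtype=float)
    T = ts.shape[0]
    lo, hi = order + 1, T - order - 1
    if hi <= lo:
        raise ValueError("series too short for circular-shift surrogates")
    rng = np.random.default_rng(seed)
    null = np.empty(n_surrogates)
    for s in range(n_surrogates):
        shift = int(rng.integers(lo, hi + 1))
        sur = ts.copy()
        sur[:, source] = np.roll(ts[:, source], shift)
        null[s] = conditional_gc(sur, source, target, cond, order)
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate surrogate null (zero variance)")
    return float((F_obs - null.mean()) / sd)


def gc_all_pairs_normalized(
    network_ts: np.ndarray,
    order: int = 1,
    n_surrogates: int = 99,
    seed: int = 0,
    names: tuple[str, ...] = ("DAN", "VAN", "AfN", "VN"),
) -> GCMatrix:
    """All-pairs conditional influences plus their surrogate-normalized scores."""
    ts = np.asarray(network_ts, dtype=float)
    ts = ts - ts.mean(axis=0)
    gm = gc_all_pairs(ts, order, names)
    d = ts.shape[1]
    z = np.full((d, d), np.nan)
    for i in range(d):
        for j in range(d):
            if i == j:
                continue
            cond = [c for c in range(d) if c not in (i, j)]
            z[i, j] = gc_normalize(
                gm.F[i, j], ts, j, i, cond, order,
                n_surrogates=n_surrogates,
                seed=(seed * 10007 + i * d + j) % (2**31 - 1),
            )
    gm.z = z
    return gm


def group_gc_test(subject_z: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Edgewise one-sample t-tests on normalized scores with BH-FDR.

    ``subject_z`` has columns subject_id, source, target, z.  Returns one
    row per directed edge with the group mean z, t, p, adjusted p and the
    significance flag.
    """
    rows = []
    for (src, tgt), grp in subject_z.groupby(["source", "target"], sort=True):
        zvals = grp["z"].to_numpy(dtype=float)
        if len(zvals) < 2:
            raise ValueError("need at least 2 subjects per edge")
        if np.allclose(zvals.std(ddof=1), 0):
            t_stat, p = 0.0, 1.0
        else:
            res = stats.ttest_1samp(zvals, 0.0)
            t_stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"source": src, "target": tgt, "mean_z": zvals.mean(),
                     "t": t_stat, "p": p, "n": len(zvals)})
    out = pd.DataFrame(rows)
    adj, rej = fdr_bh(out["p"].to_numpy(), q)
    out["p_fdr"] = adj
    out["significant"] = rej
    return out
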