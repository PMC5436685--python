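"""Behavioral correlation screen and LOOCV support-vector prediction.

Normalized effective-connectivity scores are correlated with the six
behavioral scales (Pearson, BH-FDR within group across the edge x scale
family), and a linear-kernel epsilon-SVR with leave-one-out cross
validation predicts each subject's loneliness score from the connectivity
of one edge at a time.  Features are standardized with training-fold
statistics only, so the held-out subject never leaks into the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .utils import fdr_bh

log = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    """Held-out predictions and their summary metrics."""

    predictions: np.ndarray  # per-subject held-out prediction
    actual: np.ndarray
    rmsep: float
    r_pred_actual: float
    p: float
    n_models: int
    dropped_features: list = field(default_factory=list)

    def recompute_rmsep(self) -> float:
        return float(np.sqrt(np.mean((self.predictions - self.actual) ** 2)))


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-based p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("inputs must have nonzero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def svr_loocv_predict(
    features: np.ndarray,
    scores: np.ndarray,
    C: float = 1.0,
    epsilon: float = 0.1,
) -> PredictionResult:
    """Leave-one-out linear-kernel epsilon-SVR prediction.

    For each subject, the SVR is trained on the remaining n-1 subjects
    (features standardized using training-fold mean/SD only) and predicts
    the held-out subject.  Returns all n predictions, the root-mean-square
    error of prediction, and the Pearson correlation between predicted and
    actual scores.  Constant features within a training fold are dropped
    for that fold and logged.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and np.asarray(scores).size != 1:
        X = X.T
    y = np.asarray(scores, dtype=float).ravel()
    n, f = X.shape
    if n != len(y):
        raise ValueError("features and scores must have one row per subject")
    if n < 3:
        raise ValueError("need at least 3 subjects")
    preds = np.empty(n)
    dropped: list[tuple[int, list[int]]] = []
    for i in range(n):
        train = np.delete(np.arange(n), i)
        Xt, yt = X[train], y[train]
        mu = Xt.mean(axis=0)
        sd = Xt.std(axis=0)
        keep = sd > 0
        if not keep.all():
            dropped.append((i, list(np.where(~keep)[0])))
            log.warning("fold %d: dropped constant feature(s) %s", i, np.where(~keep)[0])
        if not keep.any():
            preds[i] = yt.mean()
            continue
        Xt_s = (Xt[:, keep] - mu[keep]) / sd[keep]
        Xi_s = (X[i, keep] - mu[keep]) / sd[keep]
        model = SVR(kernel="linear", C=C, epsilon=epsilon, tol=1e-6)
        model.fit(Xt_s, yt)
        preds[i] = model.predict(Xi_s.reshape(1, -1))[0]
    rmsep = float(np.sqrt(np.mean((preds - y) ** 2)))
    r, p = pearson_corr(preds, y)
    return PredictionResult(
        predictions=preds, actual=y, rmsep=rmsep, r_pred_actual=r, p=p,
        n_models=n, dropped_features=dropped,
    )


def correlation_screen(
    edge_z: pd.DataFrame,
    behavioral: pd.DataFrame,
    edges: list[tuple[str, str]] | None = None,
    scales: tuple[str, ...] = ("Loneliness", "STAI", "SDS", "IRI-C", "Trust", "SSRS"),
    q: float = 0.05,
) -> pd.DataFrame:
    """Edge x scale Pearson correlation screen per group, BH-FDR within group.

    ``edge_z`` has columns subject_id, source, target, z; ``behavioral``
    has subject_id, group and one column per scale.  Subjects must align
    between the two tables.  FDR is controlled within each (group, scale)
    family across the tested edges: each scale is screened as its own
    hypothesis family, mirroring a primary loneliness analysis followed by
    per-scale specificity checks.
    """
    missing = set(edge_z["subject_id"]) - set(behavioral["subject_id"])
    if missing:
        raise ValueError(f"subjects in edge table missing from behavioral: {sorted(missing)}")
    merged = edge_z.merge(behavioral, on="subject_id", how="inner")
    if edges is not None:
        key = merged[["source", "target"]].apply(tuple, axis=1)
        merged = merged[key.isin(set(edges))]
    rows = []
    for group, gdf in merged.groupby("group", sort=True):
        for (src, tgt), edf in gdf.groupby(["source", "target"], sort=True):
            edf = edf.sort_values("subject_id")
            for scale in scales:
                r, p = pearson_corr(edf["z"].to_numpy(), edf[scale].to_numpy())
                rows.append({"group": group, "source": src, "target": tgt,
                             "scale": scale, "r": r, "p": p, "n": len(edf)})
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    out["significant"] = False
    for (group, scale), idx in out.groupby(["group", "scale"]).groups.items():
        adj, rej = fdr_bh(out.loc[idx, "p"].to_numpy(), q)
        out.loc[idx, "p_fdr"] = adj
        out.loc[idx, "significant"] = rej
    return out
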