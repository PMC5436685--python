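"""Resting-state network identification and group spatial statistics.

Components from the group decomposition are labeled as networks by a
template goodness-of-fit score (mean z inside the template mask minus mean
z outside); Pearson spatial correlation is computed alongside as a
cross-check.  Group-level maps are assessed with voxelwise one- and
two-sample t-tests under Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import TemplateSet
from .utils import fdr_bh

log = logging.getLogger(__name__)


@dataclass
class RSNAssignment:
    """Network -> component assignment with the full score table."""

    chosen: dict[str, int]  # network name -> component index
    scores: dict[str, float]  # network name -> winning score
    runner_up: dict[str, float]  # network name -> next-best score
    table: pd.DataFrame  # columns: network, component, score, spatial_r


@dataclass
class StatMapResult:
    """Voxelwise t/p maps with the FDR-significant mask."""

    t_map: np.ndarray
    p_map: np.ndarray
    sig_mask: np.ndarray  # boolean
    analysis_mask: np.ndarray  # voxels the test was run on
    n_flagged_zero_variance: int = 0


@dataclass
class GroupStatMaps:
    """Per-network one-sample maps per group, combined masks, and two-sample maps."""

    one_sample: dict[str, dict[str, StatMapResult]] = field(default_factory=dict)
    combined_mask: dict[str, np.ndarray] = field(default_factory=dict)
    two_sample: dict[str, StatMapResult] = field(default_factory=dict)


def template_match_score(z_map: np.ndarray, template_mask: np.ndarray) -> float:
    """Mean z inside the template minus mean z outside it."""
    z = np.asarray(z_map, dtype=float).ravel()
    m = np.asarray(template_mask, dtype=bool).ravel()
    if z.shape != m.shape:
        raise ValueError("z map and template must share the voxel grid")
    n_in = int(m.sum())
    if n_in == 0 or n_in == m.size:
        raise ValueError("template mask must be nonempty and not cover all voxels")
    return float(z[m].mean() - z[~m].mean())


def assign_components(
    component_maps: np.ndarray, templates: TemplateSet
) -> RSNAssignment:
    """Label components with networks by descending template match score.

    Every component is scored against every template; assignments are
    resolved greedily by descending score so that when two templates prefer
    the same component the higher-scoring template keeps it and the other
    falls back to its next-best component.  Disagreement between the
    difference score and the spatial-correlation ranking is warned about.
    """
    maps = np.asarray(component_maps, dtype=float)
    k = maps.shape[0]
    n_net = len(templates.names)
    if k < n_net:
        raise ValueError(f"need at least {n_net} components, got {k}")
    score = np.empty((n_net, k))
    spatial_r = np.empty((n_net, k))
    for i, name in enumerate(templates.names):
        m = templates.masks[i].astype(float)
        for c in range(k):
            score[i, c] = template_match_score(maps[c], templates.masks[i])
            spatial_r[i, c] = np.corrcoef(maps[c], m)[0, 1]

    rows = [
        {"network": templates.names[i], "component": c,
         "score": score[i, c], "spatial_r": spatial_r[i, c]}
        for i in range(n_net) for c in range(k)
    ]
    table = pd.DataFrame(rows)

    chosen: dict[str, int] = {}
    win_score: dict[str, float] = {}
    runner: dict[str, float] = {}
    taken: set[int] = set()
    remaining = set(range(n_net))
    while remaining:
        # among unassigned networks, pick the (network, free component) pair
        # with the globally highest score
        best = None
        for i in remaining:
            for c in range(k):
                if c in taken:
                    continue
                if best is None or score[i, c] > best[2]:
                    best = (i, c, score[i, c])
        i, c, s = best
        name = templates.names[i]
        chosen[name] = c
        win_score[name] = float(s)
        others = [score[i, cc] for cc in range(k) if cc != c and cc not in taken]
        runner[name] = float(max(others)) if others else float("-inf")
        taken.add(c)
        remaining.discard(i)
        if np.argmax(spatial_r[i]) != np.argmax(score[i]):
            warnings.warn(
                f"template '{name}': difference score and spatial correlation "
                "rank different components", stacklevel=2,
            )
    return RSNAssignment(chosen=chosen, scores=win_score, runner_up=runner, table=table)


def group_spatial_ttest(
    subject_maps: np.ndarray,
    mode: str = "one_sample",
    q: float = 0.05,
    mask: np.ndarray | None = None,
    subject_maps_b: np.ndarray | None = None,
) -> StatMapResult:
    """Voxelwise t-test with BH-FDR control over in-mask voxels.

    ``one_sample`` tests the stacked (subjects x voxels) maps against zero;
    ``two_sample`` compares them with ``subject_maps_b`` (requires a mask,
    per the convention that group comparisons are restricted to the
    combined network mask).  Zero-variance voxels get p = 1 and are counted
    in the log.
    """
    A = np.atleast_2d(np.asarray(subject_maps, dtype=float))
    V = A.shape[1]
    if mode not in ("one_sample", "two_sample"):
        raise ValueError("mode must be 'one_sample' or 'two_sample'")
    if mode == "two_sample":
        if subject_maps_b is None:
            raise ValueError("two_sample mode requires subject_maps_b")
        if mask is None:
            raise ValueError("two_sample mode requires an analysis mask")
        B = np.atleast_2d(np.asarray(subject_maps_b, dtype=float))
        if B.shape[1] != V:
            raise ValueError("groups must share the voxel grid")
        if A.shape[0] < 2 or B.shape[0] < 2:
            raise ValueError("need at least 2 subjects per group")
    elif A.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if mask is None:
        mask = np.ones(V, dtype=bool)
    mask = np.asarray(mask, dtype=bool).ravel()
    if mask.size != V:
        raise ValueError("mask must match the voxel grid")

    t_map = np.zeros(V)
    p_map = np.ones(V)
    idx = np.where(mask)[0]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if mode == "one_sample":
            res = stats.ttest_1samp(A[:, idx], 0.0, axis=0)
        else:
            res = stats.ttest_ind(A[:, idx], B[:, idx], axis=0)
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    # zero across-subject variance yields a non-finite t: set p = 1 and flag
    bad = ~np.isfinite(t) | ~np.isfinite(p)
    t = np.where(bad, 0.0, t)
    p = np.where(bad, 1.0, p)
    n_zero_var = int(bad.sum())
    if n_zero_var:
        log.warning("%d zero-variance voxels set to p=1", n_zero_var)
    t_map[idx] = t
    p_map[idx] = p
    _, rej = fdr_bh(p, q)
    sig = np.zeros(V, dtype=bool)
    sig[idx] = rej
    return StatMapResult(
        t_map=t_map, p_map=p_map, sig_mask=sig, analysis_mask=mask,
        n_flagged_zero_variance=n_zero_var,
    )


def build_combined_mask(
    high_masks: dict[str, np.ndarray], low_masks: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Per network, the voxelwise union of the two groups' significance masks."""
    out = {}
    for name, hm in high_masks.items():
        lm = low_masks[name]
        hm = np.asarray(hm, dtype=bool)
        lm = np.asarray(lm, dtype=bool)
        if hm.shape != lm.shape:
            raise ValueError(f"grid mismatch for network {name}")
        out[name] = hm | lm
    return out
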