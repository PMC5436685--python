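"""Shared helpers: deterministic seed derivation and FDR control."""

from __future__ import annotations

import hashlib

import numpy as np
from statsmodels.stats.multitest import multipletests

MAX_SEED = 2**31 - 1


def derive_seed(master_seed: int, *tags) -> int:
    """Derive a stable sub-seed from a master seed and a tag sequence.

    Hash-based so the result does not depend on how many other seeds were
    drawn before it (stable across insertion order of pipeline stages).
    """
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for t in tags:
        h.update(b"\x1f")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % MAX_SEED


def fdr_bh(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up adjusted p-values and significance mask.

    Parameters
    ----------
    pvals : array-like of p-values in [0, 1].
    q : FDR level.

    Returns
    -------
    adjusted : ndarray of BH-adjusted p-values (monotonicity enforced).
    mask : boolean ndarray, True where adjusted <= q.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    reject, adjusted, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return adjusted.reshape(p.shape), reject.reshape(p.shape)
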