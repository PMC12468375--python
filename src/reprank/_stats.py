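"""Shared statistical primitives.

Benjamini-Hochberg adjustment and the hypergeometric upper tail live here so
that differential expression and over-representation analysis use one
implementation each (single source of truth).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "hypergeom_tail"]


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment.

    Returns adjusted p-values in the input order: adj_p_(i) = min_{j>=i}
    (p_(j) * N / j), capped at 1.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def hypergeom_tail(overlap: int, universe_size: int, set_size: int, query_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe_size, set_size, query_size).

    The probability that a random query of ``query_size`` genes drawn without
    replacement from a universe of ``universe_size`` genes hits at least
    ``overlap`` members of a set of ``set_size`` genes.
    """
    if overlap < 0 or set_size < 0 or query_size < 0:
        raise ValueError("counts must be non-negative")
    if overlap > min(set_size, query_size):
        raise ValueError("overlap cannot exceed min(set_size, query_size)")
    if max(set_size, query_size) > universe_size:
        raise ValueError("set and query must fit in the universe")
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))
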