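"""Differential expression and signature extraction.

Implements the per-dataset, per-stage half of the pipeline: quantile
normalisation, an empirical-Bayes moderated t-statistic (case vs. control),
probe-to-symbol collapsing, and extraction of symmetric up/down signatures
(at most 150 genes per direction, adjusted p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from ._stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "Signature",
    "quantile_normalize",
    "log2_if_needed",
    "moderated_t",
    "collapse_probes",
    "extract_signature",
]

#: default signature size per direction
SIGNATURE_SIZE = 150


@dataclass
class ExpressionDataset:
    """A gene-by-sample expression matrix with case/control labels.

    matrix      : DataFrame, genes (rows) x samples (columns), log2 scale
    groups      : Series indexed by sample id, values in {"case", "control"}
    stage       : disease stage label, e.g. MGUS / sMM / MM
    dataset_id  : cohort identifier
    """

    matrix: pd.DataFrame
    groups: pd.Series
    stage: str = ""
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.matrix.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.matrix.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        self.groups = self.groups.reindex(self.matrix.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"group labels must be case/control, got {bad}")
        counts = self.groups.value_counts()
        if counts.get("case", 0) < 2 or counts.get("control", 0) < 2:
            raise ValueError("need at least 2 samples per group")

    @property
    def n_cases(self) -> int:
        return int((self.groups == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.groups == "control").sum())


@dataclass
class Signature:
    """Ordered up/down gene lists defining one stage x dataset perturbation."""

    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)
    stage: str = ""
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down lists must be disjoint")

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise columns to the mean-of-order-statistics reference.

    After normalisation every column carries the same multiset of values
    (up to within-column ties, which receive the mean of the reference
    values they span).
    """
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite entries")
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_if_needed(matrix: pd.DataFrame, threshold: float = 50.0) -> pd.DataFrame:
    """Apply log2(x+1) when the matrix looks linear-scale (max > threshold)."""
    if matrix.to_numpy().max() > threshold:
        logger.info("matrix max %.1f > %.0f: applying log2(x+1)", matrix.to_numpy().max(), threshold)
        return np.log2(matrix + 1.0)
    logger.info("matrix already on log scale; leaving untransformed")
    return matrix


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square prior.

    Fits (d0, s0^2) such that the observed residual variances look like
    s0^2 * F(df, d0) draws, working on log variances: the mean and variance
    of log s^2 identify the prior via digamma/trigamma moments.
    Returns (prior_df, prior_var); prior_df may be inf (all variances equal).
    """
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t(dataset: ExpressionDataset, prior_df: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test, case vs. control, per gene.

    Pooled per-gene variances are shrunk toward a prior estimated across
    genes by method of moments on log residual variances; the t statistic
    uses the shrunk standard error and df augmented by the prior df, and
    p-values are BH-adjusted across all genes.

    prior_df=0 disables shrinkage (ordinary two-sample t); prior_df=None
    (default) estimates it from the data.

    Returns a DataFrame indexed by gene with columns
    ``log2fc, t_stat, p_value, adj_p``.
    """
    case = dataset.matrix.loc[:, dataset.groups == "case"].to_numpy(dtype=float)
    ctrl = dataset.matrix.loc[:, dataset.groups == "control"].to_numpy(dtype=float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    df_resid = n1 + n2 - 2

    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    s2 = ((n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1)) / df_resid
    if np.all(s2 <= 0):
        raise ValueError("all genes have zero residual variance; degenerate input")

    if prior_df is None:
        d0, s0_2 = _fit_variance_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s0_2 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_2 = _fit_variance_prior(s2, df_resid)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    return pd.DataFrame(
        {"log2fc": log2fc, "t_stat": t, "p_value": p, "adj_p": bh_adjust(p)},
        index=dataset.matrix.index.rename("gene"),
    )


def collapse_probes(de: pd.DataFrame, probe_to_gene: dict[str, str] | pd.Series) -> pd.DataFrame:
    """Collapse a probe-level DE table to gene symbols.

    For each gene symbol the most differentially expressed probe (largest
    |log2fc|) is kept; ties break by smaller adj_p, then lexicographic probe
    id. Probes absent from the map are dropped with a logged count.
    """
    mapping = pd.Series(dict(probe_to_gene)) if not isinstance(probe_to_gene, pd.Series) else probe_to_gene
    if mapping.empty:
        raise ValueError("empty probe-to-gene map")
    table = de.copy()
    table["gene"] = table.index.map(mapping)
    n_dropped = int(table["gene"].isna().sum())
    if n_dropped:
        logger.info("dropping %d probes with no gene mapping", n_dropped)
        table = table.dropna(subset=["gene"])
    table = table.assign(_abs_fc=table["log2fc"].abs(), _probe=table.index)
    table = table.sort_values(
        ["_abs_fc", "adj_p", "_probe"], ascending=[False, True, True], kind="mergesort"
    )
    collapsed = table.groupby("gene", sort=True).head(1)
    collapsed = collapsed.set_index("gene").drop(columns=["_abs_fc", "_probe"]).sort_index()
    return collapsed


def extract_signature(
    de: pd.DataFrame,
    stage: str = "",
    dataset_id: str = "",
    n_per_direction: int = SIGNATURE_SIZE,
    alpha: float = 0.05,
    rank_first: bool = False,
) -> Signature:
    """Extract the symmetric up/down signature from a DE table.

    Default behaviour filters to adj_p < alpha (strict) first, then ranks the
    survivors by log2fc: the top ``n_per_direction`` over-expressed genes form
    the up list and the bottom ``n_per_direction`` the down list. With
    ``rank_first`` the order flips: rank all genes by log2fc, take the
    extremes, then apply the significance filter.

    A side with fewer than ``n_per_direction`` qualifying genes takes them
    all, with a logged warning; zero significant genes yields an empty
    signature (warning, not an exception).
    """
    if "adj_p" not in de.columns:
        raise ValueError("DE table lacks adj_p; run moderated_t first")

    def _top(table: pd.DataFrame, direction: str) -> list[str]:
        if direction == "up":
            pool = table[table["log2fc"] > 0]
            pool = pool.sort_values(["log2fc", "adj_p"], ascending=[False, True], kind="mergesort")
        else:
            pool = table[table["log2fc"] < 0]
            pool = pool.sort_values(["log2fc", "adj_p"], ascending=[True, True], kind="mergesort")
        return list(pool.index[:n_per_direction])

    if rank_first:
        up = [g for g in _top(de, "up") if de.loc[g, "adj_p"] < alpha]
        down = [g for g in _top(de, "down") if de.loc[g, "adj_p"] < alpha]
    else:
        significant = de[de["adj_p"] < alpha]
        up = _top(significant, "up")
        down = _top(significant, "down")

    if not up and not down:
        logger.warning("no significant genes at adj_p < %g; empty signature", alpha)
    elif len(up) < n_per_direction or len(down) < n_per_direction:
        logger.warning("undersized signature: %d up, %d down (target %d each)", len(up), len(down), n_per_direction)
    return Signature(up=up, down=down, stage=stage, dataset_id=dataset_id)
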