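"""Bulk expression utilities: normalisation, qPCR ΔΔCt, differential
expression selection, immune-gene enrichment and methylation–expression
correlation.

The normalisation chain mirrors common bulk-RNAseq practice: within each
sample, genes with zero counts are excluded from the quantile computation and
all values are divided by that sample's 75th percentile of nonzero abundance,
then rescaled by the cohort-mean upper quartile so magnitudes stay
interpretable; a per-sample percentile-rank transform (average ranks for
ties, values in (0, 1]) then removes residual distributional differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def upper_quartile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Upper-quartile normalise a genes x samples abundance matrix.

    Each sample is divided by the 75th percentile (linear interpolation) of
    its nonzero values and multiplied by the cohort-mean upper quartile.
    A sample with no nonzero values is an error.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    uqs = {}
    for col in matrix.columns:
        nonzero = matrix[col][matrix[col] > 0]
        if nonzero.empty:
            raise ValueError(f"sample {col!r} has no nonzero counts")
        uqs[col] = float(np.percentile(nonzero, 75))
    cohort_factor = float(np.mean(list(uqs.values())))
    return matrix / pd.Series(uqs) * cohort_factor


def percentile_rank_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace each value by its fractional rank within its sample, in (0, 1].

    Ties receive the average rank, so the output is invariant under any
    strictly monotone per-sample transform of the input.
    """
    n = matrix.shape[0]
    return matrix.apply(lambda col: stats.rankdata(col, method="average") / n, axis=0)


@dataclass
class QpcrMeasurement:
    """Ct triplicates for the target and housekeeping gene of one specimen."""

    sample_id: str
    target_ct: tuple[float, ...]
    housekeeping_ct: tuple[float, ...]
    housekeeping_gene: str = "SRP14"

    def __post_init__(self) -> None:
        if not self.target_ct or not self.housekeeping_ct:
            raise ValueError("need >= 1 replicate for target and housekeeping")
        if any(c <= 0 for c in self.target_ct) or any(c <= 0 for c in self.housekeeping_ct):
            raise ValueError("Ct values must be positive")

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.target_ct) - np.mean(self.housekeeping_ct))


def ddct_relative_expression(sample: QpcrMeasurement, calibrator: QpcrMeasurement) -> float:
    """Relative quantity by the delta-delta Ct method: 2^-(ΔCt_s - ΔCt_cal)."""
    ddct = sample.delta_ct - calibrator.delta_ct
    return float(2.0 ** (-ddct))


@dataclass
class DegResult:
    gene: str
    log2_fold_change: float
    p_value: float
    direction: str  # up | down | none


def select_degs(
    stats_table: pd.DataFrame, p_threshold: float = 0.05, lfc_threshold: float = 1.0
) -> pd.DataFrame:
    """Flag differentially expressed genes: p < 0.05 and |log2FC| > 1 (strict).

    ``stats_table`` columns: gene, log2_fold_change, p_value. Returns the
    table with a ``direction`` column (up/down/none).
    """
    out = stats_table.copy()
    sig = (out["p_value"] < p_threshold) & (out["log2_fold_change"].abs() > lfc_threshold)
    out["direction"] = "none"
    out.loc[sig & (out["log2_fold_change"] > 0), "direction"] = "up"
    out.loc[sig & (out["log2_fold_change"] < 0), "direction"] = "down"
    return out


def two_group_deg_stats(
    matrix: pd.DataFrame, group_a: list[str], group_b: list[str], pseudocount: float = 1e-9
) -> pd.DataFrame:
    """Per-gene two-sample t statistics and log2 fold changes (A vs B).

    A plain Welch test on the supplied (typically percentile-ranked) values;
    the selection thresholds, not the test engine, are the fixed part of the
    procedure.
    """
    a = matrix[group_a].to_numpy()
    b = matrix[group_b].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    lfc = np.log2((a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount))
    return pd.DataFrame(
        {"gene": matrix.index, "log2_fold_change": lfc, "p_value": np.nan_to_num(p, nan=1.0)}
    )


def immune_gene_enrichment(
    deg_genes: set[str], immune_genes: set[str], universe: set[str]
) -> tuple[float, float, np.ndarray]:
    """Fisher exact test for immune-gene enrichment among DEGs.

    Returns (odds ratio, two-sided p, 2x2 table [[DEG∩imm, DEG∖imm],
    [imm∖DEG, neither]]). Empty universe is an error; an empty DEG set
    returns (nan, 1.0, table).
    """
    if not universe:
        raise ValueError("empty gene universe")
    deg_genes = deg_genes & universe
    immune_genes = immune_genes & universe
    a = len(deg_genes & immune_genes)
    b = len(deg_genes - immune_genes)
    c = len(immune_genes - deg_genes)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    if not deg_genes:
        return float("nan"), 1.0, table
    _, p = stats.fisher_exact(table, alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return float(odds), float(p), table


def methylation_expression_correlation(percents, expressions) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between methylation % and expression."""
    percents = np.asarray(percents, dtype=float)
    expressions = np.asarray(expressions, dtype=float)
    if percents.shape != expressions.shape or len(percents) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(percents) == 0 or np.std(expressions) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(percents, expressions)
    return float(r), float(p)
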