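"""Group-wise expression statistics and cohort gene-set scoring.

Covers the strict FPKM expression filter, the per-group fraction of
genes lower-expressed in the second condition, group difference
summaries with Mann-Whitney comparisons, cumulative gene-set scores
per cohort sample, Welch's t-test and triple-negative receptor-status
labeling.

Expression tables are pandas DataFrames (genes as index, condition or
sample labels as columns); missing values are excluded pairwise, never
imputed.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from bivtrans.signature_overlap import GeneSet
from bivtrans.state_classifier import TransitionGroup, TransitionTable

logger = logging.getLogger(__name__)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a genes x columns TSV with a header row; first column = gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.columns.is_unique:
        raise ValueError("duplicate column labels in expression table")
    return df


def expression_filter(
    table: pd.DataFrame, column: str, threshold: float = 10.0
) -> GeneSet:
    """Genes with expression strictly greater than the threshold."""
    if column not in table.columns:
        raise KeyError(f"column {column!r} not in expression table")
    values = table[column]
    kept = values.index[values > threshold]
    return GeneSet.from_iterable(f"{column}_gt_{threshold:g}", kept)


def fraction_lower(
    table: pd.DataFrame,
    col_a: str,
    col_b: str,
    gene_set: Iterable[str],
) -> tuple[int, int, float]:
    """(n_lower, n_total, fraction) of genes strictly lower in column B.

    Genes absent from the table or with a missing value in either
    column are skipped (count logged). Ties never count as lower.
    """
    for col in (col_a, col_b):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in expression table")
    genes = list(gene_set)
    present = [g for g in genes if g in table.index]
    sub = table.loc[present, [col_a, col_b]].dropna()
    skipped = len(genes) - len(sub)
    if skipped:
        logger.info("fraction_lower: skipped %d genes without paired values", skipped)
    if sub.empty:
        raise ValueError("no genes with paired expression values")
    n_lower = int((sub[col_b] < sub[col_a]).sum())
    n_total = len(sub)
    return n_lower, n_total, n_lower / n_total


@dataclass(frozen=True)
class GroupExpressionSummary:
    group: str
    n_genes: int
    n_lower: int
    fraction_lower: float
    mean_difference: float
    sem_difference: float
    pairwise_p: dict[tuple[str, str], float]


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "exact"
) -> tuple[float, float]:
    """Mann-Whitney U (for x) and two-sided p.

    U counts pairs with x_i > y_j plus half-ties. Exact p enumerates
    the null U distribution (requires |x| + |y| <= 20 and no
    cross-sample ties; falls back to the normal approximation with a
    warning otherwise). The approximation is tie-corrected with a
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("both samples must be non-empty")
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < nx + ny
    if mode == "exact" and (nx + ny > 20 or has_ties):
        if has_ties:
            logger.warning("exact Mann-Whitney with ties: using normal approximation")
        mode = "normal_approx"
    if mode == "exact":
        p = _mwu_exact_p(u, nx, ny)
    elif mode == "normal_approx":
        p = _mwu_normal_p(u, x, y)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(u), float(p)


def _mwu_count_distribution(nx: int, ny: int) -> list[int]:
    """Counts of rank assignments by U value (classic recurrence)."""
    # c[n][m][u] via rolling DP: number of ways to interleave achieving U=u
    max_u = nx * ny
    prev = [[0] * (max_u + 1) for _ in range(ny + 1)]
    for m in range(ny + 1):
        prev[m][0] = 1
    for n in range(1, nx + 1):
        cur = [[0] * (max_u + 1) for _ in range(ny + 1)]
        cur[0][0] = 1
        for m in range(1, ny + 1):
            for u in range(max_u + 1):
                total = cur[m - 1][u]  # last pooled value from y
                if u - m >= 0:
                    total += prev[m][u - m]  # last pooled value from x
                cur[m][u] = total
        prev = cur
    return prev[ny]


def _mwu_exact_p(u: float, nx: int, ny: int) -> float:
    counts = _mwu_count_distribution(nx, ny)
    total = math.comb(nx + ny, nx)
    u_small = min(u, nx * ny - u)
    lower = sum(counts[k] for k in range(int(math.floor(u_small)) + 1))
    # symmetric null: two-sided p doubles the smaller tail, capped at 1
    return min(1.0, 2.0 * lower / total)


def _mwu_normal_p(u: float, x: np.ndarray, y: np.ndarray) -> float:
    from scipy import stats as sps

    nx, ny = len(x), len(y)
    n = nx + ny
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1)) if n > 1 else 0.0
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    mean = nx * ny / 2.0
    z = (abs(u - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * float(sps.norm.sf(z)))


def group_difference_summary(
    table: pd.DataFrame,
    col_a: str,
    col_b: str,
    transition_table: TransitionTable,
    pairing: str = "group_I_vs_rest",
    mwu_mode: str = "normal_approx",
) -> list[GroupExpressionSummary]:
    """Per-group expression-difference summaries with Mann-Whitney tests.

    The per-gene difference is value(col_b) - value(col_a). Pairing
    "group_I_vs_rest" tests Group I against each of II-IV (default);
    "all_pairs" tests every group pair. Groups with < 2 genes are
    skipped for testing (flagged by absence from pairwise_p).
    """
    groups = (
        TransitionGroup.I,
        TransitionGroup.II,
        TransitionGroup.III,
        TransitionGroup.IV,
    )
    diffs: dict[str, np.ndarray] = {}
    fractions: dict[str, tuple[int, int, float]] = {}
    for group in groups:
        genes = transition_table.genes_in_group(group)
        present = [g for g in genes if g in table.index]
        sub = table.loc[present, [col_a, col_b]].dropna()
        if len(sub) < len(genes):
            logger.info(
                "group %s: %d genes without expression values skipped",
                group.value,
                len(genes) - len(sub),
            )
        d = (sub[col_b] - sub[col_a]).to_numpy()
        diffs[group.value] = d
        n_lower = int(np.sum(d < 0))
        fractions[group.value] = (
            n_lower,
            len(d),
            n_lower / len(d) if len(d) else float("nan"),
        )

    if pairing == "group_I_vs_rest":
        pairs = [("I", g.value) for g in groups[1:]]
    elif pairing == "all_pairs":
        pairs = list(itertools.combinations([g.value for g in groups], 2))
    else:
        raise ValueError(f"unknown pairing {pairing!r}")

    pairwise: dict[tuple[str, str], float] = {}
    for ga, gb in pairs:
        if len(diffs[ga]) < 2 or len(diffs[gb]) < 2:
            logger.info("pair (%s, %s) skipped: group too small", ga, gb)
            continue
        _, p = mann_whitney_u(diffs[ga], diffs[gb], mode=mwu_mode)
        pairwise[(ga, gb)] = p

    summaries = []
    for group in groups:
        g = group.value
        d = diffs[g]
        n_lower, n_total, frac = fractions[g]
        mean = float(np.mean(d)) if len(d) else float("nan")
        sem = float(np.std(d, ddof=1) / math.sqrt(len(d))) if len(d) > 1 else float("nan")
        summaries.append(
            GroupExpressionSummary(
                g,
                n_total,
                n_lower,
                frac,
                mean,
                sem,
                {pair: p for pair, p in pairwise.items() if g in pair},
            )
        )
    return summaries


def geneset_cumulative_score(
    matrix: pd.DataFrame, gene_set: Iterable[str], statistic: str = "sum"
) -> pd.Series:
    """Per-sample aggregate expression over a gene set.

    ``statistic`` is "sum" (default, cumulative expression) or "mean".
    Missing genes are logged; an empty intersection is an error.
    """
    genes = list(gene_set)
    present = [g for g in genes if g in matrix.index]
    missing = len(genes) - len(present)
    if missing:
        logger.info("geneset score: %d genes absent from matrix", missing)
    if not present:
        raise ValueError("gene set has no genes in the expression matrix")
    sub = matrix.loc[present]
    if statistic == "sum":
        return sub.sum(axis=0, skipna=True)
    if statistic == "mean":
        return sub.mean(axis=0, skipna=True)
    raise ValueError(f"unknown statistic {statistic!r}")


def welch_t_test(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sided t-test: (t, df, p).

    Both samples need >= 2 observations. Zero variance in both samples
    with equal means gives t = 0, p = 1 by convention.
    """
    from scipy import stats as sps

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("Welch test requires >= 2 observations per sample")
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    mx, my = float(np.mean(x)), float(np.mean(y))
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return 0.0, float(nx + ny - 2), 1.0
        return math.copysign(math.inf, mx - my), float(nx + ny - 2), 0.0
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return t, df, min(p, 1.0)


class ReceptorStatus(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    INDETERMINATE = "indeterminate"


class CohortLabel(str, enum.Enum):
    TN = "TN"
    NON_TN = "NON_TN"
    EXCLUDED = "EXCLUDED"


def _parse_status(token: str) -> ReceptorStatus:
    try:
        return ReceptorStatus(str(token).strip().lower())
    except ValueError:
        raise ValueError(f"unknown receptor status token {token!r}") from None


def tnbc_label(er: str, pr: str, her2: str) -> CohortLabel:
    """Triple-negative labeling from ER/PR/HER2 receptor statuses.

    All three definitively negative -> TN; any definitively positive
    -> NON_TN; everything else (indeterminate without a positive) is
    EXCLUDED.
    """
    statuses = [_parse_status(s) for s in (er, pr, her2)]
    if all(s is ReceptorStatus.NEGATIVE for s in statuses):
        return CohortLabel.TN
    if any(s is ReceptorStatus.POSITIVE for s in statuses):
        return CohortLabel.NON_TN
    return CohortLabel.EXCLUDED


def label_cohort(metadata: pd.DataFrame) -> dict[str, CohortLabel]:
    """Label every sample in a cohort metadata table.

    Expects columns ER, PR, HER2 indexed by sample id (or with a
    sample_id column).
    """
    df = metadata
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    missing = [c for c in ("ER", "PR", "HER2") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort metadata missing columns: {missing}")
    return {
        str(sample): tnbc_label(row["ER"], row["PR"], row["HER2"])
        for sample, row in df.iterrows()
    }
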