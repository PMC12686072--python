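"""Cohort statistics: contingency-table association tests, subtype
proportions, two-group rank comparisons and marker correlation blocks.

Chi-square tests are plain Pearson tests without continuity correction —
the convention under which the printed clinical association statistics are
reproducible — and "Missing"/"Uncertain" categories are kept as ordinary
rows by default for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix, SampleTable
from .panels import GenePanel

__all__ = [
    "ChiSquareResult",
    "CorrelationBlocks",
    "chi_square_test",
    "association_test",
    "subtype_proportions",
    "mann_whitney",
    "correlation_blocks",
    "round_to_print",
]

SUBTYPE_ORDER = ("EPC", "HPC", "MPC")


def round_to_print(x: float, decimals: int = 1) -> float:
    """Round-half-to-even at 1 dp, the convention (R's ``round``) under
    which the published percentages are reproducible (e.g. 26/32 -> 81.2)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    low_expected_warning: bool

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ChiSquareResult(statistic={self.statistic:.3f}, df={self.df}, "
            f"p_value={self.p_value:.4g}, low_expected={self.low_expected_warning})"
        )


def _as_count_frame(table) -> pd.DataFrame:
    df = pd.DataFrame(table)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("contingency table must be numeric")
    if (arr < 0).any():
        raise ValueError("contingency table counts must be nonnegative")
    return df.astype(float)


def chi_square_test(table) -> ChiSquareResult:
    """Pearson chi-square test of independence on a contingency table.

    Zero-margin rows/columns are dropped before testing; no continuity
    correction at any table size. The upper-tail probability comes from the
    chi-square survival function (regularized upper incomplete gamma).
    A low-expected flag is raised when any expected count falls below 5.
    """
    df = _as_count_frame(table)
    df = df.loc[df.sum(axis=1) > 0, df.sum(axis=0) > 0]
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError(
            f"degenerate table after dropping zero margins: shape {df.shape}"
        )
    stat, p, dof, expected = sps.chi2_contingency(df.to_numpy(), correction=False)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(dof),
        p_value=float(p),
        expected=np.asarray(expected),
        low_expected_warning=bool((np.asarray(expected) < 5).any()),
    )


def association_test(
    assignments: pd.DataFrame,
    meta: SampleTable,
    covariate: str,
    include_missing: bool = True,
):
    """Covariate x subtype contingency table plus its chi-square test.

    ``include_missing=True`` (the default) keeps "Missing"/"Uncertain"
    categories as ordinary rows, matching how the printed clinical tables
    were tallied.
    """
    if covariate not in meta.data.columns:
        raise ValueError(f"unknown covariate {covariate!r}")
    merged = assignments.merge(
        meta.data[["sample_id", covariate]], on="sample_id", how="inner"
    )
    if not include_missing:
        merged = merged[~merged[covariate].isin(["Missing", "Uncertain"])]
    table = pd.crosstab(merged[covariate], merged["subtype"])
    table = table.reindex(columns=[s for s in SUBTYPE_ORDER if s in table.columns])
    return table, chi_square_test(table)


def subtype_proportions(
    assignments: pd.DataFrame, grouping: str | None = None, test: bool = False
):
    """Counts and 1-dp percentages of each subtype, optionally per group.

    With ``test=True`` and a grouping column, also runs a chi-square test of
    subtype distribution across groups.
    """
    if grouping is None:
        counts = assignments["subtype"].value_counts()
        counts = counts.reindex([s for s in SUBTYPE_ORDER if s in counts.index])
        total = int(counts.sum())
        out = pd.DataFrame(
            {
                "count": counts.astype(int),
                "percent": [round_to_print(100.0 * c / total) for c in counts],
            }
        )
        return (out, None) if test else out
    table = pd.crosstab(assignments[grouping], assignments["subtype"])
    table = table.reindex(columns=[s for s in SUBTYPE_ORDER if s in table.columns])
    pct = table.div(table.sum(axis=1), axis=0) * 100.0
    pct = pct.map(round_to_print)
    out = pd.concat({"count": table, "percent": pct}, axis=1)
    if test:
        return out, chi_square_test(table)
    return out


def mann_whitney(group_a, group_b):
    """Two-sided Mann-Whitney U test.

    Returns (U, p) where U counts pairs in which a value from ``group_a``
    exceeds one from ``group_b`` (ties count 1/2). Exact enumeration when
    both groups have at most 8 untied observations, tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    small = max(a.size, b.size) <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationBlocks:
    """Mean pairwise Pearson r within/between the two panel gene sets."""

    ee: float  # within epithelial
    mm: float  # within mesenchymal
    em: float  # between panels
    matrix: pd.DataFrame

    def as_dict(self) -> dict:
        return {"E&E": self.ee, "M&M": self.mm, "E&M": self.em}


def correlation_blocks(matrix: ExpressionMatrix, panel: GenePanel) -> CorrelationBlocks:
    """Pairwise Pearson correlations over samples for all panel genes,
    summarized as within-epithelial (E&E), within-mesenchymal (M&M) and
    cross-panel (E&M) block means. Diagonals are excluded from the
    within-block means.
    """
    present = set(matrix.genes)
    epi = [g for g in panel.epithelial if g in present]
    mes = [g for g in panel.mesenchymal if g in present]
    if len(epi) < 2 or len(mes) < 2:
        raise ValueError("need at least 2 genes per sub-panel for correlation blocks")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation blocks")
    sub = matrix.values.loc[epi + mes]
    corr = pd.DataFrame(
        np.corrcoef(sub.to_numpy()), index=sub.index, columns=sub.index
    )
    ee_block = corr.loc[epi, epi].to_numpy()
    mm_block = corr.loc[mes, mes].to_numpy()
    em_block = corr.loc[epi, mes].to_numpy()
    n_e, n_m = len(epi), len(mes)
    ee = float((ee_block.sum() - n_e) / (n_e * (n_e - 1)))
    mm = float((mm_block.sum() - n_m) / (n_m * (n_m - 1)))
    em = float(em_block.mean())
    return CorrelationBlocks(ee=ee, mm=mm, em=em, matrix=corr)
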