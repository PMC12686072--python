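"""Ancillary quantitative scores: single-cell E/M ratio, mIHC scoring and
IHC-based CDH1/VIM subtyping.

The E/M ratio summarizes EMT progression in an annotated single-cell sample
as the epithelial fraction of the EMT-relevant compartment (epithelial +
fibroblast + endothelial cells). mIHC staining is scored as intensity (0-3)
times positive-cell category (0-4); the CDH1/VIM score ratio maps a sample
to EPC (>= 3), MPC (<= 0.5) or HPC (in between).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["em_ratio", "em_ratio_table", "ihc_score", "ihc_subtype"]

EM_CELL_TYPES = ("epithelial", "fibroblast", "endothelial")


def em_ratio(epithelial: int, fibroblast: int, endothelial: int) -> float:
    """Epithelial fraction of the EMT compartment; NaN (flagged) when empty."""
    for name, v in zip(EM_CELL_TYPES, (epithelial, fibroblast, endothelial)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} count must be a nonnegative integer, got {v!r}")
    denom = epithelial + fibroblast + endothelial
    if denom == 0:
        return math.nan
    return epithelial / denom


def em_ratio_table(counts: pd.DataFrame) -> pd.Series:
    """Per-sample E/M ratio from a cell-type count table.

    ``counts`` must have columns epithelial, fibroblast, endothelial (other
    annotated cell types are ignored). Samples with an empty EMT compartment
    get NaN rather than 0.
    """
    missing = [c for c in EM_CELL_TYPES if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing required columns: {missing}")
    num = counts["epithelial"].astype(float)
    denom = counts[list(EM_CELL_TYPES)].sum(axis=1).astype(float)
    out = num / denom.where(denom > 0, np.nan)
    out.name = "em_ratio"
    return out


def ihc_score(intensity: int, percentage_category: int) -> int:
    """mIHC score = staining intensity (0-3) x positive-cell category (0-4)."""
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity must be in 0..3, got {intensity!r}")
    if percentage_category not in (0, 1, 2, 3, 4):
        raise ValueError(f"percentage category must be in 0..4, got {percentage_category!r}")
    return intensity * percentage_category


def ihc_subtype(cdh1_score: float, vim_score: float) -> str:
    """EMT subtype from CDH1 and VIM IHC scores.

    ratio r = CDH1/VIM: r >= 3 -> EPC; r <= 0.5 -> MPC; otherwise HPC.
    VIM = 0 with CDH1 > 0 is the r -> inf limit (EPC); both zero is
    indeterminate rather than guessed.
    """
    for name, v in (("cdh1_score", cdh1_score), ("vim_score", vim_score)):
        if not 0 <= v <= 12:
            raise ValueError(f"{name} must be in [0, 12], got {v!r}")
    if vim_score == 0:
        return "EPC" if cdh1_score > 0 else "indeterminate"
    r = cdh1_score / vim_score
    if r >= 3:
        return "EPC"
    if r <= 0.5:
        return "MPC"
    return "HPC"
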