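"""Normalization and panel-submatrix extraction.

Clustering and scoring operate on per-gene z-scores: ``auto`` mode applies
log2(x+1) first when values look like counts/FPKM (matrix maximum > 50,
a scale no log or z-scored matrix reaches) and then standardizes each gene
across samples. Z-scores use the sample standard deviation (divide by
n - 1, the R ``scale()`` convention); either convention is defensible but
one must be fixed for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .panels import GenePanel

__all__ = ["PanelMatrix", "normalize", "select_panel"]

LOG_DETECT_THRESHOLD = 50.0
DEFAULT_MIN_COVERAGE = 0.6


@dataclass
class PanelMatrix:
    """Z-scored expression restricted to panel genes.

    ``coverage`` is the fraction of each sub-panel found in the matrix;
    ``epithelial``/``mesenchymal`` are the panel genes actually retained.
    """

    values: pd.DataFrame
    epithelial: tuple
    mesenchymal: tuple
    coverage: tuple  # (epithelial fraction, mesenchymal fraction)
    panel: GenePanel

    @property
    def samples(self) -> list:
        return list(self.values.columns)


def normalize(matrix: ExpressionMatrix, mode: str = "auto") -> ExpressionMatrix:
    """Return a per-gene z-scored copy of ``matrix``.

    Modes: ``auto`` (log2(x+1) first iff max > 50), ``log_zscore``,
    ``zscore_only``, ``none``. Zero-variance genes are dropped with a
    warning under z-scoring; negative values are rejected under log.
    """
    if mode not in ("auto", "log_zscore", "zscore_only", "none"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if mode == "none":
        return matrix
    df = matrix.values
    if mode == "auto":
        mode = "log_zscore" if float(df.to_numpy().max()) > LOG_DETECT_THRESHOLD else "zscore_only"
    if mode == "log_zscore":
        if (df.to_numpy() < 0).any():
            raise ValueError("negative expression values cannot be log-transformed")
        df = np.log2(df + 1.0)
    arr = df.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)  # sample sd (n - 1)
    keep = (sd > 0).ravel()
    if not keep.all():
        dropped = df.index[~keep].tolist()
        warnings.warn(f"dropping zero-variance genes: {dropped}", stacklevel=2)
    z = (arr[keep] - mu[keep]) / sd[keep]
    out = pd.DataFrame(z, index=df.index[keep], columns=df.columns)
    return ExpressionMatrix(values=out, normalized="zscore")


def select_panel(
    matrix: ExpressionMatrix, panel: GenePanel, min_coverage: float = DEFAULT_MIN_COVERAGE
) -> PanelMatrix:
    """Restrict a z-scored matrix to panel genes, enforcing sub-panel coverage.

    Fails if either sub-panel has fewer than ``min_coverage`` of its genes
    present; below that the epithelial/mesenchymal axes are under-determined.
    Sample order is preserved.
    """
    if matrix.normalized != "zscore":
        raise ValueError("select_panel requires a z-scored matrix (run normalize first)")
    present = set(matrix.genes)
    epi = tuple(g for g in panel.epithelial if g in present)
    mes = tuple(g for g in panel.mesenchymal if g in present)
    cov = (len(epi) / len(panel.epithelial), len(mes) / len(panel.mesenchymal))
    for frac, found, full, label in (
        (cov[0], epi, panel.epithelial, "epithelial"),
        (cov[1], mes, panel.mesenchymal, "mesenchymal"),
    ):
        if frac < min_coverage:
            missing = sorted(set(full) - set(found))
            raise ValueError(
                f"{label} panel coverage {frac:.2f} below minimum {min_coverage:.2f}; "
                f"missing genes: {missing}"
            )
    sub = matrix.values.loc[list(epi) + list(mes)]
    return PanelMatrix(values=sub, epithelial=epi, mesenchymal=mes, coverage=cov, panel=panel)
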