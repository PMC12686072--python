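"""The EMT-heterogeneity typing model.

Samples are clustered on the z-scored expression of a fixed
epithelial + mesenchymal marker panel using agglomerative clustering with
complete linkage and one-minus-Pearson-correlation distance, cut into three
clusters. Clusters are named by their mean epithelial-minus-mesenchymal
score: epi-high -> EPC (epithelial phenotype cluster), epi-medium -> HPC
(hybrid), epi-low -> MPC (mesenchymal). A rank-based per-sample enrichment
score over the full transcriptome (epithelial set vs stromal/mesenchymal
set) provides an independent verification axis: each sample is tertiled on
both scores and flagged concordant or discordant with its cluster label.
Verification never reassigns a label — it is a diagnostic, not a gate.

Usage follows the model/results convention::

    model = EMTTypingModel(expr, panel=default_panel(), meta=meta)
    res = model.fit()
    res.assignments           # per-sample table
    res.summary()             # text summary
    res.association_test("lauren")
    res.transition_analysis() # paired cohorts
    res.survival("os")
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from . import transitions as _transitions
from . import stats as _stats
from .io import ExpressionMatrix, ResultBundle, SampleTable
from .panels import GenePanel, default_panel
from .preprocess import DEFAULT_MIN_COVERAGE, PanelMatrix, normalize, select_panel
from .stats import SUBTYPE_ORDER
from .survival import km_curve, logrank_test

__all__ = [
    "EmtScore",
    "ClusterLabeling",
    "EMTTypingModel",
    "EMTTypingResults",
    "compute_emt_scores",
    "cluster_samples",
    "label_clusters",
    "enrichment_score",
    "verify_assignments",
    "classify_cohort",
]


@dataclass(frozen=True)
class EmtScore:
    """Per-sample panel means: epithelial, mesenchymal, and their difference."""

    epithelial: float
    mesenchymal: float

    @property
    def delta(self) -> float:
        return self.epithelial - self.mesenchymal


@dataclass
class ClusterLabeling:
    """Bijection cluster id -> subtype, with the ordering evidence kept."""

    subtype_of: dict  # cluster id -> EPC/HPC/MPC
    mean_delta: dict  # cluster id -> mean delta
    mean_epithelial: dict
    order_record: list  # cluster ids from epi-high to epi-low


def compute_emt_scores(pm: PanelMatrix) -> pd.DataFrame:
    """Mean z-score over each sub-panel per sample, plus delta = epi - mes."""
    epi = pm.values.loc[list(pm.epithelial)].mean(axis=0)
    mes = pm.values.loc[list(pm.mesenchymal)].mean(axis=0)
    return pd.DataFrame(
        {
            "epithelial_score": epi,
            "mesenchymal_score": mes,
            "delta": epi - mes,
        }
    )


def cluster_samples(pm: PanelMatrix, k: int = 3):
    """Complete-linkage agglomeration on 1 - Pearson correlation distances.

    Returns ``(linkage_matrix, cluster_ids)`` where cluster ids are a pandas
    Series (1..k) indexed by sample. Distances are between per-sample panel
    z-score vectors (across genes).
    """
    X = pm.values.to_numpy().T  # samples x genes
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 panel genes to correlate")
    sds = X.std(axis=1)
    if (sds == 0).any():
        bad = [pm.samples[i] for i in np.nonzero(sds == 0)[0]]
        raise ValueError(f"zero-variance panel vector for samples: {bad}")
    dist = pdist(X, metric="correlation")  # 1 - Pearson r
    # correlation distance can dip epsilon-negative; clamp for monotone linkage
    dist = np.clip(dist, 0.0, None)
    Z = linkage(dist, method="complete")
    ids = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(ids)) != k:
        raise ValueError(f"could not separate {k} clusters (got {len(np.unique(ids))})")
    return Z, pd.Series(ids, index=pm.samples, name="cluster_id")


def label_clusters(cluster_ids: pd.Series, scores: pd.DataFrame) -> ClusterLabeling:
    """Name clusters EPC/HPC/MPC by descending mean delta.

    Ties on mean delta break toward the larger mean epithelial score, then
    the smaller cluster index, so the subtype map is always a bijection.
    """
    joined = scores.join(cluster_ids)
    grouped = joined.groupby("cluster_id")
    if (grouped.size() == 0).any():
        raise ValueError("empty cluster")
    mean_delta = grouped["delta"].mean()
    mean_epi = grouped["epithelial_score"].mean()
    order = sorted(
        mean_delta.index, key=lambda c: (-mean_delta[c], -mean_epi[c], c)
    )
    if len(order) != 3:
        raise ValueError(f"labeling requires exactly 3 clusters, got {len(order)}")
    subtype_of = dict(zip(order, SUBTYPE_ORDER))
    return ClusterLabeling(
        subtype_of=subtype_of,
        mean_delta=mean_delta.to_dict(),
        mean_epithelial=mean_epi.to_dict(),
        order_record=list(order),
    )


def enrichment_score(expression: pd.Series, gene_set) -> float:
    """Normalized mean-rank enrichment of ``gene_set`` in one sample.

    All G measured genes are ranked within the sample (ascending expression,
    ties get the average rank); the score is

        (mean rank of set members - (G + 1)/2) / ((G - 1)/2),

    which lies in [-1, 1] and is invariant under any strictly increasing
    transform of the expression vector. Positive means the set sits in the
    high-expression tail.
    """
    genes = set(gene_set) & set(expression.index)
    if not genes:
        raise ValueError("gene set has no overlap with measured genes")
    G = len(expression)
    if G < 2:
        raise ValueError("need at least 2 measured genes")
    ranks = pd.Series(rankdata(expression.to_numpy()), index=expression.index)
    mean_rank = float(ranks[list(genes)].mean())
    return (mean_rank - (G + 1) / 2.0) / ((G - 1) / 2.0)


def _tertile_labels(scores: pd.Series) -> pd.Series:
    """Sample-count tertiles: low / medium / high, ties to the lower tertile."""
    n = len(scores)
    r = pd.Series(rankdata(scores.to_numpy(), method="min"), index=scores.index)
    cut1 = int(np.ceil(n / 3.0))
    cut2 = int(np.ceil(2.0 * n / 3.0))
    return pd.Series(
        np.where(r <= cut1, "low", np.where(r <= cut2, "medium", "high")),
        index=scores.index,
    )


_CONCORDANT_PATTERN = {
    "EPC": lambda e, s: e == "high" and s == "low",
    "MPC": lambda e, s: e == "low" and s == "high",
    # hybrid: anything that is neither extreme pattern
    "HPC": lambda e, s: not (e == "high" and s == "low") and not (e == "low" and s == "high"),
}


def verify_assignments(assignments: pd.DataFrame) -> dict:
    """Tertile-based concordance report between cluster labels and
    epithelial/stromal enrichment scores.

    Requires columns subtype, epithelial_enrichment, stromal_enrichment.
    Returns per-subtype and overall concordance fractions; with fewer than
    3 samples tertiles are undefined and the report says so.
    """
    if len(assignments) == 0:
        return {"overall": None, "per_subtype": {}, "tertiles_defined": False}
    if len(assignments) < 3:
        return {"overall": None, "per_subtype": {}, "tertiles_defined": False}
    epi_t = _tertile_labels(assignments["epithelial_enrichment"])
    str_t = _tertile_labels(assignments["stromal_enrichment"])
    concordant = pd.Series(
        [
            _CONCORDANT_PATTERN[st](e, s)
            for st, e, s in zip(assignments["subtype"], epi_t, str_t)
        ],
        index=assignments.index,
    )
    per = {
        st: float(concordant[assignments["subtype"] == st].mean())
        for st in SUBTYPE_ORDER
        if (assignments["subtype"] == st).any()
    }
    return {
        "overall": float(concordant.mean()),
        "per_subtype": per,
        "tertiles_defined": True,
        "epithelial_tertile": epi_t,
        "stromal_tertile": str_t,
        "concordant": concordant,
    }


class EMTTypingModel:
    """EMT-heterogeneity-based typing of a bulk expression cohort.

    Parameters
    ----------
    expression : ExpressionMatrix
        Gene x sample expression (raw counts/FPKM, log, or z-scores).
    panel : GenePanel, optional
        Marker panel; the built-in default panel when omitted.
    meta : SampleTable, optional
        Sample metadata enabling the clinical-association, traceability and
        survival methods on the fitted results.
    norm : str
        Normalization mode passed to :func:`ehbmt.preprocess.normalize`.
    min_coverage : float
        Minimum fraction of each sub-panel that must be measured.
    k : int
        Number of clusters; the method is defined for k=3.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        panel: Optional[GenePanel] = None,
        meta: Optional[SampleTable] = None,
        norm: str = "auto",
        min_coverage: float = DEFAULT_MIN_COVERAGE,
        k: int = 3,
    ):
        self.expression = expression
        self.panel = panel if panel is not None else default_panel()
        self.meta = meta
        self.norm = norm
        self.min_coverage = min_coverage
        self.k = k
        if meta is not None:
            missing = set(expression.samples) - set(meta.sample_ids)
            if missing:
                raise ValueError(
                    f"samples absent from metadata: {sorted(missing)[:5]}"
                    + ("..." if len(missing) > 5 else "")
                )

    @classmethod
    def from_files(
        cls,
        expression_path,
        meta_path=None,
        panel_path=None,
        orientation: str = "genes_in_rows",
        **kwargs,
    ) -> "EMTTypingModel":
        from .io import read_expression_matrix, read_sample_table
        from .panels import load_panel

        expr = read_expression_matrix(expression_path, orientation=orientation)
        meta = read_sample_table(meta_path) if meta_path else None
        panel = load_panel(panel_path) if panel_path else None
        return cls(expr, panel=panel, meta=meta, **kwargs)

    def fit(self) -> "EMTTypingResults":
        """Run normalize -> select panel -> cluster -> score -> label -> verify."""
        normalized = normalize(self.expression, mode=self.norm)
        pm = select_panel(normalized, self.panel, min_coverage=self.min_coverage)
        Z, cluster_ids = cluster_samples(pm, k=self.k)
        scores = compute_emt_scores(pm)
        labeling = label_clusters(cluster_ids, scores)

        # verification scores use the full measured transcriptome, per sample
        full = normalized.values
        epi_set, str_set = set(self.panel.epithelial), set(self.panel.mesenchymal)
        epi_enr = full.apply(lambda col: enrichment_score(col, epi_set), axis=0)
        str_enr = full.apply(lambda col: enrichment_score(col, str_set), axis=0)

        assignments = pd.DataFrame(
            {
                "sample_id": pm.samples,
                "cluster_id": cluster_ids.values,
                "subtype": [labeling.subtype_of[c] for c in cluster_ids.values],
                "epithelial_score": scores["epithelial_score"].values,
                "mesenchymal_score": scores["mesenchymal_score"].values,
                "delta": scores["delta"].values,
                "epithelial_enrichment": epi_enr.values,
                "stromal_enrichment": str_enr.values,
            }
        )
        report = verify_assignments(assignments)
        if report["tertiles_defined"]:
            assignments["epithelial_tertile"] = report["epithelial_tertile"].values
            assignments["stromal_tertile"] = report["stromal_tertile"].values
            assignments["concordant"] = report["concordant"].values
        return EMTTypingResults(
            model=self,
            assignments=assignments,
            labeling=labeling,
            linkage_matrix=Z,
            panel_matrix=pm,
            concordance={
                k: v
                for k, v in report.items()
                if k in ("overall", "per_subtype", "tertiles_defined")
            },
        )


@dataclass
class EMTTypingResults:
    """Fitted typing: per-sample assignments plus downstream analyses."""

    model: EMTTypingModel
    assignments: pd.DataFrame
    labeling: ClusterLabeling
    linkage_matrix: np.ndarray
    panel_matrix: PanelMatrix
    concordance: dict = field(default_factory=dict)

    # -- summaries ---------------------------------------------------------
    def subtype_proportions(self, by_tissue: bool = False):
        if by_tissue:
            merged = self._with_meta(["tissue"])
            return _stats.subtype_proportions(merged, grouping="tissue")
        return _stats.subtype_proportions(self.assignments)

    def summary(self) -> str:
        props = _stats.subtype_proportions(self.assignments)
        lines = [
            "EMT-heterogeneity typing results",
            "=" * 40,
            f"samples: {len(self.assignments)}    panel: {self.model.panel.name} "
            f"v{self.model.panel.version}",
            f"panel coverage: epithelial {self.panel_matrix.coverage[0]:.0%}, "
            f"mesenchymal {self.panel_matrix.coverage[1]:.0%}",
            "",
            "subtype   n      %    mean delta",
        ]
        for st in SUBTYPE_ORDER:
            if st not in props.index:
                continue
            cid = next(c for c, s in self.labeling.subtype_of.items() if s == st)
            lines.append(
                f"{st:<8}{props.loc[st, 'count']:>4}{props.loc[st, 'percent']:>7.1f}"
                f"{self.labeling.mean_delta[cid]:>12.3f}"
            )
        if self.concordance.get("overall") is not None:
            lines += [
                "",
                f"enrichment concordance: {self.concordance['overall']:.1%} overall "
                + " ".join(
                    f"{k}={v:.1%}" for k, v in self.concordance["per_subtype"].items()
                ),
            ]
        return "\n".join(lines)

    # -- downstream analyses ------------------------------------------------
    def _require_meta(self) -> SampleTable:
        if self.model.meta is None:
            raise ValueError("this analysis requires sample metadata")
        return self.model.meta

    def _with_meta(self, columns) -> pd.DataFrame:
        meta = self._require_meta()
        return self.assignments.merge(
            meta.data[["sample_id", *columns]], on="sample_id", how="inner"
        )

    def association_test(self, covariate: str, include_missing: bool = True):
        return _stats.association_test(
            self.assignments, self._require_meta(), covariate, include_missing
        )

    def transition_analysis(self):
        """Pair samples by patient and tabulate normal -> tumor subtype flows."""
        pairs = _transitions.build_pairs(self._require_meta())
        table = _transitions.transition_table(pairs, self.assignments)
        return pairs, table

    def survival(self, endpoint: str = "os"):
        """Per-subtype KM curves and the global log-rank test.

        Returns ``(curves, (statistic, df, p))`` where ``curves`` maps
        subtype to its :class:`~ehbmt.survival.KMCurve`.
        """
        tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
        merged = self._with_meta([tcol, ecol]).dropna(subset=[tcol, ecol])
        if merged.empty:
            raise ValueError(f"no usable {endpoint} survival records")
        curves = {
            st: km_curve(grp[tcol], grp[ecol].astype(int))
            for st, grp in merged.groupby("subtype")
        }
        test = logrank_test(merged[tcol], merged[ecol].astype(int), merged["subtype"])
        return curves, test

    def to_bundle(self, extra_metadata: Optional[dict] = None) -> ResultBundle:
        meta = {
            "panel": {
                "name": self.model.panel.name,
                "version": self.model.panel.version,
                "n_epithelial": len(self.model.panel.epithelial),
                "n_mesenchymal": len(self.model.panel.mesenchymal),
                "notes": self.model.panel.notes,
            },
            "normalization": self.model.norm,
            "min_coverage": self.model.min_coverage,
            "k": self.model.k,
            "coverage": list(self.panel_matrix.coverage),
            "concordance": self.concordance,
        }
        if extra_metadata:
            meta.update(extra_metadata)
        return ResultBundle(assignments=self.assignments.copy(), metadata=meta)


def classify_cohort(
    matrix: ExpressionMatrix,
    panel: Optional[GenePanel] = None,
    meta: Optional[SampleTable] = None,
    **params,
) -> EMTTypingResults:
    """One-call convenience wrapper: build the model and fit it."""
    return EMTTypingModel(matrix, panel=panel, meta=meta, **params).fit()
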