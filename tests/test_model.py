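"""Subtyping core: panel scores, clustering vs a brute-force oracle,
cluster labeling, rank enrichment, verification and the full pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

import ehbmt
from ehbmt import (
    ExpressionMatrix,
    GenePanel,
    SimulationParams,
    classify_cohort,
    cluster_samples,
    compute_emt_scores,
    enrichment_score,
    label_clusters,
    normalize,
    select_panel,
    simulate_cohort,
    verify_assignments,
)
from ehbmt.model import _tertile_labels


# ---------------------------------------------------------------------------
# independent brute-force complete-linkage oracle

def brute_force_complete_linkage(D: np.ndarray, k: int):
    """Naive agglomeration recomputing the complete-linkage maximum at every
    step; returns (merge heights, partition at k clusters)."""
    clusters = [frozenset([i]) for i in range(len(D))]
    heights = []
    while len(clusters) > k:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(D[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    labels = np.empty(len(D), dtype=int)
    for ci, members in enumerate(clusters):
        for i in members:
            labels[i] = ci
    return heights, labels


def panel_matrix_from(values: np.ndarray, n_epi: int = 2):
    genes = [f"E{i}" for i in range(n_epi)] + [f"M{i}" for i in range(values.shape[0] - n_epi)]
    panel = GenePanel(epithelial=genes[:n_epi], mesenchymal=genes[n_epi:])
    m = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=[f"s{i}" for i in range(values.shape[1])]),
        normalized="raw",
    )
    return select_panel(normalize(m, mode="zscore_only"), panel)


# ---------------------------------------------------------------------------

class TestComputeEmtScores:
    def _pm(self, epi_rows, mes_rows, samples):
        genes = [f"E{i}" for i in range(len(epi_rows))] + [f"M{i}" for i in range(len(mes_rows))]
        panel = GenePanel(epithelial=genes[: len(epi_rows)], mesenchymal=genes[len(epi_rows):])
        vals = pd.DataFrame(epi_rows + mes_rows, index=genes, columns=samples)
        m = ExpressionMatrix(values=vals, normalized="zscore")
        return select_panel(m, panel)

    def test_zero_and_constant_cases(self):
        pm = self._pm([[0.0, 1.0], [0.0, 1.0]], [[0.0, -1.0], [0.0, -1.0]], ["a", "b"])
        scores = compute_emt_scores(pm)
        # sample a: all zeros -> (0, 0, 0); sample b: epi +1, mes -1 -> (1, -1, 2)
        assert scores.loc["a"].tolist() == [0.0, 0.0, 0.0]
        assert scores.loc["b"].tolist() == [1.0, -1.0, 2.0]

    def test_hand_mean_four_genes(self):
        pm = self._pm([[0.5], [1.5]], [[-1.0], [0.0]], ["x"])
        s = compute_emt_scores(pm).loc["x"]
        assert (s["epithelial_score"], s["mesenchymal_score"], s["delta"]) == (1.0, -0.5, 1.5)


class TestClusterSamples:
    def test_three_exact_copies_give_pure_clusters(self):
        rng = np.random.default_rng(0)
        profiles = rng.normal(size=(4, 3))
        X = np.column_stack([profiles[:, i % 3] for i in range(9)]) + 0.0
        pm = panel_matrix_from(X + rng.normal(scale=1e-9, size=X.shape))
        _, ids = cluster_samples(pm, k=3)
        truth = [i % 3 for i in range(9)]
        assert adjusted_rand_score(truth, ids.values) == 1.0

    def test_identical_samples_merge_first_at_height_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 5))
        X[:, 1] = X[:, 0]  # duplicate sample
        pm = panel_matrix_from(X)
        Z, _ = cluster_samples(pm, k=3)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("n", [6, 8])
    def test_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(5, n))
        pm = panel_matrix_from(X)
        Z, ids = cluster_samples(pm, k=3)
        V = pm.values.to_numpy().T
        Vc = V - V.mean(axis=1, keepdims=True)
        D = 1 - np.corrcoef(V)
        np.fill_diagonal(D, 0.0)
        heights, labels = brute_force_complete_linkage(D, k=3)
        np.testing.assert_allclose(Z[: n - 3, 2], heights, atol=1e-9)
        assert adjusted_rand_score(labels, ids.values) == 1.0

    def test_too_few_samples_error(self):
        pm = panel_matrix_from(np.random.default_rng(2).normal(size=(4, 2)))
        with pytest.raises(ValueError, match="at least k=3"):
            cluster_samples(pm, k=3)

    def test_zero_variance_sample_named(self):
        # correlation distance is undefined for a flat panel vector
        from ehbmt.preprocess import PanelMatrix

        X = np.random.default_rng(3).normal(size=(4, 5))
        X[:, 2] = 1.3
        genes = ["E0", "E1", "M0", "M1"]
        panel = GenePanel(epithelial=genes[:2], mesenchymal=genes[2:])
        pm = PanelMatrix(
            values=pd.DataFrame(X, index=genes, columns=[f"s{i}" for i in range(5)]),
            epithelial=tuple(genes[:2]),
            mesenchymal=tuple(genes[2:]),
            coverage=(1.0, 1.0),
            panel=panel,
        )
        with pytest.raises(ValueError, match="s2"):
            cluster_samples(pm, k=3)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 10))
        pm = panel_matrix_from(X)
        _, ids = cluster_samples(pm, k=3)
        perm = rng.permutation(10)
        pm2 = panel_matrix_from(X[:, perm])
        _, ids2 = cluster_samples(pm2, k=3)
        assert adjusted_rand_score(ids.values[perm], ids2.values) == 1.0

    def test_distance_bounds_and_monotone_heights(self):
        rng = np.random.default_rng(5)
        pm = panel_matrix_from(rng.normal(size=(6, 12)))
        Z, _ = cluster_samples(pm, k=3)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()
        assert Z[:, 2].max() <= 2.0 + 1e-9 and Z[:, 2].min() >= 0.0


class TestLabelClusters:
    def _scores(self, deltas, epis=None, cluster_of=None):
        n = len(deltas)
        epis = epis if epis is not None else [d / 2 for d in deltas]
        cluster_of = cluster_of or list(range(1, n + 1))
        scores = pd.DataFrame(
            {
                "epithelial_score": epis,
                "mesenchymal_score": [e - d for e, d in zip(epis, deltas)],
                "delta": deltas,
            },
            index=[f"s{i}" for i in range(n)],
        )
        ids = pd.Series(cluster_of, index=scores.index, name="cluster_id")
        return ids, scores

    def test_ordering(self):
        ids, scores = self._scores([2.0, 0.1, -1.9])
        lab = label_clusters(ids, scores)
        assert [lab.subtype_of[c] for c in (1, 2, 3)] == ["EPC", "HPC", "MPC"]

    def test_permuted_ordering(self):
        ids, scores = self._scores([-1.9, 2.0, 0.1])
        lab = label_clusters(ids, scores)
        assert [lab.subtype_of[c] for c in (1, 2, 3)] == ["MPC", "EPC", "HPC"]

    def test_tie_broken_by_epithelial_mean(self):
        ids, scores = self._scores([1.0, 1.0, -1.0], epis=[0.9, 0.5, -0.5])
        lab = label_clusters(ids, scores)
        assert lab.subtype_of[1] == "EPC" and lab.subtype_of[2] == "HPC"

    def test_full_tie_falls_back_to_cluster_index(self):
        ids, scores = self._scores([1.0, 1.0, -1.0], epis=[0.5, 0.5, -0.5])
        lab = label_clusters(ids, scores)
        assert lab.subtype_of == {1: "EPC", 2: "HPC", 3: "MPC"}

    def test_bijection_and_mean_delta_ordering(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            deltas = rng.normal(size=3).tolist()
            ids, scores = self._scores(deltas)
            lab = label_clusters(ids, scores)
            assert sorted(lab.subtype_of.values()) == ["EPC", "HPC", "MPC"]
            by = {v: lab.mean_delta[k] for k, v in lab.subtype_of.items()}
            assert by["EPC"] >= by["HPC"] >= by["MPC"]

    def test_not_three_clusters_is_error(self):
        ids, scores = self._scores([1.0, -1.0], cluster_of=[1, 2])
        with pytest.raises(ValueError, match="3 clusters"):
            label_clusters(ids, scores)


class TestEnrichmentScore:
    def test_top_block_formula(self):
        # set occupies the top 10 ranks of 100 genes -> (95.5-50.5)/49.5
        expr = pd.Series(np.arange(100, dtype=float), index=[f"G{i}" for i in range(100)])
        top = [f"G{i}" for i in range(90, 100)]
        assert enrichment_score(expr, top) == pytest.approx(45 / 49.5)

    def test_whole_transcriptome_scores_zero(self):
        expr = pd.Series([3.0, 1.0, 2.0], index=list("ABC"))
        assert enrichment_score(expr, list("ABC")) == pytest.approx(0.0)

    def test_empty_intersection_error(self):
        expr = pd.Series([1.0, 2.0], index=["A", "B"])
        with pytest.raises(ValueError, match="no overlap"):
            enrichment_score(expr, ["Z"])

    @settings(max_examples=50, deadline=None)
    @given(
        # 3-dp grid keeps strict monotonicity intact in float arithmetic
        # (a subnormal like 1e-260 would be absorbed by "+ 7.0", creating ties)
        values=st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False).map(
                lambda v: round(v, 3)
            ),
            min_size=4,
            max_size=30,
        ),
        scale=st.floats(min_value=0.1, max_value=5).map(lambda v: round(v, 2)),
    )
    def test_invariant_under_strictly_monotone_transforms(self, values, scale):
        expr = pd.Series(values, index=[f"G{i}" for i in range(len(values))])
        gene_set = list(expr.index[: max(1, len(values) // 3)])
        base = enrichment_score(expr, gene_set)
        assert enrichment_score(np.exp(expr / 60.0), gene_set) == pytest.approx(base)
        assert enrichment_score(expr * scale + 7.0, gene_set) == pytest.approx(base)

    def test_score_bounds(self):
        rng = np.random.default_rng(7)
        expr = pd.Series(rng.normal(size=40), index=[f"G{i}" for i in range(40)])
        for size in (1, 5, 40):
            s = enrichment_score(expr, list(expr.index[:size]))
            assert -1.0 <= s <= 1.0


class TestVerifyAssignments:
    def _idealized(self, n_per=5):
        # enrichment tertiles exactly mirror the subtype labels
        rows = []
        for i, (st_, e, s) in enumerate(
            [("EPC", 1.0, -1.0), ("HPC", 0.0, 0.0), ("MPC", -1.0, 1.0)]
        ):
            for j in range(n_per):
                rows.append(
                    {
                        "sample_id": f"{st_}{j}",
                        "subtype": st_,
                        "epithelial_enrichment": e + j * 1e-3,
                        "stromal_enrichment": s + j * 1e-3,
                    }
                )
        return pd.DataFrame(rows)

    def test_idealized_concordance_is_one(self):
        report = verify_assignments(self._idealized())
        assert report["overall"] == 1.0
        assert set(report["per_subtype"].values()) == {1.0}

    def test_permuted_labels_near_chance(self):
        df = self._idealized(n_per=30)
        rng = np.random.default_rng(8)
        # permutation-derived chance level for this cohort geometry
        chances = []
        for _ in range(200):
            shuffled = df.copy()
            shuffled["subtype"] = rng.permutation(df["subtype"].values)
            chances.append(verify_assignments(shuffled)["overall"])
        mean_chance = float(np.mean(chances))
        spread = float(np.std(chances))
        shuffled = df.copy()
        shuffled["subtype"] = rng.permutation(df["subtype"].values)
        observed = verify_assignments(shuffled)["overall"]
        assert abs(observed - mean_chance) <= 4 * spread
        assert mean_chance < 0.75  # well below the idealized 1.0

    def test_single_sample_tertiles_undefined(self):
        df = self._idealized().iloc[:1]
        report = verify_assignments(df)
        assert report["tertiles_defined"] is False and report["overall"] is None

    def test_empty_input_empty_report(self):
        report = verify_assignments(self._idealized().iloc[:0])
        assert report["overall"] is None

    def test_tertile_ties_go_low(self):
        s = pd.Series([1.0, 1.0, 1.0, 2.0, 3.0, 4.0])
        labs = _tertile_labels(s)
        assert list(labs[:3]) == ["low", "low", "low"]


class TestClassifyCohort:
    def test_separable_limit_recovers_planted_labels(self):
        params = SimulationParams(n_samples=90, noise_sd=1e-6)
        expr, meta, truth = simulate_cohort(params, seed=3)
        res = classify_cohort(expr, meta=meta)
        assert (res.assignments.set_index("sample_id")["subtype"] == truth).all()

    def test_default_cohort_high_ari(self):
        expr, meta, truth = simulate_cohort(SimulationParams(), seed=42)
        res = classify_cohort(expr, meta=meta)
        ari = adjusted_rand_score(truth.values, res.assignments["subtype"].values)
        assert ari >= 0.9

    def test_two_sample_cohort_is_error(self):
        rng = np.random.default_rng(9)
        panel = ehbmt.default_panel()
        m = ExpressionMatrix(
            values=pd.DataFrame(
                rng.normal(size=(38, 2)), index=list(panel.all_genes), columns=["a", "b"]
            )
        )
        with pytest.raises(ValueError, match="at least k=3"):
            classify_cohort(m)

    def test_deterministic_given_inputs(self):
        expr, meta, _ = simulate_cohort(SimulationParams(n_samples=60), seed=11)
        r1 = classify_cohort(expr, meta=meta)
        r2 = classify_cohort(expr, meta=meta)
        pd.testing.assert_frame_equal(r1.assignments, r2.assignments)

    def test_summary_mentions_counts_and_panel(self):
        expr, meta, _ = simulate_cohort(SimulationParams(n_samples=60), seed=12)
        res = classify_cohort(expr, meta=meta)
        text = res.summary()
        assert "emt-default" in text and "EPC" in text and "60" in text
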