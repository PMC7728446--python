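"""Label transfer, composition, randomization test, cluster correlation."""

import numpy as np
import pandas as pd
import pytest

from gastrukit import mapping as mp
from gastrukit import sc
from gastrukit import synthetic as syn


def _paired_datasets(n_ref=60, n_query=40, n_clusters=3, seed=0):
    mk = {f"C{i}": [f"MK{i}_{j}" for j in range(8)] for i in range(n_clusters)}
    stages = {f"C{i}": f"E{6 + i}.5" for i in range(n_clusters)}
    ref_spec = syn.CountSimSpec(
        n_cells_per_cluster={c: n_ref for c in mk}, n_genes=400,
        markers_per_cluster=mk, marker_fold_change=20.0,
        stage_labels=stages, seed=seed, base_seed=1234,
    )
    q_spec = syn.CountSimSpec(
        n_cells_per_cluster={c: n_query for c in mk}, n_genes=400,
        markers_per_cluster=mk, marker_fold_change=20.0,
        stage_labels=stages, seed=seed + 1, base_seed=1234,
    )
    rcm, rtruth = syn.generate_counts(ref_spec)
    qcm, qtruth = syn.generate_counts(q_spec)
    rp, qp = sc.lognormalize(rcm), sc.lognormalize(qcm)
    ref = mp.ReferenceDataset(
        matrix=rp, type_labels=rtruth["cluster"], stage_labels=rtruth["stage"]
    )
    return qp, qtruth, ref, rtruth


class TestSharedEmbedding:
    def test_self_map_identical_embeddings(self):
        qp, _, ref, _ = _paired_datasets()
        q_emb, r_emb, _ = mp.shared_embedding(ref.matrix, ref, n_features=200, n_pc=10)
        np.testing.assert_allclose(q_emb, r_emb, atol=1e-8)

    def test_disjoint_gene_sets_error(self):
        qp, _, ref, _ = _paired_datasets()
        renamed = sc.ProcessedMatrix(
            lognorm=qp.lognorm.set_axis(
                [f"ZZZ{i}" for i in range(len(qp.gene_ids))]
            ),
            cell_meta=qp.cell_meta,
        )
        with pytest.raises(ValueError, match="shared features"):
            mp.shared_embedding(renamed, ref)

    def test_nearest_reference_neighbor_in_matching_cluster(self):
        qp, qtruth, ref, rtruth = _paired_datasets()
        q_emb, r_emb, _ = mp.shared_embedding(qp, ref, n_features=200, n_pc=10)
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=1).fit(r_emb)
        _, idx = nn.kneighbors(q_emb)
        hit = (
            rtruth["cluster"].to_numpy()[idx.ravel()] == qtruth["cluster"].to_numpy()
        ).mean()
        assert hit >= 0.9

    def test_case_insensitive_symbol_matching(self):
        qp, _, ref, _ = _paired_datasets()
        lower = sc.ProcessedMatrix(
            lognorm=qp.lognorm.set_axis([g.lower() for g in qp.gene_ids]),
            cell_meta=qp.cell_meta,
        )
        q_emb, r_emb, genes = mp.shared_embedding(lower, ref, n_features=100, n_pc=5)
        assert len(genes) == 100


class TestTransferLabels:
    def test_exact_neighbor_k1_scores_one(self):
        qp, _, ref, rtruth = _paired_datasets()
        _, r_emb, _ = mp.shared_embedding(ref.matrix, ref, n_features=200, n_pc=10)
        scores = mp.transfer_labels(
            r_emb, r_emb, ref.type_labels.loc[ref.matrix.cell_ids], k=1
        )
        pred, _ = mp.assign_predicted(scores)
        assert (pred.to_numpy() == ref.type_labels.loc[ref.matrix.cell_ids].to_numpy()).all()
        assert np.allclose(scores.scores.to_numpy().max(axis=1), 1.0)

    def test_uniform_weights_fraction_example(self):
        # 4 reference points, 1 query equidistant-ish; neighbors (A,A,A,B)
        ref_emb = np.array([[0.0], [0.1], [0.2], [5.0]])
        labels = pd.Series(["A", "A", "A", "B"])
        q = np.array([[0.1]])
        scores = mp.transfer_labels(q, ref_emb, labels, k=4, weighting="uniform")
        assert scores.scores.loc[0, "A"] == pytest.approx(0.75)
        assert scores.scores.loc[0, "B"] == pytest.approx(0.25)

    def test_rows_sum_to_one(self):
        qp, _, ref, rtruth = _paired_datasets()
        q_emb, r_emb, _ = mp.shared_embedding(qp, ref, n_features=200, n_pc=10)
        for weighting in ("uniform", "gaussian"):
            s = mp.transfer_labels(
                q_emb, r_emb, ref.type_labels.loc[ref.matrix.cell_ids],
                k=10, weighting=weighting,
            )
            np.testing.assert_allclose(s.scores.sum(axis=1), 1.0, atol=1e-9)


class TestAssignPredicted:
    def test_argmax(self):
        s = mp.PredictionScoreMatrix(
            scores=pd.DataFrame([[0.75, 0.25]], columns=pd.Index(["A", "B"]))
        )
        pred, tied = mp.assign_predicted(s)
        assert pred.iloc[0] == "A"
        assert not tied.iloc[0]

    def test_exact_tie_lexicographic_and_flagged(self):
        s = mp.PredictionScoreMatrix(
            scores=pd.DataFrame([[0.5, 0.5]], columns=pd.Index(["B", "A"]))
        )
        pred, tied = mp.assign_predicted(s)
        assert pred.iloc[0] == "A"
        assert tied.iloc[0]

    def test_one_hot_identity(self):
        s = mp.PredictionScoreMatrix(
            scores=pd.DataFrame(np.eye(3), columns=pd.Index(["A", "B", "C"]))
        )
        pred, tied = mp.assign_predicted(s)
        assert list(pred) == ["A", "B", "C"]
        assert not tied.any()


class TestComposition:
    def test_counting_example(self):
        cells = pd.Index([f"c{i}" for i in range(10)])
        clusters = sc.ClusterAssignment(labels=pd.Series(["k0"] * 10, index=cells))
        pred = pd.Series(["E7.0"] * 4 + ["E6.5"] * 6, index=cells)
        tab = mp.composition(clusters, pred).fractions
        assert tab.loc["k0", "E7.0"] == pytest.approx(0.4)

    def test_rows_sum_to_one_and_match_bruteforce(self, rng):
        cells = pd.Index([f"c{i}" for i in range(200)])
        clusters = sc.ClusterAssignment(
            labels=pd.Series(rng.choice(["a", "b", "c"], 200), index=cells)
        )
        pred = pd.Series(rng.choice(["X", "Y"], 200), index=cells)
        tab = mp.composition(clusters, pred).fractions
        np.testing.assert_allclose(tab.sum(axis=1), 1.0)
        for cl in ("a", "b", "c"):
            for lb in ("X", "Y"):
                mask = clusters.labels == cl
                expected = (pred[mask] == lb).sum() / mask.sum()
                assert tab.loc[cl, lb] == pytest.approx(expected)


def _bruteforce_permutation(clusters, predicted, B, seed):
    """Independent re-implementation sharing the seed protocol: one stream,
    clusters in sorted-name order, B x n_i index draws per cluster."""
    labels = clusters.labels
    label_names = sorted(predicted.unique())
    cluster_names = sorted(labels.unique())
    cells = list(labels.index)
    rng = np.random.default_rng(seed)
    pvals = {}
    for cl in cluster_names:
        members = [c for c in cells if labels[c] == cl]
        n_i = len(members)
        obs = {
            lb: sum(predicted[c] == lb for c in members) / n_i
            for lb in label_names
        }
        draws = rng.integers(0, len(cells), size=(B, n_i))
        counts = {lb: 0 for lb in label_names}
        for k in range(B):
            resample = [predicted[cells[i]] for i in draws[k]]
            for lb in label_names:
                perc = sum(x == lb for x in resample) / n_i
                if perc >= obs[lb]:
                    counts[lb] += 1
        pvals[cl] = {lb: (counts[lb] + 1) / (B + 1) for lb in label_names}
    return pvals


class TestPermutationSignificance:
    def test_zero_observed_composition_p_is_one(self):
        cells = pd.Index([f"c{i}" for i in range(20)])
        clusters = sc.ClusterAssignment(
            labels=pd.Series(["a"] * 10 + ["b"] * 10, index=cells)
        )
        pred = pd.Series(["X"] * 10 + ["Y"] * 10, index=cells)
        res = mp.permutation_significance(clusters, pred, B=100, seed=0)
        assert res.p_values.loc["a", "Y"] == pytest.approx(1.0)
        assert res.p_values.loc["b", "X"] == pytest.approx(1.0)

    def test_ceiling_case_p_equals_one_over_b_plus_one(self):
        # cluster "a" is pure X while X is rare overall: every resample of
        # 5 cells from the 100-cell pool almost surely has Perc < 1.0
        cells = pd.Index([f"c{i}" for i in range(100)])
        labels = pd.Series(["b"] * 95 + ["a"] * 5, index=cells)
        pred = pd.Series(["Y"] * 95 + ["X"] * 5, index=cells)
        res = mp.permutation_significance(
            sc.ClusterAssignment(labels=labels), pred, B=1000, seed=1
        )
        assert res.p_values.loc["a", "X"] == pytest.approx(1 / 1001)

    def test_p_values_within_formula_bounds(self, rng):
        cells = pd.Index([f"c{i}" for i in range(60)])
        clusters = sc.ClusterAssignment(
            labels=pd.Series(rng.choice(["a", "b"], 60), index=cells)
        )
        pred = pd.Series(rng.choice(["X", "Y", "Z"], 60), index=cells)
        res = mp.permutation_significance(clusters, pred, B=1000, seed=2)
        vals = res.p_values.to_numpy()
        assert (vals >= 1 / 1001 - 1e-12).all() and (vals <= 1.0).all()

    def test_exact_agreement_with_bruteforce_oracle(self, rng):
        cells = pd.Index([f"c{i}" for i in range(6)])
        clusters = sc.ClusterAssignment(
            labels=pd.Series(["a", "a", "a", "b", "b", "b"], index=cells)
        )
        pred = pd.Series(["X", "X", "Y", "Y", "Y", "X"], index=cells)
        B, seed = 50, 7
        res = mp.permutation_significance(clusters, pred, B=B, seed=seed)
        oracle = _bruteforce_permutation(clusters, pred, B=B, seed=seed)
        for cl in ("a", "b"):
            for lb in ("X", "Y"):
                assert res.p_values.loc[cl, lb] == pytest.approx(
                    oracle[cl][lb], abs=1e-12
                )

    def test_relabeling_clusters_permutes_p_matrix(self, rng):
        cells = pd.Index([f"c{i}" for i in range(40)])
        lab = pd.Series(rng.choice(["a", "b"], 40), index=cells)
        pred = pd.Series(rng.choice(["X", "Y"], 40), index=cells)
        res1 = mp.permutation_significance(
            sc.ClusterAssignment(labels=lab), pred, B=200, seed=3
        )
        # renaming preserving sort order keeps the same draw stream
        renamed = lab.map({"a": "a2", "b": "b2"})
        res2 = mp.permutation_significance(
            sc.ClusterAssignment(labels=renamed), pred, B=200, seed=3
        )
        np.testing.assert_allclose(
            res1.p_values.to_numpy(), res2.p_values.to_numpy()
        )

    def test_empty_cluster_errors(self):
        cells = pd.Index(["c0", "c1"])
        clusters = sc.ClusterAssignment(
            labels=pd.Series(["a", "a"], index=cells).astype(
                pd.CategoricalDtype(["a", "b"])
            )
        )
        pred = pd.Series(["X", "Y"], index=cells)
        with pytest.raises(ValueError):
            mp.permutation_significance(clusters, pred, B=10)


class TestSpearmanClusterCorrelation:
    def test_self_correlation_diagonal_one(self):
        qp, qtruth, ref, rtruth = _paired_datasets()
        cl = sc.ClusterAssignment(labels=qtruth["cluster"])
        feats = qp.gene_ids[:50]
        corr = mp.spearman_cluster_correlation(qp, cl, qp, cl, features=feats)
        np.testing.assert_allclose(np.diag(corr.to_numpy()), 1.0, atol=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        qp, qtruth, ref, rtruth = _paired_datasets()
        cl = sc.ClusterAssignment(labels=qtruth["cluster"])
        feats = qp.gene_ids[:50]
        base = mp.spearman_cluster_correlation(qp, cl, ref.matrix,
                                               sc.ClusterAssignment(labels=rtruth["cluster"]),
                                               features=feats)
        # affine map commutes with averaging and preserves ranks
        warped = sc.ProcessedMatrix(lognorm=qp.lognorm * 3.0 + 1.0,
                                    cell_meta=qp.cell_meta)
        after = mp.spearman_cluster_correlation(warped, cl, ref.matrix,
                                                sc.ClusterAssignment(labels=rtruth["cluster"]),
                                                features=feats)
        np.testing.assert_allclose(base.to_numpy(), after.to_numpy(), atol=1e-12)

    def test_hand_computed_rho_one_swapped_rank(self):
        # cluster averages over single-cell clusters: 4 genes, one adjacent
        # swap between the two sides -> rho = 1 - 6*2/(4*15) = 0.8
        genes = pd.Index(["g1", "g2", "g3", "g4"])
        a = sc.ProcessedMatrix(
            lognorm=pd.DataFrame({"c0": [1.0, 2.0, 3.0, 4.0]}, index=genes),
            cell_meta=pd.DataFrame(index=pd.Index(["c0"])),
        )
        b = sc.ProcessedMatrix(
            lognorm=pd.DataFrame({"d0": [2.0, 1.0, 3.0, 4.0]}, index=genes),
            cell_meta=pd.DataFrame(index=pd.Index(["d0"])),
        )
        ca = sc.ClusterAssignment(labels=pd.Series(["A"], index=pd.Index(["c0"])))
        cb = sc.ClusterAssignment(labels=pd.Series(["B"], index=pd.Index(["d0"])))
        corr = mp.spearman_cluster_correlation(a, ca, b, cb, features=list(genes))
        assert corr.loc["A", "B"] == pytest.approx(0.8)

    def test_constant_vector_flagged_nan(self):
        genes = pd.Index(["g1", "g2", "g3"])
        a = sc.ProcessedMatrix(
            lognorm=pd.DataFrame({"c0": [1.0, 2.0, 3.0]}, index=genes),
            cell_meta=pd.DataFrame(index=pd.Index(["c0"])),
        )
        b = sc.ProcessedMatrix(
            lognorm=pd.DataFrame({"d0": [2.0, 2.0, 2.0]}, index=genes),
            cell_meta=pd.DataFrame(index=pd.Index(["d0"])),
        )
        ca = sc.ClusterAssignment(labels=pd.Series(["A"], index=pd.Index(["c0"])))
        cb = sc.ClusterAssignment(labels=pd.Series(["B"], index=pd.Index(["d0"])))
        with pytest.warns(UserWarning, match="constant"):
            corr = mp.spearman_cluster_correlation(a, ca, b, cb, features=list(genes))
        assert np.isnan(corr.loc["A", "B"])

    def test_too_few_features_errors(self):
        qp, qtruth, ref, rtruth = _paired_datasets()
        cl = sc.ClusterAssignment(labels=qtruth["cluster"])
        with pytest.raises(ValueError):
            mp.spearman_cluster_correlation(qp, cl, qp, cl, features=["MK0_0"])
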