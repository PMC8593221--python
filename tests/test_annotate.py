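import numpy as np
import pytest

from siamcell import (
    DistanceTable,
    ReferenceSet,
    assign_types,
    embed,
    knn_annotate,
    knn_graph,
    novelty_flags,
    reference_distances,
    update_reference,
)
from siamcell.prep import ScaledMatrix
from siamcell.siamese import EmbeddingMatrix


def _table_from_type_means(rows, types):
    """DistanceTable with one reference cell per type, so the per-type means
    are exactly the given values."""
    arr = np.asarray(rows, dtype=float)
    return DistanceTable(
        distances=arr,
        query_ids=[f"q{i}" for i in range(arr.shape[0])],
        ref_labels=list(types),
        ref_ids=[f"r{i}" for i in range(arr.shape[1])],
    )


class TestReferenceDistances:
    def test_query_equal_to_reference_has_zero_distance(self, tiny_trained):
        model, x, panel, _ = tiny_trained
        ref = ReferenceSet.from_panel(model, x, panel)
        i = panel.all_indices("train")[0]
        q = ScaledMatrix(x.values[[i]], [x.cell_ids[i]], list(x.gene_ids))
        dt = reference_distances(model, q, ref)
        # same cell embedded in a different batch: equal up to BLAS
        # summation order, so the self-distance is zero at float precision
        assert dt.distances.min() < 1e-9
        assert dt.ref_ids[dt.distances[0].argmin()] == x.cell_ids[i]

    def test_matches_brute_force_euclidean(self, tiny_trained):
        model, x, panel, _ = tiny_trained
        ref = ReferenceSet.from_panel(model, x, panel)
        q = ScaledMatrix(x.values[:7], x.cell_ids[:7], list(x.gene_ids))
        dt = reference_distances(model, q, ref)
        qe = embed(model, q).values
        for i in range(7):
            for j in range(ref.embeddings.shape[0]):
                brute = np.sqrt(((qe[i] - ref.embeddings[j]) ** 2).sum())
                assert abs(dt.distances[i, j] - brute) < 1e-6

    def test_row_order_matches_query(self, tiny_trained):
        model, x, panel, _ = tiny_trained
        ref = ReferenceSet.from_panel(model, x, panel)
        q = ScaledMatrix(x.values[:4], x.cell_ids[:4], list(x.gene_ids))
        assert reference_distances(model, q, ref).query_ids == x.cell_ids[:4]

    def test_empty_reference_rejected(self, tiny_trained):
        model, x, _, _ = tiny_trained
        empty = ReferenceSet(np.empty((0, model.spec.embedding_dim)), [], [])
        q = ScaledMatrix(x.values[:1], x.cell_ids[:1], list(x.gene_ids))
        with pytest.raises(ValueError, match="empty"):
            reference_distances(model, q, empty)


class TestAssignTypes:
    def test_argmin_of_type_means(self):
        dt = _table_from_type_means([[0.6, 0.2]], ["B", "T"])
        out = assign_types(dt)
        assert out.assigned_type.tolist() == ["T"]
        assert out.mean_distance.tolist() == [0.2]

    def test_tie_broken_lexicographically(self):
        dt = _table_from_type_means([[0.3, 0.3]], ["B", "A"])
        assert assign_types(dt).assigned_type.tolist() == ["A"]

    def test_single_type(self):
        dt = DistanceTable(np.array([[0.4, 0.5]]), ["q0"], ["T", "T"], ["r0", "r1"])
        assert assign_types(dt).assigned_type.tolist() == ["T"]

    def test_invariant_to_reference_permutation(self, tiny_trained):
        model, x, panel, _ = tiny_trained
        ref = ReferenceSet.from_panel(model, x, panel)
        q = ScaledMatrix(x.values[:6], x.cell_ids[:6], list(x.gene_ids))
        dt = reference_distances(model, q, ref)
        perm = np.random.default_rng(0).permutation(len(ref.labels))
        dt_perm = DistanceTable(
            dt.distances[:, perm],
            dt.query_ids,
            [dt.ref_labels[i] for i in perm],
            [dt.ref_ids[i] for i in perm],
        )
        assert assign_types(dt).assigned_type.tolist() == assign_types(dt_perm).assigned_type.tolist()


class TestNoveltyFlags:
    def test_standout_match_not_novel(self):
        # rest has mean 0.9 and sd 0.1 (ddof=1); best 0.1 -> z = 8
        rest = [0.9 - 0.1, 0.9 - np.sqrt(0.005), 0.9 + np.sqrt(0.005), 0.9 + 0.1]
        dt = _table_from_type_means([[0.1] + rest], list("ABCDE"))
        out = novelty_flags(dt)
        assert out.novelty_z.iloc[0] == pytest.approx(8.0)
        assert not out.novel.iloc[0]

    def test_weak_match_flagged_novel(self):
        rest = [0.9 - 0.1, 0.9 - np.sqrt(0.005), 0.9 + np.sqrt(0.005), 0.9 + 0.1]
        dt = _table_from_type_means([[0.8] + rest], list("ABCDE"))
        out = novelty_flags(dt)
        assert out.novelty_z.iloc[0] == pytest.approx(1.0)
        assert bool(out.novel.iloc[0])

    def test_all_equal_comparisons_novel(self):
        dt = _table_from_type_means([[0.5, 0.5, 0.5, 0.5]], list("ABCD"))
        out = novelty_flags(dt)
        assert out.novelty_z.iloc[0] == 0.0
        assert bool(out.novel.iloc[0])

    def test_zero_sd_with_standout_min_not_novel(self):
        dt = _table_from_type_means([[0.1, 0.9, 0.9, 0.9]], list("ABCD"))
        out = novelty_flags(dt)
        assert np.isinf(out.novelty_z.iloc[0])
        assert not out.novel.iloc[0]

    def test_too_few_comparisons_rejected(self):
        dt = _table_from_type_means([[0.1, 0.9]], ["A", "B"])
        with pytest.raises(ValueError, match="at least 3"):
            novelty_flags(dt)

    @pytest.mark.parametrize("shift,scale", [(0.7, 1.0), (0.0, 3.5), (1.2, 0.4)])
    def test_z_invariant_to_shift_and_positive_rescale(self, shift, scale):
        base = np.array([[0.2, 0.8, 0.9, 1.0, 0.7]])
        z0 = novelty_flags(_table_from_type_means(base, list("ABCDE"))).novelty_z[0]
        z1 = novelty_flags(
            _table_from_type_means(base * scale + shift, list("ABCDE"))
        ).novelty_z[0]
        assert z1 == pytest.approx(z0)

    def test_cell_level_option(self, tiny_trained):
        model, x, panel, _ = tiny_trained
        ref = ReferenceSet.from_panel(model, x, panel)
        q = ScaledMatrix(x.values[:5], x.cell_ids[:5], list(x.gene_ids))
        dt = reference_distances(model, q, ref)
        out = novelty_flags(dt, level="cell")
        assert len(out) == 5 and out.novelty_z.notna().all()


class TestKnnAnnotate:
    def _ref(self):
        emb = np.array([[0.0, 0], [0.1, 0], [5, 5], [5.1, 5], [5, 5.1]])
        return ReferenceSet(emb, ["T", "T", "B", "B", "B"], [f"r{i}" for i in range(5)])

    def test_coincident_query_k1(self):
        q = EmbeddingMatrix(np.array([[5.0, 5.0]]), ["q0"])
        out = knn_annotate(self._ref(), q, k=1)
        assert out.assigned_type.tolist() == ["B"]

    def test_majority_vote(self):
        # neighbors at k=3 of the origin: two T cells and one B cell
        q = EmbeddingMatrix(np.array([[0.0, 0.0]]), ["q0"])
        out = knn_annotate(self._ref(), q, k=3)
        assert out.assigned_type.tolist() == ["T"]
        assert "T:2" in out.votes.iloc[0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        ref_emb = rng.normal(size=(50, 4))
        labels = [f"t{i % 4}" for i in range(50)]
        ref = ReferenceSet(ref_emb, labels, [f"r{i}" for i in range(50)])
        q = EmbeddingMatrix(rng.normal(size=(20, 4)), [f"q{i}" for i in range(20)])
        out = knn_annotate(ref, q, k=3)
        for row, qv in zip(out.itertuples(), q.values):
            d = np.sqrt(((ref_emb - qv) ** 2).sum(axis=1))
            nearest = np.argsort(d, kind="stable")[:3]
            got = [labels[i] for i in nearest]
            counts = {t: got.count(t) for t in set(got)}
            best = sorted(
                counts.items(),
                key=lambda kv: (
                    -kv[1],
                    float(np.mean([d[i] for i in nearest if labels[i] == kv[0]])),
                    kv[0],
                ),
            )[0][0]
            assert row.assigned_type == best

    def test_k_larger_than_reference_rejected(self):
        q = EmbeddingMatrix(np.zeros((1, 2)), ["q0"])
        with pytest.raises(ValueError, match="exceeds"):
            knn_annotate(self._ref(), q, k=6)


class TestKnnGraph:
    def test_separated_clusters_have_no_cross_edges(self):
        rng = np.random.default_rng(2)
        a = rng.normal(scale=0.1, size=(15, 3))
        b = rng.normal(scale=0.1, size=(15, 3)) + 100.0
        emb = EmbeddingMatrix(np.vstack([a, b]), [f"c{i}" for i in range(30)])
        labels = ["A"] * 15 + ["B"] * 15
        g = knn_graph(emb, labels, k=3)
        assert g.number_of_nodes() == 30
        cross = [e for e in g.edges if g.nodes[e[0]]["label"] != g.nodes[e[1]]["label"]]
        assert cross == []

    def test_every_node_degree_at_least_k(self):
        rng = np.random.default_rng(3)
        emb = EmbeddingMatrix(rng.normal(size=(25, 4)), [f"c{i}" for i in range(25)])
        g = knn_graph(emb, ["x"] * 25, k=4)
        assert min(dict(g.degree).values()) >= 4

    def test_invalid_k_rejected(self):
        emb = EmbeddingMatrix(np.zeros((5, 2)), [f"c{i}" for i in range(5)])
        with pytest.raises(ValueError, match="positive"):
            knn_graph(emb, ["x"] * 5, k=0)
        with pytest.raises(ValueError, match="at least"):
            knn_graph(emb, ["x"] * 5, k=5)


class TestUpdateReference:
    def test_new_type_added_without_weight_change(self, tiny_trained):
        model, x, panel, _ = tiny_trained
        ref = ReferenceSet.from_panel(model, x, panel)
        before = [(W.copy(), b.copy()) for W, b in model.weights]
        new = ScaledMatrix(
            np.clip(x.values[:30] * 0.9, 0, 1), [f"n{i}" for i in range(30)], list(x.gene_ids)
        )
        ref2 = update_reference(ref, model, new, "Endothelial", n_ref=20, seed=0)
        assert set(ref2.types) == set(ref.types) | {"Endothelial"}
        assert ref2.embeddings.shape[0] == ref.embeddings.shape[0] + 20
        for (W1, b1), (W2, b2) in zip(before, model.weights):
            assert W1.tobytes() == W2.tobytes() and b1.tobytes() == b2.tobytes()

    def test_new_label_assignable(self, tiny_trained):
        model, x, panel, _ = tiny_trained
        ref = ReferenceSet.from_panel(model, x, panel)
        # a distinctive expression pattern shared by all cells of the new type
        pattern = np.zeros(x.values.shape[1])
        pattern[:5] = 1.0
        new = ScaledMatrix(
            np.tile(pattern, (20, 1)), [f"n{i}" for i in range(20)], list(x.gene_ids)
        )
        ref2 = update_reference(ref, model, new, "Fresh", seed=0)
        q = ScaledMatrix(pattern[None, :], ["q0"], list(x.gene_ids))
        dt = reference_distances(model, q, ref2)
        # a query identical to every new-type reference has mean distance 0
        assert assign_types(dt).assigned_type.iloc[0] == "Fresh"

    def test_duplicate_label_needs_merge_flag(self, tiny_trained):
        model, x, panel, _ = tiny_trained
        ref = ReferenceSet.from_panel(model, x, panel)
        new = ScaledMatrix(x.values[:5], [f"n{i}" for i in range(5)], list(x.gene_ids))
        existing = ref.types[0]
        with pytest.raises(ValueError, match="merge"):
            update_reference(ref, model, new, existing, seed=0)
        merged = update_reference(ref, model, new, existing, seed=0, merge=True)
        assert merged.embeddings.shape[0] == ref.embeddings.shape[0] + 5
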