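"""Channel permutations, index build, querying and rank aggregation."""

import numpy as np
import pytest

from ieegsearch.cltrain import EmbeddingModel
from ieegsearch.errors import DataError
from ieegsearch.featex import make_backend
from ieegsearch.xsearch import (
    DIHEDRAL_ORDERINGS,
    RankedResult,
    aggregate_ranks,
    build_index,
    load_index,
    permute_channels,
    query,
    save_index,
)

from conftest import small_patient


class TestPermuteChannels:
    def test_eight_variants_identity_first(self):
        rec = small_patient("P", n=1)[0]
        variants = permute_channels(rec)
        assert len(variants) == 8
        for a, b in zip(variants[0].channels, rec.channels):
            assert a is b

    def test_orderings_are_bijections(self):
        for order in DIHEDRAL_ORDERINGS:
            assert sorted(order) == [0, 1, 2, 3]
        assert len(set(DIHEDRAL_ORDERINGS)) == 8

    def test_group_closure_brute_force(self):
        """Composing any two of the 8 orderings stays inside the set."""
        s = set(DIHEDRAL_ORDERINGS)
        for g in s:
            for h in s:
                composed = tuple(g[h[i]] for i in range(4))
                assert composed in s

    def test_missing_channels_permute_as_missing(self):
        rec = small_patient("P", n=1, missing=(2,))[0]
        for variant, order in zip(permute_channels(rec), DIHEDRAL_ORDERINGS):
            for dst, src in enumerate(order):
                assert (variant.channels[dst] is None) == (src == 1)


class TestAggregateRanks:
    def test_min_dedup(self):
        pooled = [("p1", "r1", 0.5), ("p1", "r1", 0.3), ("p2", "r2", 0.4)]
        res = aggregate_ranks(pooled, k=5)
        assert res.entries == [("p1", "r1", 0.3), ("p2", "r2", 0.4)]

    def test_disjoint_sets_pooled_sort(self):
        pooled = [("a", "r1", 3.0), ("b", "r2", 1.0), ("c", "r3", 2.0)]
        res = aggregate_ranks(pooled, k=2)
        assert res.record_ids == ["r2", "r3"]

    def test_matches_exhaustive_oracle(self):
        """On <=40 pooled tuples the output equals brute-force
        sort-dedup-truncate."""
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(1, 41))
            pooled = [
                (f"p{int(rng.integers(5))}", f"r{int(rng.integers(12))}",
                 float(np.round(rng.uniform(0, 2), 3)))
                for _ in range(n)
            ]
            res = aggregate_ranks(pooled, k=5)
            # oracle: exhaustive best-distance per record, then sorted
            best = {}
            for p, r, d in pooled:
                if r not in best or d < best[r][2]:
                    best[r] = (p, r, d)
            expected = sorted(best.values(), key=lambda t: (t[2], t[0], t[1]))[:5]
            assert res.entries == expected

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            aggregate_ranks([], k=5)

    def test_result_invariants_enforced(self):
        with pytest.raises(DataError):
            RankedResult([("p", "r1", 0.2), ("p", "r1", 0.4)])
        with pytest.raises(DataError):
            RankedResult([("p", "r1", 0.4), ("p", "r2", 0.2)])


@pytest.fixture(scope="module")
def centroid_records():
    records = []
    for i in range(4):
        records += small_patient(f"S{i}", style=i, seed=30 + i, n=2)
    return records


class TestBuildAndQuery:
    def test_feature_index_has_saved_pca(self, centroid_records):
        backend = make_backend("random_init", seed=5)
        idx = build_index(centroid_records, backend, seed=0)
        assert idx.pca_model is not None
        assert idx.vectors.shape[0] == len(centroid_records)
        assert idx.vectors.shape[1] <= 50

    def test_index_determinism(self, centroid_records):
        backend = make_backend("random_init", seed=5)
        a = build_index(centroid_records, backend, seed=0)
        b = build_index(centroid_records, backend, seed=0)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_contrastive_index_vector_length(self, centroid_records):
        model = EmbeddingModel(m=16, seed=0)
        idx = build_index(centroid_records, model,
                          method="contrastive_embedding", seed=0)
        assert idx.vectors.shape == (len(centroid_records), 16)

    def test_contrastive_self_retrieval(self, centroid_records):
        """A query identical to an indexed centroid returns it at rank 1
        with distance zero."""
        model = EmbeddingModel(m=16, seed=0)
        idx = build_index(centroid_records, model,
                          method="contrastive_embedding", seed=0)
        res = query(idx, centroid_records[3], model)
        pid, rid, d = res.entries[0]
        assert rid == centroid_records[3].record_id
        assert d == 0.0

    def test_topk_unique_contract(self, centroid_records):
        backend = make_backend("random_init", seed=5)
        idx = build_index(centroid_records, backend, seed=0)
        res = query(idx, centroid_records[0], backend)
        assert len(res) <= 5
        assert len(set(res.record_ids)) == len(res)
        scores = [s for _, _, s in res.entries]
        assert scores == sorted(scores)

    def test_permutation_invariant_top1_contrastive(self, centroid_records):
        """A channel-permuted query pools over the same variant set and
        returns the same top-1."""
        model = EmbeddingModel(m=16, seed=0)
        idx = build_index(centroid_records, model,
                          method="contrastive_embedding", seed=0)
        rec = centroid_records[5]
        permuted = rec.with_channels([rec.channels[i] for i in (2, 3, 0, 1)])
        a = query(idx, rec, model)
        b = query(idx, permuted, model)
        assert a.entries[0][1] == b.entries[0][1]

    def test_pca_space_mode(self, centroid_records):
        backend = make_backend("random_init", seed=5)
        idx = build_index(centroid_records, backend, seed=0,
                          knn_space="pca_50d")
        res = query(idx, centroid_records[0], backend)
        assert res.entries[0][1] == centroid_records[0].record_id

    def test_save_load_round_trip(self, centroid_records, tmp_path):
        backend = make_backend("random_init", seed=5)
        idx = build_index(centroid_records, backend, seed=0)
        path = tmp_path / "idx.npz"
        save_index(idx, path)
        loaded = load_index(path)
        np.testing.assert_allclose(idx.vectors, loaded.vectors)
        assert loaded.record_ids == idx.record_ids
        q = query(loaded, centroid_records[1], backend)
        assert len(q) > 0

    def test_empty_index_rejected(self):
        with pytest.raises(DataError):
            build_index([], make_backend("random_init", seed=0))


class TestRetrievalBenchmark:
    def test_planted_class_agreement(self, retrieval_benchmark):
        """Queries drawn from each search patient's seizure-band
        distribution retrieve that patient at rank 1 for >=8/10 queries."""
        index, backend, queries, expected = retrieval_benchmark
        hits = 0
        for qrec, pid in zip(queries, expected):
            res = query(index, qrec, backend)
            hits += res.entries[0][0] == pid
        assert hits >= 8
        assert hits / len(queries) > 1.0 / 10.0  # far above chance
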