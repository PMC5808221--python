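"""NN baseline, cost-matrix sparsification, exact RLAP solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tractolap as tl

from conftest import enumerate_min_assignment


def _embed_target(tractogram, p=10, seed=0):
    protos = tl.sff_select_prototypes(tractogram, p=min(p, len(tractogram)), seed=seed)
    emb = tl.embed(tractogram, protos)
    return protos, emb, tl.NeighborIndex(emb)


class TestNnCorrespondence:
    def test_self_subset_maps_to_itself(self, small_tractogram):
        protos, emb_B, index = _embed_target(small_tractogram)
        tract = tl.Tract(small_tractogram, (2, 5, 9), label="self")
        emb_A = tl.embed(tract, protos)
        pairs, costs = tl.nn_correspondence(tract, index, emb_A, small_tractogram)
        assert [pairs[i] for i in range(3)] == [2, 5, 9]
        assert all(c == pytest.approx(0.0, abs=1e-12) for c in costs.values())

    def test_matches_exhaustive_embedding_search(self, small_tractogram, rng):
        protos, emb_B, index = _embed_target(small_tractogram)
        queries = [np.cumsum(rng.normal(size=(15, 3)), axis=0) for _ in range(6)]
        emb_A = tl.embed(queries, protos)
        pairs, _ = tl.nn_correspondence(queries, index, emb_A, small_tractogram)
        full = np.linalg.norm(
            emb_A.vectors[:, None, :] - emb_B.vectors[None, :, :], axis=2
        )
        for i in range(6):
            assert pairs[i] == int(np.argmin(full[i]))

    def test_empty_tract_raises(self, small_tractogram):
        protos, emb_B, index = _embed_target(small_tractogram)
        with pytest.raises(ValueError):
            tl.nn_correspondence([], index, emb_B, small_tractogram)


class TestReducedCostMatrix:
    def test_full_neighbors_gives_dense_matrix(self, small_tractogram):
        protos, emb_B, index = _embed_target(small_tractogram)
        tract = tl.Tract(small_tractogram, (0, 3, 7))
        emb_A = tl.embed(tract, protos)
        C = tl.build_reduced_cost_matrix(
            tract, small_tractogram, emb_A, index, n_neighbors=len(small_tractogram)
        )
        assert C.costs.shape == (3, len(small_tractogram))
        full = tl.mam_distance_matrix(tract.streamlines, small_tractogram.streamlines)
        np.testing.assert_allclose(C.costs, full[:, C.col_ids], atol=1e-12)

    def test_union_bounds(self, small_tractogram):
        protos, emb_B, index = _embed_target(small_tractogram)
        tract = tl.Tract(small_tractogram, (0, 3, 7))
        emb_A = tl.embed(tract, protos)
        C = tl.build_reduced_cost_matrix(
            tract, small_tractogram, emb_A, index, n_neighbors=2
        )
        assert 2 <= C.col_ids.size <= 6

    def test_entries_match_direct_mam(self, small_tractogram, rng):
        protos, emb_B, index = _embed_target(small_tractogram)
        tract = tl.Tract(small_tractogram, (1, 4, 11, 15))
        emb_A = tl.embed(tract, protos)
        C = tl.build_reduced_cost_matrix(
            tract, small_tractogram, emb_A, index, n_neighbors=5
        )
        for _ in range(10):
            i = int(rng.integers(C.k))
            j = int(rng.integers(C.col_ids.size))
            expected = tl.mam_distance(
                tract.streamlines[i], small_tractogram[C.col_ids[j]]
            )
            assert C.costs[i, j] == pytest.approx(expected, abs=1e-12)

    def test_starved_union_raises(self, small_tractogram):
        """Identical example streamlines with n_neighbors=1 give a union
        smaller than the number of rows."""
        protos, emb_B, index = _embed_target(small_tractogram)
        s = small_tractogram[0]
        emb_A = tl.embed([s, s.copy()], protos)
        with pytest.raises(ValueError, match="n_neighbors"):
            tl.build_reduced_cost_matrix(
                [s, s.copy()], small_tractogram, emb_A, index, n_neighbors=1
            )

    def test_row_without_available_column_raises(self):
        with pytest.raises(ValueError, match="no available column"):
            tl.ReducedCostMatrix(
                row_ids=np.arange(2),
                col_ids=np.arange(3),
                costs=np.array([[1.0, 2.0, 3.0], [np.inf, np.inf, np.inf]]),
            )


class TestSolveRlap:
    def test_one_by_one(self):
        C = tl.ReducedCostMatrix(np.array([0]), np.array([0]), np.array([[3.5]]))
        a = tl.solve_rlap(C)
        assert a.pairs == {0: 0}
        assert a.total_cost == 3.5

    def test_zero_diagonal_identity(self):
        cost = np.ones((3, 3)) - np.eye(3)
        C = tl.ReducedCostMatrix(np.arange(3), np.arange(3), cost)
        a = tl.solve_rlap(C)
        assert a.pairs == {0: 0, 1: 1, 2: 2}
        assert a.total_cost == 0.0

    def test_random_matrices_match_enumeration(self, rng):
        """100 random 5x8 integer matrices: exact optimality, exact
        lexicographic tie-break, and the greedy lower bound."""
        for _ in range(100):
            cost = rng.integers(0, 10, size=(5, 8)).astype(float)
            C = tl.ReducedCostMatrix(np.arange(5), np.arange(8), cost)
            a = tl.solve_rlap(C)
            best, lex_cols = enumerate_min_assignment(cost)
            assert a.total_cost == pytest.approx(best, abs=1e-9)
            assert tuple(a.pairs[i] for i in range(5)) == lex_cols
            assert cost.min(axis=1).sum() <= a.total_cost + 1e-9
            cols = list(a.pairs.values())
            assert len(set(cols)) == len(cols)  # injective

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        k=st.integers(1, 6),
        m=st.integers(6, 9),
        data=st.data(),
    )
    def test_optimality_property(self, k, m, data):
        elems = st.floats(0, 100, allow_nan=False, width=32)
        rows = data.draw(
            st.lists(st.lists(elems, min_size=m, max_size=m), min_size=k, max_size=k)
        )
        cost = np.array(rows, dtype=float)
        C = tl.ReducedCostMatrix(np.arange(k), np.arange(m), cost)
        a = tl.solve_rlap(C)
        best, _ = enumerate_min_assignment(cost)
        assert a.total_cost == pytest.approx(best, rel=1e-9, abs=1e-9)

    def test_unavailable_entries_respected(self):
        cost = np.array([[np.inf, 1.0], [2.0, np.inf]])
        C = tl.ReducedCostMatrix(np.arange(2), np.arange(2), cost)
        a = tl.solve_rlap(C)
        assert a.pairs == {0: 1, 1: 0}

    def test_figure1_matrix_recovers_identity(self, figure1):
        full = tl.mam_distance_matrix(
            figure1.example_tract.streamlines, figure1.target_tract.streamlines
        )
        C = tl.ReducedCostMatrix(np.arange(5), np.arange(5), full)
        a = tl.solve_rlap(C)
        assert a.pairs == {i: i for i in range(5)}


@pytest.fixture(scope="module")
def scene():
    config = tl.PopulationConfig(n_subjects=2, n_distractors=60, seed=42)
    target, example = tl.generate_population(config)
    protos = tl.sff_select_prototypes(target.tractogram, p=20, seed=0)
    emb_B = tl.embed(target.tractogram, protos)
    index = tl.NeighborIndex(emb_B)
    t_A = example.tractogram.subset(example.true_tract.indices)
    emb_A = tl.embed(t_A, protos)
    return target, t_A, emb_A, index


class TestSparsification:
    """Reduced-matrix solves against the full matrix, on a synthetic subject."""

    def test_full_neighbors_reproduces_full_matrix_assignment(self, scene):
        target, t_A, emb_A, index = scene
        M = len(target.tractogram)
        assert M <= 200
        C_red = tl.build_reduced_cost_matrix(
            t_A, target.tractogram, emb_A, index, n_neighbors=M
        )
        a_red = tl.solve_rlap(C_red)
        full = tl.mam_distance_matrix(t_A, target.tractogram.streamlines)
        a_full = tl.solve_rlap(
            tl.ReducedCostMatrix(np.arange(len(t_A)), np.arange(M), full)
        )
        assert a_red.pairs == a_full.pairs
        assert a_red.total_cost == pytest.approx(a_full.total_cost, rel=1e-12)

    def test_total_cost_nonincreasing_in_neighbors(self, scene):
        target, t_A, emb_A, index = scene
        M = len(target.tractogram)
        totals = []
        for n_nb in (5, 10, 20, 40, 80, M):
            C = tl.build_reduced_cost_matrix(
                t_A, target.tractogram, emb_A, index, n_neighbors=n_nb
            )
            totals.append(tl.solve_rlap(C).total_cost)
        assert all(b <= a + 1e-9 for a, b in zip(totals, totals[1:]))


class TestSingleExampleSegmentation:
    def test_self_segmentation_recovers_tract_at_zero_cost(self, small_tractogram):
        tract = tl.Tract(small_tractogram, (1, 6, 12))
        pairs, costs, total, indices = tl.segment_from_single_example(
            tract, small_tractogram, n_neighbors=len(small_tractogram), n_prototypes=8
        )
        assert indices == (1, 6, 12)
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_displaced_bundle_recovered_by_lap_not_nn(self):
        """With a shift above the bundle spacing, the assignment recovers the
        planted homologs while greedy NN collapses onto a strict subset."""
        config = tl.PopulationConfig(
            n_subjects=2,
            n_distractors=40,
            bundle_size_sd=0.0,
            jitter_mm=0.0,
            seed=77,
        )
        target, example = tl.generate_population(config)
        t_A = [
            example.tractogram[example.homolog_map[c]]
            for c in sorted(example.homolog_map)
        ]
        true_in_target = tuple(
            sorted(target.homolog_map[c] for c in sorted(example.homolog_map))
        )
        _, _, _, lap_idx = tl.segment_from_single_example(
            t_A, target.tractogram, mode="lap", n_prototypes=20, seed=0
        )
        _, _, _, nn_idx = tl.segment_from_single_example(
            t_A, target.tractogram, mode="nn", n_prototypes=20, seed=0
        )
        assert lap_idx == true_in_target
        assert set(nn_idx) < set(true_in_target)

    def test_nn_and_lap_coincide_without_displacement(self):
        config = tl.PopulationConfig(
            n_subjects=2,
            n_distractors=40,
            bundle_size_sd=0.0,
            displacement_mm=0.0,
            jitter_mm=0.0,
            seed=5,
        )
        target, example = tl.generate_population(config)
        t_A = example.tractogram.subset(example.true_tract.indices)
        _, _, _, lap_idx = tl.segment_from_single_example(
            t_A, target.tractogram, mode="lap", n_prototypes=20, seed=0
        )
        _, _, _, nn_idx = tl.segment_from_single_example(
            t_A, target.tractogram, mode="nn", n_prototypes=20, seed=0
        )
        assert lap_idx == nn_idx
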