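"""Encoding, projection, classification and the constraint system."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from latentmark import (
    decode_index,
    encode_history,
    enumerate_latent_histories,
    initialize_frequencies,
    process_data,
    project_latent,
)
from latentmark.histories import HistoryError, LatentHistory

from conftest import brute_force_feasible


class TestEncoding:
    @pytest.mark.parametrize(
        "codes,expected",
        [((1, 1), 7), ((0, 0), 1), ((4, 3), 24), ((1, 2), 8), ((0, 2, 0), 11)],
    )
    def test_base5_index(self, codes, expected):
        assert encode_history(codes) == expected

    @pytest.mark.parametrize("T", [1, 2, 3, 4])
    def test_roundtrip_exhaustive(self, T):
        for j in range(1, 5**T + 1):
            assert encode_history(decode_index(j, T)) == j

    def test_decode_examples(self):
        assert decode_index(8, 2) == (1, 2)
        assert decode_index(1, 3) == (0, 0, 0)

    def test_invalid_inputs(self):
        with pytest.raises(HistoryError):
            encode_history((0, 5))
        with pytest.raises(HistoryError):
            decode_index(0, 2)
        with pytest.raises(HistoryError):
            decode_index(26, 2)

    def test_latent_history_checks_index(self):
        h = LatentHistory((1, 2))
        assert h.index_j == 8
        with pytest.raises(HistoryError):
            LatentHistory((1, 2), index_j=9)

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_property(self, codes):
        T = len(codes)
        assert decode_index(encode_history(codes), T) == tuple(codes)


class TestEnumeration:
    @pytest.mark.parametrize("T", [1, 2, 3])
    def test_counts_per_data_type(self, T):
        assert len(enumerate_latent_histories(T, "sometimes")) == 5**T
        assert len(enumerate_latent_histories(T, "never")) == 4**T
        assert len(enumerate_latent_histories(T, "always")) == 4**T

    def test_ordered_by_index(self):
        hists = enumerate_latent_histories(2, "sometimes")
        assert [encode_history(h) for h in hists] == list(range(1, 26))


class TestProjection:
    def test_split_record(self):
        assert project_latent((1, 2)) == ((1, 0), (0, 2), None)

    def test_simultaneous_becomes_known(self):
        assert project_latent((3, 4)) == (None, None, (3, 4))

    def test_all_zero_yields_nothing(self):
        assert project_latent((0, 0)) == (None, None, None)

    def test_data_type_constraints(self):
        with pytest.raises(HistoryError):
            project_latent((4, 0), "never")
        with pytest.raises(HistoryError):
            project_latent((3, 0), "always")

    @pytest.mark.parametrize("T", [2, 3])
    def test_map_columns_match_projection(self, T, rng):
        """Aggregating the projections of the map's latent histories must
        reproduce exactly the A-matrix rows."""
        obs_rows = []
        for _ in range(5):
            codes = rng.integers(0, 4, size=T)
            if not codes.any():
                codes[0] = 1
            t1, t2, kn = project_latent(tuple(codes), "never")
            for rec in (t1, t2, kn):
                if rec is not None:
                    obs_rows.append(rec)
        obs, lmap = process_data(np.array(obs_rows), "never")
        for h, row in zip(lmap.histories, lmap.A):
            t1, t2, kn = project_latent(h, "never")
            produced = [r for r in (t1, t2, kn) if r is not None]
            labelled = [lmap.class_labels[c][1] for c in np.flatnonzero(row)]
            assert sorted(produced) == sorted(labelled)


class TestProcessData:
    def test_bobcat_style_classification(self):
        mat = [[0, 1, 1], [1, 0, 0], [0, 2, 0], [2, 0, 2], [0, 2, 0]]
        obs, lmap = process_data(mat, "never")
        assert (obs.n1, obs.n2, obs.n_known) == (2, 3, 0)

    def test_known_by_code4_and_flag(self):
        mat = [[1, 4], [1, 2]]
        obs, _ = process_data(mat, "sometimes", known_flags=[False, True])
        assert obs.n_known == 2

    def test_mixed_row_without_flag_rejected(self):
        with pytest.raises(HistoryError):
            process_data([[1, 2]], "never")

    def test_empty_matrix_rejected(self):
        with pytest.raises(HistoryError):
            process_data(np.zeros((0, 3)), "never")

    def test_all_zero_row_rejected(self):
        with pytest.raises(HistoryError):
            process_data([[0, 0], [1, 0]], "never")

    def test_code4_under_never_rejected(self):
        with pytest.raises(HistoryError):
            process_data([[1, 4]], "never")

    def test_covariate_length_checked(self):
        import pandas as pd

        with pytest.raises(HistoryError):
            process_data([[1, 0]], "never", covariates=pd.DataFrame({"c": [1.0]* 3}))

    def test_always_excludes_overlapping_merges(self):
        obs, lmap = process_data([[1, 0], [2, 0]], "always")
        # overlapping (occasion-1) merge would need a nonsimultaneous code 3
        assert all(3 not in h for h in lmap.histories)

    def test_two_record_feasible_set(self, two_record_toy):
        """One (1,0) and one (0,2) record: either two separate individuals
        or one individual detected by both types."""
        obs, lmap = two_record_toy
        feas = brute_force_feasible(lmap)
        configs = {
            tuple(sorted(h for h, c in zip(lmap.histories, x) for _ in range(c)))
            for x in feas
        }
        assert configs == {tuple(sorted([(1, 0), (0, 2)])), ((1, 2),)}


class TestConstraintSystem:
    def test_basis_spans_kernel(self, rng):
        sim_rows = []
        for _ in range(6):
            codes = tuple(int(c) for c in rng.integers(0, 4, size=3))
            for rec in project_latent(codes, "never"):
                if rec is not None:
                    sim_rows.append(rec)
        if not sim_rows:
            sim_rows = [(1, 0, 0)]
        obs, lmap = process_data(np.array(sim_rows), "never")
        for b in lmap.basis:
            assert np.array_equal(lmap.A.T @ b, np.zeros(len(lmap.observed_counts)))
        # basis size equals kernel dimension
        rank = np.linalg.matrix_rank(lmap.A.T.astype(float))
        assert lmap.basis.shape[0] == lmap.n_histories - rank

    def test_a_entries_binary(self, two_record_toy):
        _, lmap = two_record_toy
        assert set(np.unique(lmap.A)) <= {0, 1}

    def test_initialize_no_match(self, two_record_toy):
        _, lmap = two_record_toy
        x = initialize_frequencies(lmap)
        assert lmap.is_feasible(x)
        assert x.sum() == 2  # each record its own individual

    def test_known_record_pinned(self):
        obs, lmap = process_data([[1, 4], [1, 0]], "sometimes")
        x = initialize_frequencies(lmap)
        known_idx = np.flatnonzero(lmap.is_known)
        assert x[known_idx].tolist() == [1]
        # basis vectors never touch the known coordinate
        assert np.all(lmap.basis[:, known_idx] == 0)

    def test_feasibility_preserved_by_basis(self, rng):
        obs, lmap = process_data(
            [[1, 0, 1], [0, 2, 0], [1, 0, 0], [0, 0, 2]], "never"
        )
        x = initialize_frequencies(lmap)
        for b in lmap.basis:
            y = x + b
            if np.all(y >= 0):
                assert lmap.is_feasible(y)

    def test_n_bounded_by_record_count(self):
        obs, lmap = process_data([[1, 0], [0, 2], [1, 1]], "never")
        for x in brute_force_feasible(lmap):
            assert x.sum() <= obs.n1 + obs.n2 + obs.n_known
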