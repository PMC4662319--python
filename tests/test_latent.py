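"""Feasible-set Metropolis moves: nonnegativity, reversibility, exactness."""

import numpy as np
import pytest

from latentmark import SamplerConfig, initialize_frequencies, process_data
from latentmark._engine import SlotPool, latent_step
from latentmark.latent import accept_move, propose_move

from conftest import brute_force_feasible, exact_state_probs


def _random_cells(lmap, rng):
    return np.log(rng.uniform(0.05, 1.0, size=lmap.n_histories))


class TestProposeMove:
    def test_never_proposes_negative(self, rng):
        obs, lmap = process_data(
            [[1, 0, 1], [1, 0, 0], [0, 2, 0], [0, 2, 2], [2, 0, 0]], "never"
        )
        x = initialize_frequencies(lmap)
        cfg = SamplerConfig(maxnumbasis=3)
        for _ in range(500):
            x_prop, _ = propose_move(x, lmap, cfg, rng)
            assert np.all(x_prop >= 0)
            assert lmap.is_feasible(x_prop)
            if rng.uniform() < 0.5 and not np.array_equal(x_prop, x):
                x = x_prop  # wander a bit

    def test_no_moves_returns_unchanged(self, rng):
        # single-mark data: no type-2 records, empty basis
        obs, lmap = process_data([[1, 0], [0, 1]], "never")
        x = initialize_frequencies(lmap)
        x_prop, ratio = propose_move(x, lmap, SamplerConfig(1), rng)
        assert np.array_equal(x_prop, x)
        assert ratio == 0.0

    def test_two_state_toy_toggles(self, two_record_toy, rng):
        obs, lmap = two_record_toy
        split = initialize_frequencies(lmap)
        merged = np.array([0, 0, 1])
        xp, _ = propose_move(split, lmap, SamplerConfig(1), rng)
        assert np.array_equal(xp, merged)
        xp, _ = propose_move(merged, lmap, SamplerConfig(1), rng)
        assert np.array_equal(xp, split)


class TestAcceptMove:
    def test_identity_proposal_accepted(self, two_record_toy, rng):
        _, lmap = two_record_toy
        x = initialize_frequencies(lmap)
        x_next, accepted = accept_move(x, x.copy(), 0.0, lambda v: 0.0, rng)
        assert accepted and np.array_equal(x_next, x)

    def test_symmetric_toy_accepts_both_ways(self, two_record_toy, rng):
        """With equal complete-data probabilities and the count factors
        cancelled, the two-state toggle is always accepted."""
        _, lmap = two_record_toy
        split = initialize_frequencies(lmap)
        merged = np.array([0, 0, 1])
        for x, xp in [(split, merged), (merged, split)]:
            accepted = [
                accept_move(x, xp, 0.0, lambda v: 0.0, rng)[1] for _ in range(50)
            ]
            # log target equal -> acceptance prob 1
            assert all(accepted)


class TestStationarity:
    @pytest.mark.parametrize("maxnumbasis", [1, 2])
    def test_two_state_exact_probabilities(self, two_record_toy, maxnumbasis, rng):
        obs, lmap = two_record_toy
        log_cells = _random_cells(lmap, rng)
        feas = brute_force_feasible(lmap)
        exact = exact_state_probs(feas, log_cells)
        x = initialize_frequencies(lmap)
        pool = SlotPool.from_frequencies(x, ())
        counts = {tuple(f): 0 for f in feas}
        n_iter = 20000
        for _ in range(n_iter):
            x, _ = latent_step(
                x, lmap, pool, SamplerConfig(maxnumbasis), rng,
                lambda h, z: log_cells[h], lambda m, r: {},
            )
            counts[tuple(x)] += 1
        for f, p in zip(feas, exact):
            emp = counts[tuple(f)] / n_iter
            se = np.sqrt(p * (1 - p) / (n_iter / 20))
            assert abs(emp - p) < 3 * se + 0.01

    def test_duplicate_records_exact(self, rng):
        """Duplicate observed records exercise the count/choice factors."""
        obs, lmap = process_data([[1, 0]] * 2 + [[0, 2]] * 2, "never")
        log_cells = np.log(np.array([0.3, 0.25, 0.12]))
        feas = brute_force_feasible(lmap)
        exact = exact_state_probs(feas, log_cells)
        x = initialize_frequencies(lmap)
        pool = SlotPool.from_frequencies(x, ())
        counts = {tuple(f): 0 for f in feas}
        n_iter = 60000
        for _ in range(n_iter):
            x, _ = latent_step(
                x, lmap, pool, SamplerConfig(2), rng,
                lambda h, z: log_cells[h], lambda m, r: {},
            )
            counts[tuple(x)] += 1
        for f, p in zip(feas, exact):
            emp = counts[tuple(f)] / n_iter
            se = np.sqrt(p * (1 - p) / (n_iter / 30))
            assert abs(emp - p) < 3 * se + 0.01, (tuple(f), emp, p)

    def test_detailed_balance_empirical(self, two_record_toy, rng):
        obs, lmap = two_record_toy
        log_cells = np.log(np.array([0.4, 0.3, 0.35]))
        feas = brute_force_feasible(lmap)
        exact = exact_state_probs(feas, log_cells)
        labels = {tuple(f): i for i, f in enumerate(feas)}
        x = initialize_frequencies(lmap)
        pool = SlotPool.from_frequencies(x, ())
        trans = np.zeros((2, 2))
        prev = labels[tuple(x)]
        n_iter = 40000
        for _ in range(n_iter):
            x, _ = latent_step(
                x, lmap, pool, SamplerConfig(1), rng,
                lambda h, z: log_cells[h], lambda m, r: {},
            )
            cur = labels[tuple(x)]
            trans[prev, cur] += 1
            prev = cur
        # empirical flow balance: pi_i P(i->j) ~ pi_j P(j->i)
        f01, f10 = trans[0, 1] / n_iter, trans[1, 0] / n_iter
        assert abs(f01 - f10) < 4 * np.sqrt(max(f01, f10) / n_iter) + 0.01

    def test_feasibility_conserved_under_long_run(self, rng):
        obs, lmap = process_data(
            [[1, 0, 1], [0, 2, 0], [1, 0, 0], [0, 0, 2], [2, 2, 0]], "never"
        )
        log_cells = _random_cells(lmap, rng)
        x = initialize_frequencies(lmap)
        pool = SlotPool.from_frequencies(x, ())
        for _ in range(2000):
            x, _ = latent_step(
                x, lmap, pool, SamplerConfig(2), rng,
                lambda h, z: log_cells[h], lambda m, r: {},
            )
            assert lmap.is_feasible(x)
            assert np.array_equal(pool.frequencies(lmap.n_histories), x)

    def test_irreducibility_on_random_instances(self, rng):
        """Every brute-force feasible configuration is visited."""
        for trial in range(5):
            n_rec = int(rng.integers(2, 5))
            rows = []
            for _ in range(n_rec):
                kind = rng.integers(2)
                row = np.zeros(3, dtype=int)
                occ = rng.integers(0, 3, size=int(rng.integers(1, 3)))
                row[occ] = 1 + kind
                rows.append(row)
            try:
                obs, lmap = process_data(np.array(rows), "never")
            except Exception:
                continue
            feas = brute_force_feasible(lmap)
            x = initialize_frequencies(lmap)
            pool = SlotPool.from_frequencies(x, ())
            visited = set()
            for _ in range(4000):
                x, _ = latent_step(
                    x, lmap, pool, SamplerConfig(2), rng,
                    lambda h, z: 0.0 * np.asarray(h, dtype=float),
                    lambda m, r: {},
                )
                visited.add(tuple(x))
            assert visited == {tuple(f) for f in feas}
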