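import numpy as np
import pytest

from climprior.grid import SpeciesRecord
from climprior.prioritize import (
    ConservationFeature,
    PrioritizationProblem,
    PrioritizerState,
    build_problem,
    marginal_loss_abf,
    marginal_loss_basic,
    performance_curves,
    rank_cells,
    top_fraction,
)


# ---------------------------------------------------------------------------
# independent brute-force greedy oracle (plain loops, no shared code paths)


def oracle_removal_order(q, w, cost, locked, rule, z):
    """Reference greedy: recompute every delta with explicit loops each
    step, remove the smallest (ties: lowest cell id), locked cells last by
    ascending terminal delta."""
    n, f = q.shape
    remaining = set(range(n))
    Q = [sum(q[i][j] for i in range(n)) for j in range(f)]

    def delta(i):
        if rule == "basic":
            best = 0.0
            for j in range(f):
                if Q[j] > 0:
                    best = max(best, w[j] * q[i][j] / Q[j])
            return best / cost[i]
        total = 0.0
        for j in range(f):
            total += w[j] * (Q[j] ** z - max(Q[j] - q[i][j], 0.0) ** z)
        return total / cost[i]

    order = []
    while any(i in remaining and not locked[i] for i in range(n)):
        cands = sorted(i for i in remaining if not locked[i])
        deltas = [delta(i) for i in cands]
        best = cands[int(np.argmin(deltas))]
        order.append(best)
        remaining.discard(best)
        for j in range(f):
            Q[j] = max(Q[j] - q[best][j], 0.0)
    locked_ids = sorted(i for i in remaining)
    locked_ids.sort(key=lambda i: (delta(i), i))
    return order + locked_ids


def random_instance(rng, max_cells=12, max_features=4):
    n = int(rng.integers(3, max_cells + 1))
    f = int(rng.integers(1, max_features + 1))
    q = rng.random((n, f)) * (rng.random((n, f)) > 0.2)
    q[0] += 1e-3  # keep every feature non-empty
    q = q / q.sum(axis=0)
    w = rng.choice([1.0, 2.0, 3.0, 4.0, 5.0], size=f)
    cost = 1.0 + rng.random(n) if rng.random() < 0.5 else np.ones(n)
    locked = rng.random(n) < 0.2 if rng.random() < 0.5 else np.zeros(n, bool)
    if locked.all():
        locked[0] = False
    features = [ConservationFeature(f"f{j}", w[j], q[:, j]) for j in range(f)]
    z = float(rng.choice([0.25, 0.5, 1.0]))
    return q, w, cost, locked, features, z


class TestMarginalLoss:
    def _problem(self, q, w, cost, rule="basic", z=0.25):
        features = [ConservationFeature(f"f{j}", w[j], q[:, j]) for j in range(q.shape[1])]
        return PrioritizationProblem(features, cost, np.zeros(q.shape[0], bool), rule, z)

    def test_basic_single_feature_term(self):
        q = np.array([[0.2], [0.8]])
        p = self._problem(q, [1.0], np.ones(2))
        state = PrioritizerState(np.ones(2, bool), np.array([0.4]))
        assert marginal_loss_basic(0, state, p) == pytest.approx(0.5)

    def test_basic_takes_max_over_features(self):
        q = np.array([[0.5, 0.8], [0.5, 0.2]])
        p = self._problem(q, [1.0, 1.0], np.ones(2))
        state = PrioritizerState(np.ones(2, bool), np.array([1.0, 1.0]))
        assert marginal_loss_basic(0, state, p) == pytest.approx(0.8)

    def test_doubling_cost_halves_loss(self):
        q = np.array([[0.3], [0.7]])
        base = self._problem(q, [2.0], np.ones(2))
        double = self._problem(q, [2.0], np.array([2.0, 1.0]))
        state = PrioritizerState(np.ones(2, bool), np.array([1.0]))
        assert marginal_loss_basic(0, state, double) == pytest.approx(
            marginal_loss_basic(0, state, base) / 2
        )
        assert marginal_loss_abf(0, state, double) == pytest.approx(
            marginal_loss_abf(0, state, base) / 2
        )

    def test_abf_linear_case_reduces_to_weighted_sum(self):
        q = np.array([[0.1, 0.3], [0.9, 0.7]])
        p = self._problem(q, [2.0, 5.0], np.ones(2), rule="abf", z=1.0)
        state = PrioritizerState(np.ones(2, bool), q.sum(axis=0))
        assert marginal_loss_abf(0, state, p) == pytest.approx(2 * 0.1 + 5 * 0.3)

    def test_abf_worthless_cell_has_zero_loss(self):
        q = np.array([[0.0, 0.0], [1.0, 1.0]])
        p = self._problem(q, [1.0, 1.0], np.ones(2), rule="abf", z=0.25)
        state = PrioritizerState(np.ones(2, bool), q.sum(axis=0))
        assert marginal_loss_abf(0, state, p) == 0.0

    def test_abf_quarter_power_matches_closed_form(self):
        q = np.array([[0.25, 0.1], [0.75, 0.9]])
        w = [1.0, 3.0]
        p = self._problem(q, w, np.array([1.5, 1.0]), rule="abf", z=0.25)
        Q = np.array([1.0, 1.0])
        state = PrioritizerState(np.ones(2, bool), Q)
        expected = (
            1.0 * (1.0**0.25 - 0.75**0.25) + 3.0 * (1.0**0.25 - 0.9**0.25)
        ) / 1.5
        assert marginal_loss_abf(0, state, p) == pytest.approx(expected)


class TestBuildProblem:
    def test_uniform_feature_normalizes_to_inverse_n(self):
        p = build_problem({"f": np.ones(8)})
        assert np.allclose(p.features[0].q, 1 / 8)

    def test_iucn_weights_attached_to_species_features(self):
        species = [SpeciesRecord("sp1", "CR"), SpeciesRecord("sp2", "LC")]
        p = build_problem(
            {"sp1": np.ones(4), "sp2": np.ones(4), "vegetation": np.ones(4)},
            species=species, extra_weights={"vegetation": 5.0},
        )
        weights = {f.feature_id: f.weight for f in p.features}
        assert weights == {"sp1": 4.0, "sp2": 1.0, "vegetation": 5.0}

    def test_missing_cost_defaults_to_one(self):
        p = build_problem({"f": np.ones(5)})
        assert (p.cost == 1).all()

    def test_empty_feature_rejected(self):
        with pytest.raises(ValueError, match="empty feature"):
            build_problem({"f": np.zeros(5)})


class TestRankCells:
    def test_complementarity_keeps_the_irreplaceable_cell(self):
        # species A only in cell 0; everything else richer in cell 1
        p = build_problem({
            "a": np.array([1.0, 0.0, 0.0]),
            "b": np.array([0.1, 0.6, 0.3]),
        })
        result = rank_cells(p)
        assert result.removal_order[-1] == 0  # removed last = top priority

    def test_locked_cell_with_no_value_outranks_unlocked(self):
        locked = np.array([True, False, False])
        p = build_problem({"f": np.array([0.0, 0.5, 0.5]) + 1e-12}, locked=locked)
        result = rank_cells(p)
        assert result.rank_fraction[0] > result.rank_fraction[1]
        assert result.rank_fraction[0] > result.rank_fraction[2]

    def test_neutral_reduction_sorts_by_representation(self, rng):
        q = rng.random(9)
        p = build_problem({"f": q}, rule="abf", z=1.0)
        result = rank_cells(p)
        assert (result.removal_order == np.argsort(q, kind="stable")).all()

    def test_rank_fractions_are_a_permutation(self, rng):
        q, w, cost, locked, features, z = random_instance(rng)
        p = PrioritizationProblem(features, cost, locked, "abf", z)
        result = rank_cells(p)
        n = cost.size
        assert sorted(result.rank_fraction) == pytest.approx(
            [(i + 1) / n for i in range(n)]
        )

    @pytest.mark.parametrize("rule", ["basic", "abf"])
    def test_matches_brute_force_oracle(self, rule, rng):
        for _ in range(60):
            q, w, cost, locked, features, z = random_instance(rng)
            p = PrioritizationProblem(features, cost, locked, rule, z)
            result = rank_cells(p)
            expected = oracle_removal_order(q, w, cost, locked, rule, z)
            assert result.removal_order.tolist() == expected

    def test_total_value_is_non_increasing(self, rng):
        q, w, cost, locked, features, z = random_instance(rng)
        p = PrioritizationProblem(features, cost, locked, "abf", z)
        result = rank_cells(p)
        value = (result.curve_features**z * w).sum(axis=1)
        assert (np.diff(value) <= 1e-9).all()

    def test_lock_dominance(self, rng):
        for _ in range(10):
            q, w, cost, locked, features, z = random_instance(rng)
            if not locked.any():
                locked[0] = True
            p = PrioritizationProblem(features, cost, locked, "abf", z)
            result = rank_cells(p)
            assert result.rank_fraction[locked].min() > result.rank_fraction[~locked].max()


class TestPerformanceCurves:
    def test_curves_start_at_full_representation(self, rng):
        q, w, cost, locked, features, z = random_instance(rng)
        result = rank_cells(PrioritizationProblem(features, cost, locked, "abf", z))
        assert result.curve_landscape[0] == 1.0
        assert np.allclose(result.curve_features[0], 1.0)

    def test_feature_retention_is_non_increasing(self, rng):
        q, w, cost, locked, features, z = random_instance(rng)
        result = rank_cells(PrioritizationProblem(features, cost, locked, "abf", z))
        assert (np.diff(result.curve_features, axis=0) <= 1e-12).all()
        curves = performance_curves(result)
        assert set(curves) >= {"landscape_fraction", "mean_feature_fraction"}

    def test_removing_a_worthless_cell_keeps_retention(self):
        p = build_problem({"f": np.array([0.0, 0.4, 0.6]) + 1e-15})
        result = rank_cells(p)
        assert result.removal_order[0] == 0
        assert result.curve_features[1, 0] == pytest.approx(1.0)


class TestTopFraction:
    def test_count_is_rounded_fraction(self, rng):
        q = rng.random(100)
        result = rank_cells(build_problem({"f": q}))
        selected, report = top_fraction(result, 0.17)
        assert report.n_selected == 17
        assert selected.sum() == 17

    def test_reference_network_arithmetic(self):
        """820 locked cells of 11,461, 17% target: 9.8% extra needed."""
        n = 11461
        rng = np.random.default_rng(0)
        locked = np.zeros(n, bool)
        locked[rng.choice(n, 820, replace=False)] = True
        result = rank_cells(build_problem(
            {"f": rng.random(n) + 0.01}, locked=locked, rule="basic",
        ))
        _, report = top_fraction(result, 0.17)
        assert report.n_selected == 1948
        assert round(report.additional_pct, 1) == 9.8

    def test_full_fraction_selects_everything(self, rng):
        q = rng.random(10)
        locked = np.zeros(10, bool)
        locked[:2] = True
        result = rank_cells(build_problem({"f": q}, locked=locked))
        selected, report = top_fraction(result, 1.0)
        assert selected.all()
        assert report.additional_pct == pytest.approx(80.0)

    def test_target_below_existing_protection_warns(self, rng):
        q = rng.random(10)
        locked = np.ones(10, bool)
        locked[-1] = False
        result = rank_cells(build_problem({"f": q}, locked=locked))
        with pytest.warns(UserWarning, match="existing protection"):
            _, report = top_fraction(result, 0.2)
        assert report.target_met_by_existing
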