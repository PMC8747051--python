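"""Structural ego-network metrics against literal brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hhnet.kinship import EgoNetwork, build_ego_network
from hhnet.roster import Relationship as R
from hhnet.structure import (
    classify_effective_size,
    compute_structural_metrics,
    constraint,
    constraint_raw,
    degree,
    density,
    effective_size,
    efficiency,
    hierarchy,
    reduce_structural_set,
)
from conftest import make_roster
import oracles


def net_from_Z(Z: np.ndarray) -> EgoNetwork:
    return EgoNetwork(ego=None, alters=tuple(range(Z.shape[0] - 1)), Z=Z)


def clique_Z(n: int, w: float = 1.0) -> np.ndarray:
    Z = np.full((n + 1, n + 1), w)
    Z[0, :] = Z[:, 0] = 1.0
    np.fill_diagonal(Z, 0.0)
    return Z


def empty_Z(n: int) -> np.ndarray:
    Z = np.zeros((n + 1, n + 1))
    Z[0, 1:] = Z[1:, 0] = 1.0
    return Z


class TestDegree:
    def test_counts_alters(self, nuclear_roster):
        assert degree(build_ego_network(nuclear_roster)) == 3

    def test_household_of_six_gives_five(self):
        roster = make_roster(R.HEAD, R.SPOUSE, *[R.CHILD] * 4, respondent_index=1)
        assert degree(build_ego_network(roster)) == 5

    def test_single_alter(self):
        assert degree(net_from_Z(empty_Z(1))) == 1


class TestEffectiveSize:
    @pytest.mark.parametrize("n", [2, 3, 4, 6])
    def test_complete_clique_gives_one(self, n):
        assert effective_size(net_from_Z(clique_Z(n))) == pytest.approx(1.0)

    def test_unrelated_alters_give_degree(self):
        assert effective_size(net_from_Z(empty_Z(4))) == pytest.approx(4.0)

    def test_single_tie_matches_literal_summation_oracle(self):
        Z = empty_Z(3)
        Z[1, 2] = Z[2, 1] = 1.0  # A-B tied, C isolated
        net = net_from_Z(Z)
        assert effective_size(net) == pytest.approx(oracles.effective_size_oracle(Z), abs=1e-12)
        # frozen value from the oracle: ego p = 1/3 each, m = 1 for the tied pair
        assert effective_size(net) == pytest.approx(7.0 / 3.0)


class TestConstraint:
    def test_unrelated_alters_give_zero(self):
        assert constraint(net_from_Z(empty_Z(4))) == 0.0

    def test_nuclear_clique_gives_one(self, nuclear_roster):
        assert constraint(build_ego_network(nuclear_roster)) == 1.0

    def test_partial_tie_strictly_between_and_matches_oracle(self):
        Z = empty_Z(4)
        Z[1, 2] = Z[2, 1] = 1.0
        c = constraint(net_from_Z(Z))
        assert 0.0 < c < 1.0
        assert c == pytest.approx(oracles.constraint_rescaled_oracle(Z), abs=1e-12)

    def test_single_alter_convention(self):
        assert constraint(net_from_Z(empty_Z(1))) == 1.0


class TestDensityEfficiencyHierarchy:
    def test_complete_clique_density_one(self):
        assert density(net_from_Z(clique_Z(5))) == 1.0

    def test_no_ties_density_zero_efficiency_one(self):
        net = net_from_Z(empty_Z(5))
        assert density(net) == 0.0
        assert efficiency(net) == pytest.approx(1.0)

    def test_equal_dyadic_constraints_give_zero_hierarchy(self):
        assert hierarchy(net_from_Z(clique_Z(4))) == pytest.approx(0.0, abs=1e-12)
        assert hierarchy(net_from_Z(empty_Z(4))) == pytest.approx(0.0, abs=1e-12)

    def test_unequal_constraints_give_positive_hierarchy(self):
        Z = empty_Z(4)
        Z[1, 2] = Z[2, 1] = 1.0
        assert hierarchy(net_from_Z(Z)) > 0


@pytest.mark.parametrize(
    "es, expected",
    [(3.0, "low"), (3.01, "high"), (1.0, "low"), (5.5, "high")],
)
def test_effective_size_dichotomy(es, expected):
    assert classify_effective_size(es) == expected


def test_metrics_match_brute_force_on_random_networks():
    """Vectorized metrics equal the literal-formula graph oracle on 1,000
    random weighted ego networks of degree <= 8."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        Z = oracles.random_ego_Z(rng)
        net = net_from_Z(Z)
        assert effective_size(net) == pytest.approx(oracles.effective_size_oracle(Z), abs=1e-9)
        assert constraint_raw(net) == pytest.approx(oracles.constraint_raw_oracle(Z), abs=1e-9)
        assert constraint(net) == pytest.approx(oracles.constraint_rescaled_oracle(Z), abs=1e-9)
        assert hierarchy(net) == pytest.approx(oracles.hierarchy_oracle(Z), abs=1e-9)
        assert density(net) == pytest.approx(oracles.density_oracle(Z), abs=1e-12)


def test_bounds_and_es_monotonicity_on_random_networks():
    """1 <= ES <= degree, constraint in [0,1]; adding a tie never
    increases ES."""
    rng = np.random.default_rng(7)
    for _ in range(500):
        Z = oracles.random_ego_Z(rng)
        n = Z.shape[0] - 1
        net = net_from_Z(Z)
        es = effective_size(net)
        assert 1.0 <= es <= n + 1e-12
        assert 0.0 <= constraint(net) <= 1.0
        if n >= 2:
            j, k = rng.integers(1, n + 1, size=2)
            if j != k and Z[j, k] < 1.0:
                Z2 = Z.copy()
                Z2[j, k] = Z2[k, j] = min(1.0, Z[j, k] + 0.5)
                assert effective_size(net_from_Z(Z2)) <= es + 1e-9


def test_metrics_invariant_to_alter_relabelling():
    rng = np.random.default_rng(3)
    for _ in range(50):
        Z = oracles.random_ego_Z(rng, n_max=6)
        n = Z.shape[0] - 1
        perm = np.r_[0, 1 + rng.permutation(n)]
        Zp = Z[np.ix_(perm, perm)]
        a, b = net_from_Z(Z), net_from_Z(Zp)
        for f in (effective_size, constraint, density, hierarchy):
            assert f(a) == pytest.approx(f(b), abs=1e-12)


class TestReduceStructuralSet:
    def _table(self, rng, n=300):
        deg = rng.integers(1, 9, size=n).astype(float)
        es = 1 + (deg - 1) * rng.random(n)
        return pd.DataFrame(
            {
                "degree": deg,
                "effective_size": es,
                "efficiency": es / deg,
                "constraint": rng.random(n),
                "density": rng.random(n),
                "hierarchy": rng.random(n),
            }
        )

    def test_collinear_efficiency_never_retained_with_both_parents(self):
        rng = np.random.default_rng(0)
        red = reduce_structural_set(self._table(rng))
        if "efficiency" in red.retained:
            assert not {"degree", "effective_size"} <= set(red.retained)

    def test_identity_correlation_falls_back_to_conventional_trio(self):
        # exactly uncorrelated columns (orthogonalized noise): every
        # eigenvalue is exactly 1 and no component leads
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 6))
        Q, _ = np.linalg.qr(X - X.mean(axis=0))  # mean-zero orthonormal columns
        tab = pd.DataFrame(Q, columns=["degree", "density", "effective_size", "efficiency", "constraint", "hierarchy"])
        red = reduce_structural_set(tab)
        assert red.retained == ["degree", "effective_size", "constraint"]

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        tab = self._table(rng)
        tab["hierarchy"] = 0.0
        red = reduce_structural_set(tab)
        assert red.dropped_constant == ["hierarchy"]
        assert "hierarchy" not in red.variables

    def test_retains_one_variable_per_leading_component(self, calibration_cohort):
        from hhnet.structure import structural_table

        nets = ((r.household_id, build_ego_network(r)) for r in calibration_cohort.rosters[:500])
        tab = structural_table(nets)
        red = reduce_structural_set(tab)
        n_leading = int((red.eigenvalues > 1.0).sum())
        assert len(red.retained) == n_leading >= 2
        assert "degree" in red.retained  # the size axis is always its own component
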