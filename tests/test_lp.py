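"""The BME formulation: variable structure, relaxations, integer oracle."""

import numpy as np
import pytest

from bmephylo import (FormulationOptions, bme_length, build_formulation,
                      enumerate_ubts, lower_bound, run_nj, solve_integer,
                      solve_relaxation, tree_to_plm)
from bmephylo.lp import resolve_max_pathlen

from conftest import family_dm, random_dm


def brute_force_optimum(d):
    return min(bme_length(d, tree_to_plm(t)) for t in enumerate_ubts(d.n))


class TestConstruction:
    def test_n3_forced(self):
        d = random_dm(3, 0)
        sol = solve_relaxation(d)
        star = np.full((3, 3), 2)
        np.fill_diagonal(star, 0)
        assert np.allclose(sol.tau_tilde[~np.eye(3, dtype=bool)], 2.0)
        assert sol.objective_value == pytest.approx(bme_length(d, star))

    def test_variable_counts(self):
        n = 6
        d = random_dm(n, 1)
        f = build_formulation(d, FormulationOptions(include_buneman=True))
        n_pairs = n * (n - 1) // 2
        assert f.n_x == n_pairs * len(range(2, n))
        assert f.n_y == 3 * len(list(__import__("itertools").combinations(
            range(1, n), 3)))

    def test_max_pathlen_resolution(self):
        assert resolve_max_pathlen(10, "full") == 9
        # ceil(log2(9))**2 = 16 > 9: no actual reduction at n=10
        assert resolve_max_pathlen(10, "reduced") == 9
        # ceil(log2(59))**2 = 36 < 59
        assert resolve_max_pathlen(60, "reduced") == 36
        assert resolve_max_pathlen(10, 5) == 5
        with pytest.raises(ValueError, match="max_pathlen"):
            resolve_max_pathlen(10, 2)
        with pytest.raises(ValueError, match="max_pathlen"):
            resolve_max_pathlen(10, 10)


class TestIntegerOracle:
    @pytest.mark.parametrize("family,n,seed", [("C", 5, 11), ("D", 5, 12),
                                               ("C", 6, 13), ("D", 6, 14)])
    def test_optimum_matches_enumeration(self, family, n, seed):
        d = family_dm(family, n, seed)
        sol, plm = solve_integer(d)
        assert plm is not None and plm.validate().valid
        assert sol.objective_value == pytest.approx(brute_force_optimum(d),
                                                    abs=1e-7)
        # internal consistency: reported objective == re-evaluated length
        assert sol.objective_value == pytest.approx(bme_length(d, plm),
                                                    abs=1e-9)

    def test_n3_star_forced(self):
        d = random_dm(3, 5)
        sol, plm = solve_integer(d)
        assert np.all(plm.values[~np.eye(3, dtype=bool)] == 2)


class TestRelaxations:
    def test_relaxation_below_optimum(self):
        for seed in range(3):
            d = random_dm(5, 100 + seed)
            v = solve_relaxation(d).objective_value
            assert v <= brute_force_optimum(d) + 1e-9

    def test_monotone_relaxation_chain(self):
        for seed in range(3):
            d = random_dm(6, 200 + seed)
            v0 = solve_relaxation(d, FormulationOptions(
                include_buneman=False, include_triangle=False)).objective_value
            v1 = solve_relaxation(d, FormulationOptions(
                include_buneman=False, include_triangle=True)).objective_value
            v2 = solve_relaxation(d, FormulationOptions(
                include_buneman=True, include_triangle=True)).objective_value
            opt = brute_force_optimum(d)
            assert v0 <= v1 + 1e-8 <= v2 + 2e-8 <= opt + 3e-8

    def test_reduced_pathlen_never_lowers_value(self):
        # restricting L shrinks the feasible set: the value can only rise
        # (or the model become infeasible outright)
        d = random_dm(8, 7)
        base = FormulationOptions(include_buneman=False)
        full = solve_relaxation(d, base).objective_value
        feasible = 0
        for lmax in (5, 6, 7):
            opts = FormulationOptions(include_buneman=False,
                                      max_pathlen=lmax)
            sol = solve_relaxation(d, opts)
            if sol.status == "optimal":
                feasible += 1
                assert sol.objective_value >= full - 1e-8
        assert feasible >= 2

    def test_exponent_shift_pure_rescaling(self):
        d = random_dm(7, 9)
        plain = solve_relaxation(d, FormulationOptions(
            include_buneman=False)).objective_value
        shifted = solve_relaxation(d, FormulationOptions(
            include_buneman=False, exponent_shift=True)).objective_value
        assert abs(plain - shifted) / plain < 1e-7

    def test_tau_tilde_ranges(self):
        d = random_dm(6, 3)
        sol = solve_relaxation(d, FormulationOptions(include_buneman=False))
        off = ~np.eye(6, dtype=bool)
        assert np.all(sol.tau_tilde[off] >= 2 - 1e-8)
        assert np.all(sol.tau_tilde[off] <= 5 + 1e-8)
        assert np.allclose(sol.tau_tilde, sol.tau_tilde.T)
        assert np.all(np.diag(sol.tau_tilde) == 0)


class TestFeasibilityEmbedding:
    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_every_plm_embeds_in_full_model(self, n):
        d = random_dm(n, n)
        form = build_formulation(d, FormulationOptions())
        for k, t in enumerate(enumerate_ubts(n)):
            if k % 7:  # subsample for speed; deterministic
                continue
            x = form.embed_plm(tree_to_plm(t))
            assert form.check_feasible(x)
            assert form.c @ x == pytest.approx(bme_length(d, tree_to_plm(t)))


class TestLowerBound:
    def test_n3_exact(self):
        d = random_dm(3, 8)
        star = np.full((3, 3), 2) - 2 * np.eye(3, dtype=int)
        assert lower_bound(d) == pytest.approx(bme_length(d, star))

    def test_below_nj_length(self):
        for seed in range(3):
            d = family_dm("D", 8, 300 + seed)
            assert lower_bound(d) <= run_nj(d).length + 1e-8

    def test_below_enumeration_optimum_n6(self):
        for seed in range(3):
            d = family_dm("C", 6, 400 + seed)
            assert lower_bound(d) <= brute_force_optimum(d) + 1e-8
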