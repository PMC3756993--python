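"""Equilibrium enumeration, best responses, and coalition games."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

import coopeq as cq
from coopeq.games import MixedStrategy, SymmetricGame, pure_profile
from coopeq.nash import (
    CoalitionStructure,
    UnsupportedStructureError,
    coalition_game,
    nash_equilibria_2p,
)


def _symmetric_profiles(eqs):
    return [p for p in eqs.profiles if p[0] == p[1]]


class TestBestResponse:
    def test_pd_defect_against_cooperation(self, pd_worked):
        prof = pure_profile((0, 0), 2)  # both cooperate
        assert cq.best_response_set(pd_worked, 0, prof) == (1,)  # defect

    def test_td_undercut_by_one(self, td5):
        top = td5.n_strategies - 1  # claim 300
        prof = pure_profile((top, top), td5.n_strategies)
        replies = cq.best_response_set(td5, 0, prof)
        assert [td5.strategies[i] for i in replies] == ["299"]

    def test_constant_game_total_tie(self):
        g = SymmetricGame(("a", "b"), ((1, 1), (1, 1)))
        prof = pure_profile((0, 0), 2)
        assert cq.best_response_set(g, 0, prof) == (0, 1)


class TestEquilibria2P:
    def test_pd_unique_defection(self, pd_worked):
        eqs = nash_equilibria_2p(pd_worked)
        assert len(eqs.profiles) == 1 and not eqs.degenerate
        (prof,) = eqs.profiles
        assert prof == pure_profile((1, 1), 2)

    def test_chicken_two_pure_plus_mixed(self, chicken_kummerli):
        eqs = nash_equilibria_2p(chicken_kummerli)
        assert len(eqs.profiles) == 3
        pure = [p for p in eqs.profiles if p[0] != p[1]]
        assert len(pure) == 2
        (mixed,) = _symmetric_profiles(eqs)
        # (S-P)/(S-P + T-R) = 1/4 weight on cooperation
        assert mixed[0].weights == (Fraction(1, 4), Fraction(3, 4))

    def test_td_unique_floor_claim(self, td5):
        eqs = nash_equilibria_2p(td5)
        assert [
            [td5.strategies[i] for i in p[0].support()] for p in eqs.profiles
        ] == [["180"]]

    def test_equilibria_are_best_response_stable(self):
        for family in ("PD", "Chicken", "generic-2x2"):
            for seed in range(15):
                g = cq.random_symmetric_game(family, seed)
                for prof in nash_equilibria_2p(g).profiles:
                    assert cq.is_nash(g, prof), (family, seed)

    def test_degenerate_game_flagged(self):
        g = SymmetricGame(("a", "b"), ((1, 1), (1, 1)))
        assert nash_equilibria_2p(g).degenerate

    @pytest.mark.parametrize("m", [2, 3])
    def test_agreement_with_grid_search(self, m):
        """Every near-equilibrium on a fine strategy grid lies close to an
        enumerated equilibrium (and vice versa the enumerated ones have zero
        regret on the grid)."""
        import random as _random

        step = 1e-3 if m == 2 else 0.02
        for seed in range(8):
            rng = _random.Random(1000 * m + seed)
            vals = rng.sample(range(0, 1001), m * m)
            M = tuple(
                tuple(Fraction(vals[i * m + j], 1000) for j in range(m))
                for i in range(m)
            )
            g = SymmetricGame(tuple("abc"[:m]), M)
            eqs = nash_equilibria_2p(g)
            Mf = np.array([[float(x) for x in row] for row in M])
            # grid over mixed strategies
            if m == 2:
                zs = np.arange(0.0, 1.0 + step / 2, step)
                X = np.column_stack([zs, 1 - zs])
            else:
                pts = []
                k = round(1 / step)
                for i in range(k + 1):
                    for j in range(k + 1 - i):
                        pts.append((i / k, j / k, (k - i - j) / k))
                X = np.array(pts)
            U = X @ Mf @ X.T  # row-player payoff for (row mix r, col mix c)
            # row regret at (r, c): best pure reply vs c minus U[r, c]
            best_vs_c = (Mf @ X.T).max(axis=0)  # shape (n_grid,)
            reg_row = best_vs_c[None, :] - U  # (r, c)
            reg_col = reg_row.T  # symmetry: column player's game is transposed
            near = np.argwhere((reg_row < 1e-6) & (reg_col < 1e-6))
            eq_pts = np.array(
                [[float(w) for w in p[0].weights] + [float(w) for w in p[1].weights]
                 for p in eqs.profiles]
            )
            for r, c in near:
                pt = np.concatenate([X[r], X[c]])
                dist = np.abs(eq_pts - pt[None, :]).max(axis=1).min()
                assert dist < 0.06, (m, seed, pt, dist)


class TestSymmetricMixed:
    def test_chicken_indifference(self, chicken_kummerli):
        s = cq.symmetric_mixed_equilibrium(chicken_kummerli)
        pays = [
            cq.expected_payoff(chicken_kummerli, (MixedStrategy.pure(i, 2), s), 0)
            for i in range(2)
        ]
        assert pays[0] == pays[1]  # both strategies earn the same vs the mix

    def test_pd_absence(self, pd_worked):
        assert cq.symmetric_mixed_equilibrium(pd_worked) is None

    def test_uniform_mix_in_symmetric_toy(self):
        g = SymmetricGame(("a", "b"), ((0, 1), (1, 0)))  # anti-coordination
        s = cq.symmetric_mixed_equilibrium(g)
        assert s.weights == (Fraction(1, 2), Fraction(1, 2))


class TestCoalitionStructure:
    def test_distinguished_structures(self):
        s = CoalitionStructure.selfish(3)
        c = CoalitionStructure.cooperative(3)
        assert s.is_selfish and not s.is_cooperative
        assert c.is_cooperative and len(c.blocks) == 1

    def test_invalid_partitions(self):
        with pytest.raises(ValueError):
            CoalitionStructure((frozenset({0}), frozenset({0, 1})))
        with pytest.raises(ValueError):
            CoalitionStructure((frozenset({0}), frozenset({2})))


class TestCoalitionGame:
    def test_pd_grand_coalition_mutual_cooperation(self, pd_worked):
        cg = coalition_game(pd_worked, CoalitionStructure.cooperative(2))
        (prof,) = cg.equilibria().profiles
        assert prof == pure_profile((0, 0), 2)
        assert pd_worked.total_payoff((0, 0)) == Fraction("0.30")

    def test_td_grand_coalition_top_claims(self, td5):
        cg = coalition_game(td5, CoalitionStructure.cooperative(2))
        (prof,) = cg.equilibria().profiles
        assert [td5.strategies[i] for i in prof[0].support()] == ["300"]

    def test_singleton_structure_is_original_game(self, pd_worked):
        cg = coalition_game(pd_worked, CoalitionStructure.selfish(2))
        assert cg.equilibria().profiles == nash_equilibria_2p(pd_worked).profiles

    def test_merged_payoff_is_member_sum(self, pd_worked):
        cg = coalition_game(pd_worked, CoalitionStructure.cooperative(2))
        for prof_idx in itertools.product(range(2), repeat=2):
            prof = pure_profile(prof_idx, 2)
            assert cg.block_payoff(frozenset({0, 1}), prof) == pd_worked.total_payoff(
                prof_idx
            )

    def test_grand_coalition_maximizes_welfare_exhaustively(self):
        for seed in range(10):
            g = cq.random_symmetric_game("generic-2x2", seed)
            cg = coalition_game(g, CoalitionStructure.cooperative(2))
            best = max(
                g.total_payoff((i, j)) for i in range(2) for j in range(2)
            )
            for prof in cg.equilibria().profiles:
                idx = (prof[0].support()[0], prof[1].support()[0])
                assert g.total_payoff(idx) == best

    def test_intermediate_partition_unsupported_for_nplayer(self):
        g = cq.make_public_goods(4, 1, Fraction(3, 4), step=1)
        mid = CoalitionStructure((frozenset({0, 1}), frozenset({2, 3})))
        with pytest.raises(UnsupportedStructureError):
            coalition_game(g, mid).equilibria()


class TestNashPayoffInfimum:
    def test_pd_values(self, pd_worked):
        sel = CoalitionStructure.selfish(2)
        coop = CoalitionStructure.cooperative(2)
        assert cq.nash_payoff_infimum(pd_worked, sel, 0) == Fraction("0.05")
        assert cq.nash_payoff_infimum(pd_worked, coop, 0) == Fraction("0.15")

    def test_chicken_selfish_infimum_is_sucker(self, chicken_kummerli):
        # attained where the player concedes against a defector
        sel = CoalitionStructure.selfish(2)
        assert cq.nash_payoff_infimum(chicken_kummerli, sel, 0) == 2
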