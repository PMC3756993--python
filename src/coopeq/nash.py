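"""Nash-equilibrium machinery for the base game and for coalition games.

Two-player games are solved by exact support enumeration (Fractions) up to a
moderate strategy count; beyond that a vectorized pure-profile scan plus
symmetric two-point supports is used, with exact verification of every
candidate — sufficient for the dilemma families in scope, whose equilibria
are pure or symmetric with small support.

A coalition structure partitions the players; the members of a block play as
one merged player maximizing the block's summed payoff.  For the grand
coalition the merged player controls the whole profile, so its "equilibria"
are exactly the welfare-maximizing profiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import FrozenSet, List, Optional, Tuple

import numpy as np

from .games import (
    AggregativeGame,
    Game,
    MixedStrategy,
    Profile,
    SymmetricGame,
    expected_payoff,
    pure_profile,
)

SUPPORT_ENUM_LIMIT = 6  # full support enumeration up to this many strategies


class UnsupportedStructureError(ValueError):
    """Coalition structure not handled for this game shape."""


# ---------------------------------------------------------------------------
# coalition structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoalitionStructure:
    """A partition of the player set into coalitions."""

    blocks: Tuple[FrozenSet[int], ...]

    def __post_init__(self):
        blocks = tuple(frozenset(b) for b in self.blocks)
        object.__setattr__(self, "blocks", blocks)
        players = sorted(p for b in blocks for p in b)
        if len(players) != len(set(players)):
            raise ValueError("coalition blocks must be pairwise disjoint")
        if players != list(range(len(players))):
            raise ValueError("blocks must cover players 0..n-1")

    @classmethod
    def selfish(cls, n: int) -> "CoalitionStructure":
        """All singletons: every player follows her private interest."""
        return cls(tuple(frozenset({i}) for i in range(n)))

    @classmethod
    def cooperative(cls, n: int) -> "CoalitionStructure":
        """The grand coalition: all players follow the collective interest."""
        return cls((frozenset(range(n)),))

    @property
    def n_players(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def is_selfish(self) -> bool:
        return all(len(b) == 1 for b in self.blocks)

    @property
    def is_cooperative(self) -> bool:
        return len(self.blocks) == 1


@dataclass(frozen=True)
class EquilibriumSet:
    """Representative equilibria plus a degeneracy flag.

    ``degenerate`` is set when payoff ties make the equilibrium set a
    positive-dimensional component; the listed profiles are then its
    vertices, not the whole set.
    """

    profiles: Tuple[Profile, ...]
    degenerate: bool = False
    method: str = "support-enumeration"


# ---------------------------------------------------------------------------
# best responses
# ---------------------------------------------------------------------------


def pure_payoffs_vs(game: Game, player: int, others: Profile) -> List[Fraction]:
    """Expected payoff of each of ``player``'s pure strategies against
    the opponents' strategies in ``others`` (own entry ignored)."""
    m = game.n_strategies
    out = []
    for s in range(m):
        prof = tuple(
            MixedStrategy.pure(s, m) if k == player else others[k]
            for k in range(game.n_players)
        )
        out.append(expected_payoff(game, prof, player))
    return out


def best_response_set(game: Game, player: int, others: Profile) -> Tuple[int, ...]:
    """Argmax set of pure best responses; all ties are returned."""
    pay = pure_payoffs_vs(game, player, others)
    best = max(pay)
    return tuple(i for i, v in enumerate(pay) if v == best)


def is_nash(game: Game, profile: Profile, tol: Fraction = Fraction(0)) -> bool:
    """Best-response stability: no player gains more than ``tol`` by any
    pure deviation."""
    for p in range(game.n_players):
        current = expected_payoff(game, profile, p)
        if max(pure_payoffs_vs(game, p, profile)) > current + tol:
            return False
    return True


# ---------------------------------------------------------------------------
# exact linear algebra (small systems)
# ---------------------------------------------------------------------------


def _solve_linear(A: List[List[Fraction]], b: List[Fraction]) -> Optional[List[Fraction]]:
    """Gaussian elimination over Fractions; None if the system is singular."""
    n = len(A)
    M = [row[:] + [bv] for row, bv in zip(A, b)]
    for col in range(n):
        piv = next((r for r in range(col, n) if M[r][col] != 0), None)
        if piv is None:
            return None
        M[col], M[piv] = M[piv], M[col]
        inv = M[col][col]
        M[col] = [x / inv for x in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                f = M[r][col]
                M[r] = [x - f * y for x, y in zip(M[r], M[col])]
    return [M[r][n] for r in range(n)]


# ---------------------------------------------------------------------------
# two-player equilibrium enumeration
# ---------------------------------------------------------------------------


def _support_candidate(
    game: SymmetricGame, rows: Tuple[int, ...], cols: Tuple[int, ...]
) -> Tuple[Optional[Profile], bool]:
    """Try to build an equilibrium with the given supports.

    Returns (profile-or-None, degenerate_hint).  The column player's payoff
    matrix is the transpose of the row player's, per symmetry.
    """
    M = game.matrix
    k = len(rows)
    # column mixture y (over cols) making all `rows` strategies indifferent
    A = [[M[i][j] for j in cols] + [Fraction(-1)] for i in rows]
    A.append([Fraction(1)] * k + [Fraction(0)])
    sol = _solve_linear(A, [Fraction(0)] * k + [Fraction(1)])
    if sol is None:
        return None, False  # no isolated equilibrium with this support
    y_w, v = sol[:k], sol[k]
    # row mixture x (over rows) making all `cols` strategies indifferent
    A = [[M[j][i] for i in rows] + [Fraction(-1)] for j in cols]
    A.append([Fraction(1)] * k + [Fraction(0)])
    sol = _solve_linear(A, [Fraction(0)] * k + [Fraction(1)])
    if sol is None:
        return None, False
    x_w, w = sol[:k], sol[k]
    if any(t < 0 for t in x_w) or any(t < 0 for t in y_w):
        return None, False
    if any(t == 0 for t in x_w) or any(t == 0 for t in y_w):
        return None, False  # duplicates a smaller support
    degenerate = False
    m = game.n_strategies
    for i in range(m):  # row deviations against y
        if i in rows:
            continue
        dev = sum(M[i][j] * yw for j, yw in zip(cols, y_w))
        if dev > v:
            return None, False
        if dev == v:
            degenerate = True
    for j in range(m):  # column deviations against x
        if j in cols:
            continue
        dev = sum(M[j][i] * xw for i, xw in zip(rows, x_w))
        if dev > w:
            return None, False
        if dev == w:
            degenerate = True
    xs = [Fraction(0)] * m
    ys = [Fraction(0)] * m
    for i, t in zip(rows, x_w):
        xs[i] = t
    for j, t in zip(cols, y_w):
        ys[j] = t
    return (MixedStrategy(tuple(xs)), MixedStrategy(tuple(ys))), degenerate


def _enumerate_small(game: SymmetricGame) -> EquilibriumSet:
    m = game.n_strategies
    found, degenerate = [], False
    for k in range(1, m + 1):
        for rows in itertools.combinations(range(m), k):
            for cols in itertools.combinations(range(m), k):
                prof, deg = _support_candidate(game, rows, cols)
                degenerate = degenerate or deg
                if prof is not None and prof not in found:
                    found.append(prof)
    return EquilibriumSet(tuple(found), degenerate, "support-enumeration")


def _enumerate_large(game: SymmetricGame) -> EquilibriumSet:
    """Pure-profile scan plus symmetric 2-point supports, exact verification."""
    M = np.array([[float(x) for x in row] for row in game.matrix])
    m = game.n_strategies
    col_best = M.max(axis=0)  # best row payoff vs each column strategy
    found: List[Profile] = []
    degenerate = False
    rows_ok = M >= col_best[None, :] - 1e-9
    for i, j in zip(*np.nonzero(rows_ok & rows_ok.T)):
        prof = pure_profile((int(i), int(j)), m)
        if is_nash(game, prof):
            if len(best_response_set(game, 0, prof)) > 1 or len(best_response_set(game, 1, prof)) > 1:
                degenerate = True
            found.append(prof)
    # symmetric two-point supports {j,k}: indifference weight p on j, then a
    # vectorized best-reply screen; survivors are verified exactly
    J, K = np.triu_indices(m, k=1)
    den = M[J, J] - M[K, J] - M[J, K] + M[K, K]
    ok = np.abs(den) > 1e-12
    p = np.zeros_like(den)
    p[ok] = (M[K, K] - M[J, K])[ok] / den[ok]
    ok &= (p > 1e-12) & (p < 1 - 1e-12)
    if ok.any():
        Jc, Kc, pc = J[ok], K[ok], p[ok]
        dev = M[:, Jc] * pc[None, :] + M[:, Kc] * (1 - pc)[None, :]
        val = pc * dev[Jc, np.arange(len(Jc))] + (1 - pc) * dev[Kc, np.arange(len(Kc))]
        stable = dev.max(axis=0) <= val + 1e-9
        seen = {tuple(p[0].weights) for p in found}
        max_pairs = 200  # degenerate games: report vertices, not components
        pairs = 0
        for j, k in zip(Jc[stable], Kc[stable]):
            if pairs >= max_pairs:
                degenerate = True
                break
            pf = _exact_symmetric_pair(game, int(j), int(k))
            if pf is not None and tuple(pf[0].weights) not in seen:
                seen.add(tuple(pf[0].weights))
                found.append(pf)
                pairs += 1
    return EquilibriumSet(tuple(found), degenerate, "pure-scan+symmetric-pairs")


def _exact_symmetric_pair(game: SymmetricGame, j: int, k: int) -> Optional[Profile]:
    M = game.matrix
    den = M[j][j] - M[k][j] - M[j][k] + M[k][k]
    if den == 0:
        return None
    p = (M[k][k] - M[j][k]) / den
    if not (0 < p < 1):
        return None
    # direct stability check against the mixture (one player suffices by
    # symmetry of the profile)
    q = 1 - p
    val = p * (p * M[j][j] + q * M[j][k]) + q * (p * M[k][j] + q * M[k][k])
    for i in range(game.n_strategies):
        if p * M[i][j] + q * M[i][k] > val:
            return None
    w = [Fraction(0)] * game.n_strategies
    w[j], w[k] = p, q
    s = MixedStrategy(tuple(w))
    return (s, s)


def nash_equilibria_2p(game: SymmetricGame) -> EquilibriumSet:
    """All Nash equilibria of a two-player symmetric game.

    Exact support enumeration for small games; for larger games a
    representative set (all pure equilibria and symmetric equilibria with
    support at most 2), flagged via ``method``.
    """
    if game.n_players != 2:
        raise ValueError("two-player routine")
    if game.n_strategies <= SUPPORT_ENUM_LIMIT:
        return _enumerate_small(game)
    return _enumerate_large(game)


def symmetric_mixed_equilibrium(game: SymmetricGame) -> Optional[MixedStrategy]:
    """The symmetric mixed (indifference-solving) equilibrium, or None.

    For 2x2 games this is the evolutionarily stable mixture of Chicken-type
    games; for the PD no such equilibrium exists and None is returned.
    """
    if game.n_strategies == 2:
        prof = _exact_symmetric_pair(game, 0, 1)
        return prof[0] if prof is not None else None
    for prof in nash_equilibria_2p(game).profiles:
        if prof[0] == prof[1] and len(prof[0].support()) >= 2:
            return prof[0]
    return None


# ---------------------------------------------------------------------------
# coalition games
# ---------------------------------------------------------------------------


def _welfare_optima_2p(game: SymmetricGame) -> EquilibriumSet:
    m = game.n_strategies
    if m > SUPPORT_ENUM_LIMIT:
        T = np.array([[float(x) for x in row] for row in game.matrix])
        tot = T + T.T
        best = tot.max()
        cand = [(int(i), int(j)) for i, j in zip(*np.nonzero(tot >= best - 1e-9))]
        exact_best = max(game.total_payoff(c) for c in cand)
        cand = [c for c in cand if game.total_payoff(c) == exact_best]
    else:
        exact_best = max(game.total_payoff((i, j)) for i in range(m) for j in range(m))
        cand = [
            (i, j)
            for i in range(m)
            for j in range(m)
            if game.total_payoff((i, j)) == exact_best
        ]
    profiles = tuple(pure_profile(c, m) for c in cand)
    return EquilibriumSet(profiles, degenerate=len(profiles) > 1, method="welfare-argmax")


def _aggregative_selfish(game: AggregativeGame) -> EquilibriumSet:
    # own action enters the payoff only through (beta+gamma)*x_i, so a
    # dominant pure strategy exists on the grid
    slope = game.beta + game.gamma
    vals = [slope * x for x in game.grid]
    best = max(vals)
    idx = [i for i, v in enumerate(vals) if v == best]
    profs = tuple(
        pure_profile((i,) * game.n_players, game.n_strategies) for i in idx
    )
    return EquilibriumSet(profs, degenerate=len(idx) > 1, method="dominant-strategy")


def _aggregative_welfare(game: AggregativeGame) -> EquilibriumSet:
    # total payoff = n*alpha + (beta + n*gamma) * sum(x): monotone in the sum
    slope = game.beta + game.n_players * game.gamma
    if slope > 0:
        idx = [game.n_strategies - 1]
    elif slope < 0:
        idx = [0]
    else:
        idx = [0, game.n_strategies - 1]
    profs = tuple(pure_profile((i,) * game.n_players, game.n_strategies) for i in idx)
    return EquilibriumSet(profs, degenerate=slope == 0, method="welfare-argmax")


@dataclass(frozen=True)
class CoalitionGame:
    """The game G_p associated with a coalition structure p."""

    base: Game
    structure: CoalitionStructure
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        if self.structure.n_players != self.base.n_players:
            raise ValueError("structure size does not match the game")

    def block_payoff(self, block: FrozenSet[int], profile: Profile):
        """Merged payoff of a coalition: the sum of its members' payoffs."""
        return sum(expected_payoff(self.base, profile, i) for i in block)

    def equilibria(self) -> EquilibriumSet:
        if "eq" in self._cache:
            return self._cache["eq"]
        s = self.structure
        if s.is_selfish:
            if isinstance(self.base, SymmetricGame):
                out = nash_equilibria_2p(self.base)
            else:
                out = _aggregative_selfish(self.base)
        elif s.is_cooperative:
            if isinstance(self.base, SymmetricGame):
                out = _welfare_optima_2p(self.base)
            else:
                out = _aggregative_welfare(self.base)
        else:
            raise UnsupportedStructureError(
                "only the fully selfish and fully cooperative structures are "
                "required for symmetric social dilemmas; intermediate "
                "partitions are not solved"
            )
        self._cache["eq"] = out
        return out


def coalition_game(game: Game, structure: CoalitionStructure) -> CoalitionGame:
    return CoalitionGame(game, structure)


def nash_payoff_infimum(game: Game, structure: CoalitionStructure, player: int):
    """IF_i(p): infimum of the player's payoff over Nash equilibria of G_p."""
    eqs = coalition_game(game, structure).equilibria()
    return min(expected_payoff(game, prof, player) for prof in eqs.profiles)
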