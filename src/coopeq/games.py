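"""Symmetric normal-form games and the parametric social-dilemma families.

Two in-memory representations cover everything in scope:

* :class:`SymmetricGame` — an explicit two-player symmetric game.  Only the
  row player's payoff matrix is stored; the column player's matrix is its
  transpose, which is exactly the symmetry condition for two players.
* :class:`AggregativeGame` — an N-player symmetric game whose payoff is
  affine in the player's own action and in the sum of all actions,
  ``u_i = alpha + beta * x_i + gamma * sum_j x_j``.  The Public Goods game
  and the Tragedy of the Commons are both of this form.

Payoffs are exact rationals throughout (see :mod:`coopeq._numeric`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from fractions import Fraction
from typing import Optional, Sequence, Tuple, Union

from ._numeric import Numeric, to_fraction


class GameValidationError(ValueError):
    """A dilemma constructor's payoff-ordering precondition was violated."""


# ---------------------------------------------------------------------------
# strategies and profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixedStrategy:
    """A probability vector over the game's pure strategies."""

    weights: Tuple[Union[Fraction, float], ...]

    def __post_init__(self):
        w = tuple(x if isinstance(x, float) else Fraction(x) for x in self.weights)
        object.__setattr__(self, "weights", w)
        if any(x < 0 for x in w):
            raise ValueError("mixed strategy weights must be nonnegative")
        total = sum(w)
        exact = all(isinstance(x, Fraction) for x in w)
        if exact:
            if total != 1:
                raise ValueError(f"weights must sum to 1, got {total}")
        elif abs(float(total) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {float(total)}")

    @classmethod
    def pure(cls, index: int, n_strategies: int) -> "MixedStrategy":
        return _pure_strategy(index, n_strategies)

    def support(self, tol: float = 1e-12) -> Tuple[int, ...]:
        return tuple(i for i, x in enumerate(self.weights) if x > tol)

    def __len__(self) -> int:
        return len(self.weights)


Profile = Tuple[MixedStrategy, ...]


@lru_cache(maxsize=None)
def _pure_strategy(index: int, n_strategies: int) -> MixedStrategy:
    # pure strategies are immutable and requested constantly by the solvers
    w = [Fraction(0)] * n_strategies
    w[index] = Fraction(1)
    return MixedStrategy(tuple(w))



def pure_profile(indices: Sequence[int], n_strategies: int) -> Profile:
    return tuple(MixedStrategy.pure(i, n_strategies) for i in indices)


# ---------------------------------------------------------------------------
# game containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SymmetricGame:
    """Two-player symmetric normal-form game.

    ``matrix[i][j]`` is the row player's payoff when she plays strategy ``i``
    and the opponent plays ``j``; the column player's payoff at the same
    profile is ``matrix[j][i]``.
    """

    strategies: Tuple[str, ...]
    matrix: Tuple[Tuple[Fraction, ...], ...]
    values: Optional[Tuple[Fraction, ...]] = None  # numeric meaning of strategies
    family: str = "explicit"
    params: dict = field(default_factory=dict)

    n_players: int = 2

    def __post_init__(self):
        m = len(self.strategies)
        if len(self.matrix) != m or any(len(row) != m for row in self.matrix):
            raise GameValidationError("payoff matrix shape must match strategy list")
        object.__setattr__(
            self, "matrix", tuple(tuple(Fraction(x) for x in row) for row in self.matrix)
        )
        if self.values is not None:
            object.__setattr__(self, "values", tuple(Fraction(v) for v in self.values))

    @property
    def n_strategies(self) -> int:
        return len(self.strategies)

    def payoff(self, player: int, profile: Sequence[int]) -> Fraction:
        """Payoff of ``player`` at a pure profile given as strategy indices."""
        if player not in (0, 1) or len(profile) != 2:
            raise ValueError("two-player game: player in {0,1}, profile of length 2")
        i, j = profile
        return self.matrix[i][j] if player == 0 else self.matrix[j][i]

    def total_payoff(self, profile: Sequence[int]) -> Fraction:
        i, j = profile
        return self.matrix[i][j] + self.matrix[j][i]


@dataclass(frozen=True)
class AggregativeGame:
    """N-player symmetric game with payoff affine in own action and the sum.

    ``u_i(x) = alpha + beta * x_i + gamma * (x_1 + ... + x_n)`` where each
    ``x_i`` is drawn from a common finite ascending grid of numeric actions.
    """

    n_players: int
    grid: Tuple[Fraction, ...]
    alpha: Fraction
    beta: Fraction
    gamma: Fraction
    family: str = "aggregative"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_players < 2:
            raise GameValidationError("need at least two players")
        g = tuple(Fraction(v) for v in self.grid)
        if len(g) < 2 or any(a >= b for a, b in zip(g, g[1:])):
            raise GameValidationError("action grid must be strictly ascending, length >= 2")
        object.__setattr__(self, "grid", g)
        for name in ("alpha", "beta", "gamma"):
            object.__setattr__(self, name, Fraction(getattr(self, name)))

    @property
    def strategies(self) -> Tuple[str, ...]:
        return tuple(f"{float(v):g}" for v in self.grid)

    @property
    def n_strategies(self) -> int:
        return len(self.grid)

    def payoff(self, player: int, profile: Sequence[int]) -> Fraction:
        if len(profile) != self.n_players:
            raise ValueError("profile length must equal the number of players")
        xs = [self.grid[k] for k in profile]
        return self.alpha + self.beta * xs[player] + self.gamma * sum(xs)

    def payoff_from_actions(self, own, total) -> Fraction:
        """Payoff from own action and the profile total (exchangeability)."""
        return self.alpha + self.beta * Fraction(own) + self.gamma * Fraction(total)


Game = Union[SymmetricGame, AggregativeGame]


# ---------------------------------------------------------------------------
# expectation
# ---------------------------------------------------------------------------


def expected_payoff(game: Game, profile: Profile, player: int):
    """Expected payoff of ``player`` under a profile of mixed strategies.

    Multilinear expectation over the product measure; exact when all weights
    are rational.
    """
    if len(profile) != game.n_players:
        raise ValueError("profile length must equal the number of players")
    for s in profile:
        if len(s) != game.n_strategies:
            raise ValueError("mixed strategy dimension does not match the game")
    if isinstance(game, SymmetricGame):
        x, y = profile if player == 0 else (profile[1], profile[0])
        return sum(
            wx * wy * game.matrix[i][j]
            for i, wx in enumerate(x.weights)
            if wx
            for j, wy in enumerate(y.weights)
            if wy
        )
    # aggregative: payoff is affine in actions, so only means enter
    means = [sum(w * v for w, v in zip(s.weights, game.grid)) for s in profile]
    return game.alpha + game.beta * means[player] + game.gamma * sum(means)


# ---------------------------------------------------------------------------
# dilemma constructors
# ---------------------------------------------------------------------------


def _require(cond: bool, msg: str):
    if not cond:
        raise GameValidationError(msg)


def make_prisoners_dilemma(T: Numeric, R: Numeric, P: Numeric, S: Numeric) -> SymmetricGame:
    """Prisoner's dilemma with temptation/reward/punishment/sucker payoffs.

    Strategies are [C, D]; requires the strict ordering T > R > P > S, so
    defection is dominant yet mutual defection is worse than mutual
    cooperation.
    """
    T, R, P, S = map(to_fraction, (T, R, P, S))
    _require(T > R, f"need T > R, got T={T} R={R}")
    _require(R > P, f"need R > P, got R={R} P={P}")
    _require(P > S, f"need P > S, got P={P} S={S}")
    return SymmetricGame(
        strategies=("C", "D"),
        matrix=((R, S), (T, P)),
        family="PD",
        params={"T": T, "R": R, "P": P, "S": S},
    )


def make_chicken(T: Numeric, R: Numeric, S: Numeric, P: Numeric) -> SymmetricGame:
    """Chicken (snowdrift): same layout as the PD but mutual defection is worst.

    Requires T > R > S > P.  Conceding against a defector beats mutual
    defection, so the game has two asymmetric pure equilibria and a symmetric
    mixed one.
    """
    T, R, S, P = map(to_fraction, (T, R, S, P))
    _require(T > R, f"need T > R, got T={T} R={R}")
    _require(R > S, f"need R > S, got R={R} S={S}")
    _require(S > P, f"need S > P, got S={S} P={P}")
    return SymmetricGame(
        strategies=("C", "D"),
        matrix=((R, S), (T, P)),
        family="Chicken",
        params={"T": T, "R": R, "S": S, "P": P},
    )


def make_donation_pd(b: Numeric) -> SymmetricGame:
    """Parametric (donation) Prisoner's dilemma: pay a unit cost, donate ``b``.

    Payoffs (T, R, P, S) = (b, b-1, 0, -1), requiring b > 1.  The
    benefit-to-cost ratio b is the single knob that moves the cooperative
    equilibrium from pure defection (b <= 2) towards full cooperation.
    """
    b = to_fraction(b)
    _require(b > 1, f"need benefit b > 1 (cost normalized to 1), got b={b}")
    g = make_prisoners_dilemma(b, b - 1, 0, -1)
    return SymmetricGame(
        strategies=g.strategies, matrix=g.matrix, family="PD-donation", params={"b": b}
    )


def make_travelers_dilemma(low: int, high: int, bonus: Numeric) -> SymmetricGame:
    """Traveler's dilemma over integer claims ``low..high`` with a bonus/penalty.

    Equal claims m pay m to both; with unequal claims the lower claim m is
    paid to both, plus the bonus to the low claimant and minus the bonus to
    the high claimant.
    """
    if not (isinstance(low, int) and isinstance(high, int)) or isinstance(low, bool):
        raise GameValidationError("claim bounds must be integers")
    _require(low < high, f"need low < high, got {low} >= {high}")
    bonus = to_fraction(bonus)
    _require(bonus > 0, f"bonus must be positive, got {bonus}")
    claims = list(range(low, high + 1))
    matrix = []
    for ci in claims:
        row = []
        for cj in claims:
            if ci == cj:
                row.append(Fraction(ci))
            elif ci < cj:
                row.append(ci + bonus)
            else:
                row.append(cj - bonus)
        matrix.append(tuple(row))
    return SymmetricGame(
        strategies=tuple(str(c) for c in claims),
        matrix=tuple(matrix),
        values=tuple(Fraction(c) for c in claims),
        family="TD",
        params={"low": low, "high": high, "bonus": bonus},
    )


def make_public_goods(n: int, y: Numeric, a: Numeric, step: Optional[Numeric] = None) -> AggregativeGame:
    """Linear Public Goods game with constant marginal return ``a``.

    Each of ``n`` players holds endowment ``y`` and contributes an amount on
    the grid 0, step, ..., y.  Player i receives
    ``y - x_i + a * (x_1 + ... + x_n)`` — the usual multiply-and-divide pot
    with the group-size division folded into a.  The dilemma condition is
    1/n < a < 1: contributing is individually costly but socially productive.
    The default grid step is y/100.
    """
    _require(isinstance(n, int) and not isinstance(n, bool) and n >= 2, "need integer n >= 2")
    y, a = to_fraction(y), to_fraction(a)
    _require(y > 0, f"endowment must be positive, got {y}")
    _require(
        Fraction(1, n) < a < 1,
        f"marginal return a must lie in (1/{n}, 1), got {a}",
    )
    step = y / 100 if step is None else to_fraction(step)
    _require(step > 0, "grid step must be positive")
    k = y / step
    _require(k.denominator == 1, f"grid step {step} must divide the endowment {y}")
    grid = tuple(step * i for i in range(int(k) + 1))
    return AggregativeGame(
        n_players=n,
        grid=grid,
        alpha=y,
        beta=Fraction(-1),
        gamma=a,
        family="PG",
        params={"n": n, "y": y, "a": a, "step": step},
    )


def make_tragedy_commons(n: int, g: Numeric, d: Numeric) -> AggregativeGame:
    """Tragedy of the Commons: ``n`` farmers each keep a sheep or not.

    A kept sheep yields private utility ``g`` and inflicts grazing damage
    ``d`` on every farmer, so farmer i's payoff is
    ``g * s_i - d * (s_1 + ... + s_n)`` with s_i in {0, 1}.  Requires g > d
    (keeping is individually profitable) and n*d > g (collectively ruinous).
    """
    _require(isinstance(n, int) and not isinstance(n, bool) and n >= 2, "need integer n >= 2")
    g, d = to_fraction(g), to_fraction(d)
    _require(d > 0, f"damage must be positive, got {d}")
    _require(g > d, f"need g > d, got g={g} d={d}")
    _require(n * d > g, f"need n*d > g, got n*d={n * d} g={g}")
    return AggregativeGame(
        n_players=n,
        grid=(Fraction(0), Fraction(1)),
        alpha=Fraction(0),
        beta=g,
        gamma=-d,
        family="ToC",
        params={"n": n, "g": g, "d": d},
    )


def toc_to_public_goods(game: AggregativeGame) -> AggregativeGame:
    """Map a Tragedy of the Commons onto the equivalent Public Goods game.

    With contribution x_i = g * (1 - s_i) (not keeping the sheep = contributing
    the full endowment g) the commons is a Public Goods game with endowment g
    and marginal return d/g — the effective cost of a sheep — up to the
    constant -d*n, which shifts all payoffs and no strategic quantity.
    """
    if game.family != "ToC":
        raise GameValidationError("expected a Tragedy of the Commons instance")
    n, g, d = game.params["n"], game.params["g"], game.params["d"]
    return make_public_goods(n, y=g, a=d / g, step=g)
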