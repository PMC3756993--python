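"""The induced (restricted) game and the cooperative equilibrium.

Given the best structure's value v*, the induced game keeps only profiles
that guarantee every player an expected payoff of at least v*.  A
cooperative equilibrium is a Nash equilibrium of that restricted game.

Geometry drives the solvers: if a (symmetric) Nash equilibrium of the
original game is itself feasible, it is the cooperative equilibrium — the
two solution concepts are not disjoint.  Otherwise the players slide from
cooperation towards their selfish equilibrium until the value constraint
stops them, so the cooperative equilibrium is the feasible symmetric profile
on the binding boundary, i.e. the feasible point closest to the original
Nash equilibrium.  Every candidate returned here is verified by an exact
best-feasible-response check rather than trusted from the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import List, Tuple, Union

from ._numeric import sqrt_exact
from .games import (
    AggregativeGame,
    Game,
    MixedStrategy,
    Profile,
    SymmetricGame,
    expected_payoff,
)
from .nash import is_nash, nash_equilibria_2p, symmetric_mixed_equilibrium
from .coalition_value import BestStructure, best_structure

FEAS_TOL = Fraction(1, 10**9)  # slack for float-valued (irrational) weights


class UnsupportedGameError(ValueError):
    """Game shape outside the solver's scope."""


class EmptyInducedGameError(RuntimeError):
    """The feasible set of the induced game is empty — the construction
    guarantees non-emptiness, so this indicates an inconsistent threshold."""


# ---------------------------------------------------------------------------
# induced game
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InducedGame:
    """The base game restricted to profiles paying every player >= v_star."""

    base: Game
    v_star: Fraction

    def feasible(self, profile: Profile, tol: Fraction = FEAS_TOL) -> bool:
        return all(
            expected_payoff(self.base, profile, p) >= self.v_star - tol
            for p in range(self.base.n_players)
        )


def induced_game(game: Game, v_star) -> InducedGame:
    ig = InducedGame(game, v_star)
    # the equilibria of the value-defining structures witness non-emptiness:
    # every player's payoff there is at least the structure's infimum, which
    # bounds the structure's value from above
    from .nash import CoalitionStructure, coalition_game

    n = game.n_players
    witnesses = [
        prof
        for s in (CoalitionStructure.cooperative(n), CoalitionStructure.selfish(n))
        for prof in coalition_game(game, s).equilibria().profiles
    ]
    if not any(ig.feasible(w) for w in witnesses):
        raise EmptyInducedGameError(
            f"no witness profile reaches v*={v_star}; threshold inconsistent "
            "with the game"
        )
    return ig


# ---------------------------------------------------------------------------
# best feasible response (exact LP on the simplex with one cut)
# ---------------------------------------------------------------------------


def best_feasible_response(
    game: SymmetricGame, player: int, profile: Profile, v_star
):
    """Max payoff ``player`` can reach by a unilateral deviation that keeps
    the profile allowed (both players' payoffs >= v_star).

    The objective and the opponent-payoff constraint are linear in the
    deviating mixture, so the optimum sits at a pure strategy or on an edge
    between two pure strategies where the constraint binds.  Returns the
    optimal value (or None if no deviation is feasible).
    """
    m = game.n_strategies
    opp = 1 - player
    c, d = [], []  # own payoff, opponent payoff, per pure deviation
    for s in range(m):
        prof = tuple(
            MixedStrategy.pure(s, m) if k == player else profile[k] for k in range(2)
        )
        c.append(expected_payoff(game, prof, player))
        d.append(expected_payoff(game, prof, opp))
    best = None
    for s in range(m):
        if d[s] >= v_star - FEAS_TOL and (best is None or c[s] > best):
            best = c[s]
    for s in range(m):
        for t in range(s + 1, m):
            lo, hi = (s, t) if d[s] < d[t] else (t, s)
            if not (d[lo] < v_star <= d[hi]):
                continue
            lam = (v_star - d[lo]) / (d[hi] - d[lo])  # weight on hi
            val = lam * c[hi] + (1 - lam) * c[lo]
            if best is None or val > best:
                best = val
    return best


def is_restricted_equilibrium(
    game: SymmetricGame, profile: Profile, v_star, tol: Fraction = FEAS_TOL
) -> bool:
    ig = InducedGame(game, v_star)
    if not ig.feasible(profile, tol):
        return False
    for p in range(2):
        br = best_feasible_response(game, p, profile, v_star)
        if br is not None and br > expected_payoff(game, profile, p) + tol:
            return False
    return True


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CooperativeEquilibriumResult:
    game: Game
    strategy: MixedStrategy  # common symmetric strategy
    payoff: Union[Fraction, float]  # per-player expected payoff
    v_star: Fraction
    v_selfish: Fraction
    v_cooperative: Fraction
    coincides_with_nash: bool
    binding_constraints: Tuple[int, ...]
    structures: BestStructure
    diagnostics: dict = field(default_factory=dict)

    @property
    def profile(self) -> Profile:
        return tuple(self.strategy for _ in range(self.game.n_players))

    def weights_by_label(self) -> dict:
        return {
            lab: w
            for lab, w in zip(self.game.strategies, self.strategy.weights)
            if w
        }

    def support_labels(self) -> Tuple[str, ...]:
        return tuple(self.game.strategies[i] for i in self.strategy.support())

    def cooperation_rate(self) -> float:
        """Weight on the first strategy for 2x2 games (C by convention);
        mean action as a fraction of the maximum for graded games."""
        if self.game.n_strategies == 2 and getattr(self.game, "values", None) is None:
            return float(self.strategy.weights[0])
        grid = self.game.values if isinstance(self.game, SymmetricGame) else self.game.grid
        mean = sum(float(w) * float(v) for w, v in zip(self.strategy.weights, grid))
        return mean / float(max(grid))


def _result(
    game: Game,
    strategy: MixedStrategy,
    bs: BestStructure,
    coincides: bool,
    method: str,
) -> CooperativeEquilibriumResult:
    prof = tuple(strategy for _ in range(game.n_players))
    pay = expected_payoff(game, prof, 0)
    binding = tuple(
        p
        for p in range(game.n_players)
        if abs(expected_payoff(game, prof, p) - bs.v_star) <= FEAS_TOL
    )
    return CooperativeEquilibriumResult(
        game=game,
        strategy=strategy,
        payoff=pay,
        v_star=bs.v_star,
        v_selfish=bs.selfish.value,
        v_cooperative=bs.cooperative.value,
        coincides_with_nash=coincides,
        binding_constraints=binding,
        structures=bs,
        diagnostics={
            "method": method,
            "tie_between_structures": bs.tie,
            "tolerance": float(FEAS_TOL),
        },
    )


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------


def _quadratic_roots(A: Fraction, B: Fraction, C: Fraction) -> List:
    """Real roots of A z^2 + B z + C = 0, exact when rational."""
    if A == 0:
        return [] if B == 0 else [-C / B]
    disc = B * B - 4 * A * C
    if disc < 0:
        return []
    root = sqrt_exact(disc)
    return [(-B - root) / (2 * A), (-B + root) / (2 * A)]


def _diagonal_coeffs(game: SymmetricGame) -> Tuple[Fraction, Fraction, Fraction]:
    """u((z,z)) = A z^2 + B z + C with z the weight on strategy 0."""
    M = game.matrix
    A = M[0][0] - M[0][1] - M[1][0] + M[1][1]
    B = M[0][1] + M[1][0] - 2 * M[1][1]
    C = M[1][1]
    return A, B, C


def _mix2(game: SymmetricGame, z) -> MixedStrategy:
    if isinstance(z, Fraction):
        return MixedStrategy((z, 1 - z))
    return MixedStrategy((float(z), 1.0 - float(z)))


def solve_symmetric_diagonal(game: SymmetricGame, v_star) -> Tuple[MixedStrategy, bool]:
    """Symmetric cooperative equilibrium of a 2x2 symmetric game.

    Returns (strategy, coincides_with_nash).  If a symmetric Nash
    equilibrium of the original game is feasible it is returned unchanged;
    otherwise the smallest root of the diagonal-payoff equation
    u((z,z)) = v_star that survives the best-feasible-response check.
    """
    if game.n_strategies != 2:
        raise UnsupportedGameError("diagonal solver requires a 2x2 game")
    A, B, C = _diagonal_coeffs(game)

    def diag(z):
        return A * z * z + B * z + C

    # 1. feasible symmetric Nash equilibria of the original game
    nash_candidates: List[MixedStrategy] = []
    for z in (Fraction(1), Fraction(0)):
        s = _mix2(game, z)
        if is_nash(game, (s, s)):
            nash_candidates.append(s)
    ess = symmetric_mixed_equilibrium(game)
    if ess is not None:
        nash_candidates.append(ess)
    feasible_nash = [s for s in nash_candidates if diag(s.weights[0]) >= v_star]
    if feasible_nash:
        best = max(feasible_nash, key=lambda s: diag(s.weights[0]))
        return best, True

    # 2. binding boundary: roots of u((z,z)) = v*.  Several boundary points
    # can be equilibria of the restricted game; the solution concept selects
    # the feasible point closest to the original-game symmetric Nash play.
    ref = ess if ess is not None else (nash_candidates[0] if nash_candidates else None)
    ref_z = float(ref.weights[0]) if ref is not None else 0.0
    roots = [z for z in _quadratic_roots(A, B, C - v_star) if -FEAS_TOL <= z <= 1 + FEAS_TOL]
    roots = [min(max(z, Fraction(0) if isinstance(z, Fraction) else 0.0), 1) for z in roots]
    verified = []
    for z in sorted(roots):
        s = _mix2(game, z)
        if is_restricted_equilibrium(game, (s, s), v_star):
            verified.append((abs(float(z) - ref_z), s))
    if verified:
        s = min(verified)[1]
        return s, is_nash(game, (s, s), FEAS_TOL)
    # 3. no symmetric profile supports the threshold (asymmetric welfare
    # optimum): outside the solution concept's symmetric scope
    raise UnsupportedGameError(
        "no symmetric profile of the restricted game is an equilibrium; "
        "the induced game's equilibria are asymmetric"
    )


def solve_claim_game(game: SymmetricGame, v_star) -> Tuple[MixedStrategy, bool]:
    """Symmetric cooperative equilibrium over an ordered numeric strategy
    grid (Traveler's-dilemma-like games).

    Scans adjacent strategy pairs from the top of the grid downward for the
    highest pair whose mixture meets the threshold with equality and is a
    verified equilibrium of the restricted game.  All predictions in scope
    have support on at most two adjacent claims.
    """
    if game.values is None:
        raise UnsupportedGameError("claim solver requires numeric strategy values")
    m = game.n_strategies
    eqs = nash_equilibria_2p(game)
    # Nash coincidence: feasible original equilibrium (symmetric preferred)
    for prof in eqs.profiles:
        if prof[0] == prof[1] and expected_payoff(game, prof, 0) >= v_star:
            return prof[0], True

    M = game.matrix
    for h in range(m - 1, 0, -1):
        l = h - 1
        # weight p on the higher claim h
        A = M[h][h] - M[h][l] - M[l][h] + M[l][l]
        B = M[h][l] + M[l][h] - 2 * M[l][l]
        C = M[l][l]
        roots = [
            p
            for p in _quadratic_roots(A, B, C - v_star)
            if -FEAS_TOL <= p <= 1 + FEAS_TOL
        ]
        for p in sorted(roots, reverse=True):
            p = min(max(p, Fraction(0) if isinstance(p, Fraction) else 0.0), 1)
            w: List = [Fraction(0)] * m
            if isinstance(p, Fraction):
                w[h], w[l] = p, 1 - p
            else:
                w = [0.0] * m
                w[h], w[l] = p, 1.0 - p
            s = MixedStrategy(tuple(w))
            if is_restricted_equilibrium(game, (s, s), v_star):
                return s, is_nash(game, (s, s), FEAS_TOL)
    raise EmptyInducedGameError(
        f"no adjacent-support equilibrium reaches v*={v_star}"
    )


def solve_contribution_game(game: AggregativeGame, v_star) -> Tuple[MixedStrategy, bool]:
    """Symmetric cooperative equilibrium over a contribution grid
    (Public Goods / Tragedy of the Commons).

    The payoff is affine in actions, so the symmetric diagonal payoff is
    ``u(mu) = alpha + (beta + n*gamma) * mu`` in the common mean action mu.
    The equilibrium is the feasible mean closest to the selfish (dominant)
    action, realized as a mixture over the two adjacent grid points; moving
    any further toward the selfish action would push the other players below
    v*, while moving away lowers the player's own payoff.
    """
    n = game.n_players
    own_slope = game.beta + game.gamma
    diag_slope = game.beta + n * game.gamma
    selfish = max(game.grid, key=lambda x: own_slope * x)
    u_selfish = game.alpha + diag_slope * selfish
    if v_star <= u_selfish:
        idx = game.grid.index(selfish)
        return MixedStrategy.pure(idx, game.n_strategies), True
    if diag_slope == 0:
        raise UnsupportedGameError("degenerate game: welfare-neutral actions")
    if own_slope * game.gamma >= 0:
        raise UnsupportedGameError(
            "not a social dilemma: private gain does not harm the others"
        )
    mu = (Fraction(v_star) - game.alpha) / diag_slope
    lo_v = max((x for x in game.grid if x <= mu), default=None)
    hi_v = min((x for x in game.grid if x >= mu), default=None)
    if lo_v is None or hi_v is None:
        raise EmptyInducedGameError(f"threshold v*={v_star} unreachable on the grid")
    w = [Fraction(0)] * game.n_strategies
    if lo_v == hi_v:
        w[game.grid.index(lo_v)] = Fraction(1)
    else:
        p_hi = (mu - lo_v) / (hi_v - lo_v)
        w[game.grid.index(hi_v)] = p_hi
        w[game.grid.index(lo_v)] = 1 - p_hi
    return MixedStrategy(tuple(w)), False


# ---------------------------------------------------------------------------
# entry point
# ---------------------------------------------------------------------------


def cooperative_equilibrium(game: Game) -> CooperativeEquilibriumResult:
    """Compute the cooperative equilibrium of a symmetric social dilemma.

    Pipeline: assess the selfish and cooperative coalition structures,
    take the most optimistic value v*, build the induced game, and solve for
    its symmetric Nash equilibrium.
    """
    bs = best_structure(game)
    induced_game(game, bs.v_star)  # raises if inconsistent
    if isinstance(game, AggregativeGame):
        strategy, coincides = solve_contribution_game(game, bs.v_star)
        method = "contribution-grid"
    elif game.n_strategies == 2:
        strategy, coincides = solve_symmetric_diagonal(game, bs.v_star)
        method = "diagonal"
    elif game.values is not None:
        strategy, coincides = solve_claim_game(game, bs.v_star)
        method = "adjacent-claims"
    else:
        raise UnsupportedGameError(
            "explicit games with more than two strategies need numeric "
            "strategy values"
        )
    return _result(game, strategy, bs, coincides, method)
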