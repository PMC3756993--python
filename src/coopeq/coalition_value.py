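"""Incentive, risk, deviation probability, and the value of a coalition
structure.

For a coalition structure p with Nash set N(G_p) the model evaluates, from
the standpoint of one player (all players agree by symmetry):

* ``IF(p)`` — infimum of the player's payoff over N(G_p): what she is
  guaranteed if nobody abandons the structure.
* ``e(p)`` — incentive: the maximal gain from unilaterally abandoning the
  structure, i.e. the best payoff reachable by deviating from an equilibrium
  of G_p, minus the payoff at that equilibrium (never negative; zero at a
  Nash equilibrium of the base game, which is why the selfish structure is
  always stable).
* ``r(p)`` — risk: the maximal loss if she chases that maximal gain while
  the other players abandon the structure too — each either best-responding
  to her prescribed strategy (following their selfish interest) or
  best-responding to her deviation (anticipating it).
* ``tau(p) = e/(e+r)`` — the prior probability that a single player abandons
  the structure, a proportion between incentive and risk.  Conventions:
  ``e = 0`` gives 0 (a stable structure is never abandoned), ``e > 0, r = 0``
  gives 1.
* ``L(p)`` — infimum of her payoff if she keeps her prescribed strategy while
  the others play any weakly-improving deviation from the equilibrium.
* ``v(p) = (1-tau)^(n-1) * IF + (1 - (1-tau)^(n-1)) * L`` — the value: the
  payoff forecast, averaging the nobody-abandons and somebody-abandons
  scenarios.  Deviations of different players are treated as independent,
  hence the (n-1)-th power for the probability that no opponent deviates.

Deviation probabilities informed by individual covariates, and correlated
deviations, are outside this package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Tuple

from ._numeric import Numeric, to_fraction
from .games import (
    AggregativeGame,
    Game,
    MixedStrategy,
    Profile,
    SymmetricGame,
    expected_payoff,
)
from .nash import (
    CoalitionStructure,
    best_response_set,
    coalition_game,
)


def deviation_probability(e: Numeric, r: Numeric) -> Fraction:
    """Prior probability of abandoning a structure with incentive e, risk r.

    The incentive/risk proportion e/(e+r), with the conventions e=0 -> 0
    (no incentive, no deviation) and e>0, r=0 -> 1 (riskless gain is taken).
    """
    e, r = to_fraction(e), to_fraction(r)
    if e < 0 or r < 0:
        raise ValueError("incentive and risk must be nonnegative")
    if e == 0:
        return Fraction(0)
    if r == 0:
        return Fraction(1)
    return e / (e + r)


@dataclass(frozen=True)
class CoalitionAssessment:
    """Per-structure record of the model's intermediate quantities.

    The game is symmetric, so the per-player quantities coincide and are
    stored once.
    """

    structure: CoalitionStructure
    stable_infimum: Fraction  # IF(p)
    incentive: Fraction  # e(p)
    risk: Fraction  # r(p)
    deviation_probability: Fraction  # tau(p)
    deviation_infimum: Fraction  # L(p)
    value: Fraction  # v(p)
    degenerate: bool = False

    def as_dict(self) -> dict:
        from ._numeric import fraction_repr

        return {
            "blocks": [sorted(b) for b in self.structure.blocks],
            "stable_infimum": fraction_repr(self.stable_infimum),
            "incentive": fraction_repr(self.incentive),
            "risk": fraction_repr(self.risk),
            "deviation_probability": fraction_repr(self.deviation_probability),
            "deviation_infimum": fraction_repr(self.deviation_infimum),
            "value": fraction_repr(self.value),
            "degenerate": self.degenerate,
        }


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _gains(game: Game, eq: Profile, player: int) -> Tuple[Fraction, Tuple[int, ...]]:
    """Best deviation gain of ``player`` at equilibrium ``eq`` and the
    argmax pure deviations."""
    m = game.n_strategies
    current = expected_payoff(game, eq, player)
    best_val = None
    best_idx: list = []
    for s in range(m):
        prof = tuple(
            MixedStrategy.pure(s, m) if k == player else eq[k]
            for k in range(game.n_players)
        )
        val = expected_payoff(game, prof, player)
        if best_val is None or val > best_val:
            best_val, best_idx = val, [s]
        elif val == best_val:
            best_idx.append(s)
    return best_val - current, tuple(best_idx)


def _risk_2p(game: SymmetricGame, eq: Profile, dev: int) -> Fraction:
    """Maximal loss for player 0 playing deviation ``dev`` at ``eq`` while the
    opponent best-responds either to player 0's prescribed strategy or to the
    deviation itself."""
    m = game.n_strategies
    base = expected_payoff(game, eq, 0)
    dev_strat = MixedStrategy.pure(dev, m)
    replies = set(best_response_set(game, 1, eq))
    dev_prof = (dev_strat, eq[1])
    replies |= set(best_response_set(game, 1, dev_prof))
    worst = None
    for s in replies:
        val = expected_payoff(game, (dev_strat, MixedStrategy.pure(s, m)), 0)
        loss = base - val
        if worst is None or loss > worst:
            worst = loss
    return worst


def _weak_improving_set_2p(game: SymmetricGame, eq: Profile) -> Tuple[int, ...]:
    """Opponent strategies that weakly improve on her equilibrium payoff while
    player 0 keeps her prescribed strategy."""
    m = game.n_strategies
    current = expected_payoff(game, eq, 1)
    out = []
    for s in range(m):
        if expected_payoff(game, (eq[0], MixedStrategy.pure(s, m)), 1) >= current:
            out.append(s)
    return tuple(out)


def _assess_2p(game: SymmetricGame, structure: CoalitionStructure) -> CoalitionAssessment:
    eqs = coalition_game(game, structure).equilibria()
    m = game.n_strategies
    IF = min(expected_payoff(game, prof, 0) for prof in eqs.profiles)

    e = Fraction(0)
    attaining = []  # (eq, deviation) pairs attaining the maximal gain
    for prof in eqs.profiles:
        gain, devs = _gains(game, prof, 0)
        if gain > e:
            e, attaining = gain, [(prof, d) for d in devs]
        elif gain == e and gain > 0:
            attaining.extend((prof, d) for d in devs)

    if e == 0:
        r = Fraction(0)
    else:
        r = max(Fraction(0), max(_risk_2p(game, prof, d) for prof, d in attaining))

    L = min(
        expected_payoff(game, (prof[0], MixedStrategy.pure(s, m)), 0)
        for prof in eqs.profiles
        for s in _weak_improving_set_2p(game, prof)
    )

    tau = deviation_probability(e, r)
    v = (1 - tau) * IF + tau * L
    return CoalitionAssessment(structure, IF, e, r, tau, L, v, eqs.degenerate)


def _assess_aggregative(
    game: AggregativeGame, structure: CoalitionStructure
) -> CoalitionAssessment:
    n = game.n_players
    eqs = coalition_game(game, structure).equilibria()
    IF = min(expected_payoff(game, prof, 0) for prof in eqs.profiles)

    own_slope = game.beta + game.gamma
    selfish_action = max(game.grid, key=lambda x: own_slope * x)

    e = Fraction(0)
    anchors = []  # (eq action, deviation action)
    for prof in eqs.profiles:
        w = game.grid[prof[0].support()[0]]
        total = w * n
        current = game.payoff_from_actions(w, total)
        best = max(
            game.payoff_from_actions(x, total - w + x) for x in game.grid
        )
        dev = max(game.grid, key=lambda x: game.payoff_from_actions(x, total - w + x))
        gain = best - current
        if gain > e:
            e, anchors = gain, [(w, dev, current)]
        elif gain == e and gain > 0:
            anchors.append((w, dev, current))

    if e == 0:
        r = Fraction(0)
    else:
        # all opponents deviate to their (dominant) selfish best response
        r = Fraction(0)
        for w, dev, current in anchors:
            val = game.payoff_from_actions(dev, dev + (n - 1) * selfish_action)
            r = max(r, current - val)

    # L: keep the prescribed action while every opponent plays any
    # weakly-improving deviation; improvements are independent because the
    # own-action slope beta+gamma is profile-independent
    L = None
    for prof in eqs.profiles:
        w = game.grid[prof[0].support()[0]]
        improving = [x for x in game.grid if own_slope * x >= own_slope * w]
        worst_other = min(improving, key=lambda x: game.gamma * x)
        val = game.payoff_from_actions(w, w + (n - 1) * worst_other)
        L = val if L is None else min(L, val)

    tau = deviation_probability(e, r)
    nobody = (1 - tau) ** (n - 1)
    v = nobody * IF + (1 - nobody) * L
    return CoalitionAssessment(structure, IF, e, r, tau, L, v, eqs.degenerate)


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------


def assess(game: Game, structure: CoalitionStructure) -> CoalitionAssessment:
    """Full assessment (IF, e, r, tau, L, v) of a coalition structure."""
    if isinstance(game, SymmetricGame):
        return _assess_2p(game, structure)
    return _assess_aggregative(game, structure)


def incentive(game: Game, structure: CoalitionStructure, player: int = 0) -> Fraction:
    """e_i(p): maximal gain from unilaterally abandoning the structure."""
    _check_player(game, player)
    return assess(game, structure).incentive


def risk(game: Game, structure: CoalitionStructure, player: int = 0) -> Fraction:
    """r_i(p): maximal loss when the deviation meets the others' deviations."""
    _check_player(game, player)
    return assess(game, structure).risk


def value(game: Game, structure: CoalitionStructure, player: int = 0) -> Fraction:
    """v_i(p): the probability-weighted payoff forecast of the structure."""
    _check_player(game, player)
    return assess(game, structure).value


def _check_player(game: Game, player: int):
    if not 0 <= player < game.n_players:
        raise ValueError(f"player index {player} out of range")


@dataclass(frozen=True)
class BestStructure:
    structure: CoalitionStructure
    v_star: Fraction
    tie: bool
    selfish: CoalitionAssessment
    cooperative: CoalitionAssessment


def best_structure(game: Game) -> BestStructure:
    """The value-maximizing coalition structure and the threshold v*.

    Only the fully selfish and the fully cooperative structures need to be
    compared: the value of any intermediate partition is bounded by these
    two.  Ties are resolved in favour of the cooperative structure (the
    induced game does not depend on the choice) and flagged.
    """
    n = game.n_players
    a_s = assess(game, CoalitionStructure.selfish(n))
    a_c = assess(game, CoalitionStructure.cooperative(n))
    tie = a_s.value == a_c.value
    if a_c.value >= a_s.value:
        return BestStructure(a_c.structure, a_c.value, tie, a_s, a_c)
    return BestStructure(a_s.structure, a_s.value, tie, a_s, a_c)
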