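# Methods

## The solution concept

`coopeq` computes cooperative equilibria of symmetric social dilemmas.  The
concept rests on one behavioural postulate: players have an intrinsic
attitude to cooperation, so before acting they evaluate how the game would
be played under each *coalition structure* — every player for herself
(`p_s`, all singletons) or everyone together (`p_c`, the grand coalition) —
and commit to the structure with the most optimistic payoff forecast.  The
model has no free parameters: everything is computed from the payoff matrix.

### Scoring a structure

Under structure `p`, coalitions play as merged players maximizing summed
payoff; `N(G_p)` denotes the Nash set of that merged game.  For the grand
coalition the merged player controls the entire profile, so `N(G_p_c)` is
exactly the set of welfare-maximizing profiles.  Writing everything from one
player's standpoint (symmetry makes all players agree):

- `IF(p)`: infimum of her payoff over `N(G_p)`.
- incentive `e(p)`: the largest amount she can gain by unilaterally
  deviating from an equilibrium of `G_p`, clamped at zero.  At a Nash
  equilibrium of the base game no deviation gains, so `e(p_s) = 0` always.
- risk `r(p)`: the largest loss she can suffer when she plays that maximal-
  gain deviation while each opponent abandons the structure as well, playing
  a pure best reply either to her prescribed strategy (pursuing their own
  selfish interest) or to her deviation (anticipating it).  Maximal loss is
  measured against her payoff at the equilibrium she deviates from.
- deviation probability `τ = e/(e+r)`, the incentive/risk proportion, with
  `e=0 → τ=0` and `e>0, r=0 → τ=1`.
- `L(p)`: infimum of her payoff when she keeps her prescribed strategy but
  the others play any *weakly-improving* deviation from the equilibrium
  (improvement measured holding the rest of the profile fixed).  In the
  Prisoner's dilemma this is the sucker payoff.
- value `v(p) = q·IF(p) + (1−q)·L(p)` where `q = (1−τ)^(n−1)` is the
  probability that no opponent deviates; deviations of distinct players are
  assumed independent (anonymous one-shot play).  Correlated deviations and
  covariate-dependent `τ` (age, culture, decision time, …) are out of scope.

Only `p_s` and `p_c` are compared: the value of any intermediate partition
is bounded by these two in the families covered, so `best_structure`
evaluates exactly these, breaking ties toward `p_c` (the induced game does
not depend on the choice; the tie is flagged).

### The induced game and its equilibrium

`v* = max(v(p_s), v(p_c))` defines the induced game: the same game
restricted to profiles giving *every* player expected payoff at least `v*`.
A cooperative equilibrium is a Nash equilibrium of the restricted game.
Two facts drive the solvers:

1. If a symmetric Nash equilibrium of the original game is feasible, it is a
   cooperative equilibrium (coincidence case; flagged
   `coincides_with_nash`).  This covers every below-threshold regime.
2. Otherwise each player's payoff gradient points from cooperation toward
   the selfish play, so the symmetric equilibrium sits on the feasibility
   boundary `u(σ,…,σ) = v*` — the feasible point closest to the original
   Nash play.  Moving further toward selfish play would push the opponents
   below `v*` (infeasible), moving back lowers one's own payoff.

Every candidate is *verified*, not trusted from the geometry: an exact
best-feasible-response routine maximizes a player's linear payoff over the
simplex cut by the opponents' value constraint (optimum at a vertex or on a
binding edge) and the candidate is accepted only if no profitable feasible
unilateral deviation exists.  Random non-dilemma games showed the restricted
game can carry several symmetric boundary equilibria; the closest-to-Nash
selection resolves this, and when *no* symmetric profile supports `v*`
(asymmetric welfare optimum — outside the dilemmas' scope) the solver raises
`UnsupportedGameError` rather than guessing.

### Solvers by family

- **2×2 (PD, Chicken, donation PD)** — the diagonal payoff is a quadratic in
  the cooperation weight `z`; roots of `u((z,z)) = v*` are computed in
  rational arithmetic (exact when the discriminant is a perfect square,
  float otherwise).
- **Ordered claim games (Traveler's dilemma)** — the solver scans adjacent
  claim pairs `{k, k+1}` from the ceiling downward; for a pair the diagonal
  payoff is `k + p²` (bonus games), so the boundary weight is
  `p = sqrt(v* − k)`.  All published predictions have at most two-point
  adjacent support, and the equilibrium verification would reject anything
  else.
- **Aggregative games (Public Goods, Tragedy of the Commons)** — payoffs are
  affine in own action and the action sum, so the symmetric diagonal payoff
  is linear in the mean action and the equilibrium mean is
  `μ* = (v* − α)/(β + nγ)`, realized as a mixture of the two adjacent grid
  actions.  The solver checks the dilemma sign condition (private gain harms
  the others), which is what makes the binding boundary an equilibrium.

The Tragedy of the Commons (utility `g` per kept sheep, damage `d` per sheep
to everyone, `g > d`, `nd > g`) maps onto a Public Goods game with endowment
`g` and marginal return `d/g` — the effective cost of a sheep — up to an
additive constant; the package solves it natively and the equivalence is
tested exhaustively.

## Numerical choices

- **Exact rationals.**  Payoffs, values, incentives, probabilities, and
  grid-supported equilibrium weights are `fractions.Fraction`; the
  acceptance surface contains exact equalities (e.g. `v* = 1/10`,
  contribution support `{33/50, 67/100}`).  Floats appear only for
  irrational boundary weights (e.g. `sqrt(4/11)` on claim 297) with a
  feasibility slack of 1e−9, and in the float prefilters below.
- **Nash enumeration.**  Games with ≤ 6 strategies per player: exact support
  enumeration (Gaussian elimination over Fractions), all ties reported,
  degeneracy flagged when an off-support reply exactly matches the
  equilibrium payoff.  Larger games (121-claim Traveler's dilemma):
  vectorized pure-profile scan plus symmetric two-point supports with a
  float screen and exact verification — sufficient because every family in
  scope has pure or small-support symmetric equilibria.  Degenerate games
  report at most 200 vertex equilibria with the degeneracy flag set rather
  than positive-dimensional components.
- **Thresholds.**  The Public Goods cooperation threshold (smallest marginal
  return `a` where `v(p_c) > v(p_s)`) is found by bisection to 1e−6 on the
  exact value gap; the comparison involves only the zero and full
  contributions, so it is grid-free.  For `n = 2` it is exactly 2/3.
- **Brute-force oracle.**  An independent grid search over symmetric mixed
  profiles (step 1e−4 for 2×2) returns the feasible point closest to the
  original Nash play; it cross-checks the analytic solvers on the worked
  example and on 200 seeded random games.

## Scenario registry and treatment parameters

`predictions.REGISTRY` pins the nine case studies: the dollar-stakes PD
(0.20/0.15/0.05/0.00), a laboratory PD (1.00/0.80/0.35/0.00; predictions
are invariant under rescaling), the donation PD `(b, b−1, 0, −1)` swept in
the benefit `b`, the Traveler's dilemma at bonuses 5 and 180 (claims
180..300) and the 2..100-claim bonus-2 variant, the two-player Public Goods
game with marginal return 0.8 (endowment normalized to 1, grid 0.01), a
commons/public-goods equivalence instance, and a PD/Chicken pair built from
the same four payoffs {8, 5, 2, 1} with sucker and punishment swapped so
both games share the same outcome average.  Observed experimental rates are
carried as annotations in every report and are never asserted: the model
predicts population averages from payoffs, and matching individual
experiments is explicitly not a test criterion.

All scenario paths are deterministic; reports regenerate bit-identically.
Problem sizes are the published ones (121 claims, 101-point contribution
grid); the whole registry runs in about two seconds.

## What the tests do and do not show

The suite verifies the algebraic chain (incentive → risk → probability →
value → induced game → equilibrium) exactly on the published instances,
property-tests the comparative statics (cooperation monotone in the PD
benefit, predicted claims falling in the bonus, contributions rising in the
marginal return with a sharp threshold), and cross-checks the analytic
solvers against grid search.  None of this validates the behavioural
postulate itself: the model predicts population averages, abstracts from
framing effects, individual heterogeneity, and repetition, and its observed
accuracy rests on the cited experiments, not on anything a test here can
establish.

## Known limitations

- Symmetric games only; the asymmetric theory is a different (and larger)
  construction.  Games whose welfare optimum is asymmetric have no symmetric
  cooperative equilibrium and are rejected explicitly.
- Intermediate coalition structures are not solved (their values are
  dominated in these families); `coalition_game` raises for them on
  N-player games.
- Continuous strategy spaces are discretized (contribution grid, integer
  claims); equilibrium support is reported on the grid.
- Strongly degenerate games (payoff ties everywhere, e.g. a claim game with
  bonus 1) are handled through vertex truncation and flagged, not resolved
  into equilibrium components.
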