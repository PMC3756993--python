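# coopeq

Cooperative equilibria of symmetric social dilemmas — a parameter-free
solution concept that predicts population-average cooperation rates from
payoffs alone.

In a social dilemma (Prisoner's dilemma, Chicken, Traveler's dilemma, Public
Goods, Tragedy of the Commons) individually rational play is collectively
ruinous, yet laboratory subjects cooperate at rates that move systematically
with the payoffs.  `coopeq` implements a solution concept built for exactly
this observation: players do not act a priori as single agents, but forecast
how the game would unfold if they formed coalitions, then play according to
their most optimistic forecast.

## The model

For a symmetric n-player game G and a coalition structure p (a partition of
the players; only the all-singletons structure p_s and the grand coalition
p_c matter for these games), let N(G_p) be the Nash set of the game in which
each coalition plays as one merged player maximizing its summed payoff.
The structure is scored by

- **IF(p)** — the infimum of a player's payoff over N(G_p): what following
  the structure guarantees if nobody abandons it;
- **incentive e(p)** — the maximal gain from unilaterally abandoning the
  structure (zero at a Nash equilibrium, so p_s is always stable);
- **risk r(p)** — the maximal loss if the player chases that gain while each
  opponent abandons too, best-responding either to her prescribed strategy
  or to her deviation;
- **deviation probability τ = e/(e+r)** — the prior probability a player
  abandons p (conventions: e=0 → τ=0; e>0, r=0 → τ=1);
- **L(p)** — the infimum of her payoff if she keeps her prescribed strategy
  while the others play any weakly-improving deviation;
- **value v(p) = (1−τ)^(n−1) · IF(p) + (1 − (1−τ)^(n−1)) · L(p)**, with
  opponent deviations treated as independent.

The best value v* = max(v(p_s), v(p_c)) becomes a tacit binding: the
*induced game* allows only profiles giving every player at least v*, and a
**cooperative equilibrium** is a Nash equilibrium of this restricted game.
Geometrically it is the feasible profile closest to the original Nash play —
players slide from full cooperation toward their selfish equilibrium until
the value constraint stops them.  When the selfish forecast wins, the
cooperative equilibrium simply *is* the Nash equilibrium: the two concepts
are not disjoint.

## Worked example

The two-player Prisoner's dilemma in dollars with temptation 0.20, reward
0.15, punishment 0.05, sucker 0.00:

```python
import coopeq as cq

game = cq.make_prisoners_dilemma("0.20", "0.15", "0.05", "0.00")
res = cq.cooperative_equilibrium(game)
coop = res.structures.cooperative
print("v(selfish)     =", res.v_selfish)        # 1/20
print("v(cooperative) =", res.v_cooperative)    # 1/10
print("incentive      =", coop.incentive)       # 1/20
print("risk           =", coop.risk)            # 1/10
print("tau            =", coop.deviation_probability)  # 1/3
print("equilibrium    =", res.weights_by_label())      # {'C': 1/2, 'D': 1/2}
```

Output:

```
v(selfish)     = 1/20
v(cooperative) = 1/10
incentive      = 1/20
risk           = 1/10
tau            = 1/3
equilibrium    = {'C': Fraction(1, 2), 'D': Fraction(1, 2)}
```

Reading: defecting against a cooperator gains 0.05 but risks losing 0.10,
so a player abandons the grand coalition with prior probability 1/3.  The
cooperative forecast (2/3)·0.15 + (1/3)·0.00 = 0.10 beats the selfish 0.05,
and the restricted game's equilibrium has each player cooperating with
probability exactly 1/2 — against observed cooperation rates of 58% and 65%
in two framings of this game.

The same pipeline runs the other families — e.g. the Traveler's dilemma
with claims 180..300 mixes claims 296 and 297 at bonus 5 but collapses to
the Nash floor claim at bonus 180, and the two-player Public Goods game
with marginal return 0.8 contributes between 0.66 and 0.67 of the
endowment.  The full scenario registry is scriptable:

```bash
coopeq solve my_game.json          # any game-spec file
coopeq sweep PD --grid 1.5,3,5,10  # cooperation vs benefit-cost ratio
coopeq reproduce-paper --out reports/
```

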