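# Methods

## The game

One round of the Sir Philip Sidney game is a joint action (b, d) with
b ∈ {Not signal, Weak signal, Strong signal} and d ∈ {Give, Keep}, played
under a thirst state drawn once per round (thirsty with probability p).
Individual survival payoffs:

* donor: P_D = 1 if it keeps, U if it gives (0 < U < 1);
* beneficiary: base survival s = 1 with the resource, 0 if thirsty without
  it, V if not thirsty without it (0 < V < 1); a signal of cost c scales
  this multiplicatively, P_B = s·(1 − c). Costs are c = 0 (silent),
  0.25 (weak), 0.75 (strong) by default.

The multiplicative cost convention is forced by the not-thirsty
keep-after-signal payoff V(1 − c); with s = 0 it also reproduces the
thirsty keep cells, where signalling changes nothing.

Rewards are inclusive fitnesses F_B = P_B + r·P_D, F_D = P_D + r·P_B with
relatedness r ∈ [0, 1]. Two consequences drive everything else:

1. For any c > 0, F_B(N) ≥ F_B(W) ≥ F_B(S) cell by cell (strict whenever
   s > 0): signalling never pays, so the beneficiary's predicted strategy
   is always *Never signal*.
2. Against a silent beneficiary the donor prefers Give iff
   U + r > 1 + r(1 − p)V, i.e. iff r > (1 − U)/(1 − V + pV). The margin
   r − (1 − U)/(1 − V + pV) is returned alongside the verdict because
   near-threshold parameter sets are exactly those where learning
   discriminates the two actions least sharply.

The three replication presets are case1 (r=0.5, V=0.2, U=0.2; threshold
unmet, prediction {N,K}), case2 (r=0.8, V=0.1, U=0.9; met by a wide margin,
{N,G}) and case3 (r=0.9, V=0.75, U=0.95; met, but margin 0.1 — near the
limit).

## Learning agents

Both seats are independent tabular Q-learners. The observation state is the
previous round's joint action — six states NK…SG for memory m = 1, 6^m in
general (a config option appends the current thirst state to the
beneficiary's observation; it is off in the presets, which pin thirst for
the whole run). The donor, too, sees only the previous joint action, not
the beneficiary's current signal: the learning problem is treated as a
repeated simultaneous game on joint-action memory, which is what the
six-state donor tables imply.

Update rule, applied by each agent to the single entry it just played,
with the bootstrap maximum taken from the pre-update table:

    Q_t(s,a) = Q_{t-1}(s,a) + α (R_t + γ max_{a'} Q_{t-1}(s',a') − Q_{t-1}(s,a))

where s′ is the state formed by the joint action just completed. Tables are
initialised at 0. Defaults: learning rate α = 0.9, discount rate γ = 0.1,
500 rounds per dyad, the first 50 rounds fully exploratory (ε = 1),
afterwards ε = min(1, 2/N) with N the 1-based round number (≈ 0.039 at
round 51, 0.004 at round 500). Ties in the greedy argmax break uniformly at
random from the agent's own stream. Alternative decay rules ("1/N",
"constant:x") and static fixed-sequence seats are available for baseline
and robustness experiments.

The round-1 state is seeded with m uniformly random joint actions, keeping
the state space at exactly 6^m instead of adding a start-state row.

Seed discipline: run i of an experiment uses seed base_seed + i, split via
`numpy.random.SeedSequence.spawn` into one environment stream (history
seeding, thirst sampling) and one stream per agent. Re-running any seed
reproduces its record bit for bit; summaries carry the full seed ledger.

## Reading off the learned strategy

Strategies are the cyclic patterns of the taxonomy (beneficiary: NN, NW,
WW, NS, WS, NWS, NSW, SS; donor: KK, GK, GG, KKG; fallback OTHER). Two
readouts are implemented:

* **policy** (default): take both final Q-tables, form the greedy policies,
  and roll the joint dynamics out deterministically from the run's final
  state; on the finite state space this enters a cycle, and each agent's
  actions along the cycle are canonicalised (lexicographically smallest
  rotation under N<W<S, K<G) and looked up in the catalogue. This readout
  asks "what did the agent learn?" and is insensitive to the residual
  ε ≈ 0.004 exploration noise.
* **realised**: take the final 50 played actions, drop rounds flagged
  exploratory, and require exact periodicity (period ≤ 3) of the remainder.
  This readout asks "what did the agent do?". A late exploration that
  knocks an alternation out of phase sends the run to OTHER, so it
  undercounts period-2/3 strategies by design; it is the readout used for
  static seats (which have no policy table) and for validating the
  classifier on planted noisy streams, where it recovers every catalogue
  pattern at ≥ 99% under ε = 0.004 noise.

The policy readout is the default because it is the operationalisation
under which the simulator reproduces the study's reported strategy
proportions in all three cases; the realised readout reproduces case 1 but
systematically deflates the near-threshold case-3 alternations. The
classification window (50) and readout are configurable per experiment.

"Converged" Q-values are means over the final 100 rounds of each run
(snapshots are stored every round by default; a stride or 0 disables them,
as in the sweep). The donor gap statistic is grand-mean Q(Give) minus
grand-mean Q(Keep), where the grand mean averages the six per-state means
with equal weight.

## What the simulations do and do not show

Experiments are Monte-Carlo averages over 1000 independently seeded dyads —
the scale used for every reported statistic; the acceptance script runs
3 × 1000 case dyads plus 6 × 1000 sweep dyads in about 90 seconds. The
generator emulates the study's conditions exactly (fixed thirst state per
run, both p = 0 and p = 1 available; no populations, no partner choice, no
generational inheritance). It does not emulate real animal interactions:
payoffs are stationary, the opponent is the only source of
non-stationarity, and "generations" are compressed into within-dyad
learning steps. Passing tests therefore validate the algorithmic claims
about this model, not anything about biological signalling systems.

Known limitations, measured and deliberately left visible as failing
acceptance checks rather than papered over:

* **High-discount lock-in.** At γ = 0.9 the donor frequently locks into
  self-confirming Give/Keep alternations: on-cycle entries bootstrap up to
  their cyclic fixed point (≈ 9 in case 1) while off-cycle entries stay
  stale below it, and ε = 2/N supplies too little late exploration to
  discover the true optimum (≈ 11 for Always-Keep). The qualitative claim —
  for every learning rate, γ = 0.1 learns the predicted strategy at least
  as often as γ = 0.9 — holds robustly, but the sweep's Always-Keep floor
  is ~52%, not ~81%: substantially lower than the reference value, and the
  grid minimum falls at (0.9, 0.9) rather than (0.1, 0.9). No alternative
  reading of the ε schedule that we tested (constant 2/500,
  2/(N − 50), pure greedy) closes the gap without breaking the
  case-replication proportions.
* **Case-2 Q-gap level.** The converged donor gap in case 2 measures
  ≈ 0.50 (≈ 0.47 when averaged over the whole trajectory) against a
  reference value of 0.41; the case-3 gap (≈ 0.13 vs 0.139) and every
  qualitative feature (sharp separation far from the threshold, weak
  separation near it, K overtaking G in individual states) reproduce.
* **Thirst-state robustness is one-sided.** The donor's distribution and
  both modal strategies agree between p = 0 and p = 1, but the
  beneficiary's label distribution does not (case 1 NN: 88% vs 70%). This
  is structural: with p = 1 and a keeping donor, F_B = r regardless of the
  signal, so the beneficiary is reward-indifferent along the dominant path
  and its policy drifts; at p = 0, V > 0 creates a strict gradient. The
  equilibrium-level claim "p does not affect the outcome" reproduces; the
  distribution-level reading does not.

## Numerical choices

* All arithmetic is double precision; matrix-equality tests draw parameters
  on a dyadic (1/64) grid so payoff expressions are exact in binary and can
  be compared bit-for-bit against rational arithmetic.
* Threshold verdicts use the margin sign; the brute-force equivalence test
  skips |margin| < 1e-9, where division- and multiplication-form rounding
  may legitimately disagree.
* Degenerate inputs are rejected at construction (U, V ∈ (0,1) open,
  0 < c_weak < c_strong ≤ 1, rounds > explore_rounds, α ∈ (0,1] — a
  no-learning agent is expressed as a static seat, not α = 0).
* Q-values are bounded by R_max/(1 − γ); the engine's tests verify the
  bound on every snapshot rather than clamping.
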