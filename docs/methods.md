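# Methods

## Model

The package couples two descriptions of the same "mobilization-
participation" game between government resource subjects (GRSs) and
social resource subjects (SRSs).

**Well-mixed (mean-field) dynamics.** Strategies are described only by
the population fractions m (SRSs positive) and r (GRSs positive). The
expected gains of each strategy follow from averaging the payoff matrix
over the opposite population, and the replicator equations are

    dm/dt = m(1−m)[r(γ+δ) − c_e]
    dr/dt = r(1−r)[A − mB],   A = π_g−c_g+βδ+c_s+c_v,  B = c_s+βδ.

The SRS bracket shows the core dilemma: positive participation pays only
through the interventions, and only when facing a positive GRS, so the
participation fraction grows only when r(γ+δ) > c_e. Fixed points are the
four corners plus the interior candidate (A/B, c_e/(γ+δ)), which exists
only when both coordinates lie in the unit square (in particular the
interior point is undefined without interventions, γ+δ=0). Stability is
classified from the analytic Jacobian: stable iff Det(J)>0 and Tr(J)<0,
saddle iff Det(J)<0, unstable iff Det(J)>0 and Tr(J)>0, otherwise
non-hyperbolic. The interior point always has Tr(J)=0 (a center of the
asymmetric replicator flow), so it is never asymptotically stable. Note
that the textbook condition "corner (1,1) is stable when γ+δ>c_e" holds
only under the additional sign condition π_g−c_g+c_v>0; at the reference
parameters (π_g−c_g+c_v = −1) the all-positive corner is a saddle once
γ+δ>c_e. The classifier reports computed signs rather than a lookup
table.

**Networked dynamics.** Nodes carry an immutable role and a mutable
binary strategy. A round consists of (1) every node playing the stage
game with each cross-role neighbor and summing the gains into u_i —
same-role ties carry no game payoff, since the stage game is defined only
between an SRS and a GRS, but they remain learning channels; (2) a
synchronous update in which every node draws one neighbor j with
Boltzmann probability B_j ∝ exp((u_j+α_j)/λ) and adopts j's current
strategy with Fermi probability ω = 1/(1+exp((u_i−u_j)/ξ)). Strategy
labels transfer across roles: a GRS may copy "negative" from a
better-earning SRS neighbor. This cross-role imitation is what lets the
network outcome deviate from the mean-field prediction — in the
no-intervention baseline the mean field sends GRSs positive (corner (0,1)
is stable), while on the network GRSs imitate their far richer negative
SRS neighbors and the whole system collapses to all-negative.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| π_e | SRS routine operating return | 8 | payoff units |
| c_e | SRS participation cost | 2 | payoff units |
| π_g | GRS credibility gain | 3 | payoff units |
| c_g | GRS mobilization cost | 5 | payoff units |
| c_v | GRS credibility loss when passive | 1 | payoff units |
| c_s | public-dissatisfaction cost (joint negativity) | 2 | payoff units |
| β | penalty compensation rate | 0.3 | — |
| γ | reward to positive SRS facing positive GRS | 0 | payoff units |
| δ | penalty on negative SRS facing positive GRS | 0 | payoff units |
| λ | information-cost (softmax temperature) | 1 | payoff units |
| ξ | Fermi noise | 1 | payoff units |
| α_j | selection adjusting weight | 0 | payoff units |

The payoff defaults are the reference case study's calibration; γ=δ=0
encodes "no intervention". Simulations default to 100 rounds, 20
replicates, and an early stop after 20 consecutive rounds without a
strategy change (the quiescence window); the 68-node system absorbs or
settles well within that horizon, and the final-state statistic is the
replicate mean of the last window, which is robust to late single-node
flips. Replicate k is seeded `seed + k`, so each replicate is
independently reproducible and whole runs are bit-reproducible.

## Synthetic network generator

The case network the model was calibrated to (19 GRSs and 49 SRSs
extracted from news coverage of a city-level COVID-19 response, with both
cross-type and same-type cooperative ties) is not published. The
generator emulates its size, two-type composition, mixing and
connectedness: a random spanning tree guarantees connectivity, extra
uniform random edges meet a target mean degree (default 4), and a quota
of exactly round(p_same_type·edges) edges (default p_same_type = 0.3,
keeping cross-type ties dominant) is earmarked same-role, so the realized
mixing fraction concentrates tightly around the target across seeds.

What it does **not** emulate: the real network's degree distribution and
hub structure are unknown, and the generator produces a comparatively
homogeneous random graph. This matters because the imitation dynamics are
payoff-ranking dynamics, and with summed round gains the ranking is
degree-weighted. Results that depend on locally dominant hubs (see
limitations) are therefore sensitive to topology, which users can explore
through `GeneratorConfig` sweeps rather than assume away.

## Numerical choices

- Fixed-step RK4 (default step 0.01) for the replicator trajectories; the
  2-D field is smooth and non-stiff, and halving the step changes
  endpoints below 1e−8. States are clipped to the unit square only within
  round-off.
- Stability sign tests use a 1e−9 tolerance; anything inside it is
  reported non-hyperbolic rather than forced into a class.
- Softmax selection is computed with a max-shifted exponent; the Fermi
  rule short-circuits once the exponent would overflow (probability
  underflows to 0 there anyway).
- Initial strategies use exact-count assignment (round-half-up of
  fraction × group size, uniformly placed) instead of independent
  Bernoulli draws, reducing replicate variance at the stated initial
  proportions.

## Design choices on genuinely open points

- **Same-role ties**: zero game payoff, full learning connectivity. The
  payoff matrix defines only cross-role games; learning is the only
  defined channel for same-role ties.
- **Cross-role imitation**: on by default (`cross_role_learning`),
  switchable. Required for the baseline collapse described above.
- **Round gain u_i**: the per-round *sum* over neighbor games, reset each
  round (not a per-game mean), matching the usual accumulated-payoff
  convention of Fermi-rule network games.
- **Update scheme**: synchronous, all nodes each round; asynchronous
  variants are out of scope.
- **Penalty experiment**: the penalty sweep keeps γ=0 (whether any reward
  stays active there is open; it is a config switch).
- Sweep grids beyond the few published values (γ ∈ {0, 0.6, 1.2, 1.8},
  δ ∈ {0, 0.8, 1.6, 2.4, 3.2}, the four (m0, r0) pairs) are package
  defaults exposed in config, and summaries always record the grid used.

## Known limitations

- **Frozen positive clusters.** With summed round gains, an initially
  positive SRS earns at least π_e−c_e per cross edge while every GRS
  earns at most −min(c_v, c_g−π_g) per edge, so an SRS whose neighbors
  are all GRSs (or poorer SRSs) sits at a local payoff maximum; at
  λ=ξ=1 its flip probability is of order e^−8 per round and it is
  effectively frozen. This leaves a small positive residue in the
  baseline (final PPS ≈ 0.06 rather than exactly 0) and puts a floor
  under every cell of the intervention sweeps on the default generated
  topology. In particular, the penalty mechanism — negative SRSs earning
  8−δf per edge against positive SRSs' 6, with f the local fraction of
  positive GRS neighbors, crossing at δf = 2 — needs neighborhoods nearly
  saturated with positive GRSs to ignite, which the homogeneous generator
  topology does not produce from r0 = 0.1. The direction of the penalty
  and reward effects is reproduced (final PPS increases monotonically in
  both), but a sharp penalty threshold is not, and on this topology the
  sweeps separate from zero at every grid point rather than only above
  δ = 2.4.
- The engine is O(edges × rounds × replicates) pure-Python per round;
  it is sized for case-study networks (tens to hundreds of nodes), not
  for large-graph statistical physics.
- No weighted ties, dynamic rewiring, strategy mutation beyond the Fermi
  noise, or subdivided subject types.

## What passing tests show — and do not show

The test suite verifies the payoff matrix cells and their perturbation
structure exactly, the replicator closed forms against expected-gain
differences (≤1e−12 over 1000 random draws), the analytic Jacobian
against central finite differences, the corner Det/Tr closed forms, the
learning rules against brute-force normalization and direct Fermi
evaluation, and the engine's conservation/absorption/reproducibility
guarantees. The stochastic end-to-end checks run at the study scale
(68 nodes, 20 replicates) on *synthetic* networks; they show that the
implementation reproduces the qualitative intervention and
initial-condition effects under the generator's assumptions, not that
those effects hold on the unpublished real cooperation network or on
topologies with strong degree heterogeneity.
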