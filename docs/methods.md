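# Methods

`causalweb` infers directed causal networks from multivariate abundance time
series using convergent cross mapping (CCM), and ships two fully specified
community simulators used to study how the *timescale* and *taxonomic
resolution* of an analysis determine which interactions it can resolve.
This note records the models, the numerical conventions, and the design
choices made where the design was genuinely open.

## Convergent cross mapping

For a series pair (X, Y), the state space of Y is reconstructed by delay
embedding, `M_Y(t) = (y(t), y(t-τ), …, y(t-(E-1)τ))`. If X forces Y, the
attractor traced by `M_Y` carries an imprint of X, so states of Y can be
used to estimate contemporaneous or lagged values of X. The estimate at
query time t is the simplex projection over the E+1 nearest library rows
(Euclidean distance, the query's own row excluded):

    u_i = exp(-d_i / d_1),   w_i = u_i / Σu,   X̂(t+tp) = Σ w_i X(t_i+tp)

and the skill ρ is the Pearson correlation of X̂ with observed X over all
valid prediction times. High ρ is evidence that X causally influences Y; we
orient network edges accordingly (an accepted X→Y link means the states of
the *recipient* Y recover the *driver* X).

Numerical conventions:

- **Neighbor count** is E+1 (the simplex convention); configurable.
- **Ties** in neighbor distance are broken by ascending row time. Libraries
  up to 4000 rows use an exact exhaustive distance computation with this
  tie rule; larger libraries use a k-d tree with a 16-candidate surplus, in
  which exact-distance ties beyond the retrieved candidates follow the
  tree's deterministic ordering instead. Results are bit-reproducible in
  both paths.
- **Zero nearest distance**: all zero-distance neighbors share the weight
  equally; positive-distance neighbors get none.
- **Exclusion**: only the query's own time index by default; a wider
  Theiler window is available (`exclusion_radius`).
- **Degenerate results** (constant predictions or observations) carry
  ρ = NaN and a flag; they are never silently reported as zero.
- **Missing values**: embedding rows containing NaN are dropped; prediction
  times whose target is missing are excluded from ρ.
- **tp convention**: predictions target the driver at `t + tp`; the
  multiscale webs use `tp = -τ`, i.e. the recipient's present states
  recover the driver one coarse step into the past.

## Link acceptance: the two nulls

**Cross-correlation null** (model data): a link is accepted when the best
CCM ρ over the scanned embedding dimensions exceeds the maximum absolute
lagged Pearson cross-correlation between the pair, scanned over lags up to
the temporal span of the largest embedding (configurable, lag-0-only
available). This subtracts what linear association alone could achieve.

**Seasonal-surrogate null** (monthly data): the putative driver is
reshuffled within calendar months 100 times — preserving the seasonal
profile exactly, destroying all other structure — and the link is accepted
when the real ρ strictly exceeds at least 95 of the 100 surrogate ρ values.
The shuffled side is the driver by default (configurable). No
multiple-testing correction is applied by default, matching the per-link
95/100 rule; the acceptance additionally requires ρ > 0 in both nulls, as a
negative cross-map correlation is not causal skill.

## The individual-based automata (IBA) model

Three populations on a continuous 1000×1000 torus: resources (influx 500
per step, speed 10), primary consumers (PC; speed 10, feeding radius 10)
and secondary consumers (SC; speed 25, hunting radius 100). A PC that eats
nothing in a step dies; eating one resource sustains it; eating two adds
one offspring. SC survival requires 3000 prey encountered over the last 500
steps; 5000 trigger reproduction (at most once per 200 steps). The run
starts from 15,000 / 1,500 / 20 individuals and produces the three
abundance series.

Two design choices required completion beyond the headline rules, and both
were fixed by explicit viability studies, summarized here:

- **Offspring dispersal.** With offspring placed at the parent's position,
  the post-initialization famine (the initial PC population sits roughly
  three times above the influx-limited carrying capacity of ~450) is
  globally absorbing: the resource pool is exhausted everywhere at once and
  the PC bottleneck passes through ~1 individual. Offspring are therefore
  placed uniformly at random, which lets newborns sample the resource
  refugia that accumulate wherever consumers are momentarily absent; this
  yields indefinite R–PC coexistence (equilibrium ≈ 5500 resources, 405
  PCs).
- **SC consumption accounting.** A kill-and-remove reading caps each SC's
  intake at the *flux* of prey into its disc (~3 per step measured with
  immortal SCs), irreconcilable with the 3000-per-window survival
  threshold; the thresholds match *occupancy*-scale encounter counts
  (≈ 0.031·PC ≈ 12 per step at equilibrium). The model therefore credits
  each SC with every PC encountered within its radius per step, while the
  realized take is satiation-limited: each encountered PC is killed with
  probability `sc_kill_prob` (default 0.15) and removed. This keeps every
  threshold meaningful, sustains all three levels for 15,000+ steps, and
  preserves a genuine 1-step SC→PC mortality effect.

Other conventions: toroidal distances via a periodic spatial index (results
identical to exhaustive search); per-axis uniform movement in [-s, +s]
(fixed-magnitude displacement available); PCs feed exclusively in seeded
random order (a resource feeds one PC); PCs killed by SCs are removed
before the survival/reproduction phase; an SC cannot starve before it has
existed a full window (the window is undefined earlier); event order fixed
as move → PC feeding → SC hunting → PC demography → SC demography → influx.

**Emergent regime and its limits.** The default run equilibrates with PC
regulated at a few hundred and the SC count rising as a slow staircase
(reproduction events every few hundred to few thousand steps) toward a
ceiling where the 500-step prey census presses against the reproduction
threshold. The two consumer levels thus genuinely operate on separated
timescales, and the fast (τ=1) web resolves exactly the four 1-step
interactions while excluding the 500-step channel. The stationary SC count
cannot *oscillate*, however: the window-integrated census is nearly
noiseless and each ±1 change in SC shifts equilibrium PC by far less than
the gap between the survival and reproduction thresholds, so the count
always freezes into the stable band between them (verified across the kill
probability range, checkpointed versus rolling window checks, staggered
initial ages and dispersal kernels). As a consequence PC retains only a
weak slow component, and the τ=500 web resolves the links whose targets are
slow (SC→PC, SC→R, PC→R) but not the instantaneous-PC recovery demanded by
the strict PC→SC test: the skill of recovering a fast, nearly stationary
series from the slow consumer's states is information-bounded below the
lagged cross-correlation null. The integrated influence itself is fully
present — cross-mapping the 500-step rolling mean of PC from the SC states
attains ρ ≈ 0.98 — the limitation is specific to asking the slow web for
the *raw* fast series.

## The coupled logistic predator–prey model

Ten prey (P) and ten predators (R) update as

    P ← P + A_PP·R − α·P      (A_PP ≤ 0, predators depress prey)
    R ← R + A_RP·P − α·R      (A_RP ≥ 0, prey feed predators)

with α = 0.15, no within-guild couplings, and the reciprocal fold `v → 1/v`
applied elementwise wherever an abundance exceeds one. A connectance
parameter C sets the number of non-zero entries in each cross-guild block
(positions uniform without replacement; magnitudes uniform in
[0.025, 0.175], a configurable knob).

Negative values are left free rather than floored: prey receive only
non-positive inputs, so any non-negative floor forces monotone prey decay
and freezes the whole system — under the floor, zero of twenty series
retain variance at any tested magnitude and connectance. Unclipped, the
mixed-sign coupling and the fold keep trajectories bounded, and the map
sits on an onset-of-dynamics transition: below a connectance-dependent
coupling threshold the linear part is subcritical and all series collapse
to the fixed point; above it, bounded aperiodic fluctuation is sustained.
The default magnitude range places this transition inside the studied
C ∈ [0.3, 0.9], which is what generates the positive association between
fine-scale connectance and aggregate interaction strength; the range was
fixed by a pre-registered viability study (C = 0.6 runs alive in 10/10
seeds; transition visible at the low-C end).

Aggregate scoring sums the ten raw series per guild and cross-maps the
predator aggregate from the prey-aggregate embedding (E=5, τ=1, tp=−1) —
the influence of predators *on* prey, per the edge-orientation convention
above. A collapsed aggregate (variance < 1e−12) carries no dynamical
signal; its record is flagged degenerate and scored as zero resolved
strength, and such records are retained in the sweep correlation. Runs use
1000 steps with a 500-step burn-in, giving ≈ 490 usable embedding points.

## Synthetic monthly communities

The monthly generators emulate the two properties of field plankton series
that the surrogate pipeline must survive: strong cross-series seasonal
synchrony, and (optionally) genuine nonlinear coupling. Each series is a
logistic map whose growth rate is modulated by a shared sinusoidal month
effect, with small dynamical process noise (sd 0.03), observation noise
(sd 0.02), and a shared multiplicative bloom envelope (amplitude 0.5) on
the recorded values. Three details matter and were fixed by a calibration
study before the test suite was written:

- The two members of a pair have distinct base growth rates (3.7 / 3.55):
  identical maps under identical forcing entrain to the same subharmonic
  cycles, a *real* dependence beyond the monthly profile that no
  month-preserving surrogate should be expected to absorb.
- The process noise breaks residual deterministic entrainment to the
  seasonal cycle for the same reason.
- The bloom envelope, being a deterministic function of the month, is
  exactly preserved by within-month shuffles and supplies the strong
  synchrony (monthly-mean correlation 0.87–0.98 across seeds).

With these defaults the 95/100 rule accepts 6.5% of 200 uncoupled pairs
(nominal 5%) and 100% of coupling-0.4 pairs at E=3, τ=1, tp=0, n=30 years.
What passing these calibrations does *not* show: the generators have no
trend, no observation gaps, and far simpler noise than real monitoring
data, so field results additionally depend on the 35-non-zero-points
filter and the sqrt-min-max normalization applied upstream.

The two-timescale fixture couples A↔B at lag 1 and drives C from B delayed
by 24 samples. A delayed (rather than integrated) slow channel is used
deliberately: with a moving-average drive, recovery of the instantaneous
fast series is bounded below the cross-correlation null by the same
argument as in the IBA slow web, whereas a delayed chaotic drive is
invisible at τ=1 (the fast embedding's information is 24 chaotic iterations
stale) and aligns exactly with the τ=24 embedding (validated: slow link
accepted 5/5 seeds, fast link 1/5 borderline flukes).

## Analysis conventions

- Species series are normalized by sqrt-min-max (subtract the minimum,
  divide by the range, square root) before any CCM, damping
  order-of-magnitude spikes' influence on neighbor distances.
- Functional-group aggregates sum min-max-normalized members (no square
  root at that stage), giving each species equal weight.
- Monthly analyses default to E=12, τ=1, tp=0; annual-scale analyses reuse
  τ=12 with E capped so the embedding spans at most a third of the series.
- Taxa with fewer than 35 non-zero samples are dropped (inclusive
  boundary; configurable).
- The linked-versus-unlinked comparison of species-level cross-link counts
  uses a one-sided Welch t-test (alternative: linked > unlinked), reported
  descriptively when either class has fewer than two pairs.
- Every stochastic stage draws its stream from a master seed; re-running a
  configuration reproduces all outputs byte-for-byte.

## Problem sizes used in the shipped studies

The automata study runs the full 15,000 steps at the default population
sizes. The connectance sweep uses 100 simulations (the qualitative
association is stable from a few dozen onward). The surrogate calibration
uses 200 uncoupled and 50 coupled pairs of 30 years each. The CCM core
checks use 100 random oracle instances, a 500-point self-map and 50
directionality replicates.

## Known limitations

- The IBA slow web resolves the 500-step channel through the slow target
  series but not the strict instantaneous PC→SC recovery (see above); the
  package reports the full per-link table so both orientations are visible.
- The cross-correlation null is not a calibrated significance test; on
  near-independent series it admits occasional small-ρ acceptances.
- CCM assumes deterministic coupled dynamics observed without long gaps;
  heavily stochastic or non-stationary systems can defeat both nulls.
- Functional-group aggregation assumes members share a timescale; the
  aggregate of fast and slow members has no single embedding that is
  optimal for both.
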