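# Methods

## Model

The simulator couples two timescales on a circular one-dimensional
lattice of `n` trees: slow plant turnover (10% of adults replaced per
step; a step represents five years at 2%/yr mortality) and fast
microbial community dynamics on every tree. Each of the `k` plant
species is the preferred host of exactly one mutualist and one pathogen
taxon, so both guilds carry `k` taxa. A guild's compatibility with a
host is two-valued: 1 on the preferred host and the guild affinity
`s_f ∈ [0, 1]` elsewhere (`s = 0` strict specialist, `s = 1` full
generalist). All non-preferred hosts are equivalent.

Within a host, each guild follows Lotka–Volterra competition with
logistic growth toward a shared carrying capacity (normalized to 1 per
taxon per tree). Host identity enters only through powers of the
compatibility: growth rates scale as `e^q` and competitive effects as
`e^c`. We define `e^x := 0` whenever `e = 0`, so a strict specialist
has no growth and no competitive effect on non-preferred hosts even for
non-positive exponents, where the literal power would be undefined.
Guilds never interact directly; mutualists and pathogens couple only
through the seedling survival response.

Seedling survival at a cell is `ζ_j · σ(g (h θ_m − θ_p))` with the
standard logistic `σ(x) = 1/(1 + e^{-x})`. A published variant of this
response appears in print as `1/(1 − e^{-x})`, which is singular at 0
and negative for negative arguments; it is clearly a typesetting slip
and is kept only behind the `literal_logistic` flag for audit. `g`
(range 5–15) sets the steepness of the microbial impact, and `h`
(0.2–1.5) the weight of mutualist benefit relative to pathogen harm.
Plant fitness `ζ_j` is evenly spaced from `ζ_min = 0.8` to 1 across
species; because the recruitment weight is `seeds_j · ζ_j · σ_j`,
fitness acts exactly like a fecundity difference (the least-fit species
effectively produces 20% fewer seeds).

## Dispersal and propagule flow

Seeds and microbial propagules disperse with a truncated discrete
power-law kernel. On the finite circle we fold the two directions onto
the circular distance `min(|i−j|, n−|i−j|)` and renormalize the weights
over the `n` cells, so every deposition step conserves mass exactly;
the infinite-lattice half-line normalizer (e.g. `π²/6` at `b = 2`)
survives only as a cross-check in the tests. Self-deposition (distance
0) is included.

Microbial fecundity `γ_f` is the proportion of a cell's microbes
dispersed as propagules per step. The dispersed fraction leaves its
source: `F ← (1−γ) F + γ · deposit(F)`. This choice matters. An
arrivals-only (purely additive) reading lets any taxon whose within-host
decline rate `r_f s_f^{q_f}` is near zero accumulate propagule mass at
a rate of `(1+γ)` per step, equilibrating near `γ/(r s^q)` — an order
of magnitude above carrying capacity at specialist trait values — which
saturates the survival response and erases all feedback structure. The
conservative form keeps abundances at the carrying-capacity scale that
the guild dynamics assume. The additive and transient-pool variants
remain available via `propagule_mode`.

## Recruitment and the recruit's microbiome

A vacated cell censuses the seed rain of all species (continuous
expected counts; dead adults still cast seed, having been alive at the
step-start census) and the post-immigration microbial community of the
cell — the dead adult's community plus arriving propagules. One recruit
is drawn from the multinomial with weights `seeds_j · ζ_j · σ_j`.

The recruit's initial microbiome is the local community filtered by
compatibility-scaled competitive ability: taxon `i` starts at
`F_i · e_{i,recruit}^{c}`. The recruit's own taxa therefore establish
at their local propagule abundance and grow toward capacity over the
following steps, while poorly compatible taxa restart near zero and can
only re-invade through immigration. Two alternatives are implemented
and rejected as defaults: renormalizing the filtered community to the
local guild total hands the recruit's own pathogen the entire standing
load in a single step (an instantaneous home-site penalty rather than
the gradual pathogen build-up the dynamics otherwise produce), and pure
inheritance of the local community lets non-preferred loads survive
every occupancy turnover, homogenizing the survival field (pairwise
feedback collapses to ≈ −0.005 with between-species spread far below
measurable levels) and destroying coexistence.

## Measuring feedback

Pairwise feedback uses the home/away survival contrast
`I_s = S(a_A) + S(b_B) − S(a_B) − S(b_A)`; a species' focal value is
the mean of its pairwise entries, `I_max` the least-negative pairwise
entry. Survival matrices average the *microbial* survival component
`σ(g(h θ_m − θ_p))` over all cells occupied by each adult species.
Fitness `ζ_j` is excluded: it is a fecundity effect, constant across
host contexts, and including it adds `ζ_a (σ_home − σ_away)` to every
contrast — a mechanical term that makes fitter species' feedback more
negative regardless of their soil community and anti-correlates
feedback with abundance. (`survival_matrix(include_fitness=True)`
restores the literal weighted reading.)

`I_s` is always measured under one protocol: microbial communities
settle for 50 steps without host mortality (competition and immigration
only), then the survival field is censused. At the start of a run this
is measured on a fresh lattice (the initial `I_max` used as an outcome
predictor); at the end of a run the settling continues from the final
state, and the correlation `ρ` is computed against the final
pre-settling abundances. Settling removes single-snapshot measurement
noise — immediately after a mortality wave, survival fields reflect
half-grown recruit microbiomes rather than the standing community.

The equilibrium metric `P_e` is the two-sided one-sample t-test p-value
of the most-common species' abundance changes over 100-step windows in
the final 600 steps (series thinned to every 10th step). Windows are
disjoint *and share no endpoints* (five changes at the defaults):
overlapping or endpoint-sharing windows correlate the changes
(r = −1/2 between neighbours) and destroy the t-test's calibration,
whereas with independent changes `P_e` is uniform on [0, 1] for a
stationary series — the property the test suite checks. Degenerate
zero-variance series return `P_e = 1` when flat and 0 under a
deterministic trend.

Microbial richness uses a presence threshold of 0.01 (1% of one tree's
carrying capacity, lattice total) since the continuous dynamics only
reach zero asymptotically.

## Experiments

Outcome labels per run: **coexistence** (all `k` plants extant at the
end), **strong negative feedback** (initial `I_max < −1.5`), and the
**abundance correlation** criterion (`ρ > 0.8`, `σ(I_s) > 0.02`,
`I_max < 0`, plant and both microbial richnesses = `k`).

Ablations run normally to a trigger step (default 800, the equivalent
of 4 000 years) and then zero the chosen guild's effect in the survival
response, leaving the microbial populations themselves evolving (a
delete-populations variant exists). Fixed-microbiome runs freeze each
species' lattice-mean community at the trigger: existing adults adopt
their species mean, every later recruit receives it, and competition
and immigration stop. All randomness flows from one root seed through
named substreams with a fixed draw count per step, so a run and its
ablated twin are bit-identical up to the trigger.

The random-forest layer delegates to scikit-learn's
`RandomForestClassifier` (default classification hyperparameters,
out-of-bag votes for accuracy/precision/recall) on class-balanced
samples; importance is permutation importance normalized by its
standard deviation, and per-sample feature contributions are computed
by decision-path attribution (the change in node-mean positive
probability at each split credited to the split feature; bias plus
contributions reconstructs the prediction exactly).

The particle swarm uses inertia `w = 0.5` and attraction `c = 0.8`; at
each step the surrogate forest is retrained on all archived runs and
each particle is attracted toward one of the ten most promising
evaluated parameterizations; four random particles are re-randomized
per step; positions clip to the trait bounds with clipped velocity
components zeroed. The hierarchical driver halves the number of
independent swarms stage by stage (16 → 8 → 4 → 2 → 1), pooling
archives as swarms merge.

## Numerical choices

Guild dynamics integrate with classical RK4 at 10 sub-steps per
simulation step, clamping negative intermediates to zero (extinction is
absorbing); single-taxon trajectories match the closed-form logistic to
better than 1e-4. Dispersal uses FFT circular convolution (equal to the
O(n²) double loop to 1e-12). Replacement counts round half-up. Recruit
draws use one inverse-CDF uniform per vacated cell so stream
consumption is identical across intervention variants.

## Scales used in the packaged tests, and what they show

The published behaviour was established at 499 trees × 3000 steps with
48-run ensembles; the packaged suite reproduces it at reduced scales
chosen to keep the default test run on one CPU within minutes:

* reference ensemble: 5 replicates at 199 trees × 1000 steps;
* sweeps: 192 runs at 99 trees × 600 steps, plus a 1300-draw
  initial-feedback screen for the rarer strong-negative label;
* ablations: 24 paired replicates at 151 trees × 1000 steps;
* drift limits: 50 trees.

Scale matters for two statistics. The per-replicate abundance–feedback
correlation weakens as the lattice shrinks (demographic fluctuations at
199 trees blur the fitness-ordered abundance spread that the pathogen
persistence signal tracks; at 499 × 3000 the measured ρ is 0.9–1.0,
at 199 × 1000 it averages ≈ 0.7 with replicate-to-replicate spread
±0.3). And fixation of the fittest species after feedback removal is a
selection–drift race: with adjacent-fitness advantage s ≈ 5%, `2Ns ≈ 5`
at 50 trees, so the fittest fixes in ~80% of replicates (a well-mixed
Moran model at the same fitnesses gives ~60%) rather than the
near-certainty that holds at `2Ns ≈ 53` for the published lattice.
Tests assert the direction and magnitude attainable at their stated
scale.

## What the simulator does and does not emulate

All data are generated by the model itself; there is no external input.
The model abstracts away seed dormancy, age-structured fecundity,
abiotic heterogeneity, host-specific carrying capacities, microbial
evolution, and two-dimensional space (dynamics in 2-D are expected to
run faster than on the 1-D circle). Passing tests show the
implementation's internal consistency and its reproduction of the
model's published qualitative regimes — not that real forests obey
these dynamics.
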