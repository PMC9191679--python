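# Methods

This note documents the models, estimators and design choices behind
`antquorum`, in the order data flows through the package: the colony model,
the synthetic recording generator, the measurement pipeline, the
statistics, and the simulation studies with their problem sizes.

## 1. The two-stage binary network model

Each of N ants is a binary variable σᵢ ∈ {−1, +1} (+1 = behaviorally
"perturbed"/active, −1 = "relaxed"). All state changes are probabilistic
through the logistic activation

    P(σᵢ = +1) = 1 / (1 + exp(−β hᵢ)),

where hᵢ is the ant's integrated input and β sets how deterministic the
response is. The dynamics are split into two stages separated by
timescale, and the separation is absolute by assumption: stage 1 sees only
temperature, stage 2 only social input.

**Stage 1 (individual, fast).** hᵢ = T − θᵢ with individual thresholds
θᵢ drawn from 𝒩(θ_m, θ_SD), untruncated (negative draws have negligible
probability at the defaults θ_m = 34 °C, θ_SD = 2 °C). Each ant updates
once, independently. The resulting active fraction is
m₀ = (1/2N) Σ(σᵢ + 1).

**Stage 2 (social, slow).** Mean-field, all-to-all input common to every
ant:

    h(m) = N^{α_p} J_p m − N^{α_r} J_r (1 − m)   (state-dependent), or
    h(m) = N^{α_p} J_p m − N^{α_r} J_r           (state-independent),

the latter modeling a nest-marking aggregation signal that does not track
the ants' momentary states. The scaling exponents interpolate between
saturating local contact interactions (α ≈ 0) and globally pooling
pheromone-like interactions (α ≈ 1). Dynamics are asynchronous: per step
one ant, chosen uniformly at random with replacement, resamples its state
from the logistic applied to the current h(m); one cycle = N steps; runs
last 20 cycles from the all-relaxed state (stage 1 then sets the initial
condition). A sequential-permutation update scheme (each cycle updates
every ant once, in random order) is available as an option.

For β₂ large the state-dependent dynamics are bistable with stable fixed
points at m = 0 and m = 1 and a separatrix at

    m_c = N^{α_r} J_r / (N^{α_p} J_p + N^{α_r} J_r),

so the colony evacuates when stage 1 pushes m₀ past m_c, and the
collective threshold solves P(θᵢ < θ_c) = m_c:

    θ_c = θ_m + θ_SD Φ⁻¹(m_c).

With α_r > α_p, m_c grows with N and the collective threshold rises
sublinearly with colony size; with α_p = α_r it is size-invariant. In the
state-independent variant the active fixed point exists only when
N^{α_r−α_p} J_r / J_p < 1; otherwise the colony cannot respond and the
separatrix routine returns an explicit no-response flag.

**A run's collective outcome** is scored as final m ≥ 0.5. With bistable
dynamics and 20 cycles the final m is almost always near 0 or 1, so the
cutoff is immaterial; the acceptance studies confirm bimodality
implicitly through the exactness of the separatrix crossing.

**Exact finite-colony analysis.** Stage 2 is threshold-free — h depends on
the states only through the active count k — so the asynchronous dynamics
reduce to a birth–death chain on k ∈ {0..N} with up-rate (1−k/N)·p(h) and
down-rate (k/N)·(1−p(h)). Powering the (N+1)-state transition matrix over
20N steps gives exact finite-time response probabilities. These serve
three purposes: the separatrix oracle (the 0.5-crossing of the exact
absorption probability vs. the analytic m_c), validation against a fully
enumerated 2^N transition matrix in the tests, and the generator's exact
ground-truth threshold (below).

**Two corrections the closed form ignores**, both relevant when comparing
simulation to θ_m + θ_SD Φ⁻¹(m_c):

1. *Soft separatrix.* At finite β₂ the unstable fixed point of the
   stochastic dynamics solves sigmoid(β₂ h(m)) = m, not h(m) = 0. For
   m_c ≠ 1/2 this sits slightly toward the nearer absorbing state and
   biases the simulated threshold (≈ +0.03 °C at β₂ = 10, N = 100,
   m_c = 2/3 — larger than the Monte-Carlo SE at 500 runs/temperature).
   The threshold-consistency study therefore uses β₂ = 50, where the
   shift is negligible; the closed form is the deterministic limit.
2. *Binomial discreteness.* m₀·N is an integer; the continuity correction
   shifts the effective threshold by O(1/N) in m-space (≈ 0.01 °C at
   N = 100). Visible only below the Monte-Carlo noise floor here.

**Model defaults.** β₁ = 2 °C⁻¹ (stage 1), β₂ = 10 per input-unit
(stage 2), J_p = J_r = 0.1, α_p = α_r = 1, 20 cycles. Exact coupling
values behind the published figures are not available, so the defaults
are chosen to put a 36-ant colony robustly in the bistable regime
(β₂·N·J ≈ 36 ≫ 1) with a symmetric separatrix; studies that need the
deterministic limit or the asymmetric architecture say so explicitly
(§6). All parameters are dataclass fields, exposed everywhere.

## 2. The synthetic recording generator

The generator emulates the *tabular output of a video tracker* watching a
colony in a 100 × 100 mm arena — not images, not the tracker itself. Its
defaults are the study conditions: colonies of 36 workers nesting as a
Gaussian cluster (SD 5 mm) around a fixed nest point, ~5% scouts doing
reflected random walks across the arena, 15-min step-temperature events
every 2 h spanning 29–43 °C, and slow relaxation back to the nest.

Per frame it emits one blob per ant (area 2 mm² with log-normal jitter,
σ = 0.2) plus one merged "nest blob" whose area is proportional to the
count of ants within 2 scatter-SD of the nest center, calibrated
(a_unit = π(2·SD)²/N) so its circular-equivalent radius is ≈ 2·SD at full
occupancy — this single blob exercises both the area weighting of the
nest-location estimator and the nest-radius definition. Tagged
trajectories (`ants` table) carry the same positions keyed by ant.

**Behavior per event.** The spin model (run over the nest cluster: the
non-scout ants inside the 15 mm response circle) decides each ant's fate:

- *Responders* (active at the end of stage 2) depart from their nest spot
  along a shared event direction (uniform) with individual von Mises
  spread (κ = 8), walk at 5 mm/s to an exit ring 35 mm from the nest,
  stay out, and return after the event end with exponential delay
  (mean 300 s) — colony-level relaxation on the sub-hour scale.
- *Transients* (thermally excited in stage 1, or recruited at some point
  during stage 2, but relaxed at the end) make a sub-response excursion
  to an "excited ring" between the nest radius and the 15 mm circle
  (uniform 11–13.5 mm), never crossing it, with excitement persisting at
  least 180 s and relaxing on the slow timescale (180 s + Γ(2, mean
  150 s), everyone home by onset + 13 min). This is the near-nest
  excitement phase: without it, failing events would show no early
  activity at all and the early-window state distribution would be
  artificially bimodal.
- Everyone else stays put (positions get 0.3 mm measurement jitter).

**Latencies.** Fast stage: Γ(shape 2, mean 90 s) — the 1–3 min
individual response. Slow stage: 240 s + Γ(shape 2, mean 180 s), total
mean 420 s. The onset delay keeps the slow process's mass in the 4–10 min
band, consistent with the premise that at 3–4 min the fast process has
run its course while the slow one is not yet apparent; a plain
Γ(2, mean 420) would put 43% of recruit departures before 5 min and
contaminate the early window. All latencies of an event are multiplied by
a shared log-normal "tempo" factor (σ = 0.9) — fast events and slow
events, coherent across ants — calibrated once so that pooled pairwise
latency correlations land near the experimentally observed ~0.5–0.6;
per-ant draws are then truncated so every departing ant crosses the 15 mm
circle comfortably before the event ends.

**Ground truth.** The generator records, per (ant, event): missing status
(outside the 15 mm circle at onset — scouts, mostly), binary response,
crossing latency and crossing direction (computed geometrically from the
straight-line path); per event: the final order parameter and whether the
colony fully evacuated; and per recording: the colony's **exact
collective threshold** — the temperature where P(full evacuation) = 0.5,
computed by pushing the Poisson-binomial stage-1 activation distribution
(given the colony's realized θᵢ) through the exact birth–death absorption
probability into the all-active state. This per-colony definition, rather
than the population formula, is the estimand the pipeline's quorum-0.9
response actually measures; the population value differs by the
colony-to-colony threshold spread θ_SD/√N ≈ 0.34 °C. Degenerate regimes
(spontaneous cascade, or inhibition so strong the colony never fully
evacuates) return ∓∞.

Determinism: one root `numpy` Generator is spawned into independent
streams (thresholds / spin dynamics / behavior / measurement noise), so
identical seed + config reproduces byte-identical tables.

**What the generator does not emulate**, and hence what passing tests do
not establish about real data: tracker segmentation errors and identity
swaps (blobs never merge except the idealized nest blob); partial
evacuations (the mean-field colony is all-or-none, so synthetic binary
responses of ants in the same event are identical — pairwise binary
correlations are exactly 1, whereas real colonies show ≈ 0.4); nest
relocation (the nest center is stationary); temperature dynamics (the set
temperature is used directly; no heating/cooling transients); and any
interaction spatial structure (the exponents α are the abstraction).

## 3. Feature extraction from blob tables

Coordinates are millimetres, origin at the arena's lower-left corner, y
upward, distances Euclidean.

- **Nest location**: per frame, the per-axis area-weighted median of blob
  centroids (axes independent), smoothed by a **trailing** median filter
  over [t − k, t] with k = 10 min — trailing, not centered, matching the
  definition of the estimate "at" a time. Weighted-median convention:
  lower weighted median (first sorted point whose cumulative weight
  reaches half the total), with an exact tie at half resolved to the
  midpoint with the next point; the convention is oracle-tested against
  brute force and the weighted-L1-minimizer property.
- **Nest radius**: the nest blob is the blob maximizing an
  area/(distance+1 mm) score relative to the current center (largest blob
  nearest the nest, with deterministic tie-breaking); with centroid+area
  data the radius is the circular-equivalent √(area/π) times a
  configurable aspect factor (default 1 — adapters with pixel moments can
  supply the semimajor axis instead). Median-filtered with the same k;
  the same window is used for radius and location since no separate
  duration is specified anywhere.
- **Activity fraction** f_out: area share of blobs strictly farther than
  the nest radius from the nest center, with center and radius **frozen
  at the event onset**. Note this uses the nest radius (≈ 10 mm), a
  smaller circle than the 15 mm individual-response circle.
- For event-based analyses the nest estimate at one onset is computed
  directly on the frames of its trailing window (`onset_nest_estimate`),
  which is the same definition as the full trace evaluated at that time.

## 4. Response measures

- **Individual** (radius 15 mm, minimum 30 s, both exposed): b = 1 at the
  first exit of the circle that starts within the perturbation and is
  sustained ≥ 30 s; τ = time from onset to that crossing; α = angle of
  the crossing point relative to the nest→arena-center ray, in (−π, π].
  Ants outside the circle at onset are missing values. Sampling
  semantics: a run of j consecutive strictly-outside samples at spacing
  dt counts as j·dt seconds outside, and a single-frame re-entry breaks
  the run (literal reading; at 1 Hz the distinction is negligible). The
  sustaining 30 s may extend past the event end; the exit itself may not.
- **Collective** (quorum 0.9, minimum 30 s, both exposed): B = 1 iff
  f_out > 0.9 — strictly — for ≥ 30 consecutive seconds within the
  perturbation window. Trace gaps longer than the minimum duration are
  flagged. A (quorum × duration) sweep utility probes robustness;
  raising either parameter can never create a response (tested).
- **Time-course aggregates**: events are classed by the response
  probability at their temperature — strong (p > 0.9, keeping only
  B = 1 events), weak (p < 0.1, keeping only B = 0), intermediate split
  by B — and the event-aligned activity curves averaged per class. The
  fraction (not count) of active ants is used; within an experiment the
  two differ by the constant N.
- **State histograms**: per intermediate event, the median f_out in the
  3–4 min and 14–15 min windows after onset (right-closed at the event
  end). The late window's bimodality — the signature that slow social
  feedback has driven the colony to one of its two fixed points — is
  quantified with Hartigan's dip statistic and a uniform-bootstrap
  p-value, a quantitative sharpening of what histograms show visually.

**Dip statistic.** Implemented from scratch (no maintained
implementation is available in the environment): the classical iterative
greatest-convex-minorant / least-concave-majorant algorithm. It is
validated in the tests against an exact oracle that computes the dip from
its definition — the minimax sup-norm fit of a unimodal CDF to the
empirical CDF, solved as a linear program per candidate mode
(piecewise-linear CDF with knots at the data and an atom allowed at the
mode) and minimized over modes — plus closed forms (two equal atoms →
1/4; equispaced points → 1/(2n)). The bootstrap p-value simulates the
null from uniform samples, the asymptotically least-favorable unimodal
distribution, with the add-one convention.

## 5. Collectivity and threshold statistics

- **Pairwise correlations**: Pearson per ant pair across events,
  pairwise-complete over non-missing events; pairs with fewer than 3
  complete events or zero variance are undefined. Binary responses use
  Pearson on 0/1 (the phi coefficient); directions are treated linearly,
  adequate because per-event directions are narrowly dispersed around the
  event mean. Correlations are computed within colony and pooled (36
  ants → 630 pairs per colony, 1,890 over three).
- **Permutation null**: each shuffle independently permutes every ant's
  row across events (missing entries move with their positions, so each
  ant's marginal response multiset and missingness count are preserved);
  the statistic is the pooled mean pairwise correlation; one-sided
  p = #(null ≥ observed)/n, reported as "< 1/n" at zero exceedances
  (add-one convention available). Under this convention the test is
  exactly level-α for continuous statistics (ties make it conservative).
  Complete matrices take a vectorized path (batched row shuffles and one
  batched matrix product per colony) that makes 10⁵-shuffle runs cheap;
  the masked generic path and the fast path are checked against each
  other in the tests. Minimum-3-complete-events pair formation is this
  package's choice; nothing else is stated anywhere.
- **Settling filter**: keep events whose mean activity in the 15 min
  before onset is strictly below twice the median of that quantity across
  all events (median computed once, unfiltered). All-zero pre-activity is
  a documented degenerate case: everything is retained, with a warning.
- **Threshold fit**: maximum-likelihood logistic regression of B on
  temperature; θ_c = −β₀/β₁, the temperature at fitted probability 0.5 —
  the standard psychometric definition. The Newton/IRLS core is
  in-package (bootstrap and coverage studies need ~10⁵ refits; statsmodels
  is the independent cross-check in the tests, for both coefficients and
  covariance). Complete separation is detected up front; the fit is
  flagged and θ_c falls back to the midpoint between the highest all-0
  and lowest all-1 temperatures with an infinite-slope marker. Empirical
  per-temperature response probabilities carry the asymptotic normal
  binomial band.
- **Bootstrap CI**: case-resample over perturbation events (colony-level
  resampling deliberately not the default: events are the exchangeable
  unit in the pooled design), percentile 2.5/97.5 over replicate θ_c;
  one-class or single-temperature replicates are dropped and counted,
  and the CI is flagged unreliable past 50% degenerate replicates.
- **Group-size model**: per-size logistic fits (sizes with one response
  class flagged None) plus a pooled fit with temperature and group size
  as covariates; the size coefficient's Wald 95% CI is reported.
  Replicate colonies of a size are pooled unweighted, with no random
  effects and no multiple-testing correction anywhere.

## 6. Simulation studies and problem sizes

All randomness flows from explicit seeds; `scripts/acceptance.py` derives
independent sub-seeds from `--seed` and reruns everything from scratch in
about five minutes on one CPU.

- *Separatrix oracle*: five configurations at N ≤ 8; exact chain; the
  0.5-crossing agrees with m_c to within the lattice resolution 1/N.
  Deterministic.
- *Threshold consistency*: N = 100, 500 runs per temperature on a 0.5 °C
  grid, β₁ = 10 (so individual noise ≪ θ_SD), β₂ = 50 (deterministic
  separatrix; see §1), symmetric (m_c = 1/2) and J_r = 2J_p (m_c = 2/3)
  cases; Monte-Carlo SE via case bootstrap over runs.
- *Size scaling*: N ∈ {10, 20, 50, 100, 200}, 200 runs/temperature,
  β₂ = 50 — with α_p = 0 the excitatory coupling no longer grows with N,
  so a larger β₂ is what keeps small colonies bistable. Asymmetric
  (α_p=0, α_r=1, J_p=1, J_r=0.02: m_c from 0.17 to 0.80 across the
  sweep) vs. symmetric control.
- *Permutation calibration*: 1,000 independent Bernoulli(½) 36×24
  datasets, 999 shuffles each, rejection at p ≤ 0.05.
- *Pipeline recovery*: 500 replicate colonies, each a fresh 36-ant colony
  through a 30-event protocol (29–43 °C twice each), full pipeline, 200
  bootstrap replicates. Recordings are generated at 0.4 Hz with events
  40 min apart — all measurement rules are specified in seconds, so
  subsampling and schedule compression only require that relaxation
  completes before each pre-onset settling window, which the return-delay
  truncation guarantees.
- *Bimodality signature*: 10 replicate colonies (the pooled experiment's
  colony count) under the standard sweep; intermediate events classed by
  the fitted response probability in (0.1, 0.9) — with two events per
  temperature per colony the empirical frequency only takes values
  {0, ½, 1} and is too coarse to define the class; dip p-values at 1,000
  uniform bootstraps.

## 7. Known limitations

- The mean-field model has no space; the exponents α summarize interaction
  geometry, and nothing here models pheromone physics.
- All-or-none collective outcomes: partial evacuations, visible in real
  colonies, do not occur, so synthetic binary-response correlations
  saturate at 1 and the binary-measure permutation test on synthetic data
  exercises only the maximal-coordination regime.
- The generator's nest is stationary; relocation events and the resulting
  nest-tracking burden on the median filter are untested beyond the
  constructed drift fixtures.
- The state-independent inhibition variant is implemented and
  unit-tested but not exercised by the acceptance studies; its
  no-response regime is flagged rather than simulated.
- Real tracking noise (identity swaps, merged blobs, dropped frames) is
  not emulated; the gap-flagging in the collective response is the only
  concession to missing data in traces.
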