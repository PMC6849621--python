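# Methods

This note records the models implemented in `coredisorder`, the choices
made where the design was genuinely open, and what the synthetic study
conditions do and do not establish about real data.

## Competition model (`lv`)

The rate equation is

    dn_i/dt = [c_i (h_i − Σ_j α_ij n_j) − d_i] · n_i

with abundances as fractions of pristine capacity, `α_ii = 1`, and
`k_i = h_i − d_i/c_i`.  Closed forms: a dominant/subdominant pair settles
at `n_i* = (k_i − α_ij k_j) / (1 − α_ij α_ji)` (clipped at zero), and a
fugitive third species (zero delivered impact) at
`n_3* = k_3 − α_31 n_1* − α_32 n_2*`.  The numerical oracle integrates the
same equation with LSODA in geometrically growing chunks until
`max |dn/dt| < 1e-9` (horizon 1e5 time units); non-convergence is flagged,
never silently accepted.  Stiffness is not expected at these parameter
scales, and the tolerance comfortably separates the 1e-6 agreement asserted
between the two routes.

Habitat-degradation scans apply one `h` community-wide, evaluate the
piecewise closed-form equilibrium on a descending grid (default 201 points
on [0, 1]), treat abundances below 1e-8 as extinct, and refine each
threshold by bisection to 1e-6 in `h`.  Per-species `h` is supported in
the rate equation but not in scans, matching the community-wide
degradation narrative.  Abundance-dependent impact coefficients
(discontinuous regime switches) are out of scope.

## Nestedness temperature (`disorder`)

Pipeline: build the 15 × n presence matrix of a sliding window (presence =
abundance strictly above a cutoff, default 0; all-zero columns dropped —
a species absent from the whole window carries no information, while an
all-zero *row* is a real observation and is kept), pack it canonically,
solve the fill line, score surprises, scale to [0, 100].

**Packing.** Rows sort by richness, columns by incidence, both descending;
ties break by the incidence-weighted sum of the orthogonal marginals and
finally by label.  Keys move with their rows/columns, so any permutation
of the input packs to the same cell pattern (asserted as a test).

**Fill line.** In cell-centre coordinates (x rightward, y downward, unit
square), the expected-presence region is the superellipse
`x^p + y^p ≤ 1`; its area `B(1/p, 1 + 1/p) / p` (Beta closed form) is
matched to the matrix fill by Brent root-finding on log p.  The test suite
cross-checks the closed form against numerical quadrature to 1e-8.
Exponents are cached by fill value, since sliding windows revisit the same
rational fills constantly.

**Surprises.** A cell counts as a surprise only if it is (a) on the wrong
geometric side of the fill line (presence outside, absence inside) *and*
(b) discordant within its packed column — a presence below an absence, or
an absence above a presence.  Criterion (b) is the departure from a purely
geometric rule, and it is deliberate: a perfectly nested matrix has a
*staircase* boundary which always crosses the equal-area smooth fill line,
so a purely geometric rule scores spurious surprises on it (the vegan
reference implementation indeed returns 0.3–1.2° for subset chains).  With
the dual criterion the surprise set is empty exactly when rows form a
subset chain, giving the definitional 0° for perfect nestedness while the
geometry still sets every surprise's magnitude.  Deviations are measured
along the 45° transect through the cell to the fill line, normalised by
the transect length inside the unit square (the classic temperature-
calculator convention).

**Scale.** Temperature is the mean squared surprise deviation over all
cells, times `100 / 0.04145` — the worst-case mean squared deviation
constant of the classic calculators — and clipped at 100° for the rare
random matrix that would exceed it.  Exact numeric parity with any legacy
implementation is not promised; agreement is at the level of the
invariants (0° iff subset chain, permutation invariance, bounds) plus
rank correlation > 0.95 with vegan's `nestedtemp` on assorted random and
noisy-nested matrices, asserted in the suite via Rscript.

## Diversity (`diversity`)

`N2 = 1 / Σ p_i²` with `p_i = √pct_i / Σ_j √pct_j`: proportions are taken
*after* the square-root transform, the reading on which N2 is scale
invariant and bounded by richness (both asserted as property tests).

## Sequential correlation diagnostic (`signal`)

A window of 15 paired observations contributes 14 first differences; the
lead-in uses all strictly earlier differences and is reported once at
least 5 exist.  Pearson coefficients carry two-sided p-values from the
t-transform with n − 2 degrees of freedom; no multiple-testing correction
is applied across dates (the diagnostic is exploratory; per-date
significance dots are how its output is read).  Zero-variance windows
yield missing values, never zero.  Dates never enter the computation —
every coefficient is provably invariant under monotone re-dating, which
the suite asserts bit-exactly; this is what makes the diagnostic immune to
sediment compaction.

Regime labels formalise the narrative reading of the coefficient pair
(thresholds `strong = 0.3` and `alpha = 0.05` are module defaults, not
empirical constants): keystone-favored when the pretransition coefficient
is significantly negative and at least `strong` below the lead-in;
weed-favored when significantly positive and above the lead-in;
canary-favored when significantly positive but not above the lead-in
(in-phase fluctuation without amplification, the loosely-interacting
case); otherwise indeterminate.

`window_sensitivity` re-runs the whole pipeline per candidate window size
(matrix rows and correlation window move together) and averages |pre-r|
over the dates eligible for every candidate.

## Break points and forecasts (`breakpoints`)

The sequential t-test detector uses the standard settings: significance
`alpha = 0.05`, minimum regime length `cutoff = 5`, Huber weight 1.  The
critical difference between regime means uses the average within-window
variance and the two-sided t at `2·cutoff − 2` df; a candidate value
beyond it starts a confirmation pass whose cumulative Huber-weighted
regime-shift index must stay non-negative through the next `cutoff`
points.  After a failed confirmation the point is absorbed and the regime
mean recomputed over the *whole* current regime — a recency-capped mean
was found to absorb genuine shifts before they could re-trigger.

Prewhitening removes an AR(1) component estimated by subsampling:
bias-corrected (Marriott–Pope) lag-one estimates over consecutive blocks
of 10 points, dropping the largest block estimate when three or more are
available (a block astride a shift inflates its estimate), averaging the
rest, clipping to [0, 0.95]; fewer than two valid blocks disable
prewhitening.  A whole-series autocorrelation is unusable here — the mean
shifts being sought inflate it toward 1 and erase themselves.

Operating characteristics measured by the suite (1000 Monte-Carlo series
each): on stationary white noise of 40 points the confirmed-break rate per
tested point stays below the nominal level (the confirmation window and
Huber weighting make the sequential test conservative — deliberately so,
since false alarms are the costly error for an early-warning tool); a
sustained step of 3 pre-step standard deviations in AR(0.3) noise at the
midpoint of 60 points is detected in ≳98% of series.

`fit_forecast` is plumbing around statsmodels ARIMA: the differencing
order comes from an augmented Dickey–Fuller test at the 5% level, (p, q)
from AIC over a 3 × 3 grid, forecasts carry 95% prediction intervals, and
an exceedance helper reports the fraction of later observations outside
them.

## Agent-based simulator (`abm`)

Discrete-time, well-mixed, species-level binomial updates: each individual
dies with its species' realised death probability, each survivor
reproduces with probability `c_i · max(0, h − Σ_j α_ij ñ_j)` (fractional
abundances against a capacity of 600).  The expected per-capita change
matches the rate equation to first order in the per-step probabilities
(asserted within 3 standard errors over 10⁴ one-step replicates, with the
second-order `d·b` discrepancy bounded explicitly).

Pairwise impacts come from two per-species factors — delivered impact and
vulnerability — with `α_ij = vulnerability_i · deliver_j` times pair noise
U(0.8, 1.2).  The default trait regions encode the role structure and are
the calibrated study conditions of the simulation experiment:

| region   | R = c/d    | deliver    | vulnerability |
|----------|-----------|------------|---------------|
| keystone | 2.0–2.6   | 1.2–1.5    | 0.85–1.05     |
| weed     | 10–20     | 0.2–0.4    | 1.4–1.6       |
| canary   | 2.0–2.6   | 0          | 1.6–2.0       |

Three consequences of these numbers matter.  Intra-keystone coupling
slightly exceeds the intraspecific unit impact, so keystone founders
exclude later keystone arrivals and the keystone guild stays species-poor.
Keystone pressure times weed vulnerability exceeds the weed establishment
margin, so weeds are *excluded* while keystones stand and flood in when
they fall — the release that makes the period-3 richness bloom.  Canaries
are viable nowhere once the community is established; they keep arriving
(one invasion attempt per step, uniform over roles) and go rapidly
extinct, remaining the rarest category throughout.

Forcing: period 1 constant baseline `d0 = 0.05` (80 steps), period 2 a
square-wave toggle ±0.04 with half-period 40 around the same mean (160
steps), period 3 the same toggle around a mean rising 0.0012 per step
(100 steps), preceded by a 15-step discarded burn-in.  Species share the
slow mean but respond to the toggle excursion *asynchronously*: each
species' realised death probability scales the anomaly by a fresh mean-one
lognormal draw (σ = 0.8).  This is the load-bearing mechanism for the
disorder signal: under a purely community-wide mortality, die-off and
recovery are synchronized, poorer censuses are near-subsets of richer
ones, and forcing produces *ordered* (cold) loss; heterogeneous responses
to shared forcing are what scatter the losses into compositional
disorder.  A constant environment is exactly quiet under this scheme,
which is also what the control run (toggling from t = 0 turns the period-1
coefficient negative) relies on.

Censuses require at least 4 individuals for presence — the analogue of a
fixed microfossil count per section — so suppressed species flicker at the
detection limit and dying invader colonies (2 founding individuals) never
register unless they truly establish.  °disorder is computed per step on
the sliding 15-census presence window; N2 on the detected species'
percentage abundances.  The per-period correlation is the mean of
Pearson coefficients over all sliding 15-point windows of the level
series inside the period, mirroring the empirical 15-point diagnostic; a
single whole-period coefficient is dominated by the period's stationary
stretches and under-weights the transition dynamics that carry the
signal.  Cross-replicate summaries use Student-t 95% intervals over
replicate means (15 replicates by default).

Under these defaults the per-period correlation sign pattern
(non-negative, negative, positive) appears in ~95% of seeds; the suite
asserts ≥80% over 20 seeds.  The magnitudes (≈ +0.13, −0.08, +0.08) are
not calibrated to anything and should not be compared with empirical
coefficients.

## Synthetic cores (`synthetic`)

The generator is a Markov-style presence model, not the ABM: a frequent
pool of 20 species whose membership moves by nested prefixes (ordered
states) or random subsets (disordered states), plus 15 independent
ephemerals, with per-cell flip noise 0.015 and near-even abundances
(U(0.5, 1.5) weights scaled to 100%), so N2 tracks richness closely.
States alternate every `phase_length` sections; the default of 1 models
year-to-year opposite-phase fluctuation at the sampling scale — sections
at 1–2 yr intervals undersample multi-annual community cycles, and an odd
15-point window then aligns the °disorder and biodiversity differences
step by step, which is also why `window_sensitivity` peaks at 15 on these
cores.

Mode wiring: *anti-phase* alternates rich nested sections (16 frequent,
few ephemerals) with poor random subsets (5 frequent, ephemerals at
0.25); *in-phase* alternates poor nested sections with poor-frequent but
ephemeral-rich sections (ephemerals at 0.6) — ordered loss against
disordered gain; *disordered* decouples richness from ordering.  These
settings are the study conditions under which the end-to-end recovery
tests run: the final-date pretransition coefficient is significantly
negative (anti-phase) or positive (in-phase) in ≥90% of seeds, measured
at ~100% and 98% over 60 seeds when the defaults were fixed.

Dating: equal 2-yr steps with 5% jitter, or a compaction mode whose
increments grow with depth; `perturb_dates` re-maps dates by a strictly
monotone power-law stretch (non-monotone mappings are rejected) and is the
instrument for the exact compaction-robustness assertions.

**What passing these tests shows — and does not.** The synthetic cores
have near-even abundances, a fixed species pool, no taxonomic structure,
no autocorrelated dating error, and an alternation whose period is chosen;
real cores have none of these guarantees.  Green recovery tests establish
that the pipeline detects the phase structure it is defined to detect, at
realistic window sizes and noise levels — not that any particular lake
record contains that structure.

## Numerical conventions

Seeds fully determine every stochastic output (replicates spawn from a
`SeedSequence`; bit-identical reruns are asserted).  Degenerate inputs are
errors, not silent values: empty incidence matrices, all-zero abundance
vectors, zero-variance correlation windows (missing, not zero), fills of
0 or 1 (a full matrix is defined as 0°), non-monotone dates, unknown
configuration keys.  Problem sizes in the test suite (20 seeds × 15
replicates for the simulation experiment, 100 seeds per recovery mode,
10³ Monte-Carlo series for the detector) are chosen to hold the quoted
rates' Monte-Carlo error well inside the asserted margins.
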