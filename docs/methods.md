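# Methods

`ryrblock` implements the kinetic-analysis chain used in single-channel
electrophysiology to characterise gating of the cardiac ryanodine receptor
(RyR2) and its open-channel block by quaternary ammonium (QA) cations:
aggregated Markov gating models, stochastic simulation of recordings,
hidden-Markov idealization, dead-time-aware dwell-time fitting, maximum
interval likelihood (MIL) model ranking, and blocker statistics.  This note
records the models, the numerical choices, and what the synthetic-data
validation does and does not establish.

## Aggregated Markov gating models

A channel is a continuous-time Markov chain on states grouped into
conductance classes: CLOSED (0 current), OPEN (full amplitude) and BLOCKED
(a subconductance level; a QA ion partially occluding the RyR2 pore leaves
~20% residual conductance for TBA and ~14% for TPeA).  Only the class is
observable.  Off-diagonal generator entries are the rate constants k_ij
(s^-1); rows sum to zero.  Equilibrium occupancies solve pi Q = 0 (SVD null
space); Po and Pb are summed occupancies of the OPEN and BLOCKED classes.

Class sojourn times follow phase-type laws: with Q_AA the within-class
submatrix and phi the equilibrium entry distribution (stationary
probability flux into the class, matching steady-state recording), the
density f(t) = phi exp(Q_AA t)(-Q_AA)1 decomposes over the eigenvalues of
Q_AA into exponential components (tau_m, area_m).  Areas are event
fractions.  Complex eigenvalue pairs (possible for strongly cyclic
schemes) trigger a warning and only the real parts are reported; all
schemes shipped here have real spectra.

## Preset schemes and their calibration

The dwell-time tables the presets are built to reproduce give, per class,
exponential time constants and areas; the underlying rate constants are
not published.  Preset rates are therefore *derived* so the analytic
components equal the table values exactly:

- **emd4** (EMD-activated channel): C1 – O1 – O2 chain with an O1 – C2
  flicker branch and no C1–C2 edge.  Closed sojourns are single-state
  visits, so the closed components are exactly (0.35 ms, 54%) and
  (10.7 ms, 46%) by setting state exit rates to 1/tau and the O1 exit
  split to the area ratio.  The coupled open class is calibrated in closed
  form: for target eigenvalues -s1, -s2 and slow-component area A (0.35 ms
  at 14%, 23.7 ms at 86%), the O1 exit-to-closed rate is
  r1 = s1 - A(s1 - s2), the O2→O1 rate d = s1 s2 / r1 and the O1→O2 rate
  c = s1 + s2 - d - r1.  A consequence worth noting: with entry at O1, no
  rate assignment can make the O2 state lifetime itself ~24 ms *and* give
  the 23.7 ms dwell component 86% area — the long open component arises
  from O1↔O2 cycling (O2 lifetime ≈ 3.6 ms here).  The dwell table, being
  the measured quantity, wins.  Equilibrium Po is 0.80, inside the
  high-activity (Po ≥ 0.7) regime the modelling targets.
- **tba5** (TBA block): C1, C2, O, B1, B2 with B1↔O↔B2 and closings
  hanging off B1; no closed–open edges (at 200 µM blocker, direct C↔O
  transitions are unresolvable).  Blocked components exactly (0.25 ms,
  1.06 ms); closed components exactly (4.0 ms, 10.7 ms).
- **tpea5** (TPeA block): same states plus a direct B1↔B2 edge (the bound
  blocker reorients in place).  The coupled blocked class is calibrated by
  the quadratic R1 + R2 = s1 + s2, R1 R2 = s1 s2 + k12 k21 to put its
  eigen-components at (1.0 ms, 11.2 ms); flicker closings persist at
  0.6 ms.

Values the tables leave open were fixed once at realistic magnitudes and
are not experimental estimates: TBA's long closed lifetime kept at 10.7 ms
(ligand-gate closures unchanged by the blocker), brief blocked lifetimes
0.25 ms (TBA) and 1.0 ms fast mode (TPeA), mean open sojourn under block
3 ms, B1↔B2 exchange 300/60 s^-1, entry splits as in `fixtures.py`.

## Synthetic recordings

Dwell sequences are sampled exactly (Gillespie): sojourns are exponential
with mean 1/|q_ii|, successors proportional to outgoing rates.  Rendering
integrates the piecewise-constant level signal over each sample interval
(sub-sample events contribute their area, as an analog anti-alias filter
would), adds Gaussian noise, applies a digital 8-pole Bessel approximation
(-3 dB at the cutoff; bilinear design) and compensates its constant group
delay so levels stay aligned with the event clock.  Defaults are the
acquisition conditions the analysis chain expects: 20 kHz sampling, 5 kHz
cutoff, 30 pA full openings (~750 pS at +40 mV in symmetric 610 mM K+).

Noise is per class: 1.5 pA RMS at the closed baseline and 3.0 pA at the
open level (SNR ≈ 10, the default adopted for a quantity no source
states; user-settable), with blocked levels interpolated by conductance —
open-channel noise exceeding baseline noise is a robust feature of real
recordings, and it is load-bearing here: at a *uniform* 3 pA the TPeA
blocked level (4.2 pA) sits 1.4 sigma from baseline and sub-millisecond
closings from the blocked level are physically undetectable.  Noise is
added before the filter and pre-scaled so the quoted values are
post-filter RMS.

What the generator does **not** emulate: baseline drift, 50 Hz
interference, capacitance transients, multi-channel records, open-channel
noise spectra beyond a white+filter model, and voltage-dependent rates
(EMD-activated gating is treated as voltage independent).  Passing
round-trip tests therefore demonstrates correctness of the analysis chain
under stable-baseline, single-channel conditions, not robustness to every
artefact of bilayer data.

## Idealization (segmental K-means)

Initial class amplitudes come from a 1-D Gaussian-mixture EM fit to the
amplitude distribution of low-slope samples (|x[i+1] − x[i−1]| below twice
its median — the conventional all-points histogram with filter-transition
samples excluded), initialised from prominence-selected histogram peaks,
quantiles, a uniform grid and k-means, best likelihood winning.  Plain
k-means (the obvious alternative) splits the dominant open cluster rather
than separating the small closed/blocked levels and is kept only as an
option.  SKM then alternates Viterbi segmentation (numba kernel) with
re-estimation of class means, per-class SDs and the per-sample transition
matrix until the Viterbi log-likelihood is stable (rel. 1e-8, max 30
iterations); a class that loses all samples is re-seeded at a quantile
with a warning.  Class mean amplitudes are reported from event-interior
samples (two samples trimmed per edge ≈ the filter rise time) so smeared
transition samples do not bias level estimates — this is what makes the
fractional-conductance read-out accurate to well under a percentage point.

Dead time: events shorter than t_d = 0.12 ms are deleted and absorbed into
the preceding event (leading short events merge forward), then successive
same-class events are concatenated.  Total duration is conserved and the
operation is idempotent.  Censored first/last events are excluded from
duration statistics but counted in the Po/Pb time fractions.  Pb is
reported as a fraction of total time (option retained for a non-closed
denominator).

## Dwell-time fitting and missed events

Mixtures of exponentials are fitted to raw durations (histograms are
presentation only) by maximising the left-truncated likelihood
sum log f(t|theta)/S(t_cut|theta), parameterised by log tau and softmax
areas (L-BFGS-B, 8 starts: quantile-, spread- and seeded random inits).
Fitted areas therefore estimate the *untruncated* component weights.
Standard errors are delta-method transforms of the numerical observed
information.  Component count is chosen by BIC (likelihood-ratio option).

Two systematic finite-resolution effects are handled explicitly:

1. **Grid truncation.**  Idealized durations are integer sample counts.
   The truncation point is the half-sample-corrected effective dead time;
   additionally the first retained sample bin (3 samples at 20 kHz) is
   treated as unresolved — the 5 kHz filter's rise time is about one
   sample, and in validation roughly a quarter of 3-sample events are
   missed by segmentation even at high contrast.  The record is re-merged
   at one sample above the imposed dead time and the likelihood truncated
   there (`resolution_guard_samples=1`).
2. **Apparent prolongation.**  An unresolved sojourn in another class
   merges its two neighbours into one long apparent dwell.  The
   first-order retrospective correction deflates each apparent time
   constant: tau = (1 − p) tau_app − p m_gap, where p is the probability
   that a dwell of the class is followed by an unresolved excursion that
   returns, computed from the fitted mixtures of the other classes
   *conditioned on the preceding class* (in a Markov chain exit direction
   is independent of sojourn duration, so observed-event estimates of the
   branching are unbiased) and the observed class-transition frequencies.
   Without this correction the long open component of the EMD scheme is
   overestimated by ~1/(1 − F_closed(t_d)) ≈ +19%, far outside any useful
   tolerance; with it, validation recovers the generating value to a few
   percent.
3. **False events at low-contrast levels.**  When a class is bounded by a
   level only a few noise SDs away (closings interrupting the 14% TPeA
   blocked level sit ~2.4 combined-σ from it), correlated-noise dips
   masquerade as brief events of that class, concentrated just above the
   resolution limit — in validation roughly half of the 0.2–0.45 ms
   "closed" events of a TPeA record are such artifacts.  Two generic
   operations handle this: `fit_with_artifact_screen` adds one mixture
   component below twice the effective dead time (the conventional
   shortest trustworthy time constant) to absorb the false events and
   drops it from the reported fit; and, because every false event also
   *splits* a dwell of the level it interrupted,
   `correct_false_event_splitting` removes the implied rate from the
   interrupted level's components (1/τ = 1/τ_app − λ_f, with λ_f the
   screened artifact count over the time spent at that level).  The
   blocker workflows apply both to closed/blocked dwells; without them
   the TPeA flicker closing reads ~15% short and the long blocked state
   ~9% short.

## Maximum interval likelihood

The likelihood of a class-dwell sequence is the forward product
phi · prod_k exp(Q_AA t_k) Q_AB · 1 with phi the equilibrium entry vector
of the first class and per-dwell rescaling against underflow.  Within-class
propagators use the eigendecomposition of Q_AA (complex-safe), and the
sequential scan is a numba kernel, which keeps one likelihood evaluation
at ~5 ms for 2×10^4 dwells and makes multi-start quasi-Newton fitting
practical.

Missed events are handled to first order: the within-class generator is
corrected to Q'_AA = Q_AA + sum_B Q_AB (I − e^{Q_BB t_d}) (−Q_BB)^{-1} Q_BA
(brief excursions folded into the apparent dwell), the observed dwell
propagates for t − t_d under Q'_AA after e^{Q_AA t_d} for the guaranteed
first stretch, and transition blocks are likewise corrected with
through-third-class terms Q_AC (I − e^{Q_CC t_d}) (−Q_CC)^{-1} Q_CB — the
latter matter in practice because dead-time-merged records contain
apparent transitions (e.g. open→closed in a blocker scheme) whose direct
edge the topology forbids.  The exact asymptotic missed-event likelihood
is deliberately not implemented; the correction is an isolated function
and an upgrade point.

Rates are optimized on the log scale (bounds 10^-3 .. 10^7 s^-1) from a
moment-based start (class mean dwells split over outgoing edges) plus
seeded perturbations.  Standard errors on log rates come from the
numerical observed information; a near-singular information matrix flags
non-identifiability, which is expected when class aggregation hides rate
combinations.  Candidate topologies are ranked by maximized LL, ties by
parameter count then name; a failed fit ranks last with its error
recorded.  Note that ranking nested topologies by raw LL lets the larger
model win by a small margin on data from the smaller one (validation
bounds that gain at < 2 LL units for a spurious closed–closed edge).

## Blocker statistics

Block is pseudo-first-order: k_off is the reciprocal mean blocked dwell
(per state via a two-component mixture fit when supported: B1 = brief,
B2 = long), k_on the open→blocked transition rate over the blocker
concentration, K_D = k_off/k_on.  Fractional conductance is the
blocked/open mean-amplitude ratio from the edge-trimmed idealization
amplitudes.

The Pb–Po regression implements the two-gate argument: Pb at positive
potentials (where cytosolic QA blocks) against Po of the same channel at
mirrored negative potentials (no block), OLS with a seeded 2000-resample
bootstrap CI on the intercept; the "closed-state block indicated" flag
requires the whole CI above zero.  Because no slope/intercept values are
published, validation of this component is property-based, on two
labelled synthetic mechanism fixtures: a six-state two-gate scheme in
which the blocker binds whenever the ligand gate is open — including
while the distal (selectivity-filter) gate is closed — and can be trapped
by ligand-gate closure until the gate reopens, versus a pure open-block
control kept in the weak-binding regime.  The control is deliberately
weakly binding: strong open-block saturates (Pb concave in Po), and a
line fitted to a concave curve has a positive intercept of its own, which
would fake the two-gate signature.  With the default 12-activation,
10^4-event design the two-gate fixture flags in 10/10 seeds and the
control in 0/10.

## Validation design and problem sizes

Round-trip targets use one simulated recording per preset: 2×10^4
class events for the EMD scheme (~260 s of trace), 270 s for TBA (~8–9×10^3
closed events, enough to resolve the overlapping 4 ms/10.7 ms closed pair)
and 150 s for TPeA.  These sizes put estimator noise at a few percent,
comfortably under the 15–20% recovery tolerances, while keeping a full
validation run in the low minutes on one core.  Property suites
(KS agreement of simulated dwells with analytic densities,
dead-time-limit identities, topology discrimination over 10 replicates at
10^4 events, likelihood-vs-oracle agreement to 1e-8) run alongside.

## Known limitations

- First-order missed-event treatment throughout; severe resolution ratios
  (true lifetimes close to the dead time) will retain residual bias.
- The apparent-lifetime correction scales every component of a class by
  the same factor; brief components, which merging barely prolongs, are
  slightly over-corrected (a few percent of a 0.35 ms flicker).
- SKM assumes white Gaussian noise per class; filtered noise is
  correlated, which mildly weakens brief-event detection (the motivation
  for the one-sample resolution guard).
- MIL identifiability is not analysed symbolically; the information-matrix
  flag is a numerical surrogate.
- No multi-record global fitting across voltages or concentrations, and no
  voltage-dependent rate laws.
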