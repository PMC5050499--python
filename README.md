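# ryrblock

Single-channel kinetic analysis of cardiac ryanodine receptor (RyR2)
gating and its open-channel block by quaternary ammonium (QA) cations.

RyR2's unusually large K⁺ conductance means that a bound QA blocker such
as tetrabutyl- (TBA) or tetrapentyl-ammonium (TPeA) does not silence the
channel but leaves a distinct *subconductance* level (~20% of the open
amplitude for TBA, ~14% for TPeA). Blocked and closed events can therefore
be told apart directly in the current record — which makes RyR2 a unique
platform for asking how a blocker in the pore alters gating itself. This
package implements the full analysis chain that question requires, plus a
matched synthetic-data generator so every stage is testable end to end:

- **Aggregated Markov gating schemes** (`ryrblock.schemes`,
  `ryrblock.fixtures`): states grouped into CLOSED / OPEN / BLOCKED
  conductance classes, generator matrix Q, equilibrium occupancies
  (Po, Pb), and analytic phase-type dwell densities
  f(t) = φ·exp(Q_AA t)(−Q_AA)·1 decomposed into (τ, area) components.
  Built-in presets: a 4-state EMD-activated scheme (C1–O1–O2 with an
  O1–C2 flicker branch) and 5-state TBA / TPeA block schemes
  (B1↔O↔B2, and with a direct B1↔B2 link, respectively), calibrated in
  closed form so their dwell components sit at published values.
- **Synthetic recordings** (`ryrblock.synth`): exact Gillespie simulation
  of dwell sequences, rendered as sampled traces — class amplitude levels,
  per-class Gaussian noise, digital 8-pole Bessel low-pass (5 kHz),
  20 kHz digitisation.
- **Idealization** (`ryrblock.idealize`): segmental K-means — Viterbi
  segmentation under a Gaussian HMM alternated with re-estimation of
  amplitudes, noise SDs and transition probabilities — followed by a
  120 µs dead time and the summary kinetics (Po, Pb, median open/closed
  durations T_o, T_c, closing frequency, class amplitudes).
- **Dwell-time fitting** (`ryrblock.dwell_fit`): dead-time-truncated
  exponential-mixture maximum likelihood on raw durations, BIC component
  selection, log-binned (Sigworth–Sine) histograms, and first-order
  missed-event corrections for apparent lifetime prolongation and
  false-event splitting.
- **Maximum interval likelihood** (`ryrblock.mil`): likelihood of an
  idealized dwell sequence under a scheme with first-order missed-event
  correction, quasi-Newton rate fitting on log rates, and ranking of
  candidate topologies by maximized LL.
- **Blocker statistics** (`ryrblock.block`): k_on / k_off / K_D under the
  pseudo-first-order block model, fractional conductance, and the Pb–Po
  regression whose extrapolated positive intercept indicates that a
  closed channel can still be blocked (the two-gate argument).

## Worked example

Simulate a minute of EMD-activated recording, idealize it, and re-fit the
dwell mixtures:

```python
import numpy as np
from ryrblock import fixtures, synth, idealize, dwell_fit, schemes

scheme = fixtures.emd4()                      # Po = 0.80, calibrated dwell table
print(schemes.class_dwell_components(scheme, "CLOSED").components)
# ((0.35, 0.54), (10.7, 0.46))  <- analytic closed components (tau ms, area)

truth = synth.simulate_class_events(scheme, 5000, seed=1)
amps = synth.AmplitudeModel.for_scheme(scheme, open_amplitude=30.0,
                                       baseline_noise_sd=1.5, open_noise_sd=3.0)
trace = synth.render_trace(truth, amps, sampling_rate=20_000.0,
                           noise_sd=3.0, filter_cutoff=5_000.0, seed=2)
rec = idealize.impose_dead_time(
    idealize.auto_idealize(trace, 2, ("CLOSED", "OPEN")), 0.12)
print(round(idealize.summarize(rec).Po, 3))   # 0.79  (analytic Po is 0.800)

fits = dwell_fit.fit_record_classes(rec, {"CLOSED": 2, "OPEN": 2})
for tau, area in fits["CLOSED"].components:
    print(f"closed tau = {tau:.2f} ms, area = {area:.2f}")
# closed tau = 0.39 ms, area = 0.50     <- flicker closings recovered
# closed tau = 11.38 ms, area = 0.50    <- long closings recovered
```

The fitted components land within ~10% of the generating dwell table —
the brief "flicker" closing (0.35 ms, 54% of closures) and the long
closed state (10.7 ms) — despite 5 kHz filtering, noise and the 120 µs
dead time, because the fit truncates at the effective resolution and
corrects apparent lifetimes for unresolved gaps (longer recordings, as in
the validation suite, tighten this to a few percent). `examples/` contains one short
script per capability (schemes, simulation, idealization, dwell fitting,
MIL ranking, blocker statistics), each printing the numbers it computes
and what they mean.

A thin CLI mirrors the pipeline stages:

```
ryrblock full --blocker TBA --duration-s 30 --seed 1 --out-dir out_tba
```

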