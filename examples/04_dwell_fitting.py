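"""Dead-time-aware dwell-time mixture fitting.

Round trip on the EMD-activated scheme: simulate, render, idealize,
impose the dead time, fit two-component truncated mixtures to the closed
and open dwells (with the missed-event lifetime correction) and compare
against the scheme's analytic components.
"""

import warnings

from ryrblock import dwell_fit, fixtures, schemes, synth
from ryrblock.idealize import auto_idealize, impose_dead_time

warnings.simplefilter("ignore")

scheme = fixtures.emd4()
truth = synth.simulate_class_events(scheme, 8000, seed=5)
amps = synth.AmplitudeModel.for_scheme(
    scheme, 30.0, baseline_noise_sd=1.5, open_noise_sd=3.0
)
trace = synth.render_trace(truth, amps, 20_000.0, 3.0, 5_000.0, seed=6)
rec = impose_dead_time(auto_idealize(trace, 2, ("CLOSED", "OPEN")), 0.12)

fits = dwell_fit.fit_record_classes(rec, {"CLOSED": 2, "OPEN": 2})
for label in ("CLOSED", "OPEN"):
    analytic = schemes.class_dwell_components(scheme, label)
    print(f"\n{label.lower()} dwells ({fits[label].n_events} events):")
    for (tf, af), (ta, aa) in zip(fits[label].components, analytic.components):
        print(f"  fitted tau {tf:7.3f} ms ({100*af:4.1f}%)   "
              f"analytic {ta:7.3f} ms ({100*aa:4.1f}%)")

print(
    "\nThe fit truncates the likelihood at the effective resolution and"
    "\ncorrects apparent lifetimes for unresolved gaps; without that the"
    "\nlong open component would read ~20% high."
)
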