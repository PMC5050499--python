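"""Idealize a rendered trace and compare with the ground truth.

Runs segmental K-means on a 20 s TPeA recording, imposes the 120 us dead
time and prints the recovered kinetics next to the generating values.
"""

import warnings

from ryrblock import synth
from ryrblock.idealize import auto_idealize, impose_dead_time, summarize

warnings.simplefilter("ignore")

trace, truth = synth.make_block_recording("TPeA", duration_s=20.0, seed=3)
rec = impose_dead_time(auto_idealize(trace, 3, ("CLOSED", "BLOCKED", "OPEN")), 0.12)

est, ref = summarize(rec), summarize(truth)
print(f"{'':12s}{'idealized':>12s}{'ground truth':>14s}")
print(f"{'Po':12s}{est.Po:12.3f}{ref.Po:14.3f}")
print(f"{'Pb':12s}{est.Pb:12.3f}{ref.Pb:14.3f}")
print(f"{'To med (ms)':12s}{est.To_median_ms:12.2f}{ref.To_median_ms:14.2f}")
print(f"{'Tc med (ms)':12s}{est.Tc_median_ms:12.2f}{ref.Tc_median_ms:14.2f}")
amp = rec.meta["class_amplitude_pA"]
print(f"\nfitted levels: closed {amp['CLOSED']:.2f} pA, blocked {amp['BLOCKED']:.2f} pA, "
      f"open {amp['OPEN']:.2f} pA")
print(f"fractional conductance of the blocked level: {amp['BLOCKED']/amp['OPEN']:.3f} "
      "(TPeA leaves ~14% residual conductance)")
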