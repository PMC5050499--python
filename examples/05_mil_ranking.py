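"""Maximum interval likelihood: fit rates and rank topologies.

Simulates a dwell sequence from the TPeA scheme (whose blocked states
exchange directly, B1 <-> B2) and asks MIL to rank that topology against
the TBA-style alternative where blocked states only communicate through
the open state.
"""

from ryrblock import fixtures, synth
from ryrblock.mil import rank_models

gen = fixtures.tpea5()
rec = synth.simulate_class_events(gen, 8000, seed=11)
ranking = rank_models(
    rec,
    {"b1-b2 direct": fixtures.tpea5(), "through open": fixtures.tba5()},
    dead_time_ms=0.0,
    starts=2,
    seed=0,
)
print(ranking.to_text())
best_id, best = ranking.best
print(f"\nbest topology: {best_id}  (LL {best.log_likelihood:.1f})")
print("fitted rates of the winning scheme (s^-1):")
for a, b in sorted(best.scheme.connectivity):
    print(f"  {a:>3s} -> {b:<3s} {best.rate(a, b):10.1f}")
print(
    "\nThe generating topology (direct B1<->B2 exchange) attains the higher"
    "\nlog-likelihood: the dwell correlations it produces cannot be matched"
    "\nby a scheme that routes every B1-B2 transition through the open state."
)
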