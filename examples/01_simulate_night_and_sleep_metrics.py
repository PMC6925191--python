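"""Simulate one overnight recording and summarize its sleep quality.

The hypnogram is drawn from a first-order Markov chain calibrated to a
healthy young-adult sleep architecture; the standard PSG summary metrics are
then computed from the simulated stage labels.
"""

from somnostage import SimConfig, compute_sleep_metrics
from somnostage.synthetic_data import simulate_hypnogram

cfg = SimConfig(seed=7)  # 8-hour night, architecture-calibrated defaults
hyp = simulate_hypnogram(cfg)
m = compute_sleep_metrics(hyp)

print(f"epochs scored: {hyp.epoch_count} (30 s each)")
print(f"total sleep time:        {m.total_sleep_time:7.1f} min")
print(f"sleep efficiency:        {m.sleep_efficiency:7.1f} %")
print(f"sleep onset latency:     {m.sleep_onset_latency:7.1f} min")
print(f"latency persistent sleep:{m.latency_persistent_sleep:7.1f} min")
print(f"wake after sleep onset:  {m.waso:7.1f} min")
for stage, pct in m.stage_percent.items():
    print(f"  {stage:>4}: {pct:5.1f} % of sleep")
print(
    "\nThese are the conventional hypnogram summaries: efficiency is sleep "
    "time over time in bed, and stage percentages partition sleep time."
)
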