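"""Recover deliberately injected device clock errors.

Wearable studies juggle independent clocks; here the simulated actigraph is
37 s off and the wearable ECG 0.2 s off, and cross-correlation alignment
recovers both.
"""

from somnostage.align import synchronize_recording
from somnostage.synthetic_data import SimConfig, generate_cohort

cfg = SimConfig(duration=1.0, ecg_rate=250.0, actigraph_offset=37.0,
                ecg_offset=0.2, seed=9)
rec = generate_cohort(cfg, 1)[0]
print("injected lags:", rec.ground_truth.injected_lags)

sync = synchronize_recording(rec, max_lag=150.0)
print("recovered corrections:", {k: round(v, 4) for k, v in sync.applied_corrections.items()})
print(
    "\nThe actigraph lag is recovered at 1-s resolution from activity-count "
    "correlation; the ECG lag at one-sample resolution against the reference "
    "R-peak train."
)
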