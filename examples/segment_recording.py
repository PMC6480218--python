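"""Segment one TUG recording end to end.

Builds a synthetic recording (stand, walk 3 m, turn, walk back, turn, sit),
writes it to CSV in the schema a real sensor export would use, reads it
back, and runs the full pipeline.  Printed: the six sub-task intervals, the
per-sub-task mobility features, and the fall-risk category — compare the
detected boundaries against the generator's exact ground truth.
"""

import tempfile
from pathlib import Path

from tugseg import (TugScenario, read_recording, run_pipeline, simulate,
                    write_recording)

scenario = TugScenario(seed=42)
recording, truth = simulate(scenario)

with tempfile.TemporaryDirectory() as tmp:
    csv_path = Path(tmp) / "recording.csv"
    write_recording(recording, csv_path)
    recording = read_recording(csv_path)

seg, feats, risk = run_pipeline(recording)

print("sub-task intervals (s)           detected        true")
truth_iv = {
    "standing": ("standing_start", "standing_end"),
    "turn_3m": ("turn1_start", "turn1_end"),
    "presit_turn": ("turn2_start", "turn2_end"),
    "sitting": ("sitting_start", "sitting_end"),
}
for name, iv in seg.intervals().items():
    if name in truth_iv:
        a, b = truth_iv[name]
        ref = f"[{truth.boundaries[a]:5.2f}, {truth.boundaries[b]:5.2f}]"
    else:
        ref = "(between events)"
    print(f"  {name:<12} [{iv.start:5.2f}, {iv.end:5.2f}]   {ref}")

print(f"\ntotal time {seg.total_time:.2f} s (true {truth.total_time:.2f} s)"
      f" -> fall risk: {risk.category}")
print(f"steps per segment: w1={feats.steps_w1} t1={feats.steps_t1} "
      f"w2={feats.steps_w2} t2={feats.steps_t2} (true {truth.steps})")
print(f"peak turn rates: {feats.vel_t1:.0f} / {feats.vel_t2:.0f} deg/s; "
      f"trunk lean: stand {feats.pitch_su:.1f} deg, sit {feats.pitch_sd:.1f} deg")
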