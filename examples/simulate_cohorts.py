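"""Draw synthetic subjects from the young and older-adult populations.

Each draw samples sub-task durations, trunk-lean amplitudes, turn angles and
cadence from truncated normal distributions matching the validation cohorts,
then synthesizes the full 100-Hz recording.  Printed: the total test time
and risk band of a few subjects per population — older adults are slower
and more variable.
"""

from tugseg import classify_risk, random_scenario, simulate

for population in ("young", "older"):
    print(f"{population} population:")
    for seed in range(5):
        scenario = random_scenario(seed, population)
        _, truth = simulate(scenario)
        risk = classify_risk(truth.total_time)
        print(f"  subject {seed}: total {truth.total_time:5.2f} s "
              f"({risk.category} risk), turn rate "
              f"{truth.peak_rate_t1:5.1f} deg/s, "
              f"steps out/back {truth.steps['w1']}/{truth.steps['w2']}")
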