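"""Detection-threshold calibration on fall records.

Sweeps the detection threshold over the 0-5 g grid in 0.005 g steps and
selects the largest value for which every fall record still yields at least
one fall-labeled event — the largest workable threshold minimizes false
alarms on ADL data.  Prints the calibrated threshold and verifies that one
grid step higher already misses a fall.
"""

import fallseg as fs

cfg = fs.GeneratorConfig(
    sampling_rate_hz=100.0, n_fall_records=30, n_adl_records=0, seed=11
)
falls, _ = fs.generate_dataset(cfg)

theta = fs.calibrate_threshold(falls, grid_lo=0.0, grid_hi=5.0, grid_step=0.005)
print(f"calibrated threshold: {theta:.3f} g")


def detects_all(th):
    detector = fs.DetectorConfig(threshold=th)
    for rec in falls:
        avm = fs.compute_avm(rec)
        labeled = fs.label_events(rec, fs.detect_events(avm, detector), avm)
        if not any(e.truth_label == "fall" for e in labeled):
            return False
    return True


print(f"all falls detected at {theta:.3f} g: {detects_all(theta)}")
print(f"all falls detected at {theta + 0.005:.3f} g: {detects_all(theta + 0.005)}")
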