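"""Event detection, labeling, threshold calibration and excerpt extraction."""

import numpy as np
import pytest

import fallseg as fs
from fallseg.events import DetectorConfig
from helpers import brute_force_detect, make_avm_record


def _avm(values, fs_hz=100.0, record_id="r"):
    return fs.AVMSeries(np.asarray(values, float), fs_hz, record_id)


class TestDetect:
    def test_single_peak_with_quiet_tail(self):
        """One sample above threshold followed by >= 2.5 s of quiet -> one event."""
        series = [1, 1, 3] + [1] * 20  # fs=4: 20 samples = 5 s of quiet
        events = fs.detect_events(_avm(series, fs_hz=4), DetectorConfig(threshold=2))
        assert [e.t0_index for e in events] == [2]
        assert events[0].t0_time_s == pytest.approx(0.5)

    def test_recurring_peaks_defeat_quiet_period(self):
        """Peaks every 1 s with a 2.5 s quiet requirement: nothing qualifies when
        the full quiet window is required; under end-truncation only the very
        last peak does."""
        fs_hz = 10.0
        series = np.ones(100)
        series[5::10] = 3.0  # a 3 g peak every second
        strict = DetectorConfig(threshold=2, allow_truncated_quiet=False)
        assert fs.detect_events(_avm(series, fs_hz), strict) == []
        loose = DetectorConfig(threshold=2, allow_truncated_quiet=True)
        assert [e.t0_index for e in fs.detect_events(_avm(series, fs_hz), loose)] == [95]

    def test_threshold_above_max_gives_no_events(self):
        series = np.ones(50) * 1.2
        assert fs.detect_events(_avm(series), DetectorConfig(threshold=2)) == []

    def test_only_last_sample_of_a_run_qualifies(self):
        series = [1, 3, 3, 3] + [1] * 30
        events = fs.detect_events(_avm(series, fs_hz=10), DetectorConfig(threshold=2))
        assert [e.t0_index for e in events] == [3]

    @pytest.mark.parametrize("allow_truncated", [True, False])
    def test_matches_brute_force_oracle(self, allow_truncated):
        """Equivalence with the O(N*W) per-candidate scan on random series."""
        rng = np.random.default_rng(1234)
        for _ in range(200):
            n = int(rng.integers(50, 800))
            fs_hz = float(rng.choice([25, 50, 100, 200]))
            series = np.abs(rng.normal(1.0, 0.5, n))
            threshold = float(rng.uniform(0.8, 2.5))
            cfg = DetectorConfig(
                threshold=threshold, allow_truncated_quiet=allow_truncated
            )
            got = [e.t0_index for e in fs.detect_events(_avm(series, fs_hz), cfg)]
            want = brute_force_detect(
                series, fs_hz, threshold, 2.5, allow_truncated
            )
            assert got == want

    def test_threshold_monotonicity_for_isolated_peaks(self):
        """When every above-threshold excursion is an isolated peak (no peak
        within a quiet window of another), raising the threshold never adds
        events: a peak can only drop out of the crossing set."""
        rng = np.random.default_rng(77)
        series = np.ones(600)
        positions = np.arange(20, 600, 40)  # spacing 4 s at 10 Hz >> 2.5 s
        series[positions] = rng.uniform(1.5, 4.0, len(positions))
        counts = [
            len(fs.detect_events(_avm(series, fs_hz=10), DetectorConfig(threshold=t)))
            for t in np.linspace(1.2, 4.5, 34)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_threshold_monotonicity_fails_when_clusters_split(self):
        """Event counts are *not* monotone in the threshold in general: a
        medium peak that bridges two large peaks blocks both at a low
        threshold, but drops out of the crossing set at a higher one, turning
        one event into two.  This is inherent to the quiet-period rule."""
        series = [3.0, 0.0, 2.0, 0.0, 3.0, 0.0, 0.0]
        avm = _avm(series, fs_hz=1.0)  # quiet window = 2 samples (banker's round)
        low = fs.detect_events(avm, DetectorConfig(threshold=1.5))
        high = fs.detect_events(avm, DetectorConfig(threshold=2.5))
        assert [e.t0_index for e in low] == [4]
        assert [e.t0_index for e in high] == [0, 4]


class TestLabeling:
    def test_fall_record_events_before_peak_are_adl(self):
        values = np.ones(1000)
        values[100] = 2.0
        values[800] = 5.0
        rec = make_avm_record(values, class_label="fall")
        events = [
            fs.PotentialEvent("r", 100, 1.0),
            fs.PotentialEvent("r", 800, 8.0),
        ]
        labeled = fs.label_events(rec, events)
        assert [e.truth_label for e in labeled] == ["adl", "fall"]

    def test_adl_record_events_all_adl(self):
        rec = make_avm_record(np.ones(100), class_label="adl")
        labeled = fs.label_events(rec, [fs.PotentialEvent("r", 3, 0.03)])
        assert [e.truth_label for e in labeled] == ["adl"]

    def test_event_at_global_maximum_is_fall(self):
        values = np.ones(500)
        values[250] = 4.0
        rec = make_avm_record(values, class_label="fall")
        labeled = fs.label_events(rec, [fs.PotentialEvent("r", 250, 2.5)])
        assert labeled[0].truth_label == "fall"


class TestCalibration:
    def _fall(self, values, rid):
        return make_avm_record(values, fs_hz=10.0, record_id=rid, class_label="fall")

    def test_bounded_by_smallest_post_peak_crossing(self):
        """A record whose max AVM is 1.2 caps the threshold strictly below it."""
        quiet = [1.0] * 40
        falls = [
            self._fall([1] * 40 + [2.4] + quiet, "f1"),
            self._fall([1] * 40 + [1.2] + quiet, "f2"),
        ]
        theta = fs.calibrate_threshold(falls)
        assert theta == pytest.approx(1.195)

    def test_maximality_against_full_grid(self):
        rng = np.random.default_rng(5)
        falls = []
        for i in range(5):
            peak = rng.uniform(1.8, 4.0)
            values = [1.0] * 50 + [peak] + [1.0] * 50
            falls.append(self._fall(values, f"f{i}"))
        cfg = DetectorConfig(threshold=0.0)
        theta = fs.calibrate_threshold(falls, cfg=cfg)

        def all_pass(th):
            c = DetectorConfig(threshold=th)
            for rec in falls:
                avm = fs.compute_avm(rec)
                labeled = fs.label_events(rec, fs.detect_events(avm, c), avm)
                if not any(e.truth_label == "fall" for e in labeled):
                    return False
            return True

        assert all_pass(theta)
        assert not all_pass(theta + 0.005)

    def test_zero_threshold_always_feasible_with_truncation(self):
        falls = [self._fall([1.0] * 30 + [2.0] + [1.0] * 30, "f0")]
        theta = fs.calibrate_threshold(falls)
        assert theta >= 0.0

    def test_no_feasible_threshold_signalled(self):
        """A constant record has no interior quiet crossing: with the full quiet
        window required, even 0 g fails."""
        falls = [self._fall([1.0] * 30, "flat")]
        cfg = DetectorConfig(threshold=0.0, allow_truncated_quiet=False)
        with pytest.raises(fs.NoFeasibleThreshold):
            fs.calibrate_threshold(falls, cfg=cfg)

    def test_empty_fall_set_rejected(self):
        with pytest.raises(ValueError):
            fs.calibrate_threshold([])


class TestEventCentered:
    def _record_with_peak(self, peak_s, total_s, fs_hz=100.0, label="fall"):
        n = int(total_s * fs_hz)
        values = np.ones(n)
        values[int(peak_s * fs_hz)] = 5.0
        return make_avm_record(values, fs_hz=fs_hz, class_label=label)

    def test_event_too_close_to_start_dropped(self):
        rec = self._record_with_peak(2.0, 20.0)
        ecrs, retention = fs.build_event_centered([rec], DetectorConfig(threshold=2))
        assert ecrs == []
        assert retention.loc[0, "n_fall"] == 0

    def test_excerpt_geometry(self):
        """A retained event gets a 2*margin*fs + 1 excerpt centered on t0."""
        rec = self._record_with_peak(10.0, 20.0)
        ecrs, _ = fs.build_event_centered([rec], DetectorConfig(threshold=2))
        assert len(ecrs) == 1
        ecr = ecrs[0]
        assert ecr.n == 801
        assert ecr.center_index == 400
        avm_mid = np.sqrt(ecr.ax[400] ** 2 + ecr.ay[400] ** 2 + ecr.az[400] ** 2)
        assert avm_mid == pytest.approx(5.0)
        assert ecr.label == "fall"

    def test_zero_margin_retains_everything(self):
        rec = self._record_with_peak(2.0, 20.0)
        ecrs, _ = fs.build_event_centered(
            [rec], DetectorConfig(threshold=2, margin_s=0.0)
        )
        assert len(ecrs) == 1

    def test_retention_monotone_in_margin(self, small_dataset):
        """Raising the margin requirement never increases retained counts."""
        _, records, _ = small_dataset
        table = fs.retention_table(
            records, DetectorConfig(threshold=1.4), margins_s=(0.0, 2.0, 4.0, 5.0)
        )
        for col in ("n_fall", "n_adl"):
            counts = table[col].tolist()
            assert all(a >= b for a, b in zip(counts, counts[1:]))
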