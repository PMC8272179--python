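"""Synthetic accelerometer generator: morphology, determinism, error injection."""

import numpy as np
import pytest

import fallseg as fs
from fallseg.synthetic import Phase, default_templates


def _cfg(**kw):
    base = dict(sampling_rate_hz=100.0, n_fall_records=4, n_adl_records=4, seed=0)
    base.update(kw)
    return fs.GeneratorConfig(**base)


class TestWaveforms:
    def test_sample_count_matches_duration(self):
        """A 12 s template at 100 Hz yields 1200 samples."""
        t = fs.ActivityTemplate(
            "still", "adl", (Phase("rest", 12.0),), noise_sd=0.0
        )
        rec = fs.generate_adl_record(t, _cfg(), seed=1)
        assert rec.n == 1200

    def test_rest_without_noise_is_exactly_one_g(self):
        """Static gravity: AVM == 1 g at every rest sample, any orientation."""
        t = fs.ActivityTemplate("still", "adl", (Phase("rest", 2.0),), noise_sd=0.0)
        for seed in (1, 2, 3):
            avm = fs.compute_avm(fs.generate_adl_record(t, _cfg(), seed=seed))
            assert avm.values == pytest.approx(np.ones(200), abs=1e-12)

    def test_fall_three_phase_morphology(self):
        """Pre-impact dip below 1 g, peak in [1.6, 8] g + noise, rest near 1 g,
        and at least 4 s of data on both sides of the peak."""
        template = default_templates()["fall_forward"]
        cfg = _cfg()
        for seed in (7, 8, 9):
            rec = fs.generate_fall_record(template, cfg, seed=seed)
            avm = fs.compute_avm(rec).values
            peak = int(np.argmax(avm))
            fsr = rec.fs_hz
            assert 1.6 <= avm[peak] <= 8.5
            assert peak / fsr >= 4.0 and (rec.n - 1 - peak) / fsr >= 4.0
            # descent just before the impact pulse dips below 1 g
            dip = avm[peak - round(0.6 * fsr) : peak - round(0.2 * fsr)]
            assert dip.mean() < 1.0
            rest = avm[peak + round(1.5 * fsr) :]
            assert abs(rest.mean() - 1.0) < 0.05

    def test_generation_is_deterministic(self):
        """Same (template, cfg, seed) twice -> identical arrays, equal max AVM."""
        template = default_templates()["fall_forward"]
        a = fs.generate_fall_record(template, _cfg(), seed=7)
        b = fs.generate_fall_record(template, _cfg(), seed=7)
        assert np.array_equal(a.ax, b.ax)
        assert np.array_equal(a.az, b.az)
        assert fs.compute_avm(a).values.max() == fs.compute_avm(b).values.max()

    def test_class_mismatch_rejected(self):
        templates = default_templates()
        with pytest.raises(ValueError):
            fs.generate_fall_record(templates["adl_walk"], _cfg(), seed=0)
        with pytest.raises(ValueError):
            fs.generate_adl_record(templates["fall_forward"], _cfg(), seed=0)

    def test_too_short_fall_rejected(self):
        """A fall whose peak cannot honor the 4 s margins raises."""
        t = fs.ActivityTemplate(
            "stub",
            "fall",
            (
                Phase("rest", 1.0),
                Phase("impact_peak", 0.2, amplitude_g=(2.0, 8.0)),
                Phase("rest", 6.0),
            ),
        )
        with pytest.raises(ValueError, match="margins"):
            fs.generate_fall_record(t, _cfg(), seed=0)


class TestDetectorFacingTemplates:
    """The ADL templates are designed against the quiet-period detector."""

    def _detect(self, rec, threshold, allow_truncated):
        cfg = fs.DetectorConfig(threshold=threshold, allow_truncated_quiet=allow_truncated)
        return fs.detect_events(fs.compute_avm(rec), cfg)

    def test_walking_defeats_quiet_period(self):
        """Above-threshold steps recur faster than 2.5 s, so no interior sample
        is followed by quiet; only the trailing crossing can ever qualify, and
        the 4 s margin rule then drops it."""
        template = default_templates()["adl_walk"]
        for seed in (1, 2, 3):
            rec = fs.generate_adl_record(template, _cfg(), seed=seed)
            avm = fs.compute_avm(rec)
            assert avm.values.max() > 1.5  # walking does cross the threshold
            assert self._detect(rec, 1.5, allow_truncated=False) == []
            w = round(2.5 * rec.fs_hz)
            for ev in self._detect(rec, 1.5, allow_truncated=True):
                assert ev.t0_index + w > rec.n - 1  # only trailing-edge events
            ecrs, _ = fs.build_event_centered(
                [rec], fs.DetectorConfig(threshold=1.5)
            )
            assert ecrs == []

    def test_sit_down_yields_exactly_one_event(self):
        template = default_templates()["adl_sit_down"]
        for seed in (1, 2, 3):
            rec = fs.generate_adl_record(template, _cfg(), seed=seed)
            events = self._detect(rec, 1.5, allow_truncated=True)
            assert len(events) == 1

    def test_low_peak_template_below_any_threshold(self):
        template = default_templates()["adl_quiet"]
        for seed in (1, 2, 3):
            rec = fs.generate_adl_record(template, _cfg(), seed=seed)
            assert fs.compute_avm(rec).values.max() < 1.2
            assert self._detect(rec, 1.33, allow_truncated=True) == []

    def test_fall_after_adl_produces_false_then_true_event(self):
        """A sit-down before the fall triggers an ADL-labeled event before the
        fall-labeled one."""
        template = default_templates()["fall_after_sit"]
        hit = 0
        for seed in (1, 2, 3, 4):
            rec = fs.generate_fall_record(template, _cfg(), seed=seed)
            avm = fs.compute_avm(rec)
            events = fs.label_events(
                rec, self._detect(rec, 1.4, allow_truncated=True), avm
            )
            labels = [e.truth_label for e in events]
            assert labels[-1] == "fall"
            if len(labels) > 1:
                hit += 1
                assert labels[:-1] == ["adl"] * (len(labels) - 1)
        assert hit == 4  # the 1.8-2.6 g bump always crosses 1.4 g


class TestDatasetGeneration:
    def test_manifest_counts_and_columns(self):
        cfg = _cfg(n_fall_records=10, n_adl_records=10)
        records, manifest = fs.generate_dataset(cfg)
        assert len(records) == 20
        assert (manifest["class"] == "fall").sum() == 10
        assert (manifest["class"] == "adl").sum() == 10
        assert list(manifest.columns) == list(fs.records.MANIFEST_COLUMNS)

    def test_dataset_determinism_byte_identical(self):
        cfg = _cfg(n_fall_records=6, n_adl_records=6, seed=42)
        rec_a, man_a = fs.generate_dataset(cfg)
        rec_b, man_b = fs.generate_dataset(cfg)
        assert man_a.to_csv(index=False) == man_b.to_csv(index=False)
        for a, b in zip(rec_a, rec_b):
            assert np.array_equal(a.ax, b.ax)
            assert np.array_equal(a.ay, b.ay)
            assert np.array_equal(a.az, b.az)

    def test_error_injection_slots(self):
        """Fraction 0.2 over 10 falls -> exactly 2 spike and 2 low-peak records,
        matching both the manifest truth flags and the signal itself."""
        cfg = _cfg(
            n_fall_records=10,
            n_adl_records=5,
            spike_error_fraction=0.2,
            low_peak_error_fraction=0.2,
            adl_spike_error_fraction=0.2,
            seed=9,
        )
        records, manifest = fs.generate_dataset(cfg)
        peaks = {r.record_id: fs.compute_avm(r).values.max() for r in records}
        spikes = manifest[manifest["qc_error"] == "spike"]["record_id"].tolist()
        lows = manifest[manifest["qc_error"] == "low_peak"]["record_id"].tolist()
        assert len([r for r in spikes if r.startswith("F")]) == 2
        assert len([r for r in spikes if r.startswith("A")]) == 1
        assert len(lows) == 2
        for rid in spikes:
            assert peaks[rid] > 30.0
        for rid in lows:
            assert peaks[rid] < 1.1
        clean = manifest[manifest["qc_error"] == ""]["record_id"]
        assert all(1.1 <= peaks[r] <= 30.0 for r in clean if r.startswith("F"))

    def test_short_tail_records_fail_margin(self):
        cfg = _cfg(n_fall_records=6, n_adl_records=0, short_tail_fraction=0.5, seed=4)
        records, _ = fs.generate_dataset(cfg)
        short = 0
        for rec in records:
            avm = fs.compute_avm(rec).values
            peak = int(np.argmax(avm))
            if (rec.n - 1 - peak) / rec.fs_hz < 4.0:
                short += 1
        assert short == 3

    def test_roundtrip_csv(self, tmp_path):
        cfg = _cfg(n_fall_records=2, n_adl_records=2, seed=5)
        records, manifest = fs.generate_dataset(cfg, out_dir=tmp_path)
        loaded, loaded_manifest = fs.load_dataset(tmp_path / "manifest.csv")
        assert [r.record_id for r in loaded] == [r.record_id for r in records]
        for a, b in zip(records, loaded):
            assert b.ax == pytest.approx(a.ax, abs=1e-6)
            assert b.class_label == a.class_label

    def test_fs_outside_regime_warns(self):
        with pytest.warns(UserWarning, match="regime"):
            _cfg(sampling_rate_hz=10.0)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            _cfg(spike_error_fraction=1.5)

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = _cfg(n_fall_records=3, seed=12, difficulty=0.25)
        cfg.to_yaml(tmp_path / "gen.yaml")
        again = fs.GeneratorConfig.from_yaml(tmp_path / "gen.yaml")
        assert again == cfg
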