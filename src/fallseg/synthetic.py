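"""Synthetic tri-axial accelerometer records for falls and ADL.

The generator emulates the statistical and morphological structure the
pipeline assumes, so every downstream stage is testable without any external
dataset:

* falls follow the three-phase model — rest, then a pre-impact descent whose
  AVM dips below 1 g, an impact spike (primary peak drawn from a configurable
  range, by default 2-8 g and never below 1.6 g unless an error is injected),
  and a rest phase settling near 1 g;
* broken falls add a secondary, smaller peak shortly after the primary one;
* some falls are preceded by an impact-like ADL (a sit-down bump) that
  triggers a false potential fall event before the true one;
* ADL templates cover impact-like activities (a 1.5-3 g bump followed by
  quiet), sustained periodic motion (walking, whose repeated threshold
  crossings defeat the quiet-period rule) and low-peak activities that never
  approach a plausible detection threshold;
* optional error injection produces records violating the quality-control
  bounds (spikes above 30 g, falls whose AVM never reaches 1.1 g), flagged in
  the manifest for truth-testing the QC stage.

Waveforms are built on the AVM profile (half-sine impact pulses, a linear
descent dip, phase-locked two-harmonic walking oscillation) and re-projected
onto three axes along a random per-record unit gravity vector, with additive
Gaussian noise per axis; with zero noise a rest sample therefore has AVM of
exactly 1 g regardless of orientation.

The ``difficulty`` knob moves the lower end of the fall impact amplitude
range: at difficulty 0 fall peaks (>= 4 g) clear the ADL impact range
(1.5-3 g) entirely and the classes are linearly separable on the impact
maximum alone; at the default difficulty 1 fall peaks are drawn from the full
2-8 g range and the impact window alone no longer separates the classes —
the discriminative signal then lives in the pre-impact interval (descent and
rest for falls, ongoing motion for ADL) and the post-impact interval (rest
for falls, continued motion for ADL).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .records import ADL, FALL, MANIFEST_COLUMNS, AccelRecord, write_dataset

PHASE_KINDS = (
    "rest",
    "pre_impact_descent",
    "impact_peak",
    "periodic_motion",
    "posture_change",
)

#: extraction margin (s) that fall templates must honor on both peak sides
MARGIN_S = 4.0
#: sampling-rate regime of the emulated public datasets
EMULATED_FS_RANGE = (25.0, 238.0)

Range = tuple[float, float]


def _draw(value: float | Range, rng: np.random.Generator) -> float:
    if isinstance(value, (tuple, list)):
        lo, hi = value
        return float(rng.uniform(lo, hi))
    return float(value)


def _lo(value: float | Range) -> float:
    return float(value[0]) if isinstance(value, (tuple, list)) else float(value)


@dataclass(frozen=True)
class Phase:
    """One phase of an activity waveform.

    ``amplitude_g`` means: peak AVM for ``impact_peak`` / ``posture_change``,
    the final dip value for ``pre_impact_descent`` and the oscillation
    amplitude for ``periodic_motion``; it is ignored for ``rest``.  Scalar
    parameters are fixed; (lo, hi) tuples are drawn uniformly per record.
    """

    kind: str
    duration_s: float | Range
    amplitude_g: float | Range = 0.0
    freq_hz: float | Range = 2.0

    def __post_init__(self) -> None:
        if self.kind not in PHASE_KINDS:
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if _lo(self.duration_s) <= 0:
            raise ValueError("phase durations must be > 0")
        if _lo(self.amplitude_g) < 0:
            raise ValueError("phase amplitudes must be >= 0")


@dataclass(frozen=True)
class ActivityTemplate:
    """A named activity blueprint: ordered phases plus record-level options.

    ``secondary_peak`` is ``(delay_range_s, relative_amplitude_range)`` and
    adds a broken-fall second impact after the primary peak.  ``pre_activity``
    names another template whose waveform is prepended (a fall preceded by an
    ADL).  ``max_avm_cap`` rescales the finished record so its AVM maximum
    equals the cap (used for low-peak activities and error injection).
    """

    name: str
    class_label: str
    phases: tuple[Phase, ...]
    noise_sd: float = 0.03
    secondary_peak: tuple[Range, Range] | None = None
    pre_activity: str | None = None
    max_avm_cap: float | None = None
    enforce_margin: bool = True

    def __post_init__(self) -> None:
        if self.class_label not in (FALL, ADL):
            raise ValueError("class_label must be 'fall' or 'adl'")
        n_impacts = sum(p.kind == "impact_peak" for p in self.phases)
        if self.class_label == FALL and n_impacts != 1:
            raise ValueError("a fall template needs exactly one impact_peak phase")
        if self.class_label == ADL and n_impacts != 0:
            raise ValueError("ADL templates use posture_change, not impact_peak")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GeneratorConfig:
    """Dataset-level generation parameters.

    Error fractions are per class: ``spike_error_fraction`` and
    ``low_peak_error_fraction`` apply to fall records, and
    ``adl_spike_error_fraction`` to ADL records, each allocating
    ``round(fraction * n)`` deterministic slots.  ``short_tail_fraction``
    makes that share of fall records end shortly after the impact, to
    exercise the margin-based retention rule.
    """

    sampling_rate_hz: float = 100.0
    n_fall_records: int = 100
    n_adl_records: int = 100
    template_mix: dict[str, float] | None = None
    spike_error_fraction: float = 0.0
    low_peak_error_fraction: float = 0.0
    adl_spike_error_fraction: float = 0.0
    short_tail_fraction: float = 0.0
    difficulty: float = 1.0
    n_subjects: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "spike_error_fraction",
            "low_peak_error_fraction",
            "adl_spike_error_fraction",
            "short_tail_fraction",
        ):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValueError("difficulty must be in [0, 1]")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be > 0")
        lo, hi = EMULATED_FS_RANGE
        if not lo <= self.sampling_rate_hz <= hi:
            warnings.warn(
                f"sampling_rate_hz={self.sampling_rate_hz} is outside the "
                f"emulated {lo}-{hi} Hz regime",
                stacklevel=2,
            )

    def to_yaml(self, path: str | Path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def default_templates() -> dict[str, ActivityTemplate]:
    """The built-in template library.

    Falls keep the primary peak at least 4.5 s from both record ends so the
    +/-4 s extraction is always exercisable.
    """
    pre_rest = Phase("rest", (4.6, 6.0))
    descent = Phase("pre_impact_descent", (0.4, 0.8), amplitude_g=(0.3, 0.5))
    impact = Phase("impact_peak", (0.15, 0.3), amplitude_g=(2.0, 8.0))
    post_rest = Phase("rest", (4.6, 6.0))
    light_motion = Phase(
        "periodic_motion", (4.6, 5.5), amplitude_g=(0.12, 0.28), freq_hz=(1.0, 2.2)
    )
    sit_bump = Phase("posture_change", (0.15, 0.3), amplitude_g=(1.5, 3.0))
    templates = [
        ActivityTemplate(
            name="fall_forward",
            class_label=FALL,
            phases=(pre_rest, descent, impact, post_rest),
        ),
        ActivityTemplate(
            name="fall_broken",
            class_label=FALL,
            # longer tail: the detected event can sit up to ~1.4 s after the
            # primary peak (at the secondary impact) and must still leave 4 s
            phases=(pre_rest, descent, impact, Phase("rest", (6.2, 7.4))),
            secondary_peak=((0.4, 1.2), (0.5, 0.85)),
        ),
        ActivityTemplate(
            name="fall_after_sit",
            class_label=FALL,
            phases=(
                Phase("rest", (2.8, 3.5)),
                descent,
                Phase("impact_peak", (0.15, 0.3), amplitude_g=(3.0, 8.0)),
                post_rest,
            ),
            pre_activity="adl_pre_sit",
        ),
        # prefix for fall_after_sit: an impact-like ADL with a quiet gap long
        # enough for its bump to register as a (false) potential fall event
        ActivityTemplate(
            name="adl_pre_sit",
            class_label=ADL,
            phases=(
                Phase("rest", (4.6, 5.2)),
                Phase("posture_change", (0.15, 0.3), amplitude_g=(1.8, 2.6)),
            ),
        ),
        ActivityTemplate(
            name="adl_sit_down",
            class_label=ADL,
            phases=(light_motion, sit_bump, light_motion),
        ),
        ActivityTemplate(
            name="adl_walk",
            class_label=ADL,
            phases=(
                Phase(
                    "periodic_motion",
                    (9.0, 12.0),
                    amplitude_g=(0.6, 0.8),
                    freq_hz=(1.6, 2.4),
                ),
            ),
        ),
        ActivityTemplate(
            name="adl_quiet",
            class_label=ADL,
            phases=(
                Phase("rest", (4.0, 5.0)),
                Phase("posture_change", (0.3, 0.8), amplitude_g=(1.05, 1.15)),
                Phase("rest", (4.0, 5.0)),
            ),
            max_avm_cap=1.19,
        ),
    ]
    return {t.name: t for t in templates}


DEFAULT_FALL_MIX = {"fall_forward": 0.5, "fall_broken": 0.3, "fall_after_sit": 0.2}
DEFAULT_ADL_MIX = {"adl_sit_down": 0.5, "adl_walk": 0.3, "adl_quiet": 0.2}


def _render_phase(
    phase: Phase, fs: float, rng: np.random.Generator, difficulty: float
) -> tuple[np.ndarray, int | None]:
    """AVM profile of one phase; returns (samples, impact peak offset or None)."""
    dur = _draw(phase.duration_s, rng)
    n = max(2, int(round(dur * fs)))
    if phase.kind == "rest":
        return np.ones(n), None
    if phase.kind == "pre_impact_descent":
        floor = _draw(phase.amplitude_g, rng)
        return np.linspace(1.0, floor, n), None
    if phase.kind in ("impact_peak", "posture_change"):
        amp_lo = _lo(phase.amplitude_g)
        amp_hi = (
            float(phase.amplitude_g[1])
            if isinstance(phase.amplitude_g, (tuple, list))
            else amp_lo
        )
        if phase.kind == "impact_peak":
            # difficulty widens the fall amplitude range downwards: 4 g floor
            # at difficulty 0, the template's own floor at difficulty 1
            amp_lo = max(amp_lo, 4.0 - 2.0 * difficulty)
            amp_hi = max(amp_hi, amp_lo)
        amp = float(rng.uniform(amp_lo, amp_hi))
        shape = np.sin(np.pi * (np.arange(n) + 0.5) / n)
        profile = 1.0 + (amp - 1.0) * shape
        return profile, (int(np.argmax(profile)) if phase.kind == "impact_peak" else None)
    if phase.kind == "periodic_motion":
        a = _draw(phase.amplitude_g, rng)
        f = _draw(phase.freq_hz, rng)
        phi = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / fs
        # second harmonic phase-locked to the first (gait-like waveform);
        # the per-cycle maximum is then a fixed multiple (~1.135) of `a`
        profile = 1.0 + a * np.sin(2 * np.pi * f * t + phi) + 0.3 * a * np.sin(
            2 * (2 * np.pi * f * t + phi)
        )
        return np.maximum(profile, 0.05), None
    raise AssertionError(phase.kind)


def _render_template(
    template: ActivityTemplate,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    registry: Mapping[str, ActivityTemplate],
) -> tuple[np.ndarray, int | None]:
    """Noise-free AVM profile; returns (profile, primary impact index or None)."""
    fs = cfg.sampling_rate_hz
    parts: list[np.ndarray] = []
    peak_idx: int | None = None
    offset = 0
    if template.pre_activity is not None:
        pre = registry[template.pre_activity]
        pre_profile, _ = _render_template(pre, cfg, rng, registry)
        parts.append(pre_profile)
        offset = len(pre_profile)
    for phase in template.phases:
        chunk, local_peak = _render_phase(phase, fs, rng, cfg.difficulty)
        if local_peak is not None:
            peak_idx = offset + local_peak
        parts.append(chunk)
        offset += len(chunk)
    profile = np.concatenate(parts)
    if template.secondary_peak is not None and peak_idx is not None:
        delay_range, rel_range = template.secondary_peak
        delay = _draw(delay_range, rng)
        rel = _draw(rel_range, rng)
        primary_amp = profile[peak_idx]
        amp2 = 1.0 + rel * (primary_amp - 1.0)
        # the difficulty amplitude floor applies to every fall impact: the
        # detected event can land on the secondary peak, which must therefore
        # also clear the ADL range at minimum difficulty
        amp2 = min(max(amp2, 4.0 - 2.0 * cfg.difficulty), primary_amp)
        n2 = max(2, int(round(_draw((0.1, 0.2), rng) * fs)))
        j = peak_idx + int(round(delay * fs))
        if j + n2 <= len(profile):
            pulse = 1.0 + (amp2 - 1.0) * np.sin(np.pi * (np.arange(n2) + 0.5) / n2)
            profile[j : j + n2] = np.maximum(profile[j : j + n2], pulse)
    return profile, peak_idx


def _generate_record(
    template: ActivityTemplate,
    cfg: GeneratorConfig,
    seed: int,
    record_id: str,
    subject_id: str,
    registry: Mapping[str, ActivityTemplate] | None = None,
) -> AccelRecord:
    registry = registry if registry is not None else default_templates()
    rng = np.random.default_rng(seed)
    profile, peak_idx = _render_template(template, cfg, rng, registry)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    xyz = profile[:, None] * direction[None, :]
    if template.noise_sd > 0:
        xyz = xyz + rng.normal(0.0, template.noise_sd, xyz.shape)
    avm = np.sqrt((xyz**2).sum(axis=1))
    if template.max_avm_cap is not None:
        xyz *= template.max_avm_cap * 0.995 / avm.max()
        avm = np.sqrt((xyz**2).sum(axis=1))
    if template.class_label == FALL and template.enforce_margin:
        fs = cfg.sampling_rate_hz
        peak = int(np.argmax(avm))
        if peak / fs < MARGIN_S or (len(avm) - 1 - peak) / fs < MARGIN_S:
            raise ValueError(
                f"template {template.name!r}: record too short to honor the "
                f"{MARGIN_S} s margins around the impact peak"
            )
    return AccelRecord(
        record_id=record_id,
        subject_id=subject_id,
        activity_type=template.name,
        class_label=template.class_label,
        fs_hz=cfg.sampling_rate_hz,
        ax=xyz[:, 0],
        ay=xyz[:, 1],
        az=xyz[:, 2],
    )


def generate_fall_record(
    template: ActivityTemplate,
    cfg: GeneratorConfig,
    seed: int,
    record_id: str = "fall-0",
    subject_id: str = "S01",
) -> AccelRecord:
    """One fall record; deterministic given the seed."""
    if template.class_label != FALL:
        raise ValueError("generate_fall_record needs a fall template")
    return _generate_record(template, cfg, seed, record_id, subject_id)


def generate_adl_record(
    template: ActivityTemplate,
    cfg: GeneratorConfig,
    seed: int,
    record_id: str = "adl-0",
    subject_id: str = "S01",
) -> AccelRecord:
    """One ADL record; deterministic given the seed."""
    if template.class_label != ADL:
        raise ValueError("generate_adl_record needs an ADL template")
    return _generate_record(template, cfg, seed, record_id, subject_id)


def _inject_spike(record: AccelRecord, seed: int) -> None:
    """Overwrite a few samples with a >30 g artifact (sensor-error emulation)."""
    rng = np.random.default_rng([seed, 1])
    j = int(0.4 * record.n)
    mag = float(rng.uniform(31.5, 40.0))
    direction = rng.normal(size=3)
    direction = mag * direction / np.linalg.norm(direction)
    for axis, value in zip((record.ax, record.ay, record.az), direction):
        axis[j : j + 3] = value


def _rescale_max_avm(record: AccelRecord, target: float) -> None:
    avm = np.sqrt(record.ax**2 + record.ay**2 + record.az**2)
    factor = target / float(avm.max())
    record.ax *= factor
    record.ay *= factor
    record.az *= factor


def _short_tail(template: ActivityTemplate) -> ActivityTemplate:
    """Variant whose final rest is too short for the 4 s extraction margin."""
    phases = list(template.phases)
    phases[-1] = replace(phases[-1], duration_s=(1.0, 3.0))
    return replace(template, phases=tuple(phases), enforce_margin=False)


def generate_dataset(
    cfg: GeneratorConfig, out_dir: str | Path | None = None
) -> tuple[list[AccelRecord], pd.DataFrame]:
    """Generate the configured record collection plus its manifest.

    The manifest carries a ``qc_error`` truth column ("", "spike" or
    "low_peak") marking error-injected records for QC testing.  Fully
    reproducible from ``cfg.seed``; if ``out_dir`` is given, per-record CSVs
    and the manifest are also written there.
    """
    registry = default_templates()
    mix = cfg.template_mix or {**DEFAULT_FALL_MIX, **DEFAULT_ADL_MIX}
    unknown = set(mix) - set(registry)
    if unknown:
        raise ValueError(f"unknown templates in mix: {sorted(unknown)}")
    fall_names = sorted(n for n in mix if registry[n].class_label == FALL)
    adl_names = sorted(n for n in mix if registry[n].class_label == ADL)
    if cfg.n_fall_records > 0 and not fall_names:
        raise ValueError("template_mix has no fall templates")
    if cfg.n_adl_records > 0 and not adl_names:
        raise ValueError("template_mix has no ADL templates")

    def _weights(names: list[str]) -> np.ndarray:
        w = np.array([mix[n] for n in names], dtype=float)
        return w / w.sum()

    rng = np.random.default_rng(cfg.seed)
    chosen_falls = (
        rng.choice(fall_names, size=cfg.n_fall_records, p=_weights(fall_names))
        if cfg.n_fall_records
        else np.array([], dtype=object)
    )
    chosen_adls = (
        rng.choice(adl_names, size=cfg.n_adl_records, p=_weights(adl_names))
        if cfg.n_adl_records
        else np.array([], dtype=object)
    )
    seeds = rng.integers(0, 2**31 - 1, size=cfg.n_fall_records + cfg.n_adl_records)

    n_spike = int(round(cfg.spike_error_fraction * cfg.n_fall_records))
    n_low = int(round(cfg.low_peak_error_fraction * cfg.n_fall_records))
    n_short = int(round(cfg.short_tail_fraction * cfg.n_fall_records))
    if n_spike + n_low + n_short > cfg.n_fall_records:
        raise ValueError("error/short-tail fractions exceed the fall record count")
    n_adl_spike = int(round(cfg.adl_spike_error_fraction * cfg.n_adl_records))

    records: list[AccelRecord] = []
    rows = []
    for i, name in enumerate(chosen_falls):
        template = registry[name]
        qc_error = ""
        if i < n_spike:
            qc_error = "spike"
        elif i < n_spike + n_low:
            qc_error = "low_peak"
            template = replace(template, max_avm_cap=1.05)
        elif i >= cfg.n_fall_records - n_short:
            template = _short_tail(template)
        rid = f"F{i:04d}"
        rec = _generate_record(
            template,
            cfg,
            int(seeds[i]),
            rid,
            f"S{(i % cfg.n_subjects) + 1:02d}",
            registry,
        )
        if qc_error == "spike":
            _inject_spike(rec, int(seeds[i]))
        records.append(rec)
        rows.append((rec, qc_error))
    for i, name in enumerate(chosen_adls):
        template = registry[name]
        qc_error = "spike" if i < n_adl_spike else ""
        rid = f"A{i:04d}"
        rec = _generate_record(
            template,
            cfg,
            int(seeds[cfg.n_fall_records + i]),
            rid,
            f"S{(i % cfg.n_subjects) + 1:02d}",
            registry,
        )
        if qc_error == "spike":
            _inject_spike(rec, int(seeds[cfg.n_fall_records + i]))
        records.append(rec)
        rows.append((rec, qc_error))

    manifest = pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "subject_id": r.subject_id,
                "activity_type": r.activity_type,
                "class": r.class_label,
                "fs_hz": r.fs_hz,
                "path": f"records/{r.record_id}.csv",
                "qc_error": err,
            }
            for r, err in rows
        ],
        columns=list(MANIFEST_COLUMNS),
    )
    if out_dir is not None:
        write_dataset(records, manifest, out_dir)
    return records, manifest
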