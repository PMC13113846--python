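"""Seeded synthetic cohorts of MCG-like recordings.

Clinical magnetocardiography data are rarely shareable, so every stage of
the pipeline is exercised on synthetic recordings that reproduce the
statistical structure the method assumes: quasi-periodic ~800 ms cardiac
cycles built from three Gaussian wavelets (P-, QRS- and T-wave analogues),
a "healthy" class with stable morphology, and an "ischemia" class with an
ST-level shift between the QRS and T analogues, a perturbed T-wave
morphology, and chaotic beat-to-beat amplitude modulation driven by a
logistic map in its fully chaotic regime.  Recordings are contaminated
with baseline wander, power-line interference and white noise, and are
organized per subject so that subject-level data splitting is meaningful.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "BeatTemplate",
    "NoiseSpec",
    "LabeledRecording",
    "healthy_template",
    "ischemic_template",
    "generate_cycle",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]


@dataclass
class BeatTemplate:
    """Morphology of one cardiac cycle as a sum of Gaussian wavelets.

    ``wavelet_centers`` are in seconds from cycle onset, widths are
    Gaussian standard deviations in seconds, amplitudes are in arbitrary
    field units.  ``st_offset`` is a level shift applied between the
    second (QRS analogue) and third (T analogue) wavelet centers; healthy
    templates have ``st_offset == 0``.
    """

    wavelet_centers: tuple[float, ...] = (0.15, 0.35, 0.60)
    wavelet_amplitudes: tuple[float, ...] = (0.15, 1.0, 0.30)
    wavelet_widths: tuple[float, ...] = (0.025, 0.012, 0.040)
    st_offset: float = 0.0
    cycle_length: float = 0.8

    def validate(self) -> None:
        if self.cycle_length <= 0:
            raise InvalidParameterError("cycle_length must be positive")
        if len(self.wavelet_centers) != len(self.wavelet_amplitudes) or len(
            self.wavelet_centers
        ) != len(self.wavelet_widths):
            raise InvalidParameterError("wavelet fields must have equal length")
        if any(w <= 0 for w in self.wavelet_widths):
            raise InvalidParameterError("wavelet widths must be positive")


@dataclass
class NoiseSpec:
    """Additive contamination: white noise, power-line tone, baseline wander."""

    white_sd: float = 0.02
    powerline_amp: float = 0.05
    powerline_freq: float = 50.0
    wander_amp: float = 0.30
    wander_freq: float = 0.20

    def validate(self) -> None:
        if min(self.white_sd, self.powerline_amp, self.wander_amp) < 0:
            raise InvalidParameterError("noise amplitudes must be non-negative")
        if self.wander_freq >= 0.5:
            raise InvalidParameterError(
                "wander_freq must stay below the 0.5 Hz bandpass low cutoff"
            )


@dataclass
class LabeledRecording:
    """One subject's raw signal with its sampling rate and binary label
    (0 = healthy, 1 = ischemia)."""

    subject_id: str
    label: int
    samples: np.ndarray
    fs: float


def healthy_template() -> BeatTemplate:
    return BeatTemplate()


def ischemic_template() -> BeatTemplate:
    """Ischemic morphology: ST-segment depression and a flattened,
    broadened T analogue."""
    return BeatTemplate(
        wavelet_amplitudes=(0.15, 1.0, 0.18),
        wavelet_widths=(0.025, 0.012, 0.060),
        st_offset=-0.20,
    )


def _logistic_sequence(x0: float, n: int) -> np.ndarray:
    # x_{k+1} = 4 x_k (1 - x_k): the fully chaotic regime of the logistic map
    out = np.empty(n)
    x = x0
    for k in range(n):
        x = 4.0 * x * (1.0 - x)
        out[k] = x
    return out


def generate_cycle(
    template: BeatTemplate,
    chaos_level: float,
    rng: np.random.Generator,
    fs: float = 1000.0,
) -> np.ndarray:
    """Render one beat of ``template.cycle_length`` seconds at ``fs``.

    For ``chaos_level > 0`` the wavelet amplitudes are modulated by a
    logistic-map sequence (one map step per wavelet, seeded from ``rng``)
    scaled by ``chaos_level``, and the template's ST offset is added on
    the interval between the second and third wavelet centers with short
    cosine ramps so the shift stays band-limited.
    """
    template.validate()
    if fs <= 0:
        raise InvalidParameterError("fs must be positive")
    if chaos_level < 0:
        raise InvalidParameterError("chaos_level must be non-negative")

    n = int(round(template.cycle_length * fs))
    t = np.arange(n) / fs
    amps = np.asarray(template.wavelet_amplitudes, dtype=float).copy()
    if chaos_level > 0:
        x0 = rng.uniform(0.1, 0.9)
        mod = _logistic_sequence(x0, amps.size)
        amps = amps * (1.0 + chaos_level * (2.0 * mod - 1.0))

    beat = np.zeros(n)
    for c, a, w in zip(template.wavelet_centers, amps, template.wavelet_widths):
        beat += a * np.exp(-0.5 * ((t - c) / w) ** 2)

    if template.st_offset != 0.0 and len(template.wavelet_centers) >= 3:
        c1, c2 = template.wavelet_centers[1], template.wavelet_centers[2]
        ramp = 0.02  # seconds
        window = np.clip((t - c1) / ramp, 0.0, 1.0) * np.clip((c2 - t) / ramp, 0.0, 1.0)
        window = 0.5 - 0.5 * np.cos(np.pi * np.minimum(window, 1.0))
        beat += template.st_offset * window
    return beat


def _jittered(template: BeatTemplate, jitter: float, rng: np.random.Generator) -> BeatTemplate:
    """Per-subject morphology jitter: multiplicative on amplitudes/widths,
    additive (scaled by width) on centers; drawn once per subject."""
    if jitter == 0:
        return template
    k = len(template.wavelet_centers)
    amps = tuple(
        a * (1.0 + jitter * rng.standard_normal()) for a in template.wavelet_amplitudes
    )
    widths = tuple(
        max(w * (1.0 + 0.5 * jitter * rng.standard_normal()), 1e-4)
        for w in template.wavelet_widths
    )
    centers = tuple(
        c + 0.25 * jitter * w * rng.standard_normal()
        for c, w in zip(template.wavelet_centers, (0.05,) * k)
    )
    cycle_length = template.cycle_length * (1.0 + 0.5 * jitter * rng.standard_normal())
    return replace(
        template,
        wavelet_amplitudes=amps,
        wavelet_widths=widths,
        wavelet_centers=centers,
        cycle_length=max(cycle_length, 0.3),
    )


def generate_cohort(
    n_healthy: int,
    n_ischemic: int,
    cycles_per_subject: int,
    fs: float = 1000.0,
    noise: NoiseSpec | None = None,
    seed: int = 42,
    *,
    healthy: BeatTemplate | None = None,
    ischemic: BeatTemplate | None = None,
    chaos_level: float = 0.3,
    template_jitter: float = 0.05,
    rr_jitter: float = 0.02,
) -> list[LabeledRecording]:
    """Generate ``n_healthy + n_ischemic`` labeled recordings.

    Each recording concatenates ``cycles_per_subject`` beats rendered from
    a per-subject jittered copy of the class template (so cycles within a
    subject correlate), with per-beat cycle-length variation of relative
    magnitude ``rr_jitter``, then adds ``noise``.  Deterministic given
    ``seed``.
    """
    if min(n_healthy, n_ischemic, cycles_per_subject) < 1:
        raise InvalidParameterError("all counts must be >= 1")
    if fs <= 200.0:
        raise InvalidParameterError("fs must exceed 200 Hz (2 x 100 Hz bandpass edge)")
    noise = noise if noise is not None else NoiseSpec()
    noise.validate()
    if noise.powerline_amp > 0 and fs <= 2 * noise.powerline_freq:
        raise InvalidParameterError("fs too low for the requested power-line tone")

    healthy = healthy if healthy is not None else healthy_template()
    ischemic = ischemic if ischemic is not None else ischemic_template()
    rng = np.random.default_rng(seed)

    cohort: list[LabeledRecording] = []
    plan = [("H", 0, healthy, 0.0)] * n_healthy + [("I", 1, ischemic, chaos_level)] * n_ischemic
    counters = {"H": 0, "I": 0}
    for prefix, label, base, chaos in plan:
        idx = counters[prefix]
        counters[prefix] += 1
        subject = _jittered(base, template_jitter, rng)
        beats = []
        for _ in range(cycles_per_subject):
            beat_template = subject
            if rr_jitter > 0:
                stretch = 1.0 + rr_jitter * rng.standard_normal()
                beat_template = replace(
                    subject, cycle_length=max(subject.cycle_length * stretch, 0.3)
                )
            beats.append(generate_cycle(beat_template, chaos, rng, fs))
        samples = np.concatenate(beats)
        t = np.arange(samples.size) / fs
        if noise.powerline_amp > 0:
            samples = samples + noise.powerline_amp * np.sin(
                2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi)
            )
        if noise.wander_amp > 0:
            samples = samples + noise.wander_amp * np.sin(
                2 * np.pi * noise.wander_freq * t + rng.uniform(0, 2 * np.pi)
            )
        if noise.white_sd > 0:
            samples = samples + noise.white_sd * rng.standard_normal(samples.size)
        cohort.append(
            LabeledRecording(
                subject_id=f"{prefix}{idx:04d}", label=label, samples=samples, fs=fs
            )
        )
    return cohort


def write_cohort(cohort: list[LabeledRecording], outdir: str | Path) -> Path:
    """Write one CSV per subject plus a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as mf:
        writer = csv.writer(mf)
        writer.writerow(["subject_id", "label", "path"])
        for rec in cohort:
            path = outdir / f"{rec.subject_id}.csv"
            with open(path, "w") as f:
                f.write(f"# subject_id={rec.subject_id}\n")
                f.write(f"# label={rec.label}\n")
                f.write(f"# fs={rec.fs}\n")
                np.savetxt(f, rec.samples, fmt="%.9g")
            writer.writerow([rec.subject_id, rec.label, path.name])
    return manifest


def read_cohort(manifest: str | Path) -> list[LabeledRecording]:
    manifest = Path(manifest)
    cohort = []
    with open(manifest, newline="") as mf:
        for row in csv.DictReader(mf):
            path = manifest.parent / row["path"]
            header = {}
            with open(path) as f:
                for line in f:
                    if not line.startswith("#"):
                        break
                    key, _, value = line[1:].strip().partition("=")
                    header[key.strip()] = value.strip()
            samples = np.loadtxt(path, comments="#")
            cohort.append(
                LabeledRecording(
                    subject_id=row["subject_id"],
                    label=int(row["label"]),
                    samples=np.atleast_1d(samples),
                    fs=float(header.get("fs", "1000")),
                )
            )
    return cohort
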