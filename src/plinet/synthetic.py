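"""Synthetic multichannel EEG-like cohorts with planted phase coupling.

The generator emulates a two-condition task-switching cohort: each
recording is 60 channels of 1/f-shaped broadband noise (amplitude spectral
slope −1), and selected channel pairs additionally carry a shared
narrowband oscillation in a chosen rhythm.  One member of the pair receives
the oscillation delayed by a constant π/4 phase lag, so the pair's phase
difference has a consistent nonzero sign and its phase lag index rises
monotonically with the coupling fraction ``c``: each channel's narrowband
component is ``c × shared + (1 − c) × independent`` band noise.  A nonzero
lag is essential — PLI is blind to zero-lag coupling by construction.

Coupling differs between the two conditions on a configurable "planted"
edge set; per-subject Gaussian jitter on the coupling fraction (a subject
trait, shared across that subject's two recordings) creates realistic
between-subject variance for group statistics and classification.

Determinism: identical (config, seed) reproduces bit-identical cohorts;
per-recording streams are spawned from the master seed so subjects and
conditions are mutually independent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .montage import Montage, default_montage
from .preprocess import DEFAULT_BANDS, BandSpec, Recording

CONDITIONS = ("A", "B")


@dataclass(frozen=True)
class PlantedEdge:
    """A channel pair coupled in ``band`` with per-condition strengths."""

    band: str
    channels: tuple[str, str]
    coupling_a: float
    coupling_b: float

    def __post_init__(self) -> None:
        for c in (self.coupling_a, self.coupling_b):
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coupling must lie in [0, 1], got {c}")

    def coupling(self, condition: str) -> float:
        return self.coupling_a if condition == "A" else self.coupling_b


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort recipe: sizes, rhythms, planted couplings, noise and seed.

    Defaults mirror the emulated study: 20 subjects per condition,
    400-s recordings at 200 Hz, the four classical rhythms.
    """

    n_subjects: int = 20
    duration_s: float = 400.0
    fs: float = 200.0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    planted_edges: tuple[PlantedEdge, ...] = ()
    noise_sd: float = 1.0
    band_amplitude: float = 2.0
    subject_jitter_sd: float = 0.05
    seed: int = 0
    montage: Montage = field(default_factory=default_montage)

    def __post_init__(self) -> None:
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s × fs must be a whole number of samples")
        band_names = {b.name for b in self.bands}
        for pe in self.planted_edges:
            if pe.band not in band_names:
                raise ValueError(f"planted edge refers to unknown band {pe.band!r}")
            for ch in pe.channels:
                if ch not in self.montage.region_of:
                    raise ValueError(f"planted edge refers to unknown channel {ch!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      sd: float) -> np.ndarray:
    """Spectrally shaped white noise with amplitude slope f^-1, unit-free."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / f[1:]
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    shaped /= shaped.std(axis=-1, keepdims=True)
    return sd * shaped


def _narrowband(rng: np.random.Generator, band: BandSpec, fs: float,
                n_samples: int) -> np.ndarray:
    """Unit-variance band-limited noise in ``band``."""
    sos = signal.butter(4, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return x / x.std()


def _subject_jitter(config: SyntheticConfig, subject_index: int) -> np.ndarray:
    """Per-subject coupling perturbations — a subject trait, condition-free."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7_777, subject_index])
    )
    return rng.normal(0.0, config.subject_jitter_sd, size=len(config.planted_edges))


def generate_subject(config: SyntheticConfig, condition: str,
                     subject_index: int) -> Recording:
    """One 60-channel recording for (condition, subject), deterministic."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError("subject_index out of range")

    rng = np.random.default_rng(
        np.random.SeedSequence(
            [config.seed, CONDITIONS.index(condition), subject_index]
        )
    )
    n = config.n_samples
    mont = config.montage
    data = _one_over_f_noise(rng, mont.n_channels, n, config.noise_sd)

    jitter = _subject_jitter(config, subject_index)
    bands = {b.name: b for b in config.bands}
    lag = np.pi / 4
    for pe, dj in zip(config.planted_edges, jitter):
        c = float(np.clip(pe.coupling(condition) + dj, 0.0, 1.0))
        band = bands[pe.band]
        shared = _narrowband(rng, band, config.fs, n)
        # constant-lag copy via the analytic signal
        z = signal.hilbert(shared)
        lagged = np.real(z * np.exp(-1j * lag))
        lagged /= lagged.std()
        i, j = (mont.index(ch) for ch in pe.channels)
        for ch_idx, osc in ((i, shared), (j, lagged)):
            indep = _narrowband(rng, band, config.fs, n)
            data[ch_idx] += config.band_amplitude * (c * osc + (1.0 - c) * indep)

    return Recording(data=data, fs=config.fs, labels=mont.labels)


@dataclass(frozen=True)
class CohortEntry:
    subject: int
    condition: str
    recording: Recording


def generate_cohort(config: SyntheticConfig) -> list[CohortEntry]:
    """All n_subjects × 2 condition recordings, labels attached."""
    return [
        CohortEntry(s, cond, generate_subject(config, cond, s))
        for cond in CONDITIONS
        for s in range(config.n_subjects)
    ]


def planted_truth(config: SyntheticConfig) -> dict[str, list[tuple[str, str]]]:
    """Per band, the edges whose coupling differs between conditions."""
    truth: dict[str, list[tuple[str, str]]] = {b.name: [] for b in config.bands}
    for pe in config.planted_edges:
        if pe.coupling_a != pe.coupling_b:
            truth[pe.band].append(pe.channels)
    return truth


def write_cohort(cohort: list[CohortEntry], out_dir: str | Path,
                 fmt: str = "%.6e") -> Path:
    """Persist a cohort as one CSV matrix per recording plus a manifest.

    Returns the manifest path.  Matrices are channels × samples with no
    header; channel order is the montage order recorded in ``channels.txt``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "channels.txt").write_text("\n".join(cohort[0].recording.labels) + "\n")
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "condition", "path", "fs"])
        for entry in cohort:
            name = f"sub{entry.subject:03d}_cond{entry.condition}.csv"
            np.savetxt(out / name, entry.recording.data, fmt=fmt, delimiter=",")
            writer.writerow([entry.subject, entry.condition, name, entry.recording.fs])
    return manifest
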