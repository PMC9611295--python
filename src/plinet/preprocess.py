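"""Recording container, re-referencing, zero-phase band filtering, resampling.

A :class:`Recording` is a plain channels × samples matrix with a sampling
rate and ordered channel labels.  The analysis bands are the four classical
EEG rhythms (delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30 Hz); band
decomposition uses a 4th-order Butterworth applied forward–backward
(``sosfiltfilt``), i.e. zero net phase shift and an effective 8th-order
magnitude response.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class BandSpec:
    """A frequency band: ``name`` with pass-band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high, got ({self.low}, {self.high})")


#: The four analysis rhythms.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
)


@dataclass(frozen=True)
class Recording:
    """Multichannel time series: ``data`` is channels × samples."""

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels × samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous across-channel mean from every sample.

    After re-referencing the across-channel sum is zero at every time
    point; applying the operation twice is a no-op.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data)


def _band_sos(band: BandSpec, fs: float, order: int = 4) -> np.ndarray:
    if band.high >= fs / 2:
        raise ValueError(
            f"band high edge {band.high} Hz must be below Nyquist {fs / 2} Hz"
        )
    return signal.butter(order, [band.low, band.high], btype="bandpass", fs=fs, output="sos")


def bandpass_zero_phase(rec: Recording, band: BandSpec, order: int = 4) -> Recording:
    """Zero-phase band-pass: Butterworth applied forward and backward."""
    sos = _band_sos(band, rec.fs, order)
    data = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return replace(rec, data=np.ascontiguousarray(data))


def decompose_bands(
    rec: Recording, bands: tuple[BandSpec, ...] = DEFAULT_BANDS
) -> dict[str, Recording]:
    """One zero-phase filtered copy of the recording per band."""
    return {b.name: bandpass_zero_phase(rec, b) for b in bands}


def broadband_prefilter(rec: Recording, low: float = 0.3, high: float = 30.0) -> Recording:
    """Wideband 0.3–30 Hz pre-filter applied to raw recordings before analysis."""
    return bandpass_zero_phase(rec, BandSpec("broadband", low, high))


def downsample(rec: Recording, fs_new: float) -> Recording:
    """Polyphase resampling to ``fs_new`` (e.g. 200 Hz for raw EEG)."""
    if fs_new <= 0 or fs_new > rec.fs:
        raise ValueError("target rate must be in (0, fs]")
    if fs_new == rec.fs:
        return rec
    from fractions import Fraction

    frac = Fraction(fs_new / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    return Recording(data=np.ascontiguousarray(data), fs=fs_new, labels=rec.labels)


def read_matrix(path: str | Path, labels_path: str | Path, fs: float) -> Recording:
    """Read a plain-text numeric matrix (rows = channels) plus a label list."""
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    labels = tuple(
        ln.strip() for ln in Path(labels_path).read_text().splitlines() if ln.strip()
    )
    return Recording(data=data, fs=fs, labels=labels)


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file via mne (install the ``edf`` extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF input requires mne: pip install plinet[edf]") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        data=raw.get_data(), fs=float(raw.info["sfreq"]), labels=tuple(raw.ch_names)
    )
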