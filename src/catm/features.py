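"""Band decomposition and per-window EEG features.

Each trial is zero-phase bandpass filtered into the four classical rhythms
(theta 3-8 Hz, alpha 8-14 Hz, beta 14-31 Hz, gamma 31-45 Hz; 4th-order
Butterworth run forward-backward), cut into non-overlapping 0.5 s windows,
and summarized per window by four scalars:

* differential entropy  DE = 1/2 * ln(2*pi*e*sigma^2), the Gaussian
  closed form with sigma^2 the window's sample variance;
* power spectral density, the autocorrelation (Wiener-Khinchin) spectrum
  averaged over its frequencies — by Parseval this equals the window's
  mean squared amplitude, i.e. its average band power;
* nonlinear energy, the mean of y(n)^2 + H[y](n)^2 where y is the window's
  first difference and H its Hilbert transform — an envelope-type
  instantaneous energy sensitive to both amplitude and frequency;
* Petrosian fractal dimension, a waveform-complexity estimate driven by
  the count of sign changes around the window mean.

Baseline correction subtracts the mean feature of the 3 s pre-stimulus
windows from every stimulus window, per (band, feature, channel); features
are then z-scored per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "BANDS",
    "BAND_ORDER",
    "FEATURE_ORDER",
    "FeatureFrameSeries",
    "bandpass",
    "segment",
    "de",
    "psd",
    "autocorr_spectrum",
    "ne",
    "fd",
    "petrosian",
    "extract",
    "baseline_correct",
    "normalize",
    "save_features",
    "load_features",
]


class InvalidBandError(ValueError):
    """Band edges outside (0, fs/2) or reversed."""


class DegenerateSignalError(ValueError):
    """Zero-variance input where a spread is required."""


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def validate(self, fs: float) -> None:
        if not (0.0 < self.lo < self.hi < fs / 2.0):
            raise InvalidBandError(
                f"band {self.name} ({self.lo}-{self.hi} Hz) invalid for fs={fs}"
            )


BAND_ORDER = ("theta", "alpha", "beta", "gamma")
FEATURE_ORDER = ("de", "psd", "ne", "fd")
BANDS = (
    BandDefinition("theta", 3.0, 8.0),
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 14.0, 31.0),
    BandDefinition("gamma", 31.0, 45.0),
)

_FILTER_ORDER = 4  # Butterworth order, applied forward-backward (zero phase)


@dataclass
class FeatureFrameSeries:
    """Per-trial feature tensor: (windows, bands, features, channels)."""

    values: np.ndarray
    window_s: float = 0.5
    baseline_windows: int = 0
    band_names: tuple[str, ...] = BAND_ORDER
    feature_names: tuple[str, ...] = FEATURE_ORDER

    def __post_init__(self) -> None:
        if self.values.ndim != 4:
            raise ValueError("values must be windows x bands x features x channels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[3]


def bandpass(x: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the last axis."""
    band.validate(fs)
    n = x.shape[-1]
    if n < 3 * _FILTER_ORDER:
        raise ValueError(f"signal length {n} too short for order-{_FILTER_ORDER} filtering")
    sos = sps.butter(_FILTER_ORDER, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def segment(trial: np.ndarray, fs: float, window_s: float = 0.5) -> np.ndarray:
    """Split the last axis into non-overlapping windows of ``fs*window_s``
    samples (must be integer); the trailing partial window is dropped.

    Returns an array with shape ``(..., n_windows, win_len)``.
    """
    win = fs * window_s
    if abs(win - round(win)) > 1e-9:
        raise ValueError("fs * window_s must be an integer sample count")
    win = int(round(win))
    n = trial.shape[-1] // win
    if n == 0:
        raise ValueError("window longer than trial")
    trimmed = trial[..., : n * win]
    return trimmed.reshape(trial.shape[:-1] + (n, win))


# ---------------------------------------------------------------------------
# per-window scalar features (vectorized along the last axis)
# ---------------------------------------------------------------------------

def de(window: np.ndarray) -> np.ndarray:
    """Differential entropy 1/2 * ln(2*pi*e*sigma^2) (natural log,
    sample variance with ddof=1)."""
    window = np.asarray(window, dtype=float)
    if window.shape[-1] < 2:
        raise ValueError("window must have at least 2 samples")
    var = window.var(axis=-1, ddof=1)
    if np.any(var <= 0):
        raise DegenerateSignalError("zero-variance window has no finite differential entropy")
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def autocorr_spectrum(window: np.ndarray) -> np.ndarray:
    """Power spectrum P(w_k) = sum_t gamma(t) e^{-j w_k t} over the DFT
    frequencies, with gamma the biased autocorrelation.  Equals the
    periodogram |X(k)|^2 / M (computed that way here; the O(M^2) lag sum
    is the test oracle)."""
    window = np.asarray(window, dtype=float)
    m = window.shape[-1]
    spec = np.abs(np.fft.fft(window, axis=-1)) ** 2 / m
    return spec


def psd(window: np.ndarray) -> np.ndarray:
    """Average power: the autocorrelation spectrum averaged over its
    frequencies (== mean squared amplitude by Parseval)."""
    window = np.asarray(window, dtype=float)
    if window.shape[-1] < 2:
        raise ValueError("window must have at least 2 samples")
    return autocorr_spectrum(window).mean(axis=-1)


def ne(window: np.ndarray) -> np.ndarray:
    """Nonlinear energy: mean of y^2 + H[y]^2 with y the first difference
    of the window and H the Hilbert transform (analytic-signal imaginary
    part).  Non-negative; scales as the square of the amplitude."""
    window = np.asarray(window, dtype=float)
    if window.shape[-1] < 4:
        raise ValueError("window must have at least 4 samples")
    y = np.diff(window, axis=-1)
    analytic = sps.hilbert(y, axis=-1)
    gamma = y**2 + np.imag(analytic) ** 2
    return gamma.mean(axis=-1)


def petrosian(n: int, n_delta: np.ndarray | int) -> np.ndarray:
    """Petrosian fractal dimension from sample count ``n`` and sign-change
    count ``n_delta``: log10(n) / (log10(n) + log10(n / (n + 0.4*n_delta))).
    Equals 1 when there are no sign changes."""
    n_delta = np.asarray(n_delta, dtype=float)
    log_n = np.log10(float(n))
    return log_n / (log_n + np.log10(n / (n + 0.4 * n_delta)))


def _sign_changes(window: np.ndarray) -> np.ndarray:
    return np.count_nonzero(window[..., :-1] * window[..., 1:] < 0, axis=-1)


def fd(window: np.ndarray) -> np.ndarray:
    """Petrosian fractal dimension of a window.

    Sign changes are counted on the raw samples (consecutive-sample
    products < 0), which keeps the FD = 1 limit exact for sign-constant
    monotone signals; the band-passed windows this operates on in the
    pipeline are zero-mean, so a DC offset cannot hide complexity there.
    """
    window = np.asarray(window, dtype=float)
    n = window.shape[-1]
    if n < 2:
        raise ValueError("window must have at least 2 samples")
    return petrosian(n, _sign_changes(window))


_FEATURE_FUNCS = {"de": de, "psd": psd, "ne": ne, "fd": fd}


def extract(
    trial: np.ndarray,
    fs: float,
    bands: tuple[BandDefinition, ...] = BANDS,
    window_s: float = 0.5,
    baseline_s: float = 0.0,
) -> FeatureFrameSeries:
    """Extract all four features on all bands for one trial.

    ``trial`` is (channels, samples) — EEG channels only.  The full trial
    is filtered per band (zero-phase, so window boundaries are not phase
    shifted), then windowed.  Returns values of shape
    (windows, bands, features, channels).
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise ValueError("trial must be channels x samples")
    flat_var = trial.var(axis=-1)
    dead = np.flatnonzero(flat_var <= 0)
    if dead.size:
        raise DegenerateSignalError(f"zero-variance channel(s) {dead.tolist()}")
    n_base = int(round(baseline_s / window_s)) if baseline_s else 0
    per_band = []
    for band in bands:
        filtered = bandpass(trial, band, fs)            # (C, S)
        wins = segment(filtered, fs, window_s)          # (C, W, L)
        feats = []
        for name in FEATURE_ORDER:
            try:
                feats.append(_FEATURE_FUNCS[name](wins))  # (C, W)
            except (ValueError, DegenerateSignalError) as exc:
                raise DegenerateSignalError(f"feature {name}, band {band.name}: {exc}") from exc
        per_band.append(np.stack(feats, axis=0))        # (F, C, W)
    values = np.stack(per_band, axis=0)                 # (B, F, C, W)
    values = np.transpose(values, (3, 0, 1, 2))         # (W, B, F, C)
    return FeatureFrameSeries(values=values, window_s=window_s, baseline_windows=n_base)


def baseline_correct(series: FeatureFrameSeries) -> FeatureFrameSeries:
    """Subtract the mean over the leading baseline windows from every
    stimulus window; the output holds stimulus windows only."""
    if series.baseline_windows < 1:
        raise ValueError("series has no baseline windows to correct against")
    base = series.values[: series.baseline_windows].mean(axis=0, keepdims=True)
    corrected = series.values[series.baseline_windows:] - base
    return replace(series, values=corrected, baseline_windows=0)


def normalize(series_set: list[FeatureFrameSeries]) -> list[FeatureFrameSeries]:
    """Per-subject z-scoring: pooled over all stimulus windows of all the
    subject's series, each (band, feature, channel) slot gets mean 0 and
    unit variance.  Slots with zero spread are set to 0 with a warning."""
    stacked = np.concatenate([s.values[s.baseline_windows:] for s in series_set], axis=0)
    if stacked.shape[0] < 2:
        raise ValueError("need at least 2 stimulus windows to normalize")
    mean = stacked.mean(axis=0, keepdims=True)
    std = stacked.std(axis=0, ddof=0, keepdims=True)
    flat = std <= 1e-10 * np.maximum(1.0, np.abs(mean))  # zero spread up to rounding
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} constant feature slot(s) set to 0 during normalization")
        std = np.where(flat, 1.0, std)
    out = []
    for s in series_set:
        vals = s.values.copy()
        vals[s.baseline_windows:] = (vals[s.baseline_windows:] - mean) / std
        if np.any(flat):
            vals[s.baseline_windows:] = np.where(flat, 0.0, vals[s.baseline_windows:])
        out.append(replace(s, values=vals))
    return out


def save_features(series_list: list[FeatureFrameSeries], path) -> None:
    """Store per-trial feature tensors in one HDF5 file."""
    with h5py.File(path, "w") as f:
        for i, s in enumerate(series_list):
            d = f.create_dataset(f"trial_{i:03d}/features", data=s.values)
            d.attrs["window_s"] = s.window_s
            d.attrs["baseline_windows"] = s.baseline_windows
            d.attrs["band_names"] = [b.encode() for b in s.band_names]
            d.attrs["feature_names"] = [b.encode() for b in s.feature_names]


def load_features(path) -> list[FeatureFrameSeries]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            d = f[key]["features"]
            out.append(
                FeatureFrameSeries(
                    values=d[...],
                    window_s=float(d.attrs["window_s"]),
                    baseline_windows=int(d.attrs["baseline_windows"]),
                    band_names=tuple(
                        b.decode() if isinstance(b, bytes) else str(b) for b in d.attrs["band_names"]
                    ),
                    feature_names=tuple(
                        b.decode() if isinstance(b, bytes) else str(b)
                        for b in d.attrs["feature_names"]
                    ),
                )
            )
    return out
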