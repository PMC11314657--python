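"""DEAP-structured synthetic EEG generator.

The DEAP recordings this package targets are access-restricted, so the
pipeline is exercised on synthetic multichannel EEG that mirrors DEAP's
per-subject layout exactly: ``trials x channels x samples`` at 128 Hz, a
3 s pre-stimulus baseline followed by 60 s of stimulus, 40 recorded
channels of which the leading 32 are EEG, and per-trial valence/arousal
ratings on a 1-9 scale.

Each trial is a sum of one band-limited oscillation per rhythm (theta,
alpha, beta, gamma; carrier frequency drawn inside the band edges) plus
half white / half 1/f-shaped Gaussian noise.  Emotion classes modulate
band amplitudes multiplicatively in named electrode groups, and only
during the stimulus segment, so baseline correction downstream cannot
remove the class signal.  With no configured effects, ratings and signal
are statistically independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "DEAP_EEG_CHANNELS",
    "AUX_CHANNELS",
    "CHANNEL_GROUPS",
    "SyntheticSpec",
    "RawRecording",
    "planted_band_effects",
    "generate_recording",
    "write_fixture",
    "read_fixture",
]

#: The 32 EEG electrode names of the DEAP montage, in recording order.
DEAP_EEG_CHANNELS = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: DEAP's 8 trailing peripheral channels (carried as noise only).
AUX_CHANNELS = ("hEOG", "vEOG", "zEMG", "tEMG", "GSR", "Resp", "Plethysmograph", "Temp")

#: Named scalp regions used to localize class-conditional band effects.
CHANNEL_GROUPS = {
    "frontal": ("Fp1", "Fp2", "AF3", "AF4", "F3", "F4", "F7", "F8", "Fz"),
    "central": ("FC1", "FC2", "FC5", "FC6", "C3", "C4", "Cz"),
    "temporal": ("T7", "T8"),
    "parietal": ("CP1", "CP2", "CP5", "CP6", "P3", "P4", "P7", "P8", "Pz"),
    "occipital": ("PO3", "PO4", "O1", "O2", "Oz"),
}

# Band edges shared with the features module (kept numeric here to avoid
# a circular import); base amplitudes fall off with frequency.
_BAND_EDGES = {"theta": (3.0, 8.0), "alpha": (8.0, 14.0), "beta": (14.0, 31.0), "gamma": (31.0, 45.0)}
_BASE_AMPLITUDE = {"theta": 4.0, "alpha": 3.0, "beta": 2.0, "gamma": 1.5}

#: Class strata: high/low valence, high/low arousal.
CLASS_LABELS = ("HV", "LV", "HA", "LA")


class InvalidSpecError(ValueError):
    """Raised when a SyntheticSpec violates its invariants."""


class FixtureParseError(ValueError):
    """Raised when a fixture file is malformed; names the missing field."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters of the generator (defaults mirror DEAP)."""

    n_subjects: int = 32
    n_trials: int = 40
    n_channels: int = 40
    n_eeg_channels: int = 32
    fs: float = 128.0
    baseline_s: float = 3.0
    stimulus_s: float = 60.0
    #: ``{class label: {band: {channel group: amplitude multiplier}}}``
    band_effects: dict = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.fs * (self.baseline_s + self.stimulus_s)))

    def validate(self) -> None:
        if min(self.n_subjects, self.n_trials, self.n_channels, self.n_eeg_channels) <= 0:
            raise InvalidSpecError("all counts must be positive")
        if self.fs <= 0 or self.baseline_s <= 0 or self.stimulus_s <= 0:
            raise InvalidSpecError("fs and durations must be positive")
        if self.n_eeg_channels > self.n_channels:
            raise InvalidSpecError("n_eeg_channels exceeds n_channels")
        if self.n_eeg_channels > len(DEAP_EEG_CHANNELS):
            raise InvalidSpecError("at most 32 EEG channels are named in the DEAP montage")
        for label, bands in self.band_effects.items():
            if label not in CLASS_LABELS:
                raise InvalidSpecError(f"unknown class label {label!r}")
            for band, groups in bands.items():
                if band not in _BAND_EDGES:
                    raise InvalidSpecError(f"unknown band {band!r}")
                for group, mult in groups.items():
                    if group not in CHANNEL_GROUPS:
                        raise InvalidSpecError(f"unknown channel group {group!r}")
                    if mult <= 0:
                        raise InvalidSpecError("amplitude multipliers must be > 0")

    def channel_names(self) -> list[str]:
        names = list(DEAP_EEG_CHANNELS[: self.n_eeg_channels])
        n_aux = self.n_channels - self.n_eeg_channels
        for i in range(n_aux):
            names.append(AUX_CHANNELS[i] if i < len(AUX_CHANNELS) else f"AUX{i}")
        return names


@dataclass
class RawRecording:
    """One subject's block of trials, DEAP-shaped."""

    subject_id: str
    data: np.ndarray            # (trials, channels, samples), microvolt scale
    fs: float
    channel_names: list[str]
    baseline_s: float
    ratings: np.ndarray         # (trials, 2): valence, arousal in [1, 9]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal channel count")
        if self.ratings.shape != (self.data.shape[0], 2):
            raise ValueError("ratings must be (trials, 2)")
        if np.any(self.ratings < 1) or np.any(self.ratings > 9):
            raise ValueError("ratings must lie in [1, 9]")


def planted_band_effects(strength: float = 2.0) -> dict:
    """A standard planted effect: high arousal boosts frontal gamma,
    high valence boosts parietal+occipital beta, by ``strength``."""
    return {
        "HA": {"gamma": {"frontal": strength}},
        "HV": {"beta": {"parietal": strength, "occipital": strength}},
    }


def _subject_rng(spec: SyntheticSpec, subject_id: str) -> np.random.Generator:
    # stable across processes: crc32 of the id, never python hash()
    sid = zlib.crc32(str(subject_id).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((spec.seed, sid)))


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float) -> np.ndarray:
    """Gaussian noise with a 1/f amplitude spectrum along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.empty_like(freqs)
    scale[0] = 0.0
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    out /= out.std(axis=-1, keepdims=True) + 1e-12
    return out


def _trial_multipliers(spec: SyntheticSpec, labels: tuple[str, ...]) -> np.ndarray:
    """Per (band, channel) amplitude multiplier for a trial with the given
    class labels (e.g. ("HV", "LA")). Multipliers from matching classes
    compose multiplicatively."""
    names = spec.channel_names()
    mult = np.ones((len(_BAND_EDGES), spec.n_channels))
    band_index = {b: i for i, b in enumerate(_BAND_EDGES)}
    for label in labels:
        for band, groups in spec.band_effects.get(label, {}).items():
            for group, m in groups.items():
                for ch in CHANNEL_GROUPS[group]:
                    if ch in names:
                        c = names.index(ch)
                        if c < spec.n_eeg_channels:
                            mult[band_index[band], c] *= m
    return mult


def generate_recording(spec: SyntheticSpec, subject_id: str) -> RawRecording:
    """Generate one subject's synthetic recording.

    Deterministic given ``(spec.seed, subject_id)``.  Ratings are drawn so
    that each of the HV/LV and HA/LA strata is non-empty (balanced halves,
    shuffled), and class effects touch only the stimulus segment of EEG
    channels.
    """
    spec.validate()
    rng = _subject_rng(spec, subject_id)
    n_t, n_c, n_s = spec.n_trials, spec.n_channels, spec.samples_per_trial
    n_base = int(round(spec.fs * spec.baseline_s))
    t = np.arange(n_s) / spec.fs

    # balanced binary classes per dimension, then ratings inside the half-scales
    high_v = np.zeros(n_t, dtype=bool)
    high_v[: n_t // 2 or 1] = True
    rng.shuffle(high_v)
    high_a = np.zeros(n_t, dtype=bool)
    high_a[: n_t // 2 or 1] = True
    rng.shuffle(high_a)
    ratings = np.empty((n_t, 2))
    ratings[:, 0] = np.where(high_v, rng.uniform(5.5, 9.0, n_t), rng.uniform(1.0, 4.5, n_t))
    ratings[:, 1] = np.where(high_a, rng.uniform(5.5, 9.0, n_t), rng.uniform(1.0, 4.5, n_t))

    data = np.zeros((n_t, n_c, n_s))
    band_list = list(_BAND_EDGES)
    for trial in range(n_t):
        labels = ("HV" if high_v[trial] else "LV", "HA" if high_a[trial] else "LA")
        mult = _trial_multipliers(spec, labels)
        for b, band in enumerate(band_list):
            lo, hi = _BAND_EDGES[band]
            # margin keeps carriers inside the band after filtering
            f0 = rng.uniform(lo + 0.15 * (hi - lo), hi - 0.15 * (hi - lo), n_c)
            phase = rng.uniform(0.0, 2.0 * np.pi, n_c)
            osc = _BASE_AMPLITUDE[band] * np.sin(2.0 * np.pi * f0[:, None] * t[None, :] + phase[:, None])
            gain = np.ones((n_c, n_s))
            gain[: spec.n_eeg_channels, n_base:] = mult[b, : spec.n_eeg_channels, None]
            data[trial] += osc * gain
        noise = 0.5 * rng.standard_normal((n_c, n_s)) + 0.5 * _pink_noise(rng, (n_c, n_s), spec.fs)
        data[trial] += spec.noise_sd * noise
    # aux channels carry noise only
    n_aux = n_c - spec.n_eeg_channels
    if n_aux:
        data[:, spec.n_eeg_channels:, :] = spec.noise_sd * rng.standard_normal((n_t, n_aux, n_s))

    return RawRecording(
        subject_id=str(subject_id),
        data=data,
        fs=spec.fs,
        channel_names=spec.channel_names(),
        baseline_s=spec.baseline_s,
        ratings=ratings,
    )


_REQUIRED_DATASETS = ("data", "ratings")
_REQUIRED_ATTRS = ("fs", "baseline_s", "channel_names", "subject_id")


def write_fixture(rec: RawRecording, path) -> None:
    """Write one subject's recording to an HDF5 fixture file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("ratings", data=rec.ratings)
        f.attrs["fs"] = rec.fs
        f.attrs["baseline_s"] = rec.baseline_s
        f.attrs["channel_names"] = [n.encode() for n in rec.channel_names]
        f.attrs["subject_id"] = rec.subject_id


def read_fixture(path) -> RawRecording:
    """Read a fixture written by :func:`write_fixture` (lossless round trip)."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FixtureParseError(f"not a readable HDF5 fixture: {path}") from exc
    with f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise FixtureParseError(f"fixture missing dataset {name!r}")
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise FixtureParseError(f"fixture missing attribute {name!r}")
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in f.attrs["channel_names"]]
        return RawRecording(
            subject_id=str(f.attrs["subject_id"]),
            data=f["data"][...],
            fs=float(f.attrs["fs"]),
            channel_names=names,
            baseline_s=float(f.attrs["baseline_s"]),
            ratings=f["ratings"][...],
        )
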