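"""Raw multichannel signal -> band-feature observation sequences.

The chain mirrors standard EEG practice: a zero-phase low-pass at 30 Hz
(the "0-30 Hz bandpass" of scalp EEG work; DC is retained since the lower
edge is 0), wavelet-packet decomposition into the four canonical bands --
delta 0-3 Hz, theta 4-7 Hz, alpha 8-12 Hz, beta 13-30 Hz -- framed into
one observation vector per second, followed by per-column normalisation
and edge truncation. Sequences are stored as plain CSV with a JSON sidecar
manifest.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from scipy.signal import butter, sosfiltfilt

from vigilhmm.hmm_core import InputError

logger = logging.getLogger(__name__)

#: canonical EEG band edges in Hz, low edge inclusive
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}
BAND_NAMES = tuple(BAND_EDGES)
# midpoints between adjacent printed band edges; used to assign WPD bins
_BAND_BOUNDARIES = (3.5, 7.5, 12.5, 30.0)


@dataclass
class RawRecording:
    """A channels x time amplitude matrix (micro-volts) with metadata."""

    samples: np.ndarray
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)
    operator_id: str = ""
    task_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")
        if np.any(~np.isfinite(self.samples)):
            raise InputError("recording contains NaN or infinite samples")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.samples.shape[0])]
        if len(self.channel_names) != self.samples.shape[0]:
            raise InputError("channel_names length mismatch")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


@dataclass
class BandSequence:
    """Per-frame amplitudes of the four bands (columns delta..beta)."""

    bands: np.ndarray
    frame_rate: float = 1.0
    normalization: str | None = None
    operator_id: str = ""
    task_id: str = ""

    def __post_init__(self) -> None:
        self.bands = np.atleast_2d(np.asarray(self.bands, dtype=float))
        if self.bands.shape[1] % len(BAND_NAMES) != 0:
            raise InputError(
                f"band matrix columns must be a multiple of {len(BAND_NAMES)}"
            )
        if np.any(~np.isfinite(self.bands)):
            raise InputError("band matrix contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.bands.shape[0]


def band_limit(
    rec: RawRecording, high_hz: float = 30.0, order: int = 8, method: str = "fft"
) -> RawRecording:
    """Zero-phase Butterworth low-pass at ``high_hz`` (DC retained).

    ``method="fft"`` (default) applies the squared-magnitude Butterworth
    response 1 / (1 + (f / high_hz)^(2 * order)) in the frequency domain --
    exactly the amplitude response of a forward-backward Butterworth pass,
    with no edge transient. The implied circular convolution can ring near
    the record edges for non-periodic signals, which is why the pipeline
    truncates the first and last seconds downstream. ``method="sos"`` is a
    conventional time-domain forward-backward pass (second-order sections).
    """
    if rec.sampling_rate <= 2 * high_hz:
        raise InputError(
            f"sampling rate {rec.sampling_rate} Hz too low for a {high_hz} Hz cutoff"
        )
    if method == "fft":
        n = rec.samples.shape[1]
        freqs = np.fft.rfftfreq(n, 1.0 / rec.sampling_rate)
        gain = 1.0 / (1.0 + (freqs / high_hz) ** (2 * order))
        spec = np.fft.rfft(rec.samples, axis=1) * gain
        filtered = np.fft.irfft(spec, n, axis=1)
    elif method == "sos":
        sos = butter(order, high_hz, btype="low", fs=rec.sampling_rate, output="sos")
        filtered = sosfiltfilt(sos, rec.samples, axis=1)
    else:
        raise InputError(f"unknown band_limit method {method!r}")
    return replace(rec, samples=filtered)


def _wpd_level(sampling_rate: float) -> int:
    """Decomposition level giving terminal bins of width <= 2 Hz."""
    nyq = sampling_rate / 2.0
    level = max(1, math.ceil(math.log2(nyq / 2.0)))
    return level


def _bin_to_band(midpoint_hz: float) -> int | None:
    """Index of the band owning a WPD bin midpoint, or None above 30 Hz."""
    for b, hi in enumerate(_BAND_BOUNDARIES):
        if midpoint_hz <= hi:
            return b
    return None


def decompose_bands(
    rec: RawRecording,
    wavelet: str = "db4",
    frame_seconds: float = 1.0,
    channel_mode: str = "average",
) -> BandSequence:
    """Wavelet-packet band amplitudes, one observation vector per frame.

    Each channel is decomposed with an orthogonal wavelet packet (default
    Daubechies-4) to a level whose frequency-ordered terminal bins are at
    most 2 Hz wide; bins are assigned to delta/theta/alpha/beta by their
    midpoint, coefficients above 30 Hz are dropped, and per-frame band
    amplitudes are root-mean-square coefficient magnitudes. With
    ``channel_mode="average"`` the per-channel band columns are averaged
    (obs_dim 4); ``"concat"`` concatenates them (obs_dim 4 x n_channels).
    """
    fs = rec.sampling_rate
    frame_len = int(round(frame_seconds * fs))
    if rec.samples.shape[1] < frame_len:
        raise InputError("recording shorter than one decomposition frame")
    level = _wpd_level(fs)
    bin_width = fs / 2.0 / 2**level
    n_frames = rec.samples.shape[1] // frame_len
    per_channel = []
    for ch in range(rec.n_channels):
        x = rec.samples[ch, : n_frames * frame_len]
        wp = pywt.WaveletPacket(data=x, wavelet=wavelet, mode="periodization", maxlevel=level)
        nodes = wp.get_level(level, order="freq")
        step = 2**level  # samples covered by one terminal coefficient
        energy = np.zeros((n_frames, len(BAND_NAMES)))
        for i, node in enumerate(nodes):
            mid = (i + 0.5) * bin_width
            b = _bin_to_band(mid)
            if b is None:
                continue
            coefs = np.asarray(node.data, dtype=float)
            t = (np.arange(len(coefs)) + 0.5) * step / fs
            frame_idx = np.minimum((t / frame_seconds).astype(int), n_frames - 1)
            np.add.at(energy, (frame_idx, np.full(len(coefs), b)), coefs**2)
        # root band energy per frame: summing squared amplitudes over the four
        # bands recovers the frame's coefficient (= signal) energy, Parseval-style
        amp = np.sqrt(energy)
        per_channel.append(amp)
    if channel_mode == "average":
        bands = np.mean(per_channel, axis=0)
    elif channel_mode == "concat":
        bands = np.hstack(per_channel)
        return BandSequence(
            bands=bands,
            frame_rate=1.0 / frame_seconds,
            operator_id=rec.operator_id,
            task_id=rec.task_id,
        )
    else:
        raise InputError(f"unknown channel_mode {channel_mode!r}")
    return BandSequence(
        bands=bands,
        frame_rate=1.0 / frame_seconds,
        operator_id=rec.operator_id,
        task_id=rec.task_id,
    )


def band_energy_fractions(bs: BandSequence) -> np.ndarray:
    """Share of total (squared-amplitude) energy per band column."""
    e = np.sum(bs.bands[:, : len(BAND_NAMES)] ** 2, axis=0)
    total = e.sum()
    if total == 0:
        return np.zeros_like(e)
    return e / total


def normalize(bs: BandSequence, method: str = "zscore") -> BandSequence:
    """Per-column z-score (mean 0, sd 1) or min-max ([0, 1]) normalisation."""
    if bs.n_frames < 2:
        raise InputError("need at least two frames to normalize")
    x = bs.bands.copy()
    if method == "zscore":
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        zero = sd < 1e-12
        if np.any(zero):
            warnings.warn("zero-variance column(s) left at zero during zscore")
        sd = np.where(zero, 1.0, sd)
        x = (x - mu) / sd
        x[:, zero] = 0.0
    elif method == "minmax":
        lo = x.min(axis=0)
        hi = x.max(axis=0)
        span = hi - lo
        zero = span < 1e-12
        if np.any(zero):
            warnings.warn("zero-range column(s) left at zero during minmax")
        span = np.where(zero, 1.0, span)
        x = (x - lo) / span
        x[:, zero] = 0.0
    else:
        raise InputError(f"unknown normalization method {method!r}")
    return replace(bs, bands=x, normalization=method)


def truncate_edges(obj: RawRecording | BandSequence, seconds: float = 5.0):
    """Drop the first and last ``seconds`` of a recording or band sequence."""
    if seconds < 0:
        raise InputError("seconds must be non-negative")
    if seconds == 0:
        return obj
    if isinstance(obj, RawRecording):
        n = int(round(seconds * obj.sampling_rate))
        if obj.samples.shape[1] <= 2 * n:
            raise InputError("recording too short to truncate edges")
        return replace(obj, samples=obj.samples[:, n:-n])
    if isinstance(obj, BandSequence):
        n = int(round(seconds * obj.frame_rate))
        if obj.bands.shape[0] <= 2 * n:
            raise InputError("band sequence too short to truncate edges")
        return replace(obj, bands=obj.bands[n:-n])
    raise InputError(f"cannot truncate object of type {type(obj).__name__}")


def split_train_test(seqs: list, train_fraction: float, seed: int) -> tuple[list, list]:
    """Stratified (by vigilance label) random split, reproducible per seed."""
    if not 0 < train_fraction < 1:
        raise InputError("train_fraction must be in (0, 1)")
    by_label: dict[str, list] = {}
    for s in seqs:
        by_label.setdefault(s.vigilance, []).append(s)
    for label, group in by_label.items():
        if len(group) < 2:
            raise InputError(f"label {label!r} has fewer than 2 sequences")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for label in sorted(by_label):
        group = by_label[label]
        order = rng.permutation(len(group))
        n_train = int(round(train_fraction * len(group)))
        n_train = min(max(n_train, 1), len(group) - 1)
        for pos, idx in enumerate(order):
            (train if pos < n_train else test).append(group[idx])
    return train, test


# ---------------------------------------------------------------------------
# plain-text I/O: CSV + JSON sidecar manifests


def save_recording(rec: RawRecording, path: Path, manifest: dict) -> None:
    path = Path(path)
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_names)
    df.to_csv(path, index=False, float_format="%.6g")
    side = dict(manifest)
    side.setdefault("operator_id", rec.operator_id)
    side.setdefault("task_id", rec.task_id)
    side["sampling_rate"] = rec.sampling_rate
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def load_recording(path: Path) -> tuple[RawRecording, dict]:
    path = Path(path)
    manifest = _load_manifest(path.with_suffix(".json"))
    df = pd.read_csv(path)
    rec = RawRecording(
        samples=df.to_numpy().T,
        sampling_rate=float(manifest["sampling_rate"]),
        channel_names=list(df.columns),
        operator_id=str(manifest.get("operator_id", "")),
        task_id=str(manifest.get("task_id", "")),
    )
    return rec, manifest


def save_features(bs: BandSequence, path: Path, manifest: dict) -> None:
    path = Path(path)
    cols = (
        list(BAND_NAMES)
        if bs.bands.shape[1] == len(BAND_NAMES)
        else [f"f{i}" for i in range(bs.bands.shape[1])]
    )
    pd.DataFrame(bs.bands, columns=cols).to_csv(path, index=False, float_format="%.10g")
    side = dict(manifest)
    side.setdefault("operator_id", bs.operator_id)
    side.setdefault("task_id", bs.task_id)
    side["frame_rate"] = bs.frame_rate
    if bs.normalization:
        side["normalization"] = bs.normalization
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def load_features(path: Path) -> tuple[BandSequence, dict]:
    path = Path(path)
    manifest = _load_manifest(path.with_suffix(".json"))
    df = pd.read_csv(path)
    bs = BandSequence(
        bands=df.to_numpy(),
        frame_rate=float(manifest.get("frame_rate", 1.0)),
        normalization=manifest.get("normalization"),
        operator_id=str(manifest.get("operator_id", "")),
        task_id=str(manifest.get("task_id", "")),
    )
    return bs, manifest


def _load_manifest(path: Path) -> dict:
    if not path.exists():
        raise InputError(f"missing sidecar manifest {path}")
    try:
        manifest = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"corrupt manifest {path}: {exc}") from exc
    if "sampling_rate" not in manifest and "frame_rate" not in manifest:
        raise InputError(f"manifest {path} lacks a sampling_rate/frame_rate field")
    return manifest


def list_dataset(directory: Path, suffix: str = ".csv") -> list[Path]:
    """CSV files in a dataset directory that have a valid sidecar manifest."""
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"{directory} is not a directory")
    out = []
    for p in sorted(directory.glob(f"*{suffix}")):
        if p.with_suffix(".json").exists():
            out.append(p)
    if not out:
        raise InputError(f"no manifest-paired {suffix} files in {directory}")
    return out
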