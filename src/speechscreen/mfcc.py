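"""MFCC feature extraction: pre-emphasis, framing, windowing, FFT power
spectrum, mel filter bank, and DCT cepstra, plus segmentation and the JSON
feature-file format consumed by training.

The mel mapping is ``Mel(f) = C * log10(1 + f / f0)`` with the constant ``C``
chosen so that 1000 Hz maps to 1000 mels exactly:

    C = 1000 / log10(1 + 1000 / f0)

At the usual corner frequency f0 = 700 Hz, C rounds to 2595 — but the
unrounded value is used throughout so that ``hz_to_mel(1000) == 1000`` holds
to machine precision.

Dialect defaults (recorded in :class:`ExtractionParams` so oracle tests can
mirror them): 13 cepstral coefficients, FFT window 2048, hop 512, periodic
Hann window, 128 triangular mel filters from 0 Hz to Nyquist, common (base-10)
logarithm of the filter-bank energies floored at a relative epsilon, and an
orthonormal type-II DCT.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .audio_io import AudioClip

__all__ = [
    "MelScaleParams",
    "ExtractionParams",
    "FrameStack",
    "MelFilterBank",
    "MFCCMatrix",
    "FeatureSegment",
    "FeatureDataset",
    "mel_constant",
    "hz_to_mel",
    "mel_to_hz",
    "pre_emphasize",
    "frame_signal",
    "apply_hann",
    "power_spectrum",
    "build_mel_filterbank",
    "log_mel_energies",
    "dct_cepstra",
    "extract_mfcc",
    "segment_mfcc",
    "write_feature_json",
    "read_feature_json",
]


# ---------------------------------------------------------------------------
# Mel scale
# ---------------------------------------------------------------------------

def mel_constant(corner_frequency_hz: float) -> float:
    """Constant ``C = 1000 / log10(1 + 1000 / f0)``, unrounded.

    Defined so that the mel mapping sends 1000 Hz to 1000 mels exactly.
    For f0 = 700 Hz this rounds to the familiar 2595.
    """
    if corner_frequency_hz <= 0:
        raise ValueError("corner frequency must be positive")
    return 1000.0 / math.log10(1.0 + 1000.0 / corner_frequency_hz)


@dataclass(frozen=True)
class MelScaleParams:
    """Corner frequency f0 and the derived (unrounded) constant C."""

    corner_frequency_hz: float = 700.0
    constant: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.constant is None:
            object.__setattr__(self, "constant", mel_constant(self.corner_frequency_hz))
        if self.constant <= 0:
            raise ValueError("mel constant must be positive")


def hz_to_mel(f, params: MelScaleParams | None = None):
    """``Mel(f) = C * log10(1 + f / f0)``; strictly increasing, Mel(0) = 0."""
    params = params or MelScaleParams()
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = params.constant * np.log10(1.0 + f / params.corner_frequency_hz)
    return float(out) if out.ndim == 0 else out


def mel_to_hz(m, params: MelScaleParams | None = None):
    """Inverse mel mapping: ``f = f0 * (10^(m / C) - 1)``."""
    params = params or MelScaleParams()
    m = np.asarray(m, dtype=np.float64)
    out = params.corner_frequency_hz * (np.power(10.0, m / params.constant) - 1.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Extraction dialect
# ---------------------------------------------------------------------------

@dataclass
class ExtractionParams:
    """Every knob of the extraction pipeline, serialised with the features."""

    sample_rate: int | None = None  # None: taken from the clip
    n_mfcc: int = 13
    n_fft: int = 2048
    hop_length: int = 512
    pre_emphasis: float = 0.97
    n_mels: int = 128
    fmin: float = 0.0
    fmax: float | None = None  # None: Nyquist
    corner_frequency_hz: float = 700.0
    log_base: str = "10"  # common logarithm of mel energies
    rel_floor: float = 1e-10  # log floor, relative to the max filterbank energy
    frames_per_segment: int = 100

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractionParams":
        return cls(**d)


# ---------------------------------------------------------------------------
# Stage types
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    """Overlapping analysis frames: ``frames`` is n_frames x frame_length."""

    frames: np.ndarray
    frame_length: int
    hop_length: int

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 2 or self.frames.shape[0] < 1:
            raise ValueError("FrameStack needs at least one frame")
        if self.frames.shape[1] != self.frame_length:
            raise ValueError("frame width does not match frame_length")
        if not (1 <= self.hop_length <= self.frame_length):
            raise ValueError("hop_length must be in [1, frame_length]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class MelFilterBank:
    """Triangular filters: ``weights`` is n_mels x n_spectral_bins."""

    weights: np.ndarray
    band_edges_hz: np.ndarray  # n_mels x 3: (low, centre, high)

    @property
    def n_mels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_bins(self) -> int:
        return self.weights.shape[1]


@dataclass
class MFCCMatrix:
    """Per-frame cepstral coefficients: n_frames x n_coefficients."""

    coefficients: np.ndarray
    n_coefficients: int = 13
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.ndim != 2:
            raise ValueError("coefficients must be 2-D")
        if self.coefficients.shape[1] != self.n_coefficients:
            raise ValueError("column count does not match n_coefficients")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("MFCC entries must be finite")

    @property
    def n_frames(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class FeatureSegment:
    """A fixed-length block of MFCC frames carrying its participant's label."""

    features: np.ndarray  # frames_per_segment x n_mfcc
    label: int
    participant_id: str

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("segment features must be 2-D")
        if self.label not in (0, 1):
            raise ValueError("segment label must be 0 or 1")


@dataclass
class FeatureDataset:
    """Uniform-shape feature segments plus the dialect that produced them."""

    segments: list[FeatureSegment]
    label_names: list[str] = field(default_factory=lambda: ["control", "mtbi"])
    extraction_params: ExtractionParams = field(default_factory=ExtractionParams)

    def __post_init__(self) -> None:
        shapes = {seg.features.shape for seg in self.segments}
        if len(shapes) > 1:
            raise ValueError(f"segments have mixed shapes: {sorted(shapes)}")

    @property
    def segment_shape(self) -> tuple[int, int]:
        if not self.segments:
            raise ValueError("dataset is empty")
        return self.segments[0].features.shape

    def arrays(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Stack into (X, y, participant_ids) for model consumption."""
        X = np.stack([seg.features for seg in self.segments])
        y = np.array([seg.label for seg in self.segments], dtype=np.int64)
        pids = [seg.participant_id for seg in self.segments]
        return X, y, pids

    def participant_ids(self) -> list[str]:
        return sorted({seg.participant_id for seg in self.segments})


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def pre_emphasize(clip: AudioClip, alpha: float = 0.97) -> AudioClip:
    """First-difference high-pass: ``y[t] = x[t] - alpha * x[t-1]``, y[0] = x[0]."""
    if not (0.0 <= alpha < 1.0):
        raise ValueError("pre-emphasis coefficient must be in [0, 1)")
    x = clip.samples
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - alpha * x[:-1]
    return AudioClip(samples=y, sample_rate=clip.sample_rate, source_id=clip.source_id)


def frame_signal(clip: AudioClip, frame_length: int = 2048, hop_length: int = 512) -> FrameStack:
    """Slice into overlapping frames, zero-padding the tail to fill the last.

    For signal length L > frame_length the frame count is
    ``1 + ceil((L - frame_length) / hop_length)``; shorter signals yield a
    single zero-padded frame.
    """
    if frame_length < 1:
        raise ValueError("frame_length must be >= 1")
    if not (1 <= hop_length <= frame_length):
        raise ValueError("hop_length must be in [1, frame_length]")
    x = clip.samples
    L = x.size
    if L == 0:
        raise ValueError("cannot frame an empty signal")
    if L <= frame_length:
        n_frames = 1
    else:
        n_frames = 1 + math.ceil((L - frame_length) / hop_length)
    padded_len = frame_length + (n_frames - 1) * hop_length
    if padded_len > L:
        x = np.concatenate([x, np.zeros(padded_len - L)])
    idx = np.arange(frame_length)[None, :] + hop_length * np.arange(n_frames)[:, None]
    return FrameStack(frames=x[idx], frame_length=frame_length, hop_length=hop_length)


def hann_window(n: int) -> np.ndarray:
    """Periodic Hann window ``0.5 - 0.5 cos(2 pi k / n)``; sums to n/2."""
    k = np.arange(n)
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * k / n)


def apply_hann(stack: FrameStack) -> FrameStack:
    """Multiply every frame by the periodic Hann window."""
    w = hann_window(stack.frame_length)
    return FrameStack(
        frames=stack.frames * w[None, :],
        frame_length=stack.frame_length,
        hop_length=stack.hop_length,
    )


def power_spectrum(stack: FrameStack, n_fft: int | None = None) -> np.ndarray:
    """Squared-magnitude DFT per frame over ``n_fft`` points.

    Returns n_frames x (n_fft // 2 + 1), keeping the non-negative-frequency
    bins only.
    """
    n_fft = n_fft or stack.frame_length
    if n_fft < stack.frame_length:
        raise ValueError("n_fft must be >= frame_length")
    spectrum = np.fft.rfft(stack.frames, n=n_fft, axis=1)
    return np.abs(spectrum) ** 2


def build_mel_filterbank(
    n_mels: int,
    n_fft: int,
    sample_rate: float,
    params: MelScaleParams | None = None,
    fmin: float = 0.0,
    fmax: float | None = None,
) -> MelFilterBank:
    """Triangular filters with centres equally spaced on the mel axis.

    ``n_mels + 2`` break points are laid out uniformly in mels between
    ``fmin`` and ``fmax``, mapped back to Hz, and each triangle is evaluated
    at the FFT bin frequencies. Adjacent filters share edges: filter *i*
    spans break points (i, i+1, i+2) and peaks at the middle one.
    """
    params = params or MelScaleParams()
    fmax = sample_rate / 2.0 if fmax is None else fmax
    if n_mels < 1:
        raise ValueError("n_mels must be >= 1")
    if fmin >= fmax:
        raise ValueError("fmin must be < fmax")
    if fmax > sample_rate / 2.0 + 1e-9:
        raise ValueError("fmax exceeds the Nyquist frequency")

    mel_pts = np.linspace(hz_to_mel(fmin, params), hz_to_mel(fmax, params), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts, params)
    n_bins = n_fft // 2 + 1
    bin_freqs = np.arange(n_bins) * sample_rate / n_fft

    low, centre, high = hz_pts[:-2], hz_pts[1:-1], hz_pts[2:]
    with np.errstate(divide="ignore", invalid="ignore"):
        up = (bin_freqs[None, :] - low[:, None]) / (centre - low)[:, None]
        down = (high[:, None] - bin_freqs[None, :]) / (high - centre)[:, None]
    weights = np.maximum(0.0, np.minimum(up, down))

    if np.any(weights.sum(axis=1) == 0.0):
        raise ValueError(
            f"{n_mels} mel filters exceed the spectral resolution of "
            f"n_fft={n_fft} at {sample_rate} Hz (empty filter)"
        )
    edges = np.stack([low, centre, high], axis=1)
    return MelFilterBank(weights=weights, band_edges_hz=edges)


def log_mel_energies(
    spectra: np.ndarray, bank: MelFilterBank, rel_floor: float = 1e-10
) -> np.ndarray:
    """Common log of the filter-bank energies, floored for stability.

    The floor is ``rel_floor`` times the maximum filter-bank energy of the
    matrix (absolute ``rel_floor`` when the input is all zero).
    """
    spectra = np.asarray(spectra, dtype=np.float64)
    if spectra.shape[1] != bank.n_bins:
        raise ValueError(
            f"spectral bin mismatch: spectra have {spectra.shape[1]}, "
            f"filter bank expects {bank.n_bins}"
        )
    energies = spectra @ bank.weights.T
    peak = energies.max() if energies.size else 0.0
    floor = rel_floor * peak if peak > 0 else rel_floor
    return np.log10(np.maximum(energies, floor))


def dct_cepstra(log_energies: np.ndarray, n_coefficients: int = 13) -> MFCCMatrix:
    """First ``n_coefficients`` type-II DCT coefficients per frame.

    Orthonormal scaling; coefficient 0 carries the mean (overall log energy)
    and successive coefficients describe progressively finer spectral detail.
    The basis is built explicitly from the DCT-II definition.
    """
    log_energies = np.asarray(log_energies, dtype=np.float64)
    n = log_energies.shape[1]
    if n_coefficients > n:
        raise ValueError("n_coefficients cannot exceed the number of mel bands")
    k = np.arange(n_coefficients)[:, None]
    m = np.arange(n)[None, :]
    basis = np.cos(np.pi * k * (2 * m + 1) / (2 * n)) * np.sqrt(2.0 / n)
    basis[0, :] *= 1.0 / np.sqrt(2.0)
    coeffs = log_energies @ basis.T
    return MFCCMatrix(coefficients=coeffs, n_coefficients=n_coefficients)


def extract_mfcc(clip: AudioClip, params: ExtractionParams | None = None) -> MFCCMatrix:
    """Full pipeline: pre-emphasis, framing, Hann, power spectrum, mel
    filter bank, log, DCT. Stateless composition of the stage functions."""
    p = params or ExtractionParams()
    sr = p.sample_rate or clip.sample_rate
    emphasized = pre_emphasize(clip, p.pre_emphasis)
    stack = frame_signal(emphasized, p.n_fft, p.hop_length)
    windowed = apply_hann(stack)
    spectra = power_spectrum(windowed, p.n_fft)
    bank = build_mel_filterbank(
        p.n_mels, p.n_fft, sr,
        MelScaleParams(p.corner_frequency_hz),
        fmin=p.fmin, fmax=p.fmax,
    )
    energies = log_mel_energies(spectra, bank, p.rel_floor)
    mat = dct_cepstra(energies, p.n_mfcc)
    mat.source_id = clip.source_id
    return mat


def segment_mfcc(
    mat: MFCCMatrix, frames_per_segment: int, label: int, participant_id: str = ""
) -> list[FeatureSegment]:
    """Split into consecutive non-overlapping blocks; the ragged tail is
    dropped. Shorter-than-one-segment input yields an empty list with a
    warning."""
    if frames_per_segment < 1:
        raise ValueError("frames_per_segment must be >= 1")
    pid = participant_id or mat.source_id
    n_segments = mat.n_frames // frames_per_segment
    if n_segments == 0:
        warnings.warn(
            f"clip {pid!r}: {mat.n_frames} frames < one segment "
            f"({frames_per_segment}); no segments produced",
            stacklevel=2,
        )
        return []
    segments = []
    for i in range(n_segments):
        block = mat.coefficients[i * frames_per_segment:(i + 1) * frames_per_segment]
        segments.append(FeatureSegment(features=block.copy(), label=label, participant_id=pid))
    return segments


# ---------------------------------------------------------------------------
# JSON feature file
# ---------------------------------------------------------------------------

def write_feature_json(ds: FeatureDataset, path: str | os.PathLike) -> Path:
    """Serialise a dataset to the JSON feature-file schema.

    Keys: ``extraction_params``, ``label_names``, ``participant_ids``,
    ``labels``, ``mfcc`` (n_segments x frames_per_segment x n_mfcc).
    """
    if not ds.segments:
        raise ValueError("refusing to write an empty dataset")
    if len({seg.features.shape for seg in ds.segments}) > 1:
        raise ValueError("refusing to write mixed segment shapes")
    payload = {
        "extraction_params": ds.extraction_params.to_dict(),
        "label_names": list(ds.label_names),
        "participant_ids": [seg.participant_id for seg in ds.segments],
        "labels": [int(seg.label) for seg in ds.segments],
        "mfcc": [seg.features.tolist() for seg in ds.segments],
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh)
    return path


def read_feature_json(path: str | os.PathLike) -> FeatureDataset:
    """Read and validate a JSON feature file written by
    :func:`write_feature_json`."""
    with open(path) as fh:
        payload = json.load(fh)
    for key in ("extraction_params", "label_names", "participant_ids", "labels", "mfcc"):
        if key not in payload:
            raise ValueError(f"feature file missing key {key!r}")
    label_names = payload["label_names"]
    n_classes = len(label_names)
    labels = payload["labels"]
    if any(not (0 <= int(l) < n_classes) for l in labels):
        raise ValueError("label outside label_names range")
    mfcc = [np.asarray(block, dtype=np.float64) for block in payload["mfcc"]]
    if len({b.shape for b in mfcc}) > 1:
        raise ValueError("inconsistent segment shapes in feature file")
    if not (len(mfcc) == len(labels) == len(payload["participant_ids"])):
        raise ValueError("segment/label/participant count mismatch")
    segments = [
        FeatureSegment(features=b, label=int(l), participant_id=pid)
        for b, l, pid in zip(mfcc, labels, payload["participant_ids"])
    ]
    return FeatureDataset(
        segments=segments,
        label_names=label_names,
        extraction_params=ExtractionParams.from_dict(payload["extraction_params"]),
    )
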