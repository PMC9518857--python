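"""Mono audio clip I/O with exact sample bookkeeping.

WAV files are RIFF PCM, read and written through :mod:`scipy.io.wavfile`.
Samples are held as float64 in ``[-1, 1]``; the header sample rate is always
taken from the file, never assumed. Stereo input is down-mixed by channel
mean. Output is 16-bit PCM.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "AudioClip",
    "ParticipantRecord",
    "read_wav",
    "write_wav",
    "truncate_clip",
    "read_manifest",
    "write_manifest",
]

#: Full-scale divisor per integer PCM dtype.
_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


@dataclass
class AudioClip:
    """A mono amplitude sequence with its sample rate.

    Attributes
    ----------
    samples : numpy.ndarray
        1-D float array of amplitudes in ``[-1, 1]``.
    sample_rate : int
        Samples per second, strictly positive.
    source_id : str
        Opaque participant/file identifier.
    """

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("AudioClip requires a non-empty 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioClip samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        """Clip duration in seconds."""
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class ParticipantRecord:
    """One manifest row: participant id, binary label, clip location."""

    participant_id: str
    label: int
    clip_path: str = ""

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


def read_wav(path: str | os.PathLike) -> AudioClip:
    """Read a PCM WAV file into an :class:`AudioClip`.

    Integer PCM is rescaled to ``[-1, 1]`` by the dtype's full-scale value;
    float payloads pass through unchanged. Multi-channel audio is down-mixed
    by channel mean.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise ValueError(f"{path} is not a readable WAV file: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"{path} contains a zero-length audio stream")
    dtype = np.dtype(data.dtype)
    if dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[dtype]
    elif dtype == np.dtype(np.uint8):
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32/float64 payloads
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioClip(samples=samples, sample_rate=int(rate), source_id=path.stem)


def write_wav(clip: AudioClip, path: str | os.PathLike) -> Path:
    """Write a clip as 16-bit PCM WAV; returns the written path.

    Raises ``ValueError`` if any sample lies outside ``[-1, 1]`` — clipping
    silently would break the read/write round-trip guarantee.
    """
    path = Path(path)
    peak = np.max(np.abs(clip.samples)) if clip.samples.size else 0.0
    if peak > 1.0:
        raise ValueError(f"samples exceed [-1, 1] (peak {peak:.6f}); normalise first")
    pcm = np.clip(np.rint(clip.samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(clip.sample_rate), pcm)
    return path


def truncate_clip(clip: AudioClip, start_s: float, end_s: float) -> AudioClip:
    """Keep samples in ``[start_s, end_s)`` seconds; rate unchanged.

    The returned length is ``round((end_s - start_s) * sample_rate)``.
    """
    if not (0.0 <= start_s < end_s <= clip.duration_s + 1e-12):
        raise ValueError(
            f"invalid bounds [{start_s}, {end_s}] for a {clip.duration_s:.6f}s clip"
        )
    start = int(round(start_s * clip.sample_rate))
    length = int(round((end_s - start_s) * clip.sample_rate))
    stop = min(start + length, clip.samples.size)
    return AudioClip(
        samples=clip.samples[start:stop].copy(),
        sample_rate=clip.sample_rate,
        source_id=clip.source_id,
    )


def read_manifest(path: str | os.PathLike) -> list[ParticipantRecord]:
    """Read a participant manifest CSV (participant_id,label,clip_path)."""
    path = Path(path)
    records: list[ParticipantRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"participant_id", "label", "clip_path"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"manifest {path} must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            pid = row["participant_id"]
            if pid in seen:
                raise ValueError(f"duplicate participant_id {pid!r} in manifest")
            seen.add(pid)
            records.append(
                ParticipantRecord(
                    participant_id=pid,
                    label=int(row["label"]),
                    clip_path=row["clip_path"],
                )
            )
    if not records:
        raise ValueError(f"manifest {path} is empty")
    return records


def write_manifest(records: list[ParticipantRecord], path: str | os.PathLike) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "label", "clip_path"])
        for rec in records:
            writer.writerow([rec.participant_id, rec.label, rec.clip_path])
    return path
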