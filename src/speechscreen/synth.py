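"""Synthetic two-class speech-like cohort generator.

A crude but fully seeded source-filter synthesiser: each utterance is a
string of vowel-like syllables (glottal pulse train shaped by 2-3 formant
resonators) with amplitude-modulated envelopes, interrupted by silent
pauses. The two class profiles differ in syllable rate, pause occurrence
and length, a multiplicative formant shift, and pitch-period jitter —
slowed, pause-heavy speech for the positive class.

No claim of phonetic realism is made; the generator exists so that every
downstream stage (feature extraction, training, evaluation) can be
exercised end to end with a controllable, reproducible signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .audio_io import AudioClip, ParticipantRecord, write_manifest, write_wav

__all__ = [
    "ClassProfile",
    "CohortSpec",
    "CONTROL_PROFILE",
    "POSITIVE_PROFILE",
    "interpolate_profile",
    "generate_utterance",
    "generate_cohort",
]

# Vowel formant templates (Hz): rough /a/, /i/, /u/ with bandwidths.
_VOWELS = (
    ((730, 90), (1090, 110), (2440, 160)),
    ((270, 60), (2290, 100), (3010, 170)),
    ((300, 60), (870, 100), (2240, 160)),
)


@dataclass(frozen=True)
class ClassProfile:
    """Generator parameters for one class of speakers."""

    syllable_rate: float = 4.5      # syllables per second
    pause_rate: float = 6.0         # silent pauses per minute
    pause_length_mean: float = 0.35  # seconds
    formant_shift: float = 1.0      # multiplies formant centre frequencies
    jitter_sd: float = 0.01         # relative pitch-period perturbation

    def __post_init__(self) -> None:
        if min(self.syllable_rate, self.pause_rate, self.pause_length_mean) < 0:
            raise ValueError("rates and lengths must be non-negative")
        if self.formant_shift <= 0:
            raise ValueError("formant_shift must be positive")


CONTROL_PROFILE = ClassProfile(
    syllable_rate=4.5, pause_rate=6.0, pause_length_mean=0.35,
    formant_shift=1.0, jitter_sd=0.01,
)
POSITIVE_PROFILE = ClassProfile(
    syllable_rate=3.2, pause_rate=14.0, pause_length_mean=0.8,
    formant_shift=0.94, jitter_sd=0.08,
)


@dataclass(frozen=True)
class CohortSpec:
    """Shape of a synthetic cohort."""

    n_participants: int = 46
    prevalence: float = 7 / 46
    effect_size: float = 1.0
    clip_duration_s: float = 10.0
    sample_rate: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be in [0, 1]")
        if not (0.0 <= self.effect_size <= 1.0):
            raise ValueError("effect_size must be in [0, 1]")
        if self.clip_duration_s <= 0:
            raise ValueError("clip_duration_s must be positive")


def interpolate_profile(
    control: ClassProfile, positive: ClassProfile, effect_size: float
) -> ClassProfile:
    """Linear interpolation from control (0) to the full positive profile (1)."""
    t = float(effect_size)
    mix = lambda a, b: (1.0 - t) * a + t * b
    return ClassProfile(
        syllable_rate=mix(control.syllable_rate, positive.syllable_rate),
        pause_rate=mix(control.pause_rate, positive.pause_rate),
        pause_length_mean=mix(control.pause_length_mean, positive.pause_length_mean),
        formant_shift=mix(control.formant_shift, positive.formant_shift),
        jitter_sd=mix(control.jitter_sd, positive.jitter_sd),
    )


def _resonator_coeffs(freq: float, bandwidth: float, sr: float):
    # two-pole resonator at freq with the given -3 dB bandwidth
    r = np.exp(-np.pi * bandwidth / sr)
    theta = 2.0 * np.pi * freq / sr
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    b = [1.0 - r]
    return b, a


def _synth_syllable(
    rng: np.random.Generator,
    n_samples: int,
    sr: float,
    f0: float,
    formants,
    jitter_sd: float,
) -> np.ndarray:
    """One vowel-like syllable: jittered pulse train through resonators."""
    src = np.zeros(n_samples)
    t = 0.0
    while t < n_samples:
        src[int(t)] = 1.0 + 0.1 * rng.standard_normal()  # mild shimmer
        period = sr / f0 * (1.0 + jitter_sd * rng.standard_normal())
        t += max(period, 2.0)
    out = src
    for freq, bw in formants:
        if freq < 0.45 * sr:  # keep resonators safely below Nyquist
            b, a = _resonator_coeffs(freq, bw, sr)
            out = lfilter(b, a, out)
    # raised-sine envelope with a floor: syllables touch but never go silent
    env = 0.15 + 0.85 * np.sin(np.pi * np.arange(n_samples) / n_samples)
    return out * env


def generate_utterance(
    profile: ClassProfile,
    duration_s: float,
    sample_rate: int = 44100,
    seed: int | np.random.Generator = 0,
    f0: float = 115.0,
    vocal_tract_factor: float = 1.0,
    source_id: str = "synthetic",
) -> AudioClip:
    """Synthesise one utterance; bit-deterministic given the seed.

    Syllables are drawn from three vowel templates, scaled by the profile's
    formant shift and the speaker's vocal-tract factor. After each syllable
    a silent pause of exponential length is inserted with probability
    ``pause_rate / 60 / syllable_rate`` (pauses per syllable).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sr = float(sample_rate)
    n_total = int(round(duration_s * sr))
    syll_len = max(int(round(sr / profile.syllable_rate)), 32)
    p_pause = (
        min(profile.pause_rate / 60.0 / profile.syllable_rate, 1.0)
        if profile.syllable_rate > 0 else 0.0
    )

    pieces: list[np.ndarray] = []
    produced = 0
    while produced < n_total:
        vowel = _VOWELS[rng.integers(len(_VOWELS))]
        formants = [
            (freq * profile.formant_shift * vocal_tract_factor, bw)
            for freq, bw in vowel
        ]
        syl_f0 = f0 * (1.0 + 0.05 * rng.standard_normal())
        syl = _synth_syllable(rng, syll_len, sr, syl_f0, formants, profile.jitter_sd)
        pieces.append(syl)
        produced += syll_len
        if p_pause > 0 and rng.random() < p_pause:
            pause_len = int(round(rng.exponential(profile.pause_length_mean) * sr))
            if pause_len > 0:
                pieces.append(np.zeros(pause_len))
                produced += pause_len
    samples = np.concatenate(pieces)[:n_total]
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples = 0.9 * samples / peak
    return AudioClip(samples=samples, sample_rate=sample_rate, source_id=source_id)


def generate_cohort(
    spec: CohortSpec,
    out_dir: str | os.PathLike,
    control: ClassProfile = CONTROL_PROFILE,
    positive: ClassProfile = POSITIVE_PROFILE,
) -> tuple[list[ParticipantRecord], Path]:
    """Generate a labelled cohort of WAV files plus its manifest CSV.

    ``round(prevalence * n)`` participants are positive; each speaker gets a
    random vocal-tract baseline and pitch so speakers differ within class.
    Returns (records, manifest path). Fully deterministic given
    ``spec.seed``.
    """
    n_pos = int(round(spec.prevalence * spec.n_participants))
    if n_pos == 0 or n_pos == spec.n_participants:
        raise ValueError(
            f"prevalence {spec.prevalence} leaves a class empty for "
            f"n={spec.n_participants}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(spec.n_participants, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    positive_profile = interpolate_profile(control, positive, spec.effect_size)
    records: list[ParticipantRecord] = []
    for i, label in enumerate(labels):
        pid = f"P{i:03d}"
        profile = positive_profile if label == 1 else control
        clip = generate_utterance(
            profile,
            spec.clip_duration_s,
            spec.sample_rate,
            seed=np.random.default_rng(rng.integers(2**63)),
            f0=float(rng.uniform(105.0, 130.0)),
            vocal_tract_factor=float(rng.uniform(0.98, 1.02)),
            source_id=pid,
        )
        path = out_dir / f"{pid}.wav"
        write_wav(clip, path)
        records.append(ParticipantRecord(pid, int(label), str(path)))
    manifest_path = write_manifest(records, out_dir / "manifest.csv")
    return records, manifest_path
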