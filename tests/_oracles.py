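"""Independent reference implementations used only to check the package.

These deliberately take different code paths from the package: scipy
windows/DCT, loop-built filter bank, pairwise-count AUROC, exhaustive
search. They must never import the modules they are used to verify beyond
plain numpy/scipy.
"""

from __future__ import annotations

import numpy as np
import scipy.fft
import scipy.signal


def reference_mfcc(
    x: np.ndarray,
    sr: float,
    n_mfcc: int = 13,
    n_fft: int = 2048,
    hop: int = 512,
    alpha: float = 0.97,
    n_mels: int = 128,
    fmin: float = 0.0,
    fmax: float | None = None,
    rel_floor: float = 1e-10,
) -> np.ndarray:
    """MFCC under the identical dialect, built from scipy primitives."""
    fmax = sr / 2.0 if fmax is None else fmax
    y = np.append(x[0], x[1:] - alpha * x[:-1])
    L = len(y)
    n_frames = 1 if L <= n_fft else 1 + int(np.ceil((L - n_fft) / hop))
    y = np.pad(y, (0, n_fft + (n_frames - 1) * hop - L))
    win = scipy.signal.get_window("hann", n_fft, fftbins=True)
    frames = np.stack([y[i * hop:i * hop + n_fft] * win for i in range(n_frames)])
    P = np.abs(scipy.fft.rfft(frames, axis=1)) ** 2

    C = 1000.0 / np.log10(1.0 + 1000.0 / 700.0)
    mel = lambda f: C * np.log10(1.0 + np.asarray(f) / 700.0)
    imel = lambda m: 700.0 * (10.0 ** (np.asarray(m) / C) - 1.0)
    pts = imel(np.linspace(mel(fmin), mel(fmax), n_mels + 2))
    freqs = np.arange(n_fft // 2 + 1) * sr / n_fft
    W = np.zeros((n_mels, freqs.size))
    for i in range(n_mels):
        lo, cen, hi = pts[i], pts[i + 1], pts[i + 2]
        W[i] = np.clip(
            np.minimum((freqs - lo) / (cen - lo), (hi - freqs) / (hi - cen)), 0.0, None
        )
    E = P @ W.T
    peak = E.max()
    logE = np.log10(np.maximum(E, rel_floor * peak if peak > 0 else rel_floor))
    return scipy.fft.dct(logE, type=2, norm="ortho", axis=1)[:, :n_mfcc]


def rank_sum_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise probability-of-correct-ranking estimator, half credit for ties."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * equal) / (len(pos) * len(neg))


def brute_force_minimum(space, fitness) -> float:
    """Exhaustive-search minimum fitness over every assignment in the space."""
    return min(fitness(a) for a in space.all_assignments())


def count_onsets(samples: np.ndarray, sample_rate: float) -> int:
    """Syllable-onset proxy: peaks of the smoothed short-time energy envelope."""
    win = int(0.025 * sample_rate)
    energy = np.convolve(samples**2, np.ones(win) / win, mode="same")
    smooth = int(0.04 * sample_rate)
    env = np.convolve(energy, np.ones(smooth) / smooth, mode="same")
    peaks, _ = scipy.signal.find_peaks(
        env, distance=int(0.09 * sample_rate), prominence=0.1 * env.max()
    )
    return len(peaks)
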