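"""Welch power-spectral-density estimation and band-power features.

The estimator follows the classical segment-average construction: split the
signal into K overlapping length-M segments offset by S samples, window each
segment, take the squared-magnitude DFT normalised by the window energy
W = sum_m w[m]^2 (the modified periodogram), and average the K periodograms.
The one-sided frequency grid is v = i/M for i = 0..M/2, mapped to Hz by
multiplying by the sampling rate; DC and Nyquist bins are not doubled and no
1/fs density scaling is applied, so for a rectangular window with S = M the
average of the two-sided periodogram equals the mean squared amplitude of
the analysed samples (Parseval).

A trial's 22-dimensional feature vector is the log mean PSD in fixed
frequency bands per channel: 8 bands each for T3 and T4 spanning 0.5-45 Hz
and 6 bands for FP1 spanning 0.5-30 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .synthetic import CHANNELS, Trial

N_FEATURES = 22
LOG_EPS = 1e-12

#: default per-channel band edges (Hz); 8 + 8 + 6 = 22 features
DEFAULT_BAND_PLAN: dict[str, tuple[float, ...]] = {
    "T3": (0.5, 4.0, 8.0, 13.0, 18.0, 24.0, 30.0, 38.0, 45.0),
    "T4": (0.5, 4.0, 8.0, 13.0, 18.0, 24.0, 30.0, 38.0, 45.0),
    "FP1": (0.5, 4.0, 8.0, 13.0, 20.0, 25.0, 30.0),
}


@dataclass(frozen=True)
class WelchConfig:
    """Segmentation and taper parameters of the Welch estimator.

    M is the segment (block) length in samples, S the shift between the
    starts of successive segments; K = floor((N - M)/S) + 1 segments fit in
    a length-N signal, trailing samples not covered by a full segment are
    dropped.
    """

    M: int = 256
    S: int = 128
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("segment length M must be >= 1")
        if not 1 <= self.S <= self.M:
            raise ValueError("shift S must satisfy 1 <= S <= M")

    def n_segments(self, n: int) -> int:
        if n < self.M:
            raise ValueError(f"signal length {n} shorter than segment length {self.M}")
        return (n - self.M) // self.S + 1

    def taper(self) -> np.ndarray:
        if self.window in ("rectangular", "boxcar"):
            return np.ones(self.M)
        # periodic=False: symmetric taper, the classical spectral-analysis choice
        return get_window(self.window, self.M, fftbins=False)


@dataclass(frozen=True)
class SpectrumEstimate:
    """One-sided Welch PSD per channel."""

    freqs: np.ndarray  # Hz, strictly increasing, [0, fs/2]
    psd: np.ndarray  # (channels x freqs) or (freqs,), nonnegative
    config: WelchConfig
    fs: float

    def band_power(self, lo: float, hi: float) -> np.ndarray:
        """Mean PSD over freqs in [lo, hi)."""
        if lo < 0 or hi > self.fs / 2 + 1e-9:
            raise ValueError(f"band [{lo}, {hi}) outside [0, {self.fs / 2}] Hz")
        mask = (self.freqs >= lo) & (self.freqs < hi)
        if not mask.any():
            raise ValueError(f"band [{lo}, {hi}) Hz contains no frequency bins")
        return np.atleast_2d(self.psd)[:, mask].mean(axis=-1)


def segment(x: np.ndarray, cfg: WelchConfig) -> np.ndarray:
    """Split a 1-D signal into K overlapping segments (rows) of length M.

    Segment k (0-based) covers samples [k*S, k*S + M).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("segment() expects a 1-D signal")
    k = cfg.n_segments(x.size)
    starts = np.arange(k) * cfg.S
    return np.stack([x[s : s + cfg.M] for s in starts])


def modified_periodogram(seg: np.ndarray, window: np.ndarray) -> np.ndarray:
    """|DFT(w * x)|^2 / W on the one-sided grid, W = sum(w^2).

    Accepts a single segment or a (K x M) stack; returns M//2 + 1 bins.
    """
    seg = np.asarray(seg, dtype=float)
    window = np.asarray(window, dtype=float)
    if seg.shape[-1] != window.size:
        raise ValueError(
            f"segment length {seg.shape[-1]} does not match window length {window.size}"
        )
    w_norm = float(np.sum(window**2))
    spec = np.fft.rfft(seg * window, axis=-1)
    return (spec.real**2 + spec.imag**2) / w_norm


def welch(x: np.ndarray, cfg: WelchConfig, fs: float) -> SpectrumEstimate:
    """Welch PSD of a 1-D signal or a (channels x time) array."""
    x = np.asarray(x, dtype=float)
    window = cfg.taper()
    if x.ndim == 1:
        psd = modified_periodogram(segment(x, cfg), window).mean(axis=0)
    elif x.ndim == 2:
        psd = np.stack(
            [modified_periodogram(segment(row, cfg), window).mean(axis=0) for row in x]
        )
    else:
        raise ValueError("welch() expects a 1-D or 2-D array")
    freqs = np.arange(cfg.M // 2 + 1) / cfg.M * fs
    return SpectrumEstimate(freqs=freqs, psd=psd, config=cfg, fs=fs)


@dataclass(frozen=True)
class FeatureVector:
    """22 log band-power features plus trial metadata."""

    values: np.ndarray
    subject_id: str
    label: str
    mode: str
    trial_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size != N_FEATURES or not np.all(np.isfinite(v)):
            raise ValueError(f"feature vector must hold {N_FEATURES} finite values")


def feature_names(band_plan: dict[str, tuple[float, ...]] | None = None) -> list[str]:
    plan = band_plan or DEFAULT_BAND_PLAN
    names = []
    for ch in CHANNELS:
        edges = plan[ch]
        names += [f"{ch}_{lo:g}-{hi:g}Hz" for lo, hi in zip(edges[:-1], edges[1:])]
    return names


def extract_features(
    trial: Trial,
    cfg: WelchConfig = WelchConfig(),
    band_plan: dict[str, tuple[float, ...]] | None = None,
) -> FeatureVector:
    """Condense one (preprocessed) trial into its 22-dim feature vector.

    Features are log(mean band PSD + eps), channel-major in the order
    T3, T4, FP1, bands low to high within each channel.
    """
    plan = band_plan or DEFAULT_BAND_PLAN
    est = welch(trial.samples, cfg, trial.fs)
    values = []
    for ci, ch in enumerate(CHANNELS):
        edges = plan[ch]
        for lo, hi in zip(edges[:-1], edges[1:]):
            values.append(np.log(est.band_power(lo, hi)[ci] + LOG_EPS))
    values = np.asarray(values)
    if values.size != N_FEATURES:
        raise ValueError(
            f"band plan yields {values.size} features; the contract is {N_FEATURES}"
        )
    return FeatureVector(
        values=values,
        subject_id=trial.subject_id,
        label=trial.label,
        mode=trial.mode,
        trial_index=trial.trial_index,
    )


def features_to_frame(feature_vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into the tabular form the model consumes."""
    rows = []
    for fv in feature_vectors:
        row = {
            "subject_id": fv.subject_id,
            "label": fv.label,
            "mode": fv.mode,
            "trial_index": fv.trial_index,
        }
        row.update({f"f{i + 1}": v for i, v in enumerate(fv.values)})
        rows.append(row)
    return pd.DataFrame(rows)
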