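"""Mains-interference removal.

The only preprocessing the pipeline applies to raw trials is a narrow notch
filter at the mains frequency (50 Hz), implemented as a second-order IIR
notch run forward-backward per channel so the output is zero-phase and keeps
the trial's exact sample count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic import Trial


@dataclass(frozen=True)
class NotchSpec:
    """Notch filter parameters.

    quality_factor Q sets the stop-band width: -3 dB bandwidth = f0 / Q.
    """

    centre_freq: float = 50.0
    quality_factor: float = 30.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.centre_freq <= 0:
            raise ValueError("centre_freq must be positive")
        if self.quality_factor <= 0:
            raise ValueError("quality_factor must be positive")


def notch_filter_array(x: np.ndarray, fs: float, spec: NotchSpec = NotchSpec()) -> np.ndarray:
    """Apply the notch to a 1-D signal or (channels x time) array."""
    if fs <= 2.0 * spec.centre_freq:
        raise ValueError(
            f"sampling rate {fs:g} Hz too low to notch at {spec.centre_freq:g} Hz "
            f"(needs fs > {2 * spec.centre_freq:g} Hz)"
        )
    b, a = signal.iirnotch(spec.centre_freq, spec.quality_factor, fs=fs)
    if spec.zero_phase:
        return signal.filtfilt(b, a, x, axis=-1)
    return signal.lfilter(b, a, x, axis=-1)


def notch_filter(trial: Trial, spec: NotchSpec = NotchSpec()) -> Trial:
    """Remove the mains line from a trial; shape and metadata are unchanged."""
    return trial.with_samples(notch_filter_array(trial.samples, trial.fs, spec))
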