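"""Raw-signal conditioning: epoching on triggers, trial averaging, baseline
detrending, and zero-phase band-limited resampling."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import ValidationError
from .geometry import ElectrodeGrid, EvokedPotential

log = logging.getLogger(__name__)

#: Default low-pass filter order.  The filter is applied forward-backward
#: (zero phase), so the effective magnitude response is squared; order 8 is
#: the default so that content 20 % above the cut-off is attenuated by more
#: than 20 dB after the bidirectional pass.
DEFAULT_FILTER_ORDER = 8


@dataclass
class TrialSet:
    """Stimulus-locked signal epochs: trials x channels x samples, mV."""

    grid: ElectrodeGrid
    trials: np.ndarray
    pre: float  # ms before stimulus
    post: float  # ms after stimulus
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 3:
            raise ValidationError("trials must be a 3-D (trials, channels, samples) array")
        if self.pre <= 0 or self.post <= 0:
            raise ValidationError("epoch window must cover t = 0 (pre, post > 0)")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample instants in ms relative to the stimulus."""
        dt = 1000.0 / self.sampling_rate
        pre_s = int(round(self.pre / dt))
        n = self.trials.shape[2]
        return (np.arange(n) - pre_s) * dt


def extract_epochs(
    raw: np.ndarray,
    sampling_rate: float,
    triggers,
    pre: float,
    post: float,
    grid: ElectrodeGrid | None = None,
) -> TrialSet:
    """Cut one epoch per trigger from a channels x samples recording.

    ``triggers`` are stimulus times in ms from recording start.  Epochs span
    ``pre`` ms before to ``post`` ms after each trigger, inclusive of both
    endpoints.  Triggers whose window exceeds the recording are dropped and
    counted in a log message; zero usable triggers is an error.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValidationError("raw must be a 2-D channels x samples array")
    if pre <= 0 or post <= 0:
        raise ValidationError("pre and post must be > 0")
    dt = 1000.0 / sampling_rate
    pre_s = int(round(pre / dt))
    post_s = int(round(post / dt))
    n_samples = raw.shape[1]
    epochs, dropped = [], 0
    for trig in triggers:
        i0 = int(round(trig / dt))
        lo, hi = i0 - pre_s, i0 + post_s
        if lo < 0 or hi >= n_samples:
            dropped += 1
            continue
        epochs.append(raw[:, lo : hi + 1])
    if dropped:
        log.info("dropped %d trigger(s) whose window exceeds the recording", dropped)
    if not epochs:
        raise ValidationError("no usable triggers inside the recording")
    if grid is None:
        grid = ElectrodeGrid(
            channel_ids=[f"ch{i}" for i in range(raw.shape[0])],
            positions=np.column_stack(
                [np.zeros(raw.shape[0]), np.zeros(raw.shape[0]), np.arange(raw.shape[0], dtype=float)]
            ),
            broken=np.zeros(raw.shape[0], dtype=bool),
        )
    return TrialSet(
        grid=grid,
        trials=np.stack(epochs),
        pre=pre,
        post=post,
        sampling_rate=sampling_rate,
    )


def detrend_baseline(ep: EvokedPotential) -> EvokedPotential:
    """Subtract each channel's mean over the pre-stimulus interval [-pre, 0).

    Idempotent: the baseline of an already-detrended EP is zero.
    """
    base = ep.times < 0
    if not np.any(base):
        return ep
    values = ep.values - ep.values[:, base].mean(axis=1, keepdims=True)
    return EvokedPotential(
        grid=ep.grid, times=ep.times, values=values, sampling_rate=ep.sampling_rate
    )


def average_and_detrend(trials: TrialSet) -> EvokedPotential:
    """Mean across trials, then per-channel baseline subtraction."""
    mean = trials.trials.mean(axis=0)
    ep = EvokedPotential(
        grid=trials.grid,
        times=trials.times,
        values=mean,
        sampling_rate=trials.sampling_rate,
    )
    return detrend_baseline(ep)


def resample_band(
    ep: EvokedPotential,
    f_max: float,
    f_s: float,
    order: int = DEFAULT_FILTER_ORDER,
) -> EvokedPotential:
    """Zero-phase low-pass at ``f_max`` then resample to ``f_s``.

    The filter is a Butterworth of the given order applied forward-backward
    (no latency shift).  The new time axis is anchored so that a sample
    falls exactly at t = 0.
    """
    if f_s > ep.sampling_rate * (1.0 + 1e-9):
        raise ValidationError(
            f"target rate {f_s} Hz exceeds original rate {ep.sampling_rate} Hz"
        )
    if f_max >= f_s / 2:
        raise ValidationError(
            f"f_max={f_max} Hz must be below the target Nyquist {f_s / 2} Hz"
        )
    sos = signal.butter(order, f_max, btype="low", fs=ep.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, ep.values, axis=1)
    new_dt = 1000.0 / f_s
    # grid of multiples of new_dt inside the original span, including t=0
    k_lo = int(np.ceil(ep.times[0] / new_dt - 1e-9))
    k_hi = int(np.floor(ep.times[-1] / new_dt + 1e-9))
    new_times = np.arange(k_lo, k_hi + 1) * new_dt
    new_values = np.empty((ep.values.shape[0], new_times.size))
    for c in range(ep.values.shape[0]):
        new_values[c] = np.interp(new_times, ep.times, filtered[c])
    return EvokedPotential(
        grid=ep.grid, times=new_times, values=new_values, sampling_rate=f_s
    )
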