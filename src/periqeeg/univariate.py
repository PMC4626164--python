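"""Univariate channel measures: absolute slope and forbidden ordinal patterns.

Absolute slope S
    The mean absolute first difference |x(t+dt) - x(t)| / dt within a
    moving window (1024 samples, i.e. 2 s at 512 Hz).  Up to a scale
    factor this is the classical "line length" feature: it is large both
    for slow high-amplitude and for fast low-amplitude epileptiform
    activity.

Forbidden ordinal patterns N
    Each embedding vector of d = 5 delayed samples (delay tau = 1) is
    encoded as the permutation of its values' rank order; ties are broken
    by time of appearance.  N is d! minus the number of distinct patterns
    observed among the T - (d-1)*tau maximally overlapping vectors of a
    window.  Deterministic dynamics forbid many patterns (N large); for
    stochastic signals nearly all patterns occur (N near 0).

Both series are normalized channel-wise by the standard deviation of the
window values falling inside the pre-ictal reference period.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import EpochPlan
from .recording import Recording

__all__ = [
    "WindowGrid",
    "OrdinalConfig",
    "MeasureSeries",
    "absolute_slope_series",
    "ordinal_pattern_encode",
    "ordinal_pattern_codes",
    "forbidden_pattern_count",
    "forbidden_pattern_series",
    "normalize_by_reference",
]


@dataclass(frozen=True)
class WindowGrid:
    """Right-aligned moving-window grid; a window's timestamp is its final sample."""

    window_len: int
    step: int
    starts: np.ndarray
    sampling_rate: float

    @classmethod
    def over(cls, n_samples: int, window_len: int, step: int, sampling_rate: float) -> "WindowGrid":
        if window_len > n_samples:
            raise ValueError("window does not fit in the recording")
        n_win = (n_samples - window_len) // step + 1
        starts = np.arange(n_win) * step
        return cls(window_len=window_len, step=step, starts=starts, sampling_rate=sampling_rate)

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def timestamps(self) -> np.ndarray:
        """End sample of each window."""
        return self.starts + self.window_len

    @property
    def times_s(self) -> np.ndarray:
        return self.timestamps / self.sampling_rate

    def windows_inside(self, interval: tuple[int, int]) -> np.ndarray:
        """Boolean selector of windows lying wholly inside [start, stop)."""
        start, stop = interval
        return (self.starts >= start) & (self.timestamps <= stop)


@dataclass(frozen=True)
class OrdinalConfig:
    """Ordinal-pattern parameters: order d, delay tau (samples) and window length T."""

    d: int = 5
    tau: int = 1
    window_len: int = 1024

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("pattern order d must be > 1")
        if self.tau < 1:
            raise ValueError("delay tau must be >= 1")
        if self.window_len - (self.d - 1) * self.tau < 1:
            raise ValueError("window too short: need T - (d-1)*tau >= 1")

    @property
    def span(self) -> int:
        return (self.d - 1) * self.tau + 1

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.d)


@dataclass
class MeasureSeries:
    """Channel x time-step matrix of one qEEG measure on a window grid."""

    measure_id: str
    values: np.ndarray
    grid: WindowGrid
    channel_labels: tuple[str, ...] = ()
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.n_windows:
            raise ValueError("values must be (n_channels, n_windows)")
        if not self.channel_labels:
            self.channel_labels = tuple(f"CH{i:03d}" for i in range(self.values.shape[0]))

    @property
    def times_s(self) -> np.ndarray:
        return self.grid.times_s

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.channel_labels), columns=self.times_s)


def absolute_slope_series(recording: Recording, grid: WindowGrid) -> MeasureSeries:
    """Mean absolute signal slope per channel per window (unnormalized)."""
    dt = 1.0 / recording.sampling_rate
    absdiff = np.abs(np.diff(recording.signals, axis=1)) / dt
    # prefix sums give O(1) window means over the window's successive sample pairs
    csum = np.concatenate(
        [np.zeros((recording.n_channels, 1)), np.cumsum(absdiff, axis=1)], axis=1
    )
    starts = grid.starts
    stops = grid.timestamps - 1  # T samples -> T-1 successive pairs
    vals = (csum[:, stops] - csum[:, starts]) / (grid.window_len - 1)
    return MeasureSeries(
        measure_id="S", values=vals, grid=grid, channel_labels=recording.channel_labels
    )


def ordinal_pattern_encode(vector: np.ndarray) -> tuple[int, ...]:
    """Encode a d-sample embedding vector (oldest first) as an ordinal pattern.

    The returned permutation pi lists the delay multipliers k of
    x(t - k*tau*dt) sorted ascending by value; equal values are ordered by
    their time of appearance in the vector.  E.g. the vector
    (1.26, 6.38, 0.63, 1.26, 4.92) encodes to (2, 4, 1, 0, 3).
    """
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1:
        raise ValueError("embedding vector must be 1-D")
    if not np.all(np.isfinite(v)):
        raise ValueError("embedding vector contains non-finite values")
    d = len(v)
    order = np.argsort(v, kind="stable")  # positions ascending by value, earlier-first ties
    return tuple(int(d - 1 - pos) for pos in order)


def ordinal_pattern_codes(x: np.ndarray, config: OrdinalConfig) -> np.ndarray:
    """Integer pattern code for every maximally overlapping embedding vector of a signal.

    Codes are a bijective base-d encoding of the pattern permutation; only
    identity of codes matters downstream.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < config.span:
        raise ValueError("signal shorter than the embedding span")
    emb = sliding_window_view(x, config.span)[:, :: config.tau]  # oldest first
    order = np.argsort(emb, axis=1, kind="stable")
    pi = (config.d - 1) - order
    radix = config.d ** np.arange(config.d)
    return pi @ radix


def forbidden_pattern_count(window: np.ndarray, config: OrdinalConfig = OrdinalConfig()) -> int:
    """Number of ordinal patterns never observed in one window: N = d! - #distinct."""
    window = np.asarray(window, dtype=float)
    if len(window) != config.window_len:
        raise ValueError(
            f"window has {len(window)} samples, expected T = {config.window_len}"
        )
    codes = ordinal_pattern_codes(window, config)
    return config.n_patterns - len(np.unique(codes))


def forbidden_pattern_series(
    recording: Recording, grid: WindowGrid, config: OrdinalConfig | None = None
) -> MeasureSeries:
    """Forbidden-pattern count per channel per window (unnormalized)."""
    if config is None:
        config = OrdinalConfig(window_len=grid.window_len)
    if config.window_len != grid.window_len:
        raise ValueError("ordinal window length must match the grid window length")
    n_ch = recording.n_channels
    vals = np.empty((n_ch, grid.n_windows))
    n_embed = grid.window_len - (config.d - 1) * config.tau
    for ch in range(n_ch):
        codes = ordinal_pattern_codes(recording.signals[ch], config)
        for w, start in enumerate(grid.starts):
            window_codes = codes[start : start + n_embed]
            vals[ch, w] = config.n_patterns - len(np.unique(window_codes))
    return MeasureSeries(
        measure_id="N", values=vals, grid=grid, channel_labels=recording.channel_labels
    )


def normalize_by_reference(series: MeasureSeries, plan: EpochPlan) -> MeasureSeries:
    """Divide each channel by the SD of its values inside the pre-ictal reference window.

    Channels with zero reference variability cannot be normalized; their
    values become NaN and a warning is issued.
    """
    sel = series.grid.windows_inside(plan.reference)
    if int(sel.sum()) < 2:
        raise ValueError("need at least 2 window values inside the reference period")
    ref = series.values[:, sel]
    sd = np.std(ref, axis=1, ddof=1)
    degenerate = ~(sd > 0) | ~np.isfinite(sd)
    if np.any(degenerate):
        bad = [series.channel_labels[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"zero reference-period variability; channels set to missing: {bad}",
            RuntimeWarning,
            stacklevel=2,
        )
    sd_safe = np.where(degenerate, 1.0, sd)
    vals = series.values / sd_safe[:, None]
    vals[degenerate, :] = np.nan
    return MeasureSeries(
        measure_id=series.measure_id,
        values=vals,
        grid=series.grid,
        channel_labels=series.channel_labels,
        normalized=True,
    )
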