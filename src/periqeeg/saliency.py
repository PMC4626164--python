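"""Data-driven saliency: channels above the upper Tukey fence per time step.

At each time step the cross-channel distribution of a measure defines the
quartiles Q1, Q3 and IQR = Q3 - Q1; channels with values strictly larger
than Q3 + w*IQR (whisker w = 1.5, the standard box-plot outlier choice)
are "salient".  The fence is recomputed independently on every step, so no
assumption on the shape (or stationarity) of the distribution is needed,
and by construction at most a quarter of the channels can be salient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .univariate import MeasureSeries

__all__ = ["SaliencyConfig", "SaliencyMask", "salient_channels", "saliency_series"]


@dataclass(frozen=True)
class SaliencyConfig:
    """Upper Tukey-fence parameters.

    ``quartile_method`` is the interpolation convention handed to
    ``numpy.nanpercentile``; fence membership near the boundary can depend
    on it, hence it is exposed.
    """

    whisker: float = 1.5
    quartile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.whisker <= 0:
            raise ValueError("whisker must be positive")


@dataclass
class SaliencyMask:
    """Boolean channel x time-step saliency matrix with per-step counts."""

    mask: np.ndarray
    times_s: np.ndarray
    channel_labels: tuple[str, ...] = ()

    @property
    def n_salient(self) -> np.ndarray:
        return self.mask.sum(axis=0)


def salient_channels(values: np.ndarray, config: SaliencyConfig | None = None) -> np.ndarray:
    """Boolean saliency vector for one time step's cross-channel values.

    Missing (NaN) values are excluded from the quartiles and never salient;
    fewer than 4 non-missing values yield an all-false result with a warning.
    """
    if config is None:
        config = SaliencyConfig()
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        warnings.warn(
            "fewer than 4 non-missing values; no saliency determined",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros_like(v, dtype=bool)
    q1, q3 = np.percentile(v[finite], [25.0, 75.0], method=config.quartile_method)
    fence = q3 + config.whisker * (q3 - q1)
    out = np.zeros_like(v, dtype=bool)
    out[finite] = v[finite] > fence
    return out


def saliency_series(series: MeasureSeries, config: SaliencyConfig | None = None) -> SaliencyMask:
    """Apply the Tukey fence independently on every time step of a measure series."""
    if config is None:
        config = SaliencyConfig()
    vals = series.values
    n_ch, n_steps = vals.shape
    mask = np.zeros((n_ch, n_steps), dtype=bool)
    finite = np.isfinite(vals)
    counts = finite.sum(axis=0)
    ok = counts >= 4
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} time steps have fewer than 4 non-missing values; "
            "no saliency determined there",
            RuntimeWarning,
            stacklevel=2,
        )
    if ok.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            q1 = np.nanpercentile(vals[:, ok], 25.0, axis=0, method=config.quartile_method)
            q3 = np.nanpercentile(vals[:, ok], 75.0, axis=0, method=config.quartile_method)
        fence = q3 + config.whisker * (q3 - q1)
        sub = vals[:, ok]
        mask[:, ok] = np.where(np.isfinite(sub), sub > fence[None, :], False)
    return SaliencyMask(
        mask=mask, times_s=series.times_s, channel_labels=series.channel_labels
    )
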