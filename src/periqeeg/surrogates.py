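"""Iterated amplitude adjusted Fourier transform (IAAFT) surrogates.

Surrogate time series implement the linear-stochastic null hypotheses used
to correct the interrelation measures:

* Univariate surrogates randomize Fourier phases independently per channel
  while iteratively restoring the original amplitude spectrum and the
  exact amplitude distribution.  They realize the null of independent
  stationary linear auto-correlated Gaussian processes observed through
  invertible (possibly nonlinear) measurement functions.
* Multivariate surrogates (Schreiber-Schmitz variant) add a single random
  phase vector to *all* channels, so relative Fourier phases - and with
  them the linear cross-correlation structure - are preserved, and then
  iterate per-channel amplitude/spectrum adjustment jointly with a phase
  coherence restoration step.  They realize the null of one stationary
  multivariate linear auto- and cross-correlated Gaussian process.

Each iteration alternates (a) replacing Fourier amplitudes with the
original's and (b) rank-remapping onto the original sorted values; the
iteration stops when the rank permutation is a fixed point or after
``max_iterations``.  The amplitude distribution is therefore preserved as
an exact multiset in every returned surrogate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["SurrogateConfig", "iaaft_univariate", "iaaft_multivariate"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurrogateConfig:
    """IAAFT parameters: ensemble size, iteration cap and convergence tolerance."""

    n_surr: int = 10
    max_iterations: int = 100
    convergence_tol: float = 2e-3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_surr < 1:
            raise ValueError("n_surr must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def _rank_remap(x: np.ndarray, sorted_target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remap each row of x onto the target value multiset, preserving rank order."""
    order = np.argsort(x, axis=-1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(x.shape[-1])[None, :], axis=-1)
    remapped = np.take_along_axis(np.broadcast_to(sorted_target, x.shape), ranks, axis=-1)
    return remapped, ranks


def iaaft_univariate(
    window: np.ndarray,
    config: SurrogateConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate ``n_surr`` univariate IAAFT surrogates of one signal window.

    Returns an array of shape (n_surr, T).  Sorted surrogate values equal
    the sorted original values exactly; the periodogram matches the
    original approximately (non-convergence within ``max_iterations``
    returns the best iterate and logs a debug message).
    """
    if config is None:
        config = SurrogateConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = np.asarray(window, dtype=float)
    if x.ndim != 1:
        raise ValueError("window must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite values")
    T = len(x)
    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    target_pow = target_amp**2
    pow_norm = np.linalg.norm(target_pow) or 1.0

    # independent random initialization per surrogate
    surr = np.stack([rng.permutation(x) for _ in range(config.n_surr)])
    prev_ranks = np.full((config.n_surr, T), -1, dtype=int)
    active = np.ones(config.n_surr, dtype=bool)
    for it in range(config.max_iterations):
        spec = np.fft.rfft(surr[active], axis=-1)
        phase = np.angle(spec)
        surr_spec = target_amp[None, :] * np.exp(1j * phase)
        shaped = np.fft.irfft(surr_spec, n=T, axis=-1)
        remapped, ranks = _rank_remap(shaped, sorted_x)
        surr[active] = remapped
        # stop a surrogate when its rank permutation is a fixed point or its
        # periodogram is within tolerance of the original's
        unchanged = np.all(ranks == prev_ranks[active], axis=-1)
        if it > 0:
            pow_err = (
                np.linalg.norm(np.abs(spec) ** 2 - target_pow[None, :], axis=-1) / pow_norm
            )
            unchanged |= pow_err < config.convergence_tol
        prev_ranks[active] = ranks
        idx_active = np.flatnonzero(active)
        active[idx_active[unchanged]] = False
        if not active.any():
            break
    if active.any():
        logger.debug(
            "IAAFT: %d/%d surrogates not rank-converged after %d iterations",
            int(active.sum()),
            config.n_surr,
            config.max_iterations,
        )
    return surr


def iaaft_multivariate(
    windows: np.ndarray,
    config: SurrogateConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate ``n_surr`` multivariate IAAFT surrogate matrices.

    Parameters
    ----------
    windows : ndarray, shape (n_channels, T)
        One analysis window of all channels.

    Returns
    -------
    ndarray, shape (n_surr, n_channels, T).  Per-channel sorted values
    equal the originals exactly; relative Fourier phases between channels
    (the cross-spectrum) are approximately preserved.
    """
    if config is None:
        config = SurrogateConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = np.asarray(windows, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("windows must be (n_channels >= 2, T)")
    n_ch, T = X.shape
    nf = T // 2 + 1
    spec0 = np.fft.rfft(X, axis=-1)
    amp0 = np.abs(spec0)
    phase0 = np.angle(spec0)
    sorted_x = np.sort(X, axis=-1)

    # one common random phase shift per surrogate and frequency preserves
    # the relative phases between channels; DC (and Nyquist for even T)
    # must stay real
    psi = rng.uniform(0.0, 2.0 * np.pi, size=(config.n_surr, 1, nf))
    psi[:, :, 0] = 0.0
    if T % 2 == 0:
        psi[:, :, -1] = 0.0

    surr = np.fft.irfft(amp0[None] * np.exp(1j * (phase0[None] + psi)), n=T, axis=-1)
    surr, prev_ranks = _rank_remap(
        surr.reshape(config.n_surr * n_ch, T), np.tile(sorted_x, (config.n_surr, 1))
    )
    surr = surr.reshape(config.n_surr, n_ch, T)
    prev_ranks = prev_ranks.reshape(config.n_surr, n_ch, T)

    pow0 = amp0**2
    pow_norm = np.linalg.norm(pow0) or 1.0
    for it in range(config.max_iterations):
        spec = np.fft.rfft(surr, axis=-1)
        if it > 0:
            pow_err = np.linalg.norm(np.abs(spec) ** 2 - pow0[None], axis=(1, 2)) / pow_norm
            if np.all(pow_err < config.convergence_tol):
                break
        phase = np.angle(spec)
        # optimal common rotation per surrogate and frequency: restore the
        # original *relative* phases as closely as possible
        rot = np.angle(np.sum(np.exp(1j * (phase - phase0[None])), axis=1, keepdims=True))
        rot[:, :, 0] = 0.0
        if T % 2 == 0:
            rot[:, :, -1] = 0.0
        new_phase = phase0[None] + rot
        shaped = np.fft.irfft(amp0[None] * np.exp(1j * new_phase), n=T, axis=-1)
        remapped, ranks = _rank_remap(
            shaped.reshape(config.n_surr * n_ch, T), np.tile(sorted_x, (config.n_surr, 1))
        )
        surr = remapped.reshape(config.n_surr, n_ch, T)
        ranks = ranks.reshape(config.n_surr, n_ch, T)
        if np.array_equal(ranks, prev_ranks):
            break
        prev_ranks = ranks
    return surr
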