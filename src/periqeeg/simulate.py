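"""Synthetic peri-ictal iEEG generator with ground-truth channel zones.

Because clinical iEEG cannot be redistributed, this module generates
labeled recordings whose statistical structure matches what the analysis
pipeline assumes:

* background channels are stationary Gaussian AR(2) noise with a spectral
  peak near 10 Hz (an alpha-like 1/f-ish background with nontrivial
  autocorrelation, so IAAFT surrogates are exercised meaningfully);
* during the annotated seizure interval, designated "generator" channels
  superimpose a shared spike-and-wave-like drive (a ~3 Hz sinusoid, its
  rectified sharpened harmonic and a coherent low-voltage fast component)
  with an amplitude ramp-up.  The drive simultaneously produces elevated
  absolute slope, reduced ordinal-pattern diversity and elevated pairwise
  interrelation among the generator channels - the three signal features
  the qEEG measures target;
* a simulated resected channel set (RBT) and seizure onset zone (SOZ) are
  returned as ground truth, with configurable overlap between the
  generators and the RBT ("favorable" resections contain the generators,
  "unfavorable" ones miss them entirely).

All randomness derives from one seed; per-channel sub-streams are spawned
deterministically, and the background is independent of the zone layout,
so favorable/unfavorable scenario pairs share bit-identical signals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .recording import Recording
from .zonestats import ZoneAssignment

__all__ = ["SimulationConfig", "generate_recording", "make_scenario"]

_BURN_IN = 4096


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario parameters of the synthetic recording generator.

    Durations are in seconds; channel sets are index tuples into
    ``range(n_channels)``.  ``coupling_strength`` in [0, 1] sets the shared
    fraction of the ictal drive, ``ictal_amplitude_gain`` (>= 1) its
    amplitude relative to the background SD (gain 1 means no added
    component), ``ictal_spike_rate`` the spike-and-wave repetition rate in
    Hz.  ``background_ar_coeffs`` are the AR(2) coefficients (default:
    spectral peak near 10 Hz at 512 Hz sampling).  ``reference_lead_s`` is
    the pre-onset lead of the 60-s normalization reference window the
    pre-ictal epoch must contain.
    """

    n_channels: int = 32
    sampling_rate: float = 512.0
    pre_s: float = 240.0
    ictal_s: float = 120.0
    post_s: float = 180.0
    generator_channels: tuple[int, ...] = (0, 1, 2, 3)
    rbt_channels: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    soz_channels: tuple[int, ...] = (0, 1, 2, 3)
    coupling_strength: float = 0.9
    ictal_amplitude_gain: float = 4.0
    ictal_spike_rate: float = 3.0
    background_ar_coeffs: tuple[float, ...] = (1.885708, -0.9025)
    noise_sd: float = 1.0
    reference_lead_s: float = 180.0
    artifact_channels: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        for name in ("generator_channels", "rbt_channels", "soz_channels", "artifact_channels"):
            idx = getattr(self, name)
            if idx and (min(idx) < 0 or max(idx) >= self.n_channels):
                raise ValueError(f"{name} must be a subset of [0, {self.n_channels})")
            if len(set(idx)) != len(idx):
                raise ValueError(f"{name} contains duplicate indices")
        if min(self.pre_s, self.ictal_s, self.post_s) <= 0:
            raise ValueError("epoch durations must be positive")
        if self.pre_s < self.reference_lead_s:
            raise ValueError(
                f"pre-ictal epoch ({self.pre_s} s) cannot contain the reference "
                f"window starting {self.reference_lead_s} s before onset"
            )
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.ictal_amplitude_gain < 1.0:
            raise ValueError("ictal_amplitude_gain must be >= 1")
        if self.noise_sd <= 0 or self.ictal_spike_rate <= 0:
            raise ValueError("noise_sd and ictal_spike_rate must be positive")


def _ar2_stationary_sd_ratio(a1: float, a2: float) -> float:
    # sqrt(gamma_0 / sigma_e^2) for a stationary AR(2)
    num = 1.0 - a2
    den = (1.0 + a2) * ((1.0 - a2) ** 2 - a1**2)
    if den <= 0:
        raise ValueError("AR(2) coefficients are not stationary")
    return float(np.sqrt(num / den))


def _spike_wave(theta: np.ndarray) -> np.ndarray:
    """Spike-and-wave-like waveform: slow wave plus a sharpened rectified spike."""
    return 0.8 * np.sin(theta) + 2.5 * np.maximum(np.sin(theta), 0.0) ** 8


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate_recording(config: SimulationConfig) -> tuple[Recording, ZoneAssignment]:
    """Generate one labeled synthetic recording (deterministic for a fixed seed)."""
    fs = config.sampling_rate
    n_pre = int(round(config.pre_s * fs))
    n_ict = int(round(config.ictal_s * fs))
    n_post = int(round(config.post_s * fs))
    n_samples = n_pre + n_ict + n_post
    n_ch = config.n_channels

    a1, a2 = config.background_ar_coeffs
    sigma_e = config.noise_sd / _ar2_stationary_sd_ratio(a1, a2)

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 * n_ch + 1)
    bg_streams = children[:n_ch]
    drive_stream = np.random.default_rng(children[n_ch])
    ch_streams = children[n_ch + 1 :]

    signals = np.empty((n_ch, n_samples))
    for ch in range(n_ch):
        rng = np.random.default_rng(bg_streams[ch])
        e = rng.normal(0.0, sigma_e, size=n_samples + _BURN_IN)
        x = lfilter([1.0], [1.0, -a1, -a2], e)
        signals[ch] = x[_BURN_IN:]

    # shared ictal drive, active exactly on [onset, termination)
    generators = sorted(config.generator_channels)
    amp = (config.ictal_amplitude_gain - 1.0) * config.noise_sd
    if generators and amp > 0:
        t = np.arange(n_ict) / fs
        f = config.ictal_spike_rate
        f_fast = 8.0 * f  # low-voltage fast activity riding on the spike-wave cycle
        phi0 = drive_stream.uniform(0.0, 2.0 * np.pi)
        theta_c = 2.0 * np.pi * f * t + phi0
        common = _standardize(_spike_wave(theta_c))
        # burst envelope waxing with the spike-wave cycle; carriers are
        # channel-specific, so the shared part of the fast component couples
        # the generator channels through amplitude co-modulation (a strongly
        # nonlinear dependence with near-zero linear cross-correlation), the
        # way low-voltage fast activity rides on spike-and-wave discharges
        env_common = 0.02 + np.maximum(np.sin(theta_c), 0.0) ** 6
        ramp = np.minimum(t / max(min(5.0, 0.2 * config.ictal_s), 1.0 / fs), 1.0)
        c = config.coupling_strength
        w_fast = 0.9
        w_slow = np.sqrt(1.0 - w_fast**2)
        for ch in generators:
            rng = np.random.default_rng(ch_streams[ch])
            phi = rng.uniform(0.0, 2.0 * np.pi)
            jitter = rng.uniform(0.95, 1.05)
            gain = rng.uniform(0.8, 1.2)
            carrier_jitter = rng.uniform(0.9, 1.1)
            own = _standardize(_spike_wave(2.0 * np.pi * f * jitter * t + phi))
            slow = np.sqrt(c) * common + np.sqrt(1.0 - c) * own
            env_own = 0.02 + np.maximum(np.sin(2.0 * np.pi * f * jitter * t + phi), 0.0) ** 6
            envelope = np.sqrt(c) * env_common + np.sqrt(1.0 - c) * env_own
            fast = _standardize(
                envelope * np.sin(2.0 * np.pi * f_fast * carrier_jitter * t + phi)
            )
            mix = w_slow * slow + w_fast * fast
            signals[ch, n_pre : n_pre + n_ict] += amp * gain * ramp * mix

    artifact_free = np.ones(n_ch, dtype=bool)
    artifact_free[list(config.artifact_channels)] = False
    recording = Recording(
        signals=signals,
        sampling_rate=fs,
        onset_sample=n_pre,
        termination_sample=n_pre + n_ict,
        artifact_free=artifact_free,
    )
    zones = ZoneAssignment.from_sets(
        n_ch, config.rbt_channels, config.soz_channels, labels=recording.channel_labels
    )
    return recording, zones


def make_scenario(name: str, base: SimulationConfig) -> SimulationConfig:
    """Derive a favorable or unfavorable resection scenario from a base config.

    * ``favorable``: the resected set contains all generator channels.
    * ``unfavorable``: the resected set is disjoint from the generators.

    The resected set size and everything else (including all random
    sub-streams, hence the signals themselves) are preserved, so the two
    scenarios differ only in zone placement.
    """
    gen = sorted(set(base.generator_channels))
    n_rbt = len(base.rbt_channels)
    others = [ch for ch in range(base.n_channels) if ch not in set(gen)]
    if name == "favorable":
        if n_rbt < len(gen):
            raise ValueError(
                f"cannot place {len(gen)} generator channels inside a resected set "
                f"of size {n_rbt}"
            )
        rbt = tuple(gen + others[: n_rbt - len(gen)])
    elif name == "unfavorable":
        if len(others) < n_rbt:
            raise ValueError(
                f"cannot build a resected set of size {n_rbt} disjoint from "
                f"{len(gen)} generator channels with only {base.n_channels} channels"
            )
        rbt = tuple(others[:n_rbt])
    else:
        raise ValueError("scenario name must be 'favorable' or 'unfavorable'")
    return replace(base, rbt_channels=rbt, soz_channels=tuple(gen))
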