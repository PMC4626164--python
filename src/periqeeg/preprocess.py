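"""Signal conditioning and peri-ictal epoch planning.

The conditioning chain mirrors standard clinical qEEG practice: zero-phase
(forward-backward) 4th-order Butterworth band-pass between 0.5 and 150 Hz,
integer-factor down-sampling to 512 Hz with anti-aliasing, and
re-referencing of every channel against the per-sample median of the
artifact-free channels.

The epoch planner lays out the peri-ictal analysis structure: a pre-ictal
reference window (60 s, starting 180 s before onset, used to normalize the
univariate measures), three 1-minute pre-ictal segments, six equal ictal
segments (first/second half = early/late ictal), and three 1-minute
post-ictal segments.  All intervals are 0-based half-open sample ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import Recording

__all__ = ["EpochPlan", "bandpass_filter", "downsample", "median_rereference", "plan_epochs"]

Interval = tuple[int, int]


@dataclass(frozen=True)
class EpochPlan:
    """Peri-ictal epoch layout in samples at the working sampling rate."""

    sampling_rate: float
    reference: Interval
    pre_segments: tuple[Interval, ...]
    ictal_segments: tuple[Interval, ...]
    post_segments: tuple[Interval, ...]
    phases: dict[str, tuple[Interval, ...]] = field(default_factory=dict)

    @property
    def segments(self) -> tuple[tuple[str, Interval], ...]:
        """All 12 peri-ictal segments in temporal order, tagged with their phase."""
        out: list[tuple[str, Interval]] = []
        out += [("pre", iv) for iv in self.pre_segments]
        n_ict = len(self.ictal_segments)
        for k, iv in enumerate(self.ictal_segments):
            out.append(("early_ictal" if k < n_ict // 2 else "late_ictal", iv))
        out += [("post", iv) for iv in self.post_segments]
        return tuple(out)


def bandpass_filter(
    recording: Recording, low: float = 0.5, high: float = 150.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass; two passes square the magnitude response."""
    nyq = recording.sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError("require 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=recording.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.signals, axis=1)
    return recording.copy_with(signals=filtered)


def downsample(recording: Recording, target: float = 512.0) -> Recording:
    """Anti-aliased decimation to an integer-divisor target rate.

    A zero-phase 8th-order Butterworth low-pass at 0.8x the new Nyquist
    frequency is applied before taking every q-th sample; seizure
    annotations are rescaled to the new sample indices.
    """
    ratio = recording.sampling_rate / target
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"sampling rate {recording.sampling_rate} Hz is not an integer "
            f"multiple of target {target} Hz"
        )
    if q == 1:
        return recording
    cutoff = 0.8 * (target / 2.0)
    sos = sps.butter(8, cutoff, btype="lowpass", fs=recording.sampling_rate, output="sos")
    lowpassed = sps.sosfiltfilt(sos, recording.signals, axis=1)
    return recording.copy_with(
        signals=lowpassed[:, ::q],
        sampling_rate=target,
        onset_sample=recording.onset_sample // q,
        termination_sample=recording.termination_sample // q,
    )


def median_rereference(recording: Recording) -> Recording:
    """Subtract the per-sample median over artifact-free channels from every channel."""
    if int(recording.artifact_free.sum()) < 2:
        raise ValueError("median re-reference needs at least 2 artifact-free channels")
    ref = np.median(recording.signals[recording.artifact_free], axis=0)
    return recording.copy_with(signals=recording.signals - ref[None, :])


def _balanced_partition(start: int, stop: int, parts: int) -> tuple[Interval, ...]:
    # remainder samples go to the earliest segments; lengths differ by <= 1
    total = stop - start
    base, rem = divmod(total, parts)
    out = []
    cursor = start
    for k in range(parts):
        length = base + (1 if k < rem else 0)
        out.append((cursor, cursor + length))
        cursor += length
    assert cursor == stop
    return tuple(out)


def plan_epochs(
    recording: Recording,
    *,
    reference_lead_s: float = 180.0,
    reference_duration_s: float = 60.0,
    n_pre: int = 3,
    pre_segment_s: float = 60.0,
    n_ictal: int = 6,
    n_post: int = 3,
    post_segment_s: float = 60.0,
) -> EpochPlan:
    """Lay out reference window and peri-ictal segments around the seizure.

    Raises a ValueError naming the missing duration when the recording does
    not contain enough pre- or post-ictal context.
    """
    fs = recording.sampling_rate
    onset, term = recording.onset_sample, recording.termination_sample
    need_pre_s = max(reference_lead_s, n_pre * pre_segment_s)
    need_pre = int(round(need_pre_s * fs))
    if onset < need_pre:
        raise ValueError(
            f"insufficient pre-ictal context: need {need_pre_s:.0f} s before onset, "
            f"have {onset / fs:.1f} s (missing {(need_pre - onset) / fs:.1f} s)"
        )
    need_post = int(round(n_post * post_segment_s * fs))
    if recording.n_samples - term < need_post:
        raise ValueError(
            f"insufficient post-ictal context: need {n_post * post_segment_s:.0f} s after "
            f"termination, have {(recording.n_samples - term) / fs:.1f} s "
            f"(missing {(need_post - (recording.n_samples - term)) / fs:.1f} s)"
        )

    ref_start = onset - int(round(reference_lead_s * fs))
    ref_stop = ref_start + int(round(reference_duration_s * fs))
    if ref_stop > onset:
        raise ValueError("reference window extends past seizure onset")

    pre_len = int(round(pre_segment_s * fs))
    pre = tuple((onset - (n_pre - k) * pre_len, onset - (n_pre - k - 1) * pre_len) for k in range(n_pre))
    ictal = _balanced_partition(onset, term, n_ictal)
    post_len = int(round(post_segment_s * fs))
    post = tuple((term + k * post_len, term + (k + 1) * post_len) for k in range(n_post))

    n_half = n_ictal // 2
    phases = {
        "pre": pre,
        "early_ictal": ictal[:n_half],
        "late_ictal": ictal[n_half:],
        "post": post,
    }
    return EpochPlan(
        sampling_rate=fs,
        reference=(ref_start, ref_stop),
        pre_segments=pre,
        ictal_segments=ictal,
        post_segments=post,
        phases=phases,
    )
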