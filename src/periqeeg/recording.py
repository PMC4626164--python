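"""Multichannel iEEG-like recording container and file I/O.

A :class:`Recording` holds a channel-by-sample signal matrix together with
the sampling rate, channel labels, the annotated seizure interval
(half-open, in samples) and per-channel artifact flags.  Channels marked as
artifact-contaminated stay in the matrix but are excluded from the median
reference and from all statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Recording", "read_hdf5", "write_hdf5", "read_edf"]


@dataclass
class Recording:
    """One peri-ictal multichannel recording.

    Parameters
    ----------
    signals : ndarray, shape (n_channels, n_samples)
        Signal matrix in arbitrary amplitude units.
    sampling_rate : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        One label per channel.
    onset_sample, termination_sample : int
        Seizure interval ``[onset, termination)`` as 0-based sample indices.
    artifact_free : ndarray of bool, shape (n_channels,)
        False marks channels with permanent artifacts.
    """

    signals: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...] = ()
    onset_sample: int = 0
    termination_sample: int = 0
    artifact_free: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a (n_channels, n_samples) matrix")
        n_ch, n_samp = self.signals.shape
        if not self.channel_labels:
            self.channel_labels = tuple(f"CH{i:03d}" for i in range(n_ch))
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel_labels length does not match signal matrix")
        if self.artifact_free is None:
            self.artifact_free = np.ones(n_ch, dtype=bool)
        self.artifact_free = np.asarray(self.artifact_free, dtype=bool)
        if self.artifact_free.shape != (n_ch,):
            raise ValueError("artifact_free must have one flag per channel")
        if not (0 <= self.onset_sample < self.termination_sample <= n_samp):
            raise ValueError(
                f"invalid seizure interval [{self.onset_sample}, "
                f"{self.termination_sample}) for {n_samp} samples"
            )
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")
        if int(self.artifact_free.sum()) < 2:
            raise ValueError("need at least 2 artifact-free channels")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


def write_hdf5(recording: Recording, path: str | Path) -> None:
    """Write a recording to a plain HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        dset = f.create_dataset("signals", data=recording.signals)
        dset.attrs["sampling_rate"] = float(recording.sampling_rate)
        dset.attrs["onset_sample"] = int(recording.onset_sample)
        dset.attrs["termination_sample"] = int(recording.termination_sample)
        f.create_dataset(
            "channel_labels",
            data=np.array([s.encode() for s in recording.channel_labels]),
        )
        f.create_dataset("artifact_free", data=recording.artifact_free)


def read_hdf5(path: str | Path) -> Recording:
    """Read a recording from the HDF5 container written by :func:`write_hdf5`."""
    import h5py

    with h5py.File(path, "r") as f:
        dset = f["signals"]
        return Recording(
            signals=dset[()],
            sampling_rate=float(dset.attrs["sampling_rate"]),
            channel_labels=tuple(s.decode() for s in f["channel_labels"][()]),
            onset_sample=int(dset.attrs["onset_sample"]),
            termination_sample=int(dset.attrs["termination_sample"]),
            artifact_free=f["artifact_free"][()],
        )


def read_edf(
    path: str | Path,
    onset_s: float | None = None,
    termination_s: float | None = None,
) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording`.

    Seizure onset/termination are taken from EDF+ annotations named
    ``onset``/``termination`` (case-insensitive) unless given explicitly in
    seconds.  Requires the optional ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "reading EDF requires the optional dependency 'mne' "
            "(pip install periqeeg[edf])"
        ) from exc

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    fs = float(raw.info["sfreq"])
    if onset_s is None or termination_s is None:
        marks = {
            str(d).strip().lower(): float(t)
            for t, d in zip(raw.annotations.onset, raw.annotations.description)
        }
        if onset_s is None:
            onset_s = marks.get("onset")
        if termination_s is None:
            termination_s = marks.get("termination")
    if onset_s is None or termination_s is None:
        raise ValueError(
            "seizure onset/termination not found: provide onset_s/termination_s "
            "or EDF+ annotations named 'onset' and 'termination'"
        )
    return Recording(
        signals=raw.get_data(),
        sampling_rate=fs,
        channel_labels=tuple(raw.ch_names),
        onset_sample=int(round(onset_s * fs)),
        termination_sample=int(round(termination_s * fs)),
    )
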