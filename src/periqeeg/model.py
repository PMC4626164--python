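"""Model-style front end tying the pipeline stages together.

:class:`PeriIctalAnalysis` is constructed from a recording plus a channel
zone table and holds all stage configurations; :meth:`PeriIctalAnalysis.fit`
runs preprocessing, the selected qEEG measures, saliency detection and the
zone over-representation statistics, and returns a
:class:`PeriIctalResults` carrying the per-step series, masks and
summaries with a ``summary()`` table and TSV export.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .interrelation import EnsembleConfig, InterrelationResult, interrelation_series
from .preprocess import EpochPlan, bandpass_filter, downsample, median_rereference, plan_epochs
from .recording import Recording
from .saliency import SaliencyConfig, SaliencyMask, saliency_series
from .simulate import SimulationConfig, generate_recording
from .univariate import (
    MeasureSeries,
    OrdinalConfig,
    WindowGrid,
    absolute_slope_series,
    forbidden_pattern_series,
    normalize_by_reference,
)
from .zonestats import ZoneAssignment, jaccard_index, zone_series
from .group import phase_means

__all__ = ["PeriIctalAnalysis", "PeriIctalResults"]

MEASURES = ("S", "N", "C", "M")


@dataclass
class PeriIctalResults:
    """Fitted peri-ictal analysis: series, saliency masks and zone statistics."""

    model: "PeriIctalAnalysis"
    recording: Recording
    plan: EpochPlan
    zones: ZoneAssignment | None
    series: dict[str, MeasureSeries]
    masks: dict[str, SaliencyMask]
    interrelation: dict[str, InterrelationResult] = field(default_factory=dict)
    zone_stats: pd.DataFrame | None = None
    phase_summary: pd.DataFrame | None = None
    runtime_s: float = 0.0

    def periictal_means(self) -> pd.DataFrame | None:
        """Seizure-wise peri-ictal means (mean over the 12 segment means)."""
        if self.phase_summary is None:
            return None
        return self.phase_summary[self.phase_summary["phase"] == "periictal"].reset_index(
            drop=True
        )

    def summary(self) -> str:
        rec = self.recording
        lines = []
        lines.append("Peri-ictal quantitative EEG saliency analysis")
        lines.append("=" * 61)
        lines.append(f"channels (artifact-free):  {rec.n_channels}")
        lines.append(f"sampling rate:             {rec.sampling_rate:g} Hz")
        lines.append(
            f"seizure interval:          [{rec.onset_sample / rec.sampling_rate:.1f}, "
            f"{rec.termination_sample / rec.sampling_rate:.1f}) s "
            f"({(rec.termination_sample - rec.onset_sample) / rec.sampling_rate:.1f} s)"
        )
        lines.append(f"measures:                  {', '.join(self.series)}")
        if self.zones is not None:
            sizes = self.zones.sizes()
            j = jaccard_index(self.zones)
            lines.append(
                "zones:                     "
                + ", ".join(f"{z}={sizes[z]}" for z in ("RBT", "SOZ", "OVL", "NON"))
                + (f", Jaccard={j:.3f}" if np.isfinite(j) else "")
            )
        pm = self.periictal_means()
        if pm is not None and len(pm):
            lines.append("")
            lines.append("Seizure-wise peri-ictal means (over the 12 segment means)")
            lines.append("-" * 61)
            lines.append(f"{'measure':>8} {'zone':>5} {'mean F':>9} {'mean L':>9}")
            for _, row in pm.iterrows():
                lines.append(
                    f"{row['measure']:>8} {row['zone']:>5} "
                    f"{row['mean_F']:>9.3f} {row['mean_L']:>9.3f}"
                )
        lines.append("-" * 61)
        lines.append(f"runtime: {self.runtime_s:.1f} s   periqeeg {_version}")
        return "\n".join(lines)

    def save(self, outdir: str | Path, manifest_extra: dict | None = None) -> dict:
        """Write TSV outputs and a JSON manifest; returns the manifest dict."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        outputs: list[str] = []
        for mid, series in self.series.items():
            path = outdir / f"measure_{mid}.tsv"
            series.to_frame().to_csv(path, sep="\t")
            outputs.append(path.name)
            mpath = outdir / f"saliency_{mid}.tsv"
            mask = self.masks[mid]
            pd.DataFrame(
                mask.mask.astype(int),
                index=list(mask.channel_labels),
                columns=mask.times_s,
            ).to_csv(mpath, sep="\t")
            outputs.append(mpath.name)
        if self.zone_stats is not None:
            self.zone_stats.to_csv(outdir / "zone_stats.tsv", sep="\t", index=False)
            outputs.append("zone_stats.tsv")
        if self.phase_summary is not None:
            self.phase_summary.to_csv(outdir / "phase_summary.tsv", sep="\t", index=False)
            outputs.append("phase_summary.tsv")
        manifest = {
            "periqeeg_version": _version,
            "seed": self.model.seed,
            "measures": list(self.series),
            "config": self.model.config_dict(),
            "runtime_s": self.runtime_s,
            "outputs": outputs,
        }
        if manifest_extra:
            manifest.update(manifest_extra)
        with open(outdir / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, default=str)
        return manifest


class PeriIctalAnalysis:
    """Peri-ictal saliency / zone over-representation analysis of one seizure.

    Parameters
    ----------
    recording : Recording
        The peri-ictal multichannel recording (any amplitude units).
    zones : ZoneAssignment, optional
        Channel zone table; omit to compute measures and saliency only.
    measures : subset of {"S", "N", "C", "M"}
        S: absolute slope, N: forbidden ordinal patterns, C/M: node
        strength of the surrogate-corrected correlation / mutual
        information matrix.
    preprocess : bool
        Apply 0.5-150 Hz zero-phase band-pass, down-sampling to 512 Hz
        (when the rate is a higher integer multiple) and median
        re-referencing before analysis.
    epoch_params : dict, optional
        Overrides for :func:`periqeeg.preprocess.plan_epochs` (e.g. a
        shorter reference lead for scaled-down runs).
    seed : int
        Master seed for the surrogate ensembles (sub-streams are derived
        per measure).
    """

    def __init__(
        self,
        recording: Recording,
        zones: ZoneAssignment | None = None,
        measures: tuple[str, ...] = MEASURES,
        *,
        preprocess: bool = True,
        epoch_params: dict | None = None,
        uni_window: int = 1024,
        uni_step: int = 512,
        ordinal_config: OrdinalConfig | None = None,
        ensemble_config: EnsembleConfig | None = None,
        saliency_config: SaliencyConfig | None = None,
        seed: int = 0,
    ) -> None:
        unknown = set(measures) - set(MEASURES)
        if unknown or not measures:
            raise ValueError(f"measures must be a nonempty subset of {MEASURES}")
        self.recording = recording
        self.zones = zones
        self.measures = tuple(measures)
        self.preprocess = preprocess
        self.epoch_params = dict(epoch_params or {})
        self.uni_window = uni_window
        self.uni_step = uni_step
        self.ordinal_config = ordinal_config or OrdinalConfig(window_len=uni_window)
        self.ensemble_config = ensemble_config or EnsembleConfig()
        self.saliency_config = saliency_config or SaliencyConfig()
        self.seed = seed

    @classmethod
    def from_simulation(
        cls, config: SimulationConfig, **kwargs
    ) -> "PeriIctalAnalysis":
        """Build the analysis from a synthetic scenario (zones = ground truth)."""
        recording, zones = generate_recording(config)
        kwargs.setdefault(
            "epoch_params", {"reference_lead_s": config.reference_lead_s}
        )
        return cls(recording, zones, **kwargs)

    def config_dict(self) -> dict:
        return {
            "measures": list(self.measures),
            "preprocess": self.preprocess,
            "epoch_params": self.epoch_params,
            "uni_window": self.uni_window,
            "uni_step": self.uni_step,
            "ordinal": asdict(self.ordinal_config),
            "ensemble": asdict(self.ensemble_config),
            "saliency": asdict(self.saliency_config),
            "seed": self.seed,
        }

    def fit(self) -> PeriIctalResults:
        t0 = time.perf_counter()
        rec = self.recording
        if self.preprocess:
            ratio = rec.sampling_rate / 512.0
            if ratio > 1 and abs(ratio - round(ratio)) < 1e-9:
                rec = downsample(rec, 512.0)
            high = min(150.0, 0.45 * rec.sampling_rate)
            rec = bandpass_filter(rec, 0.5, high)
            rec = median_rereference(rec)
        # analysis runs on artifact-free channels only
        zones = self.zones
        if not rec.artifact_free.all():
            keep = rec.artifact_free
            if zones is not None:
                zones = zones.reorder(rec.channel_labels).subset(keep)
            rec = rec.copy_with(
                signals=rec.signals[keep],
                channel_labels=tuple(np.array(rec.channel_labels, dtype=object)[keep]),
                artifact_free=np.ones(int(keep.sum()), dtype=bool),
            )
        elif zones is not None:
            zones = zones.reorder(rec.channel_labels)

        plan = plan_epochs(rec, **self.epoch_params)
        seed_seq = np.random.SeedSequence(self.seed)
        child_seeds = {
            m: int(s.generate_state(1)[0] % (2**31))
            for m, s in zip(("C", "M"), seed_seq.spawn(2))
        }

        series: dict[str, MeasureSeries] = {}
        inter: dict[str, InterrelationResult] = {}
        uni_grid = WindowGrid.over(
            rec.n_samples, self.uni_window, self.uni_step, rec.sampling_rate
        )
        for m in self.measures:
            if m == "S":
                series[m] = normalize_by_reference(absolute_slope_series(rec, uni_grid), plan)
            elif m == "N":
                series[m] = normalize_by_reference(
                    forbidden_pattern_series(rec, uni_grid, self.ordinal_config), plan
                )
            else:
                s, res = interrelation_series(
                    rec, self.ensemble_config, kind=m, seed=child_seeds[m]
                )
                series[m] = s
                inter[m] = res

        masks = {m: saliency_series(s, self.saliency_config) for m, s in series.items()}

        zstats = None
        summary = None
        if zones is not None:
            frames = []
            for m in self.measures:
                zf = zone_series(masks[m], zones)
                zf.insert(0, "measure", m)
                frames.append(zf)
            zstats = pd.concat(frames, ignore_index=True)
            summary = phase_means(zstats, plan)

        return PeriIctalResults(
            model=self,
            recording=rec,
            plan=plan,
            zones=zones,
            series=series,
            masks=masks,
            interrelation=inter,
            zone_stats=zstats,
            phase_summary=summary,
            runtime_s=time.perf_counter() - t0,
        )
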