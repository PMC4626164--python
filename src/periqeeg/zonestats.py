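"""Channel zones and hypergeometric over-representation statistics.

Channels are assigned to anatomically defined zones: RBT (resected brain
tissue), SOZ (seizure onset zone), their overlap OVL and the complement
NON.  Given a per-time-step saliency mask, this module quantifies, for
each zone Z and measure X, the fraction of salient channels falling into
the zone,

    F_Z^X = n_{Z∩X} / n_X,

and the significance of that overlap under the hypergeometric null of
salient channels placed uniformly at random:

    P = sum_{nu=m}^{nu_max} p(nu),   L = -log10(P),

where ``p`` is the hypergeometric pmf with population ``n``, zone size
``n_Z`` and draw size ``n_X``, and ``m`` is the observed intersection
count.  Time steps without any salient channel leave F and L undefined
(NaN), producing the discontinuities seen in per-seizure time courses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "ZoneAssignment",
    "fraction_in_zone",
    "hypergeometric_pmf",
    "overrepresentation_pvalue",
    "log_probability",
    "jaccard_index",
    "zone_series",
    "read_zone_table",
    "write_zone_table",
]

ZONES = ("RBT", "SOZ", "OVL", "NON")


@dataclass(frozen=True)
class ZoneAssignment:
    """Per-channel membership in the resected tissue and seizure onset zone.

    OVL and NON are derived: OVL = RBT ∩ SOZ, NON = complement of RBT ∪ SOZ.
    """

    labels: tuple[str, ...]
    in_rbt: np.ndarray
    in_soz: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "in_rbt", np.asarray(self.in_rbt, dtype=bool))
        object.__setattr__(self, "in_soz", np.asarray(self.in_soz, dtype=bool))
        n = len(self.labels)
        if self.in_rbt.shape != (n,) or self.in_soz.shape != (n,):
            raise ValueError("zone flags must have one entry per channel label")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate channel labels in zone assignment")

    @classmethod
    def from_sets(
        cls,
        n_channels: int,
        rbt: set[int] | tuple[int, ...],
        soz: set[int] | tuple[int, ...],
        labels: tuple[str, ...] | None = None,
    ) -> "ZoneAssignment":
        rbt, soz = set(rbt), set(soz)
        for name, s in (("rbt", rbt), ("soz", soz)):
            if s and (min(s) < 0 or max(s) >= n_channels):
                raise ValueError(f"{name} channel indices outside [0, {n_channels})")
        if labels is None:
            labels = tuple(f"CH{i:03d}" for i in range(n_channels))
        in_rbt = np.zeros(n_channels, dtype=bool)
        in_soz = np.zeros(n_channels, dtype=bool)
        in_rbt[list(rbt)] = True
        in_soz[list(soz)] = True
        return cls(labels=labels, in_rbt=in_rbt, in_soz=in_soz)

    @property
    def n(self) -> int:
        return len(self.labels)

    def membership(self, zone: str) -> np.ndarray:
        """Boolean membership vector for one of RBT, SOZ, OVL, NON."""
        if zone == "RBT":
            return self.in_rbt
        if zone == "SOZ":
            return self.in_soz
        if zone == "OVL":
            return self.in_rbt & self.in_soz
        if zone == "NON":
            return ~(self.in_rbt | self.in_soz)
        raise KeyError(f"unknown zone {zone!r}")

    def size(self, zone: str) -> int:
        return int(self.membership(zone).sum())

    def sizes(self) -> dict[str, int]:
        return {z: self.size(z) for z in ZONES}

    def subset(self, keep: np.ndarray) -> "ZoneAssignment":
        """Restrict to a boolean channel subset (e.g. artifact-free channels)."""
        keep = np.asarray(keep, dtype=bool)
        return ZoneAssignment(
            labels=tuple(np.array(self.labels, dtype=object)[keep]),
            in_rbt=self.in_rbt[keep],
            in_soz=self.in_soz[keep],
        )

    def reorder(self, labels: tuple[str, ...]) -> "ZoneAssignment":
        """Align to a recording's channel order; unmatched labels raise."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise ValueError(f"zone table has no entry for channels: {missing}")
        order = [index[lab] for lab in labels]
        return ZoneAssignment(
            labels=tuple(labels),
            in_rbt=self.in_rbt[order],
            in_soz=self.in_soz[order],
        )


def fraction_in_zone(n_x: int, n_intersect: int) -> float:
    """Fraction F = n_{Z∩X}/n_X of salient channels inside a zone.

    Returns NaN when there is no salient channel (F undefined).
    """
    if n_intersect < 0 or n_intersect > n_x:
        raise ValueError("intersection count exceeds number of salient channels")
    if n_x == 0:
        return float("nan")
    return n_intersect / n_x


def hypergeometric_pmf(n: int, n_z: int, n_x: int, nu: int) -> float:
    """Probability of exactly ``nu`` of the ``n_x`` salient channels in a zone of size ``n_z``."""
    if min(n, n_z, n_x) < 0 or n_z > n or n_x > n:
        raise ValueError("invalid hypergeometric parameters")
    return float(hypergeom.pmf(nu, n, n_z, n_x))


def overrepresentation_pvalue(n: int, n_z: int, n_x: int, m: int) -> float:
    """Upper-tail hypergeometric probability of ``m`` or more salient channels in the zone."""
    if min(n, n_z, n_x) < 0 or n_z > n or n_x > n:
        raise ValueError("invalid hypergeometric parameters")
    nu_max = min(n_z, n_x)
    if m > nu_max:
        raise ValueError(f"observed intersection {m} exceeds max possible {nu_max}")
    nu_min = max(0, n_z + n_x - n)
    if m <= nu_min:
        return 1.0
    p = float(hypergeom.sf(m - 1, n, n_z, n_x))
    # guard the open interval (0, 1]: the single-term tail at nu_max is positive
    return min(max(p, 5e-324), 1.0)


def log_probability(p: float) -> float:
    """Log-probability score L = -log10(P); large values mean strong over-representation."""
    if not 0.0 < p <= 1.0:
        raise ValueError("P must lie in (0, 1]")
    return float(-np.log10(p))


def jaccard_index(assignment: ZoneAssignment) -> float:
    """Jaccard index |RBT ∩ SOZ| / |RBT ∪ SOZ|; NaN for an empty union."""
    union = int((assignment.in_rbt | assignment.in_soz).sum())
    if union == 0:
        return float("nan")
    return assignment.size("OVL") / union


def zone_series(mask, assignment: ZoneAssignment) -> pd.DataFrame:
    """Per-time-step zone statistics for one measure's saliency mask.

    Parameters
    ----------
    mask : SaliencyMask
        Boolean channel x time-step matrix from :mod:`periqeeg.saliency`.
    assignment : ZoneAssignment
        Channel zone table aligned to the mask's channels.

    Returns
    -------
    DataFrame with one row per (zone, step): columns ``zone, step,
    time_s, n, n_Z, n_X, n_intersect, F, P, L``.  F and L are NaN on
    steps without salient channels.
    """
    m = np.asarray(mask.mask, dtype=bool)
    if m.shape[0] != assignment.n:
        raise ValueError(
            f"mask has {m.shape[0]} channels but zone assignment has {assignment.n}"
        )
    n = assignment.n
    n_x = m.sum(axis=0)
    frames = []
    times = np.asarray(mask.times_s, dtype=float)
    for zone in ZONES:
        member = assignment.membership(zone)
        n_z = int(member.sum())
        n_int = m[member].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_x > 0, n_int / np.maximum(n_x, 1), np.nan)
        # sf(m-1) is 1 whenever m <= nu_min, including the n_X = 0 steps
        pvals = hypergeom.sf(n_int - 1, n, n_z, n_x)
        pvals = np.clip(pvals, 5e-324, 1.0)
        lvals = np.where(n_x > 0, -np.log10(pvals), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "zone": zone,
                    "step": np.arange(m.shape[1]),
                    "time_s": times,
                    "n": n,
                    "n_Z": n_z,
                    "n_X": n_x,
                    "n_intersect": n_int,
                    "F": frac,
                    "P": pvals,
                    "L": lvals,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def read_zone_table(path: str | Path) -> ZoneAssignment:
    """Read a TSV zone table with columns channel_label, in_rbt, in_soz (0/1)."""
    df = pd.read_csv(path, sep="\t")
    required = {"channel_label", "in_rbt", "in_soz"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"zone table must have columns {sorted(required)}; got {list(df.columns)}"
        )
    for col in ("in_rbt", "in_soz"):
        vals = set(pd.unique(df[col]))
        if not vals <= {0, 1}:
            raise ValueError(f"column {col} must be 0/1, found values {sorted(vals)}")
    labels = tuple(str(x) for x in df["channel_label"])
    return ZoneAssignment(
        labels=labels,
        in_rbt=df["in_rbt"].to_numpy(dtype=bool),
        in_soz=df["in_soz"].to_numpy(dtype=bool),
    )


def write_zone_table(assignment: ZoneAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {
            "channel_label": assignment.labels,
            "in_rbt": assignment.in_rbt.astype(int),
            "in_soz": assignment.in_soz.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)
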