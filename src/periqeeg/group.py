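"""Phase/seizure summaries and group-level nonparametric comparisons.

Per-seizure, the per-step zone quantifiers F (fraction of salient channels
in a zone) and L (-log10 of the hypergeometric over-representation P) are
averaged within each of the 12 peri-ictal segments; phase means (pre,
early ictal, late ictal, post) average their segments, and the seizure-wise
peri-ictal mean averages all 12 segment means (the quantity the radar-plot
area encodes).  Across surgical-outcome classes the seizure-wise means are
compared with a first-level Kruskal-Wallis test followed - only when the
first level rejects at alpha - by pairwise Mann-Whitney-Wilcoxon tests
(uncorrected, as appropriate for an explorative contrast).  Categorical
variables are compared with a chi-square statistic whose p-value is
estimated by randomly reallocating the group labels.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import EpochPlan

__all__ = [
    "phase_means",
    "kruskal_wallis",
    "mww_pairwise",
    "chi2_resampled",
    "outcome_contrast",
]

PHASES = ("pre", "early_ictal", "late_ictal", "post")


def _segment_of(times_samples: np.ndarray, plan: EpochPlan) -> np.ndarray:
    """Index (0..11) of the containing peri-ictal segment, -1 outside all."""
    out = np.full(len(times_samples), -1, dtype=int)
    for k, (_, (start, stop)) in enumerate(plan.segments):
        sel = (times_samples >= start) & (times_samples < stop)
        out[sel] = k
    return out


def phase_means(zone_stats: pd.DataFrame, plan: EpochPlan) -> pd.DataFrame:
    """Phase and seizure-wise means of F and L from per-step zone statistics.

    Parameters
    ----------
    zone_stats : DataFrame
        Long-format per-step statistics (columns ``zone, time_s, F, L`` at
        least), e.g. from :func:`periqeeg.zonestats.zone_series`; an optional
        ``measure`` column is carried through.
    plan : EpochPlan
        Peri-ictal segment layout; steps are assigned to segments by their
        window-end timestamp, steps between epochs are ignored.

    Returns
    -------
    DataFrame with one row per (measure, zone, phase) plus a ``periictal``
    row per (measure, zone) holding the mean over the 12 segment means.
    Missing per-step values (no salient channel) are excluded; a segment
    without any defined step is missing and excluded from its phase.
    95% confidence half-widths use the normal approximation on the
    contributing steps.
    """
    df = zone_stats.copy()
    if "measure" not in df.columns:
        df["measure"] = "X"
    seg_names = [name for name, _ in plan.segments]
    df["segment"] = _segment_of(
        np.round(df["time_s"].to_numpy() * plan.sampling_rate).astype(int), plan
    )
    df = df[df["segment"] >= 0]
    rows = []
    for (measure, zone), grp in df.groupby(["measure", "zone"], sort=False):
        seg_mean_f = grp.groupby("segment")["F"].mean()
        seg_mean_l = grp.groupby("segment")["L"].mean()
        for phase in PHASES:
            segs = [k for k, name in enumerate(seg_names) if name == phase]
            in_phase = grp[grp["segment"].isin(segs)]
            f_vals = in_phase["F"].dropna()
            l_vals = in_phase["L"].dropna()
            rows.append(
                {
                    "measure": measure,
                    "zone": zone,
                    "phase": phase,
                    "mean_F": seg_mean_f.reindex(segs).mean(),
                    "mean_L": seg_mean_l.reindex(segs).mean(),
                    "ci_F": 1.96 * f_vals.sem() if len(f_vals) > 1 else np.nan,
                    "ci_L": 1.96 * l_vals.sem() if len(l_vals) > 1 else np.nan,
                    "n_steps": int(len(in_phase)),
                }
            )
        f_all = grp["F"].dropna()
        l_all = grp["L"].dropna()
        rows.append(
            {
                "measure": measure,
                "zone": zone,
                "phase": "periictal",
                "mean_F": seg_mean_f.mean(),
                "mean_L": seg_mean_l.mean(),
                "ci_F": 1.96 * f_all.sem() if len(f_all) > 1 else np.nan,
                "ci_L": 1.96 * l_all.sem() if len(l_all) > 1 else np.nan,
                "n_steps": int(len(grp)),
            }
        )
    return pd.DataFrame(rows)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H and p (chi-square approximation, tie corrected)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def mww_pairwise(
    sample_a: np.ndarray, sample_b: np.ndarray, sided: str = "two"
) -> tuple[float, float]:
    """Mann-Whitney-Wilcoxon U test between two samples.

    Exact null distribution for combined sizes <= 20 without ties, normal
    approximation with tie correction otherwise.  ``sided`` is ``"two"``
    or ``"one"`` (one-sided: a stochastically greater than b).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    alternative = {"two": "two-sided", "one": "greater"}[sided]
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def chi2_resampled(
    table: np.ndarray, n_resamples: int = 10_000, seed: int | None = None
) -> float:
    """Permutation p-value of the chi-square statistic of a contingency table.

    Rows are the outcome groups, columns the categories.  The group
    allocation is randomly reallocated ``n_resamples`` times holding the
    margins of the grouping variable; p = (1 + #{chi2* >= chi2}) /
    (n_resamples + 1).  Degenerate tables (a zero margin) give p = 1.
    """
    tab = np.asarray(table)
    if tab.ndim != 2 or np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        raise ValueError("table must be a nonnegative integer matrix")
    row_m = tab.sum(axis=1)
    col_m = tab.sum(axis=0)
    if np.any(row_m == 0) or np.any(col_m == 0) or tab.sum() == 0:
        return 1.0

    def _chi2(t: np.ndarray) -> float:
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = (t - expected) ** 2 / expected
        return float(np.nansum(terms))

    observed = _chi2(tab)
    # expand to individual observations, permute the group labels
    groups = np.repeat(np.arange(tab.shape[0]), row_m)
    cats = np.concatenate([np.repeat(np.arange(tab.shape[1]), tab[g]) for g in range(tab.shape[0])])
    rng = np.random.default_rng(seed)
    n_groups, n_cats = tab.shape
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(groups)
        resampled = np.zeros_like(tab)
        np.add.at(resampled, (perm, cats), 1)
        if _chi2(resampled) >= observed - 1e-12:
            count += 1
    return (1 + count) / (n_resamples + 1)


def outcome_contrast(
    summaries: pd.DataFrame,
    value: str = "mean_F",
    alpha: float = 0.05,
    sided: str = "two",
) -> pd.DataFrame:
    """Class-wise comparison of seizure-wise peri-ictal means.

    Parameters
    ----------
    summaries : DataFrame
        One row per (seizure, measure, zone) with columns ``seizure,
        label, measure, zone`` and the summary column named by ``value``
        (typically the ``periictal`` rows of :func:`phase_means`).
    value : column holding the seizure-wise quantity to compare.
    alpha : first-level test level gating the post-hoc pairwise tests.

    Returns
    -------
    DataFrame with one row per (measure, zone): first-level
    Kruskal-Wallis p, and pairwise MWW p-values (only when the first
    level rejected; ``n.a.`` otherwise, mirroring conditional post-hoc
    testing).
    """
    required = {"seizure", "label", "measure", "zone", value}
    if not required.issubset(summaries.columns):
        raise ValueError(f"summaries must have columns {sorted(required)}")
    rows = []
    for (measure, zone), grp in summaries.groupby(["measure", "zone"], sort=False):
        by_class = {
            lab: sub[value].dropna().to_numpy() for lab, sub in grp.groupby("label")
        }
        by_class = {lab: v for lab, v in by_class.items() if len(v) > 0}
        labels = sorted(by_class)
        row: dict[str, object] = {"measure": measure, "zone": zone}
        for lab in labels:
            row[f"median_{lab}"] = float(np.median(by_class[lab]))
        if len(labels) < 2:
            row["p_first"] = np.nan
            row["pairwise"] = "n.a."
        else:
            _, p_first = kruskal_wallis([by_class[lab] for lab in labels])
            row["p_first"] = p_first
            if p_first < alpha:
                parts = []
                for la, lb in combinations(labels, 2):
                    _, p = mww_pairwise(by_class[la], by_class[lb], sided=sided)
                    parts.append(f"{la} vs {lb}: p={p:.4g}")
                row["pairwise"] = "; ".join(parts)
            else:
                row["pairwise"] = "n.a."
        rows.append(row)
    return pd.DataFrame(rows)
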