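"""Surrogate-corrected interrelation matrices C (correlation) and M (mutual information).

For every moving window (4096 samples, shifted by 512) an ensemble of
pairwise interrelation values is computed on ``n_ens`` subsegments of
1024 samples distributed over the window with minimal overlap.  The same
ensembles are computed on IAAFT surrogates (univariate for C, multivariate
for M), yielding ``n_ens * n_surr`` null values per channel pair.  A
one-sided Mann-Whitney-Wilcoxon test on the absolute values, Bonferroni
corrected over the n(n-1)/2 pairs of the time step, sets the significance
factor s of each pair, and the corrected value is

    C = (rho - <rho_surr>) / (1 - <rho_surr>) * s

with rho the median of the original ensemble and <rho_surr> the median of
the surrogate ensemble (applied to magnitudes, sign restored; mu replaces
rho for the matrix M, after Joe's normalization sqrt(1 - exp(-2*I)) maps
the Kraskov-Stoegbauer-Grassberger MI estimate to [0, 1)).  Channel-wise
node strength, the sum of absolute incident matrix entries divided by
n - 1, reduces each matrix to one value per channel and time step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma
from scipy.stats import norm, rankdata

from .recording import Recording
from .surrogates import SurrogateConfig, iaaft_multivariate, iaaft_univariate
from .univariate import MeasureSeries, WindowGrid

try:  # compiled k-NN kernel; the numpy path below is the reference
    import numba as _numba
except ImportError:  # pragma: no cover - numba is a hard dependency normally
    _numba = None

__all__ = [
    "EnsembleConfig",
    "InterrelationResult",
    "subsegment_layout",
    "pearson_ensemble",
    "ksg_mutual_information",
    "joe_normalize",
    "corrected_matrix",
    "node_strength",
    "interrelation_series",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Moving-window and ensemble parameters for the C/M protocol."""

    window_len: int = 4096
    step: int = 512
    subsegment_len: int = 1024
    n_ens: int = 10
    n_surr: int = 10
    alpha: float = 0.05
    mi_k: int = 3
    mi_decimation: int = 1
    surrogate_max_iterations: int = 100
    store_matrices: bool = False

    def __post_init__(self) -> None:
        if self.subsegment_len > self.window_len:
            raise ValueError("subsegment_len must not exceed window_len")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_ens < 1 or self.n_surr < 1:
            raise ValueError("n_ens and n_surr must be >= 1")
        if self.mi_decimation < 1:
            raise ValueError("mi_decimation must be >= 1")


@dataclass
class InterrelationResult:
    """Per-window matrices of the corrected interrelation analysis (optional payload)."""

    kind: str
    grid: WindowGrid
    node_strength: np.ndarray
    corrected: np.ndarray | None = None
    raw_median: np.ndarray | None = None
    surrogate_median: np.ndarray | None = None
    significance: np.ndarray | None = None


def subsegment_layout(window_len: int, subsegment_len: int, n_ens: int) -> np.ndarray:
    """Start offsets of ``n_ens`` subsegments distributed over the window with minimal overlap."""
    if subsegment_len > window_len:
        raise ValueError("subsegment longer than window")
    span = window_len - subsegment_len
    if n_ens == 1:
        return np.array([span // 2])
    return np.round(np.arange(n_ens) * span / (n_ens - 1)).astype(int)


def pearson_ensemble(
    x: np.ndarray, y: np.ndarray, offsets: np.ndarray, subsegment_len: int
) -> np.ndarray:
    """Zero-lag Pearson coefficient of one channel pair on each subsegment.

    Subsegments where either channel has zero variance yield NaN (excluded
    from medians downstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.empty(len(offsets))
    for i, off in enumerate(offsets):
        xs = x[off : off + subsegment_len]
        ys = y[off : off + subsegment_len]
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            out[i] = np.nan
        else:
            out[i] = np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy)
    return out


def _corr_ensembles(W: np.ndarray, offsets: np.ndarray, T: int) -> np.ndarray:
    """Correlation matrices of all channels on each subsegment: (n_ens, n, n)."""
    n = W.shape[0]
    out = np.empty((len(offsets), n, n))
    for i, off in enumerate(offsets):
        seg = W[:, off : off + T]
        sd = seg.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(seg)
        c[~np.isfinite(c)] = np.nan
        c[sd == 0, :] = np.nan
        c[:, sd == 0] = np.nan
        out[i] = c
    return out


def ksg_mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    k: int = 3,
    rng: np.random.Generator | None = None,
) -> float:
    """Kraskov-Stoegbauer-Grassberger MI estimate (variant 1), in nats, clipped at 0.

    Chebyshev metric in the joint space; ``n_x``/``n_y`` count marginal
    neighbors strictly within the distance to the k-th joint neighbor.
    Duplicate values are broken by deterministic jitter at 1e-10 of the
    value range (seeded; the rank statistics of the estimator require
    distinct values).
    """
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    T = len(x)
    if len(y) != T:
        raise ValueError("x and y must have equal length")
    if T < k + 1:
        raise ValueError("need at least k+1 samples")
    if rng is None:
        rng = np.random.default_rng(987654321)
    for v in (x, y):
        if len(np.unique(v)) < T:
            ptp = float(np.ptp(v)) or 1.0
            v += rng.uniform(-1.0, 1.0, size=T) * 1e-10 * ptp
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    xs, ys = np.sort(x), np.sort(y)
    n_x = np.searchsorted(xs, x + eps, side="left") - np.searchsorted(xs, x - eps, side="right") - 1
    n_y = np.searchsorted(ys, y + eps, side="left") - np.searchsorted(ys, y - eps, side="right") - 1
    mi = digamma(k) + digamma(T) - np.mean(digamma(n_x + 1) + digamma(n_y + 1))
    return float(max(mi, 0.0))


def joe_normalize(mi: float | np.ndarray) -> float | np.ndarray:
    """Map an MI value (nats, >= 0) to [0, 1) via sqrt(1 - exp(-2*I)).

    For bivariate Gaussian data this equals |rho| exactly.
    """
    mi = np.clip(mi, 0.0, None)
    return np.sqrt(1.0 - np.exp(-2.0 * mi))


if _numba is not None:

    @_numba.njit(cache=False, fastmath=True)
    def _ksg_pair_sum(xi, xj, sorted_i, order_i, rank_i, sorted_j, k, psi_table):  # pragma: no cover
        """Sum over points of psi(n_x + 1) + psi(n_y + 1) for one channel pair.

        The k-th joint Chebyshev neighbor is found by sweeping outward from
        each point along the x-sorted order and stopping once the x-distance
        alone exceeds the current k-th best joint distance.
        """
        T = xi.shape[0]
        kbest = np.empty(k, dtype=np.float64)
        acc = 0.0
        for a in range(T):
            for q in range(k):
                kbest[q] = np.inf
            xa = xi[a]
            ya = xj[a]
            left = rank_i[a] - 1
            right = rank_i[a] + 1
            while True:
                dxl = xa - sorted_i[left] if left >= 0 else np.inf
                dxr = sorted_i[right] - xa if right < T else np.inf
                if dxl <= dxr:
                    if dxl >= kbest[k - 1]:
                        break
                    b = order_i[left]
                    left -= 1
                    dx = dxl
                else:
                    if dxr >= kbest[k - 1]:
                        break
                    b = order_i[right]
                    right += 1
                    dx = dxr
                dy = abs(xj[b] - ya)
                d = dx if dx > dy else dy
                if d < kbest[k - 1]:
                    q = k - 1
                    while q > 0 and kbest[q - 1] > d:
                        kbest[q] = kbest[q - 1]
                        q -= 1
                    kbest[q] = d
            eps = kbest[k - 1]
            n_x = (
                np.searchsorted(sorted_i, xa + eps, side="left")
                - np.searchsorted(sorted_i, xa - eps, side="right")
                - 1
            )
            n_y = (
                np.searchsorted(sorted_j, ya + eps, side="left")
                - np.searchsorted(sorted_j, ya - eps, side="right")
                - 1
            )
            acc += psi_table[n_x + 1] + psi_table[n_y + 1]
        return acc


def _mi_matrices(
    W: np.ndarray,
    offsets: np.ndarray,
    T: int,
    k: int,
    rng: np.random.Generator,
    decimation: int = 1,
) -> np.ndarray:
    """Joe-normalized KSG MI matrices on each subsegment: (n_ens, n, n).

    Batched implementation sharing per-channel distance matrices across
    pairs; numerically equivalent to :func:`ksg_mutual_information` on each
    pair (asserted in the test suite).  ``decimation`` > 1 estimates MI on
    every ``decimation``-th sample of each subsegment (scaled-down runs:
    fewer, less autocorrelated points).
    """
    n = W.shape[0]
    out = np.full((len(offsets), n, n), np.nan)
    n_pts = len(range(0, T, decimation))
    psi_table = digamma(np.arange(1, n_pts + 3))  # psi(m) at index m-1
    psi_kT = digamma(k) + digamma(n_pts)
    psi_lookup = np.concatenate([[np.nan], psi_table])  # psi(m) at index m
    iu, ju = np.triu_indices(n, 1)
    for s_idx, off in enumerate(offsets):
        seg = W[:, off : off + T : decimation].astype(np.float64)
        # deterministic tie-breaking jitter, only on channels with duplicates
        # (the estimator's boundary counts are sensitive to gratuitous jitter)
        jitter = rng.uniform(-1.0, 1.0, size=seg.shape)
        has_dup = np.array(
            [len(np.unique(row)) < row.shape[0] for row in seg], dtype=bool
        )
        if has_dup.any():
            ptp = np.ptp(seg, axis=1, keepdims=True)
            ptp[ptp == 0] = 1.0
            seg = seg + np.where(has_dup[:, None], jitter * 1e-10 * ptp, 0.0)
        mis = np.zeros(len(iu))
        if _numba is not None:
            seg_order = np.argsort(seg, axis=1)
            seg_sorted = np.take_along_axis(seg, seg_order, axis=1)
            seg_rank = np.empty_like(seg_order)
            np.put_along_axis(seg_rank, seg_order, np.arange(seg.shape[1])[None, :], axis=1)
            for p, (i, j) in enumerate(zip(iu, ju)):
                acc = _ksg_pair_sum(
                    seg[i], seg[j], seg_sorted[i], seg_order[i], seg_rank[i],
                    seg_sorted[j], k, psi_lookup,
                )
                mis[p] = max(psi_kT - acc / n_pts, 0.0)
        else:
            D = np.abs(seg[:, :, None] - seg[:, None, :]).astype(np.float32)
            for p, (i, j) in enumerate(zip(iu, ju)):
                Dij = np.maximum(D[i], D[j])
                eps = np.partition(Dij, k, axis=1)[:, k]  # k-th neighbor, self excluded
                n_x = np.count_nonzero(D[i] < eps[:, None], axis=1) - 1
                n_y = np.count_nonzero(D[j] < eps[:, None], axis=1) - 1
                mi = psi_kT - np.mean(psi_table[n_x] + psi_table[n_y])
                mis[p] = max(mi, 0.0)
        mu = joe_normalize(mis)
        out[s_idx][iu, ju] = mu
        out[s_idx][ju, iu] = mu
        np.fill_diagonal(out[s_idx], np.nan)
    return out


def _tie_term(row: np.ndarray) -> float:
    _, counts = np.unique(row, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t**3 - t))


def _mww_greater(
    A: np.ndarray,
    B: np.ndarray,
    rng: np.random.Generator | None = None,
    refine_threshold: float = 0.02,
    n_perm: int = 19_999,
) -> np.ndarray:
    """Row-wise one-sided MWW p-values testing that A's values exceed B's.

    Normal approximation with tie and continuity correction; rows where
    all values are tied (zero variance) get p = 1.  NaN entries are
    excluded row-wise.  Because the normal approximation cannot resolve
    p-values below its small-sample floor (which matters under Bonferroni
    correction), rows with approximate p below ``refine_threshold`` are
    refined by a seeded Monte-Carlo permutation test of the rank sum
    (minimum attainable p = 1/(n_perm + 1)).
    """
    P, na = A.shape
    nb = B.shape[1]
    comb = np.concatenate([A, B], axis=1)
    pvals = np.ones(P)
    nan_rows = np.isnan(comb).any(axis=1)
    clean = ~nan_rows
    if clean.any():
        sub = comb[clean]
        ranks = rankdata(sub, axis=1)
        R1 = ranks[:, :na].sum(axis=1)
        U = R1 - na * (na + 1) / 2.0
        n = na + nb
        mu = na * nb / 2.0
        ties = np.array([_tie_term(r) for r in sub])
        var = na * nb / 12.0 * ((n + 1) - ties / (n * (n - 1)))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (U - mu - 0.5) / np.sqrt(var)
        p = np.where(var > 0, norm.sf(z), 1.0)
        refine = (p < refine_threshold) & (var > 0)
        if refine.any():
            if rng is None:
                rng = np.random.default_rng(192837465)
            for row, r1 in zip(np.flatnonzero(refine), R1[refine]):
                row_ranks = ranks[row]
                # random na-subsets via top-na of random keys
                keys = rng.random((n_perm, n))
                idx = np.argpartition(keys, na, axis=1)[:, :na]
                r_star = row_ranks[idx].sum(axis=1)
                p[row] = (1 + np.count_nonzero(r_star >= r1)) / (n_perm + 1)
        pvals[clean] = p
    if nan_rows.any():
        from scipy.stats import mannwhitneyu

        for r in np.flatnonzero(nan_rows):
            a = A[r][np.isfinite(A[r])]
            b = B[r][np.isfinite(B[r])]
            if len(a) < 2 or len(b) < 2 or (np.ptp(np.concatenate([a, b])) == 0):
                pvals[r] = 1.0
            else:
                pvals[r] = mannwhitneyu(a, b, alternative="greater").pvalue
    return pvals


def corrected_matrix(
    orig_ensemble: np.ndarray,
    surr_ensemble: np.ndarray,
    alpha: float = 0.05,
    n_pairs: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Surrogate-corrected interrelation matrix for one time step.

    Parameters
    ----------
    orig_ensemble : (n_ens, n, n) symmetric matrices from the original data.
    surr_ensemble : (n_ens * n_surr, n, n) matrices from the surrogates.
    alpha : base test level; Bonferroni divided by ``n_pairs``.
    n_pairs : number of simultaneous pair tests (defaults to n(n-1)/2).

    Returns
    -------
    corrected, s, raw_median, surrogate_median : each (n, n); the corrected
    value is zero wherever the significance factor s is zero.
    """
    n = orig_ensemble.shape[1]
    if n_pairs is None:
        n_pairs = n * (n - 1) // 2
    iu, ju = np.triu_indices(n, 1)
    rho = np.nanmedian(orig_ensemble[:, iu, ju], axis=0)
    rho_s = np.nanmedian(surr_ensemble[:, iu, ju], axis=0)
    A = np.abs(orig_ensemble[:, iu, ju]).T  # (n_pairs_total, n_ens)
    B = np.abs(surr_ensemble[:, iu, ju]).T
    pvals = _mww_greater(A, B, rng=rng)
    s = (pvals < alpha / n_pairs).astype(float)
    s[~np.isfinite(rho) | ~np.isfinite(rho_s)] = 0.0

    mag_rho = np.abs(rho)
    mag_surr = np.abs(rho_s)
    denom = 1.0 - mag_surr
    with np.errstate(invalid="ignore", divide="ignore"):
        mag = np.where(denom > 1e-12, (mag_rho - mag_surr) / denom, 1.0)
    mag = np.clip(mag, 0.0, 1.0)
    vals = np.sign(rho) * mag * s
    vals = np.where(np.isfinite(vals), vals, 0.0)

    def _sym(flat: np.ndarray, fill: float = np.nan) -> np.ndarray:
        m = np.full((n, n), fill)
        m[iu, ju] = flat
        m[ju, iu] = flat
        np.fill_diagonal(m, np.nan)
        return m

    return _sym(vals, 0.0), _sym(s, 0.0), _sym(rho), _sym(rho_s)


def node_strength(matrix: np.ndarray) -> np.ndarray:
    """Normalized node strength: sum of absolute incident entries over n - 1."""
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if m.ndim != 2 or m.shape[1] != n or n < 2:
        raise ValueError("need a square matrix over at least 2 channels")
    work = np.abs(m.copy())
    np.fill_diagonal(work, 0.0)
    work = np.nan_to_num(work, nan=0.0)
    return work.sum(axis=1) / (n - 1)


def interrelation_series(
    recording: Recording,
    config: EnsembleConfig | None = None,
    kind: str = "C",
    seed: int | None = None,
) -> tuple[MeasureSeries, InterrelationResult]:
    """Moving-window node-strength series of the corrected matrix C or M.

    The node-strength series is *not* reference-normalized: the matrices
    are already normalized to [-1, 1] (C) or [0, 1] (M) and the strength
    to [0, 1] by the n - 1 divisor; saliency detection is scale-free.
    """
    if kind not in ("C", "M"):
        raise ValueError("kind must be 'C' or 'M'")
    if config is None:
        config = EnsembleConfig()
    X = recording.signals
    n_ch = recording.n_channels
    if n_ch < 2:
        raise ValueError("interrelation analysis needs at least 2 channels")
    grid = WindowGrid.over(
        recording.n_samples, config.window_len, config.step, recording.sampling_rate
    )
    offsets = subsegment_layout(config.window_len, config.subsegment_len, config.n_ens)
    T = config.subsegment_len
    scfg = SurrogateConfig(
        n_surr=config.n_surr, max_iterations=config.surrogate_max_iterations
    )
    rng = np.random.default_rng(seed)
    strengths = np.empty((n_ch, grid.n_windows))
    keep = config.store_matrices
    store = (
        {
            "corrected": np.empty((grid.n_windows, n_ch, n_ch)),
            "raw": np.empty((grid.n_windows, n_ch, n_ch)),
            "surr": np.empty((grid.n_windows, n_ch, n_ch)),
            "sig": np.empty((grid.n_windows, n_ch, n_ch)),
        }
        if keep
        else None
    )
    for w, start in enumerate(grid.starts):
        W = X[:, start : start + config.window_len]
        if kind == "C":
            orig = _corr_ensembles(W, offsets, T)
            surr_mats = []
            surr_set = np.stack(
                [iaaft_univariate(W[c], scfg, rng) for c in range(n_ch)]
            )  # (n_ch, n_surr, T_w)
            for r in range(config.n_surr):
                surr_mats.append(_corr_ensembles(surr_set[:, r, :], offsets, T))
            surr = np.concatenate(surr_mats, axis=0)
        else:
            orig = _mi_matrices(W, offsets, T, config.mi_k, rng, config.mi_decimation)
            surr_set = iaaft_multivariate(W, scfg, rng)  # (n_surr, n_ch, T_w)
            surr = np.concatenate(
                [
                    _mi_matrices(surr_set[r], offsets, T, config.mi_k, rng, config.mi_decimation)
                    for r in range(config.n_surr)
                ],
                axis=0,
            )
        Cmat, smat, raw_med, surr_med = corrected_matrix(orig, surr, config.alpha, rng=rng)
        strengths[:, w] = node_strength(Cmat)
        if keep:
            store["corrected"][w] = Cmat
            store["raw"][w] = raw_med
            store["surr"][w] = surr_med
            store["sig"][w] = smat
    series = MeasureSeries(
        measure_id=kind,
        values=strengths,
        grid=grid,
        channel_labels=recording.channel_labels,
        normalized=False,
    )
    result = InterrelationResult(
        kind=kind,
        grid=grid,
        node_strength=strengths,
        corrected=store["corrected"] if keep else None,
        raw_median=store["raw"] if keep else None,
        surrogate_median=store["surr"] if keep else None,
        significance=store["sig"] if keep else None,
    )
    return series, result
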