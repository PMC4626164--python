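# Methods

This note documents the models, estimators, numerical choices and scaled
problem sizes used by `periqeeg`, in enough detail to reproduce or audit
any stage.

## Signal conditioning and peri-ictal structure

Recordings are band-pass filtered between 0.5 and 150 Hz with a
4th-order Butterworth filter applied forward and backward
(`scipy.signal.sosfiltfilt`), which cancels phase distortion and squares
the magnitude response — the test tolerances on pass/stop-band gains
account for the two passes.  Rates above 512 Hz that are integer
multiples of 512 are decimated after a zero-phase 8th-order Butterworth
low-pass at 0.8× the new Nyquist frequency (the anti-aliasing choice is
ours; only *that* an anti-aliasing filter is needed is given).  Every
channel is then re-referenced against the per-sample median of the
artifact-free channels; artifact channels are excluded from the median
but still re-referenced, and all downstream statistics run on the n
artifact-free channels only.

The peri-ictal layout comprises a 60-s reference window starting 180 s
before the annotated onset, three 1-minute pre-ictal segments, six equal
ictal segments partitioning [onset, termination) — remainder samples go
to the earliest segments so the partition is exact — and three 1-minute
post-ictal segments.  The first/second half of the ictal segments form
the early/late ictal phases.  All intervals are 0-based half-open sample
ranges.  The reference lead, segment lengths and counts are parameters
of `plan_epochs`, because scaled-down synthetic runs (below) use a
shorter pre/post context.

## Univariate measures

**Absolute slope S** is the mean of |x(t+Δt) − x(t)|/Δt over the T−1
successive sample pairs of a T = 1024-sample window.  **Forbidden
ordinal patterns N** uses order d = 5, delay τ = 1: each of the
T − (d−1)τ maximally overlapping embedding vectors (oldest sample first)
is encoded as the permutation π of delay multipliers sorted ascending by
value, ties broken by time of appearance — the vector
(1.26, 6.38, 0.63, 1.26, 4.92) encodes to (2, 4, 1, 0, 3) — and
N = d! minus the number of distinct patterns.  Both series are computed
on a 1024-sample window moved in 512-sample steps; the step is our
alignment choice (it matches the C/M grid) since only the averaging
length is prescribed.  Both are normalized by the channel-wise *sample*
standard deviation (ddof = 1; the convention is not prescribed) of the
window values lying wholly inside the reference window; channels with
zero reference variability are set to missing with a warning.

## IAAFT surrogates

Univariate surrogates iterate (a) replacing Fourier amplitudes with the
original's and (b) rank-remapping onto the original sorted values,
starting from an independent random permutation per surrogate.  A
surrogate stops when its rank permutation is a fixed point, when its
periodogram is within a relative L2 tolerance of the original's, or
after `max_iterations` (default 100, best iterate returned).  The
tolerance default is 2e-3: white-noise windows plateau at ~1.3e-3, so a
tighter rule would never trigger; 2e-3 keeps the periodogram error far
below the 5% the test suite enforces while stopping within ~10-20
iterations.

Multivariate surrogates (Schreiber–Schmitz variant) initialize with a
single random phase vector added to *all* channels (DC and Nyquist bins
kept real), preserving relative Fourier phases and hence the linear
cross-correlation structure; each iteration finds, per frequency, the
common rotation closest to the current phases (circular mean of the
phase deviations), restores per-channel amplitudes, and rank-remaps per
channel.  Amplitude distributions are preserved exactly as multisets in
both variants.

## Interrelation matrices C and M

Windows of 4096 samples are moved in 512-sample steps.  Within each
window, n_ens = 10 subsegments of T = 1024 samples are placed with
minimal overlap (offsets round(i·(W−T)/(n_ens−1))).  Pearson
coefficients (for C) or Joe-normalized KSG mutual information (for M)
are computed per channel pair on each subsegment, and likewise on
n_surr = 10 surrogates (univariate for C, multivariate for M), giving
n_ens original and n_ens·n_surr null values per pair.

The significance factor s is 1 when a one-sided Mann-Whitney-Wilcoxon
test on the absolute values rejects at α/n_pairs (α = 0.05, Bonferroni
over n(n−1)/2 pairs per time step; sidedness and base level are our
choices).  The normal approximation with tie and continuity correction
cannot produce p-values below its small-sample floor, which sits near
the Bonferroni threshold at scaled ensemble sizes, so any pair with
approximate p < 0.02 is refined by a seeded Monte-Carlo permutation test
of the rank sum (19,999 permutations, minimum p 5e-5).  The corrected
value applies the baseline formula to magnitudes — (|ρ| − |ρ_surr|) /
(1 − |ρ_surr|), clipped to [0, 1] — with the sign of ρ restored; how the
baseline correction should treat negative ρ is not uniquely determined,
and this mirrored-magnitude rule is the package's documented choice.
Medians are used for ρ and ⟨ρ_surr⟩, consistent with the MWW framing.
Degenerate (all-tied or undefined) ensembles yield s = 0.  Node strength
Σ_{j≠i} |value_ij|/(n−1) reduces each matrix to one value per channel;
node-strength series are *not* reference-normalized (they are already
bounded and the Tukey fence is scale-free).

**KSG estimator.**  Variant 1 with Chebyshev metric: MI = ψ(k) + ψ(T) −
⟨ψ(n_x+1) + ψ(n_y+1)⟩ where n_x, n_y count marginal neighbors strictly
within the distance to the k-th joint neighbor; k = 3; negative
estimates are clipped to 0.  Duplicate values are broken by
deterministic seeded jitter at 1e-10 of the value range — applied *only*
when duplicates exist, because gratuitous jitter flips the estimator's
strict-inequality boundary counts.  The production path is a compiled
(numba) sweep along the x-sorted order, asserted in the tests to agree
with an independent kd-tree implementation; `mi_decimation` > 1
estimates MI on every k-th sample of a subsegment, which both reduces
cost and de-correlates the points (the estimator's bias under strong
autocorrelation is substantial at small sample counts).

## Saliency and zone statistics

Per time step, Q1 and Q3 of the cross-channel distribution (linear
interpolation between order statistics; the convention is configurable
because fence membership near the boundary depends on it) give the fence
Q3 + 1.5·IQR; channels strictly above it are salient, so at most ⌈n/4⌉
channels can be salient.  Missing values never count and steps with
fewer than 4 defined values yield no saliency.

For each zone Z ∈ {RBT, SOZ, OVL, NON} and step: F = n_{Z∩X}/n_X
(missing when n_X = 0), and the hypergeometric upper tail
P = Σ_{ν≥m} p(ν) with m the observed intersection, computed via
`scipy.stats.hypergeom` (log-gamma based; validated against exhaustive
subset enumeration for all n ≤ 12 in the tests); L = −log10 P.  Missing
F/L are excluded (not zero-filled) from all downstream means.

## Summaries and group statistics

Steps are assigned to peri-ictal segments by their window-end timestamp;
segment means over defined steps, phase means over segments, and the
seizure-wise peri-ictal mean over all 12 segment means (the radar-plot
"area" is monotone in this mean, so the mean itself is the summary).
95% CIs use mean ± 1.96·SEM over contributing steps.  Across outcome
classes, seizure-wise means enter a Kruskal-Wallis test; pairwise
Mann-Whitney tests (two-sided by default, exact for combined n ≤ 20
without ties) run only when the first level rejects at 0.05, and are
reported uncorrected as befits an explorative contrast.  Categorical
tables use the chi-square statistic with a permutation p-value from
10,000 random reallocations of the group labels.

## The synthetic recording generator

Background channels are stationary Gaussian AR(2) noise (coefficients
1.8857, −0.9025: spectral peak near 10 Hz at 512 Hz, modulus 0.95) — an
alpha-like background with nontrivial autocorrelation so that surrogate
correction is exercised meaningfully.  It is a stand-in, not a claim
about any patient population's spectra.

During [onset, termination) generator channels add, at amplitude
(gain − 1)·σ_background (default gain 4) with a ramp-up over the first
min(5 s, 20% of the seizure):

* a 3 Hz spike-and-wave component (sine plus a sharpened rectified
  harmonic), mixed from a shared drive and a channel-specific one with
  weights √c and √(1−c), c = `coupling_strength` (default 0.9) —
  producing high slope, reduced ordinal diversity and mildly elevated
  linear correlation;
* low-voltage fast activity: a 24 Hz channel-specific carrier (per
  channel frequency jitter and phase) amplitude-modulated by a burst
  envelope (0.02 + relu(sin θ)^6) tied to the shared spike-wave cycle.
  The envelope sharing creates genuinely *nonlinear* interdependence
  with near-zero linear cross-correlation — the kind of dependence the
  multivariate-surrogate-corrected M detects while C largely does not,
  matching the empirical ordering of the measures on clinical data.

All randomness flows from one seed through per-channel spawned
sub-streams, and the background is independent of zone placement, so the
favorable scenario (generators inside the resected set) and the
unfavorable one (resected set disjoint from the generators, same size)
share bit-identical signals and differ only in labels.  The synthetic
data are stationary Gaussian outside the seizure, contain no artifacts,
volume conduction, electrode geometry or inter-patient variability;
passing tests therefore demonstrate correctness of the *pipeline* and
recoverability of a planted contrast, not clinical performance.

## Scaled problem sizes

The full protocol is expensive (the multivariate surrogate plus k-NN MI
stage in particular), so the simulation studies run scaled-down
configurations, chosen by runtime arithmetic and kept fixed:

* **End-to-end contrast study** (tests and acceptance script): 16
  channels, 2 min pre / 1 min ictal / 2 min post, 3 generator channels,
  resected set of 4; S and N at full resolution; C/M-class measures on
  2048-sample windows stepped by 12,800 samples, subsegments of 1024
  decimated by 4 for MI (256 points), n_ens = 5, n_surr = 5, 10 IAAFT
  iterations.  Epochs: 60-s reference starting 120 s before onset,
  3×40-s pre and post segments.  20 seizures per scenario in the test
  suite, 10 in the acceptance script.
* **Type-I error study**: 16 independent white-noise channels, 60 s,
  C with the full window/ensemble protocol but n_surr = 5 and a 2-s
  step; 20 seeds in the suite, 5 in the acceptance script.

## Known limitations

* The negative-ρ branch of the baseline correction is a mirrored-
  magnitude stand-in (see above).
* The MWW-based significance factor is conservative for heavily tied
  ensembles (clipped-at-zero MI values).
* For strictly monochromatic signals the IAAFT null keeps a coherent
  tone with random phase, so large random correlations remain under the
  null and pairs driven by a pure sinusoid may legitimately fail to
  reach significance; finite-bandwidth drives do not have this issue.
* EDF files are supported as input (via `mne`) but not written; the
  plain HDF5 container plus TSV zone table is the native interchange
  format.
* Median re-referencing is nonlinear across channels and therefore does
  not commute with filtering; the pipeline fixes the order: filter,
  then re-reference.
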