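# periqeeg

Peri-ictal quantitative EEG analysis for epilepsy surgery evaluation:
channel-wise qEEG measures in moving windows, data-driven detection of
*salient* channels, and hypergeometric over-representation of salient
channels within anatomically defined channel zones — the resected brain
tissue (RBT), the seizure onset zone (SOZ), their overlap (OVL) and the
complement (NON) — plus group-level nonparametric comparisons across
surgical-outcome classes.

The package is aimed at researchers in computational neurophysiology who
want to relate intracranial EEG (iEEG) dynamics around seizures to the
spatial extent of a resection, and at methodologists who need a tested
reference implementation of the underlying signal statistics.  Because
clinical iEEG cannot be redistributed, a synthetic-recording generator
with ground-truth zones is a first-class part of the package.

## The measures and statistics

Four measures are computed per channel in moving windows and separated
into *salient* vs normal channels at each time step:

* **S — absolute signal slope.**  Mean of |x(t+Δt) − x(t)|/Δt over a
  2-s window (the "line length" feature up to scale); sensitive to both
  slow high-amplitude and fast low-amplitude epileptiform activity.
* **N — number of forbidden ordinal patterns.**  Each embedding vector
  of d = 5 delayed samples (τ = 1) maps to the permutation of its rank
  order (ties broken by time of appearance); N = 5! minus the number of
  distinct patterns observed in the window, a measure of determinism.
  S and N are normalized by their channel-wise standard deviation over a
  60-s pre-ictal reference window.
* **C — surrogate-corrected cross-correlation strength.**  Zero-lag
  Pearson coefficients on ensembles of subsegments, compared against
  univariate IAAFT surrogates (which preserve each channel's amplitude
  distribution exactly and power spectrum approximately):

      C = (ρ − ⟨ρ_surr⟩) / (1 − ⟨ρ_surr⟩) · s,

  where ρ and ⟨ρ_surr⟩ are ensemble medians and the significance factor
  s ∈ {0, 1} comes from a one-sided Mann-Whitney-Wilcoxon test with
  Bonferroni correction over the n(n−1)/2 channel pairs of each time
  step.  The matrix is reduced to a per-channel node strength
  Σ_j |C_ij| / (n−1).
* **M — surrogate-corrected mutual information.**  Same protocol with μ,
  the Kraskov–Stögbauer–Grassberger k-NN estimate (k = 3) mapped to
  [0, 1) by Joe's normalization √(1 − e^(−2I)), and *multivariate* IAAFT
  surrogates that additionally preserve linear cross-correlations — so M
  reflects interdependence beyond a stationary linear Gaussian process.

Per time step, channels above the upper Tukey fence Q3 + 1.5·IQR of the
cross-channel distribution are salient.  For each zone Z the fraction
F = n_{Z∩X}/n_X of salient channels inside Z and the hypergeometric
upper-tail probability P of that overlap (reported as L = −log10 P) are
computed, summarized per peri-ictal phase (3×1 min pre-ictal, six equal
ictal segments, 3×1 min post-ictal) and per seizure, and compared across
outcome classes with Kruskal–Wallis plus conditional pairwise
Mann-Whitney tests.

## Worked example

```python
from periqeeg import (EnsembleConfig, PeriIctalAnalysis, SimulationConfig,
                      make_scenario)

base = SimulationConfig(
    n_channels=16, pre_s=120, ictal_s=60, post_s=120,
    generator_channels=(0, 1, 2), rbt_channels=(0, 1, 2, 3),
    soz_channels=(0, 1, 2), reference_lead_s=120.0, seed=11,
)
model = PeriIctalAnalysis.from_simulation(
    make_scenario("favorable", base),
    measures=("S", "N", "M"),
    epoch_params={"reference_lead_s": 120.0, "pre_segment_s": 40.0,
                  "post_segment_s": 40.0},
    ensemble_config=EnsembleConfig(
        window_len=2048, step=12800, subsegment_len=1024, n_ens=5,
        n_surr=5, mi_decimation=4, surrogate_max_iterations=10),
    seed=3,
)
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Peri-ictal quantitative EEG saliency analysis
=============================================================
channels (artifact-free):  16
sampling rate:             512 Hz
seizure interval:          [120.0, 180.0) s (60.0 s)
measures:                  S, N, M
zones:                     RBT=4, SOZ=3, OVL=3, NON=12, Jaccard=0.750

Seizure-wise peri-ictal means (over the 12 segment means)
-------------------------------------------------------------
 measure  zone    mean F    mean L
       S   RBT     0.512     1.084
       S   SOZ     0.512     1.387
       ...
       M   RBT     0.500     0.535
```

Here `mean F` for zone RBT is the seizure-wise mean fraction of salient
channels that lie in the simulated resection: in this *favorable*
scenario (all epileptogenic generator channels resected) roughly half of
the salient channels fall inside the RBT, while the matching
*unfavorable* scenario — identical signals, resection moved away from
the generators — yields means around 0.09-0.23.  `mean L` is the mean
log-probability of the zone overlap; values above −log10(0.05) = 1.30
indicate more salient channels in the zone than expected by chance.
`results.zone_stats` carries the full per-time-step table and
`results.save(outdir)` writes everything as TSV plus a JSON manifest.

A thin CLI covers the same pipeline for file-based use:

```bash
periqeeg simulate --scenario favorable --out rec.h5 --zones-out zones.tsv
periqeeg run --recording rec.h5 --zones zones.tsv --measures S,N --outdir out/
periqeeg zones --zones zones.tsv
periqeeg summarize --table runs.tsv
```

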