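# megnet

Frequency-resolved functional brain networks from resting-state MEG source
series: weighted phase lag index (wPLI) connectivity called against a
phase-randomized surrogate null, graph construction under an S-exponent
density criterion, rich-club topology with randomized-network normalization,
and small-cohort statistics relating alcohol-naïve network properties to
future drinking.

The package is aimed at researchers analysing source-reconstructed
electrophysiology (ROI × time matrices) who want a tested, seedable
implementation of this pipeline, plus a synthetic-data module that plants
known coupling structure so every stage can be validated end to end without
any recordings.

## The method

For each subject, every pair of ROI source series *x, y* is summarized by
the weighted phase lag index over Welch segments (2 s Hann tapers, 50%
overlap, 1–80 Hz at 0.5 Hz):

```
wPLI(f) = | E_seg[ Im S_xy(f) ] | / E_seg[ | Im S_xy(f) | ]
```

wPLI is insensitive to source amplitude and to zero-lag (volume-conduction
like) coupling. Its sampling distribution under no coupling is estimated per
subject from a surrogate ensemble: 5,000 unique (ROI pair, realization)
draws of phase-randomized series (amplitude spectra preserved exactly,
phases i.i.d. uniform with conjugate symmetry), pooled into a per-frequency
mean μ(f) and SD σ(f). A pair's connection is called at the frequency
maximizing

```
z(f) = (wPLI(f) − μ(f)) / σ(f)
```

and discarded unless max z ≥ 2.5 SD. Gated candidates are then thresholded
to the density implied by S = log(N)/log(K) with S = 2.5 — average degree
K = N^(1/S), so a 41-node network keeps E = round(N·K/2) = 91 edges — by
retaining the E candidates with the largest z.

The binary graph is characterized by: mean clustering coefficient, global
efficiency, degree assortativity, Louvain module count (averaged over 500
runs), hubs (top 10% of nodes by degree; n = 4 at N = 41), per-edge
connection frequencies (mean and canonical band counts), and the rich club:
φ(k) = density among nodes of degree > k, normalized by its mean over 500
Maslov–Sneppen degree-preserving rewirings; the club is read off at the k
maximizing normalized φ, reporting its node count, minimum degree and
normalized coefficient.

Group statistics follow the study design the pipeline targets: paired
t-tests on metric change and on hub / rich-club membership-count
distributions across regions (bilateral ROI aspects collapsed by logical
OR), exact McNemar tests of per-region membership change, Spearman
correlations (exact permutation p at n ≤ 8) between baseline metrics and
drinking (g/kg per day), and Cohen's d effect sizes.

## Worked example

`examples/` holds one short script per capability. For instance:

```
$ python examples/06_published_checks.py
rich-club membership change: t(9) = 2.74, p = 0.023
hub membership change:       t(5) = 1.37, p = 0.229
free-access intake: mean 4.7 g/kg, SD 1.0
  one-sample d vs 1.5 g/kg induction dose: 3.09
```

The rich-club membership counts across regions became significantly less
consistent between the alcohol-naïve and free-access timepoints, while the
hub distribution did not change reliably; the intake summary reproduces the
published cohort mean/SD.

```
$ python examples/05_cohort_statistics.py   # (abridged)
baseline-metric vs drinking screen (Spearman, exact p at n=6):
                           rho      p
rich_club_min_degree     -0.97  0.003
...
The planted association shows up as a negative Spearman rho (-0.97)
between baseline rich-club minimum degree and intake.
```

Here six synthetic subjects carry planted rich clubs of minimum degree 3–8
whose outcome is negatively coupled to the planted degree; the full
pipeline (surrogate null → gate → threshold → rich club → Spearman screen)
recovers the negative association from the raw series alone.

## Layout

- `src/megnet/synthetic.py` — coupled-oscillator series, toy graphs, cohorts
- `src/megnet/connectivity.py` — cross-spectra, wPLI, surrogates, gating
- `src/megnet/network.py` — S-exponent density thresholding
- `src/megnet/metrics.py` — topology metrics, rich club, hubs, bands
- `src/megnet/stats.py` — paired t, exact McNemar, exact Spearman, Cohen's d
- `src/megnet/pipeline.py`, `io.py` — orchestration, config, TSV/HDF5/JSON I/O
- `src/megnet/published.py` — published group-level tables as statistical inputs
- `docs/methods.md` — model assumptions, parameter choices, limitations
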