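# Methods

## Pipeline model and assumptions

The pipeline operates on per-subject ROI source series (real matrix,
ROI × samples, with sampling rate and labels) and assumes the upstream
source reconstruction (beamforming, co-registration, artifact screening) has
already happened. Connectivity is purely phase-based: the weighted phase
lag index (wPLI) over segmented cross-spectra,

    wPLI(f) = |E_seg[Im S_xy(f)]| / E_seg[|Im S_xy(f)|],

which discards zero-lag coupling by construction. The estimator assumes
approximate stationarity across segments and needs enough segments for the
segment average to be meaningful; the implementation refuses fewer than 8
segments and the wPLI itself is undefined below 2.

### Spectral estimator

The underlying spectral machinery is Welch-style: 2 s Hann-tapered segments
at 50% overlap, giving a 0.5 Hz grid restricted to 1–80 Hz. The source
study does not state its estimator; segmented averaging is the standard
substrate for wPLI and yields 59 segments per minute of data. All of
`SpectralParams` is configurable, with `grid_step` pinned to
1/segment-length so configurations stay self-consistent.

### Surrogate null and gating

Each subject's null is built from phase-randomized surrogates
(amplitude spectrum preserved exactly, uniform phases with conjugate
symmetry, DC/Nyquist untouched). A draw is one unordered ROI pair (chosen
at random from the subject's pairs) with fresh independent randomizations of
both series; draws are unique by construction because every draw has a
distinct realization index. The default ensemble is 5,000 draws, pooled —
per subject, not per pair — into μ(f) and σ(f). A per-pair null is
available (`pair=` argument) but is not the default. z-scores use the σ of
each frequency separately. Connections are called at argmax z (ties to the
lowest frequency, deterministically) and gated at 2.5 SD.

Two properties of this design matter for interpretation:

- z_max is a maximum over ~159 grid frequencies, so under no coupling its
  distribution sits around 2.5–4 SD and most noise pairs pass the gate.
  The gate is a noise floor for *per-frequency* excess, not a family-wise
  test; the density threshold downstream is what fixes the edge budget.
  Per-frequency calibration is what the tests assert (the exceedance rate
  of z at a single fixed frequency stays within the binomial envelope of
  the one-sided normal tail).
- On strictly periodic noiseless signals the surrogate transform preserves
  the (constant) phase relation of a shared sinusoid, so a subject whose
  series contain nothing but planted sinusoids has a degenerate null
  (σ = 0 at uncoupled frequencies — rejected with an explicit error) and a
  2-ROI set's pooled null absorbs its own coupling. Null validity therefore
  requires broadband noise and several ROIs, which all defaults provide.

### Density thresholding

The density criterion S = log(N)/log(K) with S = 2.5 fixes the average
degree K = N^(1/S) and edge budget E = round(N·K/2) (half-up rounding;
at N = 41, 90.55 → 91). Candidates are ranked by gate effect size z — the
only effect size the pipeline defines — with ties broken by lower
connection frequency, then label order. Gating precedes densification: if
fewer than E candidates pass 2.5 SD the network is left sparser than S
requires and flagged, rather than relaxing the noise floor.

### Metrics

Clustering (per-node triangle density averaged over nodes, zero for degree
< 2), global efficiency (mean inverse shortest path, zero for disconnected
pairs) and Louvain communities are delegated to networkx; assortativity is
computed directly as the Pearson correlation of endpoint degrees over both
edge orientations (NaN on regular graphs, where it is undefined). Louvain
is run 500 times by default, reporting the mean module count (every node
assigned; isolates are their own modules) and mean modularity.

The rich club uses φ(k) = 2·E_{>k}/(N_{>k}(N_{>k}−1)) over nodes of degree
> k, for every k with at least two such nodes, normalized by the mean φ
over 500 Maslov–Sneppen degree-preserving rewirings (10 attempted swaps per
edge, failed swaps skipped — the standard normalization conditioning on the
degree sequence). The source description reports a single club per network
without stating the selection rule; here the club level k* is the argmax of
normalized φ (ties to the smallest k), the members are exactly the nodes of
degree > k*, and the reported coefficient is the normalized value at k*.
Levels where the rewired mean is zero but the real curve is positive
normalize to +inf (maximally differentiated); levels where both are zero
are not selectable.

Hubs are the max(1, floor(0.10·N)) highest-degree nodes (ties by label) —
4 nodes at N = 41. Band counts use delta [1,4), theta [4,8), alpha [8,13),
beta [13,30), gamma [30,80] Hz (half-open, top edge closed); the counted
edge set is configurable between gated candidates (default) and the
thresholded network, because published per-band counts at the study's scale
(≈260 at baseline) are consistent only with pre-threshold counting while
the thresholded network holds ≈91 edges.

### Group statistics

Paired t-tests are two-tailed with df = n−1; zero difference variance is
flagged, not silently zero. McNemar is exact by default —
min(1, 2·BinomCDF(min(b,c); b+c, ½)) on the discordant counts — because the
asymptotic chi-square version is invalid at six subjects; the
continuity-corrected chi-square form is available behind a flag. Spearman
p-values are exact by full permutation for n ≤ 8 (720 orderings at n = 6)
and fall back to the t approximation above. No multiplicity correction is
applied by default, matching the analysis design the pipeline mirrors; Holm
step-down adjustment is available as an option. Cohen's d is offered in
paired and one-sample forms because the published intake effect size does
not state its baseline; the one-sample reading against the 1.5 g/kg final
induction dose gives d ≈ 3.09, which does not reproduce the printed 5.23
under either form — the package exposes the computations and asserts
neither.

## Synthetic data: what it emulates and what it does not

Oscillators are pure sinusoids with constant phase offsets, one per planted
edge, plus independent Gaussian noise per channel. This makes the wPLI
limit exact and testable (noiseless constant non-zero lag ⇒ wPLI = 1 at the
planted bin) but is not a claim about MEG statistics: real source series
are broadband and nonstationary, their surrogate nulls are narrower, and
their connection frequencies are not isolated spectral lines. Consequences
built into the generator:

- Coupling frequencies are assigned on a 1.5 Hz grid (three analysis bins
  apart, 3–79 Hz, 51 slots). An on-bin sinusoid under a Hann taper leaks
  into exactly one bin on either side; closer spacing lets two unrelated
  edges deposit constant-phase energy in a shared bin and manufacture a
  phantom connection between their endpoints. Graphs needing more than 51
  oscillators are rejected rather than reusing frequencies (reuse plants
  phantom couplings between all endpoints of the sharing edges).
- "Noiseless" end-to-end recovery is exercised at high SNR (noise SD 0.05,
  amplitude 1) rather than exactly zero noise, because a strictly periodic
  noiseless subject has a degenerate surrogate null by the pipeline's own
  σ > 0 requirement.

Cohorts plant, per subject, a rich club as a clique of size (minimum degree
+ 1) over 30 ROIs with a 12-node degree-2 ring periphery (remaining
channels pure noise), realized as couplings and generated at 200 Hz for
60 s — 59 Welch segments, enough for planted-edge z (≈6–9) to separate
cleanly from the max-statistic noise floor (≈4–5). The follow-up timepoint
re-realizes a degree-preserving rewiring of the baseline graph, emulating
membership reorganization without a degree-sequence change. The outcome is
intercept + slope·(planted minimum degree) + Gaussian noise on the g/kg
scale; defaults (intercept 4.7, slope −0.35, noise SD 0.15, planted degrees
3–8) put outcomes in the published intake range with the planted negative
association dominating the noise. The density threshold back-fills the edge
budget (58 edges at N = 30) with weak noise candidates beyond the planted
edges; this inflates recovered club degrees by a subject-dependent amount
and is the main reason recovered−planted rank agreement is strong but not
perfect. Passing tests therefore demonstrate correctness of the estimators
and the recoverability of planted structure under the stated conditions —
not performance on real MEG.

All generators draw every random quantity through a single documented
seed-splitting scheme (`megnet._seeds`: SeedSequence with CRC-32-hashed
spawn keys), so any subject, stage or draw is independently reproducible.

## Problem sizes in tests and the acceptance script

The library defaults mirror the study constants (5,000 surrogate draws,
500 rewired networks, 500 Louvain runs). The validation suite runs reduced
but statistically adequate sizes chosen once: 100–400 surrogate draws
(400 where exact edge-set recovery is asserted, because σ(f) estimation
noise inflates the max-statistic of noise pairs), 100 rewirings in the
100-cohort phenotype screen, 25–200 elsewhere; cohorts use 6 subjects ×
60 s × 200 Hz. The acceptance script reports, per quantity, the problem
size it used.

## Known limitations

- The sinusoid+noise generator cannot probe amplitude nonstationarity,
  1/f backgrounds, or volume-conduction leakage between ROIs.
- Rich-club extraction at argmax normalized φ is one defensible reading of
  "the" rich club; published per-network club statistics could derive from
  a different selection rule, so those values are treated as context, not
  reproduction targets.
- With six subjects the Spearman screen has a coarse exact p-value lattice
  (multiples of 1/720) and low power; the pipeline reports it as designed
  rather than attempting shrinkage or pooling.
- Weighted-graph variants (weighted clustering/efficiency, strength-based
  hubs) are out of scope; edges carry frequency and z annotations only.
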