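# Methods

This note documents the models, procedures, numerical choices and known
limitations of `lgpc`. It is written for users who want to understand what
the package computes and what passing its tests does — and does not — show.

## The paradigm and its regularity statistics

Each trial delivers five 50 ms tones with a 150 ms inter-tone interval; the
first four are identical (tone x) and the fifth either repeats (xx
sequence) or deviates (xy). Blocks of 100 trials begin with 20 habituation
presentations of the block's standard sequence followed by a shuffled
mixture of 64 standard and 16 deviant sequences; inter-sequence gaps are
drawn uniformly from 950–1150 ms using the block seed. Crossing the
within-trial (local) and across-trial (global) regularities yields the
four trial types xx|xx, xy|xx, xy|xy, xx|xy.

Two statistics summarize a block:

* **Transition probability (TP, `q`)** — the probability of an x→y tone
  transition, counted over *all four* within-sequence transitions of every
  counted trial. This convention, rather than using only the 4→5
  transition, is what makes TP (0.05 in an xx block) differ from the
  fifth-tone deviance rate (0.2) and gives the second level something to
  predict. For the default mixture it gives q = 16/320 = 0.05 (xx block)
  and q = 64/320 = 0.20 (xy block).
* **Sequence probability (SP, `d`)** — the probability of the block's rare
  sequence: 16/80 = 0.2 in both contexts.

Habituation trials are excluded from both estimators by default (the
regularities they establish are what the mixture is measured against); a
flag includes them, in which case d = 0.16.

## The hierarchical predictive-coding model

The model describes steady-state signaling during the fifth tone after
both regularities have been learned. Three levels (sensory S, local 1,
global 2) by two streams (x, y):

* Sensory drive: `I_x = s0` if the fifth tone is x, else 0; `I_y = 1` if
  it is y, else 0. The factor `s0 ∈ [0, 1]` expresses adaptation of the
  repeated tone (1 = no adaptation, i.e. full sensory sensitivity).
* Level-1 prediction (MSE-optimal conditional expectation scaled by `s1`):
  `P1_x = s1 (1−q) s0`, `P1_y = s1 q`. The x-stream target is the
  *adapted* input `(1−q)s0` — adaptation precedes prediction; a switch
  (`adapt_before_predict=False`) exposes the `(1−q)` alternative.
  Signed level-1 errors: `e1_s = I_s − P1_s`.
* Level-2 prediction targets the level-1 error signal expected under the
  block's sequence mix: `P2_s = s2 [(1−d) e1_s(standard) + d e1_s(deviant)]`,
  with d fixed at the design value 0.2 for both contexts. Signed level-2
  errors: `e2_s = e1_s − P2_s`.

Errors propagate *signed* between levels; the observables are magnitude
sums, `PE1 = |e1_x| + |e1_y|` and `PE2 = |e2_x| + |e2_y|`, because
spectral-power contrasts are magnitudes. `s1 = s2 = 1` are optimal
predictions; values below 1 under-predict ("hypo"), above 1 over-predict
("hyper"). The 2×2 contrast design matrix A has rows c1 = xy|xx − xx|xx
and c2 = xy|xy − xx|xy and columns (PE1, PE2); for (s0, s1, s2) =
(0.4, 0.85, 0.75) it equals [[1.1610, 0.92025], [0.8040, −0.4290]].
These formulas are isolated in `lgpc.model` so an alternative formulation
can be swapped at one point; an independent brute-force enumerator in the
test suite reproduces them to 1e−12.

### Identifiability of the scaling factors

Two structural facts about this model matter for interpreting grid-search
results:

1. **Exact degeneracy at s1 = 1.** When the local prediction is optimal,
   every stream error — and hence every PE value and the whole matrix A —
   scales by the common factor (1 + s0). Since a global scale of the fixed
   Contrast factor is absorbed by the free IC loadings, RSS and core
   consistency are *constant in s0* along the s1 = 1 grid line: s0 cannot
   be recovered there. The benchmark triple (0.95, 1.0, 1.7) is kept in
   the recovery study precisely to document this behavior.
2. **Near-degeneracy elsewhere.** Fit quality identifies A only up to
   per-column scaling, and the map (s0, s1, s2) → A-up-to-column-scaling
   is poorly conditioned: adjacent cells of the 21×21×21 grid differ by
   only ~0.3% in relative model distance, and some *distant* cells (e.g.
   (0.8, 0.5, 0.6) vs (0.4, 0.8, 0.7)) are column-proportional to within
   1–2%. Exact-cell recovery therefore requires contrast-level noise well
   below 0.1% of signal; at realistic noise the recovered optimum can sit
   far from the generating parameters while fitting essentially as well.
   This weak determination is a property of the method, not of the
   implementation, and is worth bearing in mind when interpreting fitted
   scaling factors on real data.

## Spectral analysis

Per-trial time-frequency power is computed with 7-cycle Morlet wavelets at
1–150 Hz (1 Hz steps) on 300 Hz signals spanning −0.3 to 1.7 s around
first-tone onset (fifth-tone onset at 0.8 s), giving the standard 150×600
grid, then converted per frequency to dB against the −0.3–0 s baseline of
the same trial (a per-condition-average baseline is available as a flag).
The wavelet transform delegates to `mne.time_frequency.tfr_array_morlet`
with zero-padding to cover the longest wavelet; frequencies whose wavelet
support exceeds the epoch are retained and flagged (`edge_flags_`), not
masked. Two caveats any user of single-trial dB maps should know: the mean
of dB values over noise is negative (chi-square log bias, about −2.5 dB
for single trials), and a single-trial baseline has few effective degrees
of freedom after wavelet smoothing, which biases dB maps slightly
positive; the tests therefore check "no offset" claims on the power-ratio
scale. A polyphase resampler (`resample_to`, Kaiser-windowed FIR) is
provided as plumbing for data at other acquisition rates.

## Deviant detection

Deviant responses are per-bin two-sample pooled-variance t maps of the two
contrasts, corrected by a cluster-based permutation test: cluster-forming
threshold at the two-sided per-bin α = 0.05 t-quantile, 4-connectivity on
the frequency×time grid, cluster mass = summed t, and a max-|mass| null
over 500 full trial-relabelings pooled across positive and negative
clusters (separate signed clusters, one two-sided null). Corrected
p-values use the (1 + exceedances)/(n_perm + 1) estimator; non-significant
bins are zeroed with cluster signs preserved. An IC is *significant* if
either contrast contains at least one cluster with corrected p ≤ α.
FieldTrip's implementation leaves the cluster-forming threshold and
connectivity unstated in the protocol we follow; the values above are this
package's documented defaults. Note that selection controls the error rate
per IC×contrast: with many signal-free ICs, ~5% of them will be selected
by chance, which is expected behavior, not a defect.

## Tensor decomposition and grid search

Masked deviant maps of the significant ICs form the 2 × n_sig × (F·T)
tensor (frequency-major flattening, recorded in metadata). The rank-2 CP
decomposition fixes the Contrast factor A to the model matrix and updates
only the IC loadings B and spectro-temporal loadings C by alternating
least squares, unconstrained, stopping when the relative change in fit
falls below 1e−6 (default cap 500 iterations). Two starts are run and the
better RSS kept: a deterministic start (project the tensor onto pinv(A)
along the Contrast mode and take the dominant rank-1 structure of each
component slab) and one seeded random start — the classical direct
trilinear initialization is ill-posed with a length-2 fixed mode. The
B/C scale indeterminacy is fixed by unit-norm C columns; RSS is invariant
to this and to column scaling of A. RSS is non-increasing over ALS
iterations.

Core consistency treats the fixed A as an ordinary factor: the
least-squares Tucker core G given (A, B, C) is compared to the
superdiagonal identity T, cc = 100·(1 − ‖G − T‖² / ‖T‖²). Exact rank-2
structure gives ≈100; a rank-3 tensor forced into the rank-2 fit falls
well below 80; degenerate loadings give NaN (reported, not silently
dropped).

The grid search fits every combination of s0 ∈ {0, 0.05, …, 1} and
s1, s2 ∈ {0, 0.1, …, 2} — 21³ = 9261 models — using a batched ALS that
updates all cells simultaneously (identical results to per-cell fits;
evaluation order irrelevant). Cells whose A is singular (s2 = 0 collapses
the PE2 column onto PE1; (1, 0, 0) zeroes A) are recorded as invalid with
infinite RSS rather than fitted. The best model is the minimum-RSS cell
among those with core consistency strictly above the threshold (default
80%); an empty qualifying set returns an explicit empty result, never a
silently relaxed one.

## Post-hoc summaries

Joint topography averages per-IC normalized |spatial coefficients|
(|·|/max per IC); regional fractions divide the in-region sum by the total
over electrodes. Peak latency is the post-fifth-tone argmax of the
frequency-averaged |map| (ties toward earlier bins); mean frequency is the
amplitude-weighted mean of the time-averaged |map|. Component brain maps
combine normalized IC maps weighted by |B| loadings.

Single-trial projections compute S·ERSP·FT per component: IC weights
S = |B|ᵀ, and FT the across-dataset average of each component's
normalized spectro-temporal map gated by the high-gamma mask — the top 75%
of values at frequencies above 40 Hz, interpreted as the 25th-percentile
threshold within that region (reference order: normalize → average →
mask). The default FT is the mask-gated *weighted* structure; a binary
mask is available via the same functions. Variability statistics follow
the averaged-first convention: per-type means and SDs are averaged across
types per component, CV = averaged SD / averaged mean, and the signal
variability SV is the mean SD across components and types. The
sensitivity sweep repeats best-model selection at thresholds 40–100% in
1% steps (61 rows), recording the selected parameters and SV (projections
cached per selected cell); thresholds with no qualifying model produce NaN
rows. Group comparisons use two-sided Wilcoxon rank-sum (unpaired,
midranks for ties, exact for small samples) and signed-rank (paired)
tests with Bonferroni correction over the pairwise family; all-equal
degenerate inputs report p = 1.

## Synthetic data

The generator plants the structure the analysis assumes: per trial j of
type τ,

    ERSP_j(ic, f, t) = Σ_k g_{j,k} · m_k(τ) · w_k(ic) · K_k(f, t) + ε,

with m_k the model PE magnitude of type τ under the planted scaling
factors, w_k nonnegative IC loadings, K_k unit-energy separable Gaussian
spectro-temporal kernels (defaults: PE1 at 65 ms / 95 Hz, PE2 at
100 ms / 90 Hz after fifth-tone onset, SDs 20 ms / 10 Hz — PE1 earlier
and more posterior than PE2), g log-normal trial gains with mean 1
(natural-scale SD `trial_gain_sd`), and ε white Gaussian noise on the dB
scale. The baseline period carries pure noise. Default loadings place PE1
on posterior-labeled ICs and PE2 on anterior ones with overlap in the
middle; default region labels split a 96-electrode array into
pTC/aTC/aPFC/other blocks. An optional extra kernel acts as a nuisance
component for rank-misspecification studies. `simulate_timeseries`
produces raw 300 Hz source signals (Gaussian-envelope narrow-band bursts
on white noise) whose Morlet ERSP reproduces the planted peaks, for
end-to-end tests of the spectral stage.

What the generator does *not* emulate: raw mixed-channel ECoG, ICA
unmixing, realistic 1/f background and artifacts, correlated noise across
bins/ICs, or learning dynamics across trials. Passing tests on this data
therefore validates the analysis machinery — contrasts, significance
masking, decomposition, projection, sweep — not the biological realism of
any recovered parameter value.

### Study conditions and problem sizes

Reduced-resolution studies use a grid zoomed on the post-fifth-tone gamma
region (40–150 Hz × 0.75–1.15 s) rather than a coarsened full epoch: at
30 full-epoch bins the 67 ms spacing cannot resolve the two kernels 35 ms
apart, which would destroy identifiability for reasons unrelated to the
machinery under test.

* **Default dataset conditions** (deviant detection, variability studies):
  128 trials per type, noise SD 0.25 dB, gain SD 0.1 — cluster masks then
  cover the kernel supports and core consistency sits comfortably above
  80%.
* **Recovery benchmark** (`lgpc.benchmarks.recovery_config`): 16×24 ROI
  grid, 128 trials per type, loadings scaled so planted peak contrasts are
  ~1.5–2 dB (the size of observed deviant responses), noise SD 0.005 dB
  and gain SD 0.005. The near-noise-free regime follows from the
  identifiability analysis above: it is the regime in which exact
  grid-cell recovery is a determinate outcome, and the benchmark's purpose
  is to verify the machinery, not to simulate recording noise. At
  realistic noise the same harness shows graceful degradation to
  nearby-or-column-proportional cells.
* **Null calibration**: 200 simulations of 20-vs-20 pure-noise trials on a
  12×25 grid with 200 permutations.
* **Two-group variability study**: unexposed-like (s0=0.4, s1=0.8, s2=0.7,
  gain SD 0.1) vs VPA-like (s0=0.75, s1=0.3, s2=0.2, gain SD 0.5)
  configurations, 64 trials per type; the group contrast is evaluated by a
  two-sided rank-sum test on trial-level absolute deviations from the
  per-type mean (a scale test on trials) together with the SV ordering.
  Comparing SV distributions across the 61 sweep models per group, as one
  would across subjects, is not meaningful within a single synthetic
  repetition and is left to multi-dataset analyses.

## Known limitations

* The supplementary closed-form equations of the published model variant
  were not available; the reference formulation above satisfies every
  textual constraint but may differ in detail (e.g. whether level-2 input
  is rectified). It is isolated in one module for exactly this reason.
* The uniform 21-point grids cannot represent optima off the 0.05/0.1
  steps; no refinement step is attempted.
* Best-model selection breaks exact RSS ties by first grid index, which
  matters only on the degenerate s1 = 1 line.
* The resampling utility's anti-aliasing filter (Kaiser-windowed FIR via
  `scipy.signal.resample_poly`) is a documented implementation choice and
  is excluded from headline properties.
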