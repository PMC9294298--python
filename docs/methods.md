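# Methods

This note records the models, conventions and numerical choices behind
`capfreq`, and what the synthetic validation does and does not establish.

## Signal model and band decomposition

The pipeline consumes per-subject frames × ROIs matrices (defaults mirror a
common acquisition: 235 frames at TR = 2 s over 408 ROIs, i.e. a 400-parcel
cortical atlas plus 8 subcortical regions). Five bands are built in:
typical 0.01–0.08 Hz and the sub-bands slow-5 0.01–0.027, slow-4
0.027–0.073, slow-3 0.073–0.198, slow-2 0.198–0.25 Hz. The sub-bands tile
[0.01, 0.25] Hz with shared edges.

Filtering is a 4th-order Butterworth band-pass applied forward and backward
(`scipy.signal.sosfiltfilt`), chosen because zero net phase shift preserves
the frame timing that frame-wise state assignment depends on; columns are
linearly detrended first so drift does not leak through the band edges.
Slow-2's upper edge coincides with the Nyquist frequency at TR = 2 s; the
digital edge is nudged to 0.999·f_Nyq, which is far below the filter's own
roll-off resolution. Series shorter than the filter's padding requirement
(~27 frames at these orders) are rejected rather than silently padded.

Z-scoring is per ROI with the population-SD convention (divide by T), fixed
so that documented hand examples are exact. A constant ROI is treated as a
data defect and raises, naming the ROI. Constant detection tolerates the
~1e-16 numerical residue that floating-point SDs leave on constant columns.

## CAP states

Frames are row-standardized (per-frame mean 0, SD 1 across ROIs) before
K-means, making squared Euclidean distance a monotone transform of
1 − Pearson r. This keeps the training geometry identical to the projection
rule, which assigns each new frame to the state whose Z-map it correlates
with most strongly. K-means uses k-means++ with 10 replicates and a fixed
seed, keeping the best replicate by within-cluster cost. K defaults to 6
(supported by silhouette curves on data with planted structure) but is a
parameter. States are defined on the control cohort only; patient frames
are always projected, never clustered.

A state's Z-map is the member-frame mean divided by the member-frame SD per
ROI (population SD). States need ≥ 2 member frames, and a zero within-state
SD raises. Exact assignment ties go to the lowest state index and are
logged; they have measure zero on continuous data.

Cross-band correspondence uses the Hungarian algorithm on cost 1 − r, which
maximizes total matched Pearson similarity; the result is invariant to
adding a constant to every similarity entry. Because K-means numbering is
arbitrary, `relabel_states` renumbers label sequences into a reference
set's ordering before any state-specific cross-band comparison — omitting
this step silently destroys paired state contrasts.

## Dynamics metrics

All metrics are run-length statistics of the per-subject label sequence:
fraction of time N_A/N, counts = number of maximal runs, persistence =
TR × mean run length (s). Runs truncated by scan boundaries count as full
episodes; with that convention the identity
fraction · T · TR = counts · persistence holds exactly, which the tests
assert for every simulated subject. A state a subject never visits has
fraction and counts 0 and *undefined* (NaN) persistence, excluded from
group means rather than entered as zero. Transition probabilities exclude
the final frame (no successor), so every defined row sums to 1; resilience
is the diagonal. Metrics are computed per subject and then aggregated —
sequences are never concatenated across subjects, which would fabricate
transitions at the seams.

Normalized persistence multiplies persistence by the band's arithmetic
center frequency ((f_low + f_high)/2), expressing dwell in cycles of the
band center. This discounts the mechanical slowing a narrow low band
imposes on any signal passed through it; residual band differences in this
quantity are not attributable to the filtering alone.

## Statistical battery

* Repeated-measures ANOVA: classical within-subject decomposition computed
  in closed form (SS_cond on b−1 df against the subject × condition
  residual); cross-checked against an independent implementation in the
  test suite. An all-equal matrix reports F = 0, p = 1.
* Mixed group-by-band ANOVA: with exactly two within-subject levels the
  split-plot design decomposes exactly — the group effect is tested on
  subject means, the band and interaction effects on within-subject band
  differences — via OLS with centered covariates (age, sex coded 0/1,
  mean FD), reporting F = t² on (1, df) df. Sphericity is vacuous with two
  levels. Type-I error of the interaction test is verified at 0.05 ± 0.02
  on 1000 null replicates.
* Covariate-adjusted two-sample test: t-test on the group coefficient of
  outcome ~ group + covariates; it reduces to the plain (Welch) two-sample
  t-test when no covariates are given. Welch is the default because the
  equal-n matched-cohort case reproduces pooled results to printed
  precision.
* Permutation test: two-sided on the mean difference with the add-one
  estimator p = (1 + #{|Δ*| ≥ |Δ|})/(1 + n_perm), seeded and vectorized.
* Chi-square: Pearson statistic without continuity correction, so a table
  with identical margins yields p = 1 exactly.
* Multiplicity: Bonferroni as min(1, p·m) with an explicit family size m,
  and Benjamini–Hochberg step-up (delegated to statsmodels, verified
  against a literal sort/scale/cummin oracle).

## Classification

Per-subject spatial features are the per-state mean of the subject's
z-scored frames assigned to that state (K × R values per band; a
subject-level mean/SD variant is available behind `mode="zmap"`). F-score
ranking uses within-class sample variances (ddof = 1); undefined scores
(both classes constant) rank last. The SVM is linear with C = 1; the
feature count is swept (default 20–1500 step 20) and ties in maximal
cross-validated accuracy resolve to the smallest count. Feature selection
happens strictly inside each training fold — a negative-control test shows
that ranking on the full data before cross-validation measurably inflates
null accuracy, and a label-permutation test through the full stack stays at
chance. AUC is the rank statistic on decision values pooled across folds.
The hold-out experiment re-clusters CAPs on a random control subset
disjoint from the classification sample each repetition, projects the
held-out controls and an age/sex-matched patient subset, and averages
repeated LOPO runs; consensus features are those selected in ≥ 80% of a
repetition's iterations and flagged in ≥ 80% of repetitions. Control
matching is greedy nearest-age within sex strata without replacement,
processing patients in age order.

## Synthetic cohorts and what they show

Templates are K/2 base patterns with disjoint active ROI blocks (amplitude
1 with 30% seeded jitter), mean-centered, each paired with its exact
negation. The active fraction is kept below 1/6 of the ROIs so cross-pair
correlations of the mean-zero rows stay below 0.2 in magnitude
(|r| = m/(1−m) for active fraction m).

State sequences are Markov chains with state-wise self-transition
p = 1 − 1/dwell (geometric run lengths, mean = dwell frames) and
off-diagonal mass proportional to target occupancy; with uniform occupancy
the stationary distribution is exactly uniform. Default band dwells are
6 / 2.5 / 1.3 / 1.1 frames for slow-5…slow-2, i.e. roughly 12 s, 5 s and
~2 s at TR = 2 s. Frames are amplitude·template + white Gaussian ROI noise
(amplitude 1, SD 0.5 by default); when a band is requested the summed
signal is passed through the same zero-phase filter as real data, so the
noise carries band-limited autocorrelation. The patient-like group differs
only in dynamics — a +50% dwell multiplier on the state-3/4 opposite pair
by default — while spatial templates are identical across groups; ages are
drawn from overlapping normals (means 43 vs 46, SD 12, clipped to 18–75),
sexes alternate for balance, and mean FD is log-normal (median 0.085,
σ = 0.5).

On the default 20+20-subject cohort the full pipeline recovers planted
templates with mean aligned correlation ≥ 0.95 and planted dwell within
10% relative error, and recovers the planted slow-5 > slow-4 > slow-3 >
slow-2 persistence ordering strictly. These checks validate the
*machinery*; they do not establish anything about real fMRI, where states
are not generated by a first-order Markov chain over fixed templates, noise
is neither white nor Gaussian before filtering, and motion, physiology and
hemodynamics are absent from the generator. Detecting the planted group
dwell effect per state needs ~40 subjects per group: per-subject
persistence of a state visited only a handful of times per scan is noisy,
so the 20-per-group mixed-ANOVA tables in `analysis/04` are honestly
underpowered for the group contrast while band effects are overwhelming.

## Problem sizes

Tests and the acceptance script run the study at desk scale: 20 + 20
subjects (40 per group where the group contrast itself is under test),
235 frames × 408 ROIs, 10 K-means replicates, 1000 replicates for type-I
calibration, 100 random matrices for the Hungarian oracle, and scaled-down
classification sweeps (grids up to 300 features, 5 hold-out repetitions × 2
LOPO repeats in the analysis driver). These sizes were chosen so the whole
validation runs on a single CPU in minutes while keeping every estimate's
Monte-Carlo error well inside the asserted tolerances.
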