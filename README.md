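# capfreq — frequency-resolved coactivation-pattern (CAP) analysis

`capfreq` implements a complete pipeline for studying how recurring brain
states in resting-state fMRI depend on the frequency band of the BOLD
signal, and for using those states as diagnostic features in case-control
cohorts (e.g. schizophrenia vs. healthy controls). It is aimed at
researchers working with parcellated ROI time series (e.g. a Schaefer-400
cortical + subcortical parcellation) who want frame-wise brain-state
analysis rather than sliding-window connectivity.

## What the pipeline does

1. **Band decomposition** (`signal_band`). Each ROI's time series is
   linearly detrended and band-pass filtered (zero-phase Butterworth) into
   the typical low-frequency range (0.01–0.08 Hz) or the sub-bands slow-5
   (0.01–0.027), slow-4 (0.027–0.073), slow-3 (0.073–0.198) and slow-2
   (0.198–0.25 Hz), then z-scored per ROI so |Z| measures momentary
   deviation from baseline.
2. **CAP states** (`cap_states`). All frames of the control cohort are
   pooled and clustered with K-means (K = 6 by default, validated by
   silhouette curves) under a Pearson-correlation geometry. Each state's
   spatial map is its Z-map (member-frame mean / SD per ROI). New subjects
   are projected by assigning each frame to the state of highest spatial
   correlation; CAP sets from different bands are matched with the
   Hungarian algorithm.
3. **State dynamics** (`state_dynamics`). Per subject and state: fraction
   of time `N_A / N`, counts (episodes per scan), persistence (mean episode
   duration, s), the transition matrix `P(A→B) = N_{A→B} / N_A` and its
   diagonal (resilience), plus center-frequency-normalized persistence.
4. **Statistics** (`group_stats`). Repeated-measures ANOVA for band
   effects, a two-group × two-band mixed ANOVA with age/sex/mean-FD
   covariates, paired and covariate-adjusted two-sample t-tests, a
   permutation test, chi-square, Bonferroni and Benjamini–Hochberg FDR.
5. **Classification** (`classification`). Per-subject CAP spatial features
   (K × R = 2448 per band), F-score feature ranking inside each training
   fold, linear SVM (C = 1) with a swept feature count, leave-one-pair-out
   and leave-one-out cross-validation, a hold-out experiment that defines
   CAPs on a disjoint control subset, and two-stage consensus-feature
   extraction.
6. **Synthetic cohorts** (`synthetic_data`). A generator that plants known
   CAP templates (three opposite-sign pairs), Markov state sequences with
   band-dependent dwell times, band-limited noise, a patient-like group with
   altered dynamics, and realistic demographics — so every stage can be
   validated against ground truth.

## Worked example

```python
from capfreq import (BANDS, SUB_BANDS, SimulationConfig, CAPSet,
                     simulate_multiband_cohort, zscore_rois, cluster_caps,
                     align_capsets, assign_frames, cohort_dynamics)

cfg = SimulationConfig(master_seed=11)          # 20+20 subjects, 408 ROIs
multi = simulate_multiband_cohort(cfg, {b: BANDS[b] for b in SUB_BANDS})
for name, (ts_set, meta, truth) in multi.items():
    z = {s: zscore_rois(ts) for s, ts in ts_set.items()}
    hc = [z[s] for s in z if truth.group[s] == "HC"]
    capset, _ = cluster_caps(hc, n_states=6, seed=3, n_replicates=5)
    r = align_capsets(capset, CAPSet(zmaps=truth.templates)).similarity.mean()
    dyn = cohort_dynamics({s: assign_frames(z[s], capset) for s in z}, 6)
    print(name, round(r, 3), round(dyn.table.persistence_s.mean(), 2))
```

prints

```
slow5 0.948 12.7
slow4 0.985 5.22
slow3 0.993 2.38
slow2 0.955 2.01
```

i.e. the planted spatial templates are recovered in every band (mean
aligned correlation ≥ 0.95) and the group-mean persistence falls
monotonically from ~12 s in slow-5 to ~2 s in slow-2 — lower-frequency
bands dwell longer in each state while higher bands switch faster and
accumulate more episodes.

The numbered drivers in `analysis/` run the full study on the synthetic
cohorts (simulation → clustering/alignment → dynamics → group statistics →
classification) and write their tables under `results/`.

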