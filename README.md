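# mstates

Resting-state EEG microstate analysis with microstate-conditioned
source connectivity and nonparametric group statistics — built for
studies that compare clinical groups (e.g. prolonged disorders of
consciousness vs healthy controls) on few-channel clinical EEG.

The package covers the full chain:

1. **Preprocessing** — zero-phase 1–30 Hz band-pass, bad-channel
   handling, extreme-value rejection, resampling to 250 Hz, average
   reference.
2. **Microstates** — GFP-peak clustering with a polarity-insensitive
   modified k-means (`ModifiedKMeans`, a scikit-learn estimator), model
   selection over K = 2–8 by a cross-validation criterion, backfitting,
   and the temporal parameters Duration, Occurrence, Coverage plus GEV.
3. **Connectivity** — sLORETA inversion (`SLORETAInverse`) of each
   state's GFP-peak data through a (supplied or toy spherical)
   leadfield, parcel-averaged region series, Pearson edges and
   thresholded edge lists.
4. **Statistics** — Mann–Whitney U with asymptotic Z for the parameter
   tables, two-sample Z for pooled connectivity, descriptive cohort
   summaries.
5. **Synthetic cohorts** — a fully ground-truthed generator (template
   dynamics, alpha-like amplitude, planted region correlations, two
   groups with configurable effect sizes) so every stage is testable by
   parameter recovery.

The core quantities, in the field's standard notation: GFP is the
spatial standard deviation of the scalp map; the modified k-means
assigns map `x` to `argmax_k (T_k·x)²` and updates `T_k` as the
principal eigenvector of the assigned maps' scatter;
`GEV = Σ_t (GFP_t · corr(x_t, T_{L(t)}))² / Σ_t GFP_t²`;
`CV = σ̂²((C−1)/(C−1−K))²`; sLORETA standardises the minimum-norm
estimate `Gᵀ(GGᵀ+αH)⁺ x` by the square root of the resolution
diagonal. See `docs/methods.md` for definitions, defaults and limits.

## Worked example

Simulate one subject at realistic conditions (19-channel 10–20 montage,
4 states, 100 ms mean duration, amplitude SNR 4, 60 s at 250 Hz),
cluster its GFP peaks, and recover the planted structure:

```python
import numpy as np
import mstates as ms

montage = ms.standard_1020_montage()
templates = ms.generate_templates(4, montage, max_abs_corr=0.5, seed=1)
labels = ms.generate_label_sequence(4, 15_000, 250.0,
                                    mean_durations=100.0, seed=2,
                                    min_samples=13)
rec, truth = ms.generate_eeg(templates, labels, 250.0, snr=4.0,
                             seed=3, montage=montage)

gfp = ms.compute_gfp(rec)
model = ms.ModifiedKMeans(n_clusters=4, n_init=50,
                          random_state=0).fit(rec.data[:, gfp.peak_indices].T)
print("GEV = %.3f, CV = %.4f" % (model.gev_, model.cv_))

perm, signs, corr = ms.match_templates(truth.templates, model.templates_)
print("template |corr| vs planted:", np.round(corr[np.arange(4), perm], 4))

seg = ms.backfit(model.templates_, rec, gfp)
print(ms.compute_parameters(seg, 4).round(3).to_string(index=False))
```

which prints

```
GEV = 0.972, CV = 0.2652
template |corr| vs planted: [1. 1. 1. 1.]
 state  duration_ms  occurrence_hz  coverage  n_segments
     0       97.730          2.467     0.241     148
     1       92.128          2.600     0.240     156
     2      103.605          2.533     0.262     152
     3      102.093          2.517     0.257     151
```

The fitted templates match the planted ones exactly (|spatial
correlation| = 1 to four decimals), 97% of the GFP-weighted variance is
explained, and the per-state mean Durations recover the planted 100 ms
within a few percent — the residual spread is the sampling variability
of ~150 segments per state. Coverage ≈ Occurrence × Duration holds
(e.g. 2.467 s⁻¹ × 0.0977 s ≈ 0.241).

## Command line

```bash
mstates simulate  --seed 1 --subjects 17 23 --length 60 --out sim/
mstates preprocess sim/A01.tsv --montage sim/montage.sfp --sfreq 250 --out clean/
mstates microstate sim/A01.tsv --montage sim/montage.sfp --sfreq 250 --k 4 --out msout/
mstates run-all   --seed 1 --out results/run/
```

`run-all` executes the whole pipeline on a synthetic two-group cohort —
per-group template fitting, per-subject backfit and parameters,
per-state connectivity, group statistics — and writes tidy TSV tables,
edge lists, a text report ("Z = …, p = …" per cell) and a JSON manifest
with config, seed and output hashes. Recordings are exchanged as plain
TSV matrices or EDF; montages as `.sfp` text.

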