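# Methods

This note documents the models, algorithms, defaults and known limits of
`mstates`. It is the reference for *why* the package computes what it
computes; the README covers *how* to run it.

## The microstate model

Resting EEG is modelled as a sequence of quasi-stable scalp topographies
("microstates"): at time *t* the average-referenced sensor vector is

    x(t) = a(t) · T_{L(t)} + ε(t)

with `T_k` a zero-mean, unit-norm map over channels, `L(t)` a
piecewise-constant state sequence, `a(t)` a signed amplitude, and `ε`
sensor noise. Because only the *direction* of the map carries state
information, every operation in the package is polarity-insensitive:
`x` and `−x` are the same microstate.

**GFP.** Global field power is the spatial population standard deviation
of the map, `GFP(t) = ‖x(t) − x̄(t)‖ / √C`. Its local maxima are the
moments of highest topographic signal-to-noise and are the samples used
for clustering (minimum peak separation is configurable, default one
sample; peak search never crosses an artifact splice).

**Modified k-means.** `ModifiedKMeans` clusters GFP-peak maps with the
polarity-insensitive variant of k-means: assignment maximises the
squared projection `(T_k·x)²`; the update sets `T_k` to the principal
eigenvector of the within-cluster scatter `Σ x xᵀ`. Convergence is a
relative change of total GEV below `tol` (default 1e-7, max 300
iterations); 50 random restarts by default, best restart chosen by GEV.
Ties in assignment go to the lowest state index; an emptied cluster is
re-seeded from the worst-fit map. On eight 3-channel maps the
best-of-restarts GEV equals the brute-force optimum over all 2⁸ label
assignments (tested over 20 seeds).

**GEV and CV.** Global explained variance is
`GEV = Σ_t (GFP_t · corr(x_t, T_{L(t)}))² / Σ_t GFP_t²`; per-state
contributions sum to the total, unassigned samples contribute zero to
the numerator. The model-order criterion is the predictive
residual-variance form `CV = σ̂² · ((C−1)/(C−1−K))²` with
`σ̂² = Σ_t (‖x_t‖² − (T_{L(t)}·x_t)²) / (N(C−1))`. K is scanned over
2–8; the default selection rule is the CV minimum, with a forced-K=4
mode for reporting the four classical states (the convention used for
group comparisons) and a GEV-elbow rule as an alternative.

**Backfitting and parameters.** Group templates are fitted once per
group on the concatenated GFP-peak maps of all its subjects, then
backfitted to each subject (the two-level subject-then-group aggregation
is not implemented; the concatenation choice is recorded in the output
metadata). In the default peak mode each GFP peak takes the label with
the largest squared spatial correlation and other samples inherit the
nearest peak's label without crossing splice boundaries; an all-samples
mode labels every sample directly. Label smoothing (minimum-duration
absorption into the better-correlated neighbour) exists but defaults to
off. Temporal parameters per state: **Duration** = mean segment length
(ms), **Occurrence** = segments per second of labelled time, **Coverage**
= fraction of labelled samples; coverages plus the unassigned fraction
sum to one exactly, and Coverage ≈ Occurrence × Duration within ~2%
when edge segments are included. States are named A–D by Hungarian
matching against four idealised canonical topographies built from the
montage geometry (diagonal, diagonal, anterior–posterior,
fronto-central); these canonical maps are synthetic naming anchors, not
empirical group averages.

## Source imaging and connectivity

**Toy head model.** A single-shell spherical conductor with
fixed-orientation radial dipoles at 80% of the sensor radius. The
surface potential of a radial dipole at eccentricity *f* and angular
distance γ has the closed form `2(x−f)/s³ + (1/s − 1)/f` with
`x = cos γ`, `s = √(1 − 2fx + f²)`; gain columns are scaled to unit
norm. Sources sit on a Fibonacci lattice (z > −0.5); the parcellation
assigns each source to the nearest of R farthest-point-sampled seed
sources, giving contiguous, non-empty regions. This deliberately
replaces individual-anatomy BEM modelling: it is analytic, desk-scale,
and sufficient to exercise the inverse operator's contract.

**sLORETA.** With `H` the average-reference projector and `G = H·gain`,
the minimum-norm kernel is `K = Gᵀ(GGᵀ + αH)⁺` and source *j*'s estimate
is standardised by `√((KG)_jj)`. At α→0 this has exactly zero
localisation error for noiseless single sources (verified for all
sources of the toy model). α defaults to 1e-6 in the pipeline;
estimates shrink monotonically with α. At α=0 with a rank-deficient
system the pseudo-inverse path is taken and a warning is recorded.

**Connectivity.** For each microstate, the sensor columns at that
state's GFP peaks are inverted, averaged into region series (each
member source sign-flipped to correlate positively with the region's
first principal temporal direction — fixed-orientation estimates carry
arbitrary polarity), and correlated pairwise (Pearson). Three
device-physics facts shape the defaults and are easy to forget:

1. *A globally coherent source is invisible.* A component shared by all
   regions projects to a nearly uniform scalp map, which the average
   reference removes; recovered correlations of such a component come
   out near zero or negative. Planted connectivity must therefore be
   differential (region pairs), and real-world "global" coupling is
   outside what referenced EEG can measure.
2. *The microstate mode saturates its own peaks.* At a state's GFP
   peaks the data is rank-one dominated by that state's topography, so
   all region pairs inherit near-±1 correlations regardless of genuine
   coupling. The pipeline therefore projects the state's fitted
   template out of its peak maps before inversion
   (`remove_template=True`, switchable), computing connectivity on the
   residual fluctuations.
3. *Pair polarity is arbitrary.* After sign-aligned parcel averaging
   the sign of a region-pair correlation is not identifiable, so pooled
   summaries use |r| by default (`magnitude=False` restores raw-r
   pooling; a Fisher-z averaging mode exists).

A small systematic bias remains even in the identity-leadfield test: the
average reference subtracts the cross-region mean, lowering a planted
r = 0.8 to ≈ 0.77 at 10⁵ samples. This is a property of referenced EEG,
not an estimation error.

Pooled group summaries (mean ± SD over all upper-triangle edges of all
subjects) are compared with a two-sample Z test that treats edges as
independent observations; that simplification is flagged in the output,
because edges of one subject share an inverse operator and are not
independent.

## Group statistics

Microstate parameters are compared per (state × metric) with the
Mann–Whitney U test, reported as the tie-corrected asymptotic Z without
continuity correction — the convention of mainstream clinical software,
so Z values are comparable with published tables. A continuity-corrected
mode and an exact-enumeration p (used automatically for min(n) ≤ 8
without ties) are available; the continuity-corrected asymptotic p
agrees with exact enumeration to within 0.011 at n = 8 vs 8, while the
uncorrected form can deviate by up to ~0.05 there (an intrinsic property
of the uncorrected normal approximation, which is why the accuracy check
uses the corrected mode). No multiple-testing correction is applied by
default, mirroring common practice in this literature; a Holm option is
provided and documented as a deviation. Under the null the empirical
type-I error of the full 12-cell comparison is ≈ 0.048 per cell at
α = 0.05 (400 simulated cohort pairs per cell).

Descriptive cohort tables report mean ± SD for numeric attributes and
counts with half-up-rounded percentages (one decimal, or integer display
per column) for categorical ones.

## The synthetic cohort generator

The generator's defaults are the study conditions every recovery claim
is made under: 19-channel 10–20 montage (canonical spherical
coordinates shipped as `data/standard_1020.sfp`), 4 states, 250 Hz,
60 s records, amplitude SNR 4, mean state duration 100 ms.

* **Templates**: random zero-mean unit-norm maps with pairwise
  |spatial corr| ≤ 0.5 (orthogonal on request via Gram–Schmidt).
* **State dynamics**: a semi-Markov chain with geometric segment
  lengths (memoryless above a floor). `generate_label_sequence`
  defaults to a 2-sample floor; the cohort uses a 50 ms floor because
  sub-50 ms microstates are neither physiological (the classical
  stability range is 80–120 ms) nor resolvable by any GFP-peak method.
  Occurrence effects for the patient-like group enter through the
  transition matrix (entry probabilities scaled per state), duration
  effects through the per-state means.
* **Amplitude**: within each segment a sinusoid at the envelope
  frequency (default 10 Hz, alpha-like), phase-reset at the transition
  and frequency-nudged so the segment holds a whole number of
  half-cycles. Consequences: the GFP of the noiseless signal is exactly
  a rectified sinusoid whose troughs coincide with transitions (the
  empirical observation that justifies peak-based clustering), each
  segment integrates to zero so the 1 Hz high-pass does not smear
  microstate topographies across segments, and the signal stays inside
  the 1–30 Hz analysis band. A signed amplitude is indistinguishable
  from an unsigned one downstream because the method ignores polarity.
* **Noise**: white Gaussian sensor noise scaled so
  RMS(signal)/RMS(noise) over the whole record equals the requested
  SNR.
* **Connectivity component** (optional, `source_mix > 0`): region-level
  latent series, band-limited to 1–30 Hz (instantaneous correlations
  are invariant under a common filter), mixed per state by the factor
  of a disjoint-pair coupling target (pairs rotate with state), copied
  to member sources, projected through the toy leadfield and added at a
  configurable RMS ratio to the microstate signal. The patient-like
  group scales the planted coupling by `connectivity_multiplier`.
* **Reproducibility**: per-subject seeds derive from
  `SeedSequence((master_seed, group_index, subject_index))`, so a
  cohort is bit-reproducible subject-by-subject and adding subjects
  never changes existing ones.

What the generator does **not** emulate: ocular/muscle artifacts (the
ICA stage is a no-op hook), 1/f background spectra, non-stationary
amplitude statistics, volume-conduction from non-radial or deep
sources, inter-subject topography variability, and any systematic
relation between microstate dynamics and the connectivity component.
Passing recovery tests therefore demonstrates correctness of the
algorithms under the model's assumptions, not clinical validity on
patient EEG.

## Preprocessing

Order: zero-phase band-pass (Butterworth order 4, forward–backward,
1–30 Hz) → bad-channel detection (flat < 0.1 µV peak-to-peak or
|z(log variance)| > 3) with optional inverse-distance interpolation →
extreme-value rejection (non-overlapping 1 s windows dropped when any
channel exceeds ±100 µV — standard clinical defaults; there is no
canonical published value) → polyphase
resampling to 250 Hz (the 1–30 Hz band needs no more) → average
reference. Splice points from rejection are carried through
segmentation so no microstate segment spans a cut.

One honest limit: the band-pass has ~160 ms of memory (the 1 Hz edge),
so within that distance of a state transition filtered topographies are
mixtures. With 100 ms mean segments *every* sample is within filter
memory of a transition and per-peak purity cannot reach |corr| > 0.99;
the preservation property is therefore asserted where its premise holds
(400 ms segments, peaks ≥ 50 ms from a transition; measured minimum
0.995). Template recovery at the 100 ms study conditions is unaffected
(eigenvector averaging over thousands of peaks; recovered |corr| >
0.999).

## Problem sizes used in the shipped checks

Scales were chosen to keep the full suite and the acceptance script at
around a minute each on one CPU while leaving every claim's margin
wide: template/duration recovery on 4 subjects × 60 s; K-selection over
20 independent single-subject runs (15 restarts per K; selection is
insensitive to restarts at SNR 4); connectivity ordering on 30 000
samples; calibration on 400 null cohort pairs and 50 power replicates
at the published group sizes (17 vs 23); determinism on a 3 + 3 subject,
15 s pipeline run (determinism is size-independent). The full 17 + 23 ×
60 s pipeline runs in well under 15 minutes on one CPU via
`mstates run-all`.
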