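# Methods

## Signal model of the synthetic cohorts

A cohort is a set of metabolite templates, each observed as one singly
charged cation adduct ([M+H]⁺, [M+Na]⁺ or [M+K]⁺) with
m/z = M + m_cation − m_e (electron-mass correction on by default, a flag
accommodates legacy tables that quote bare atomic masses). Per sample and
template the log intensity is

    log I = b + Δ(group)·σ + ε,   ε ~ N(0, σ²),   σ = √log(1 + cv²),

so `cv` is the natural-scale coefficient of variation and Δ is the
planted **standardized** effect (Cohen's *d* on log intensities). Two
consequences anchor the tests: the natural-scale fold change converges to
exp(Δ·σ), and a single marker of effect Δ has binormal AUC Φ(Δ/√2)
regardless of σ, because AUC is rank-based.

Spectral rendering adds, on an m/z grid no coarser than a third of the
peak width: Gaussian peaks of constant width σ_mz (apex = the drawn
intensity), an exponentially decaying baseline, m/z jitter, additive
Gaussian noise clipped at zero, and independent per-peak dropout.
Defaults emulate a clean nanoparticle-assisted LDI acquisition:

| parameter | default | meaning |
|---|---|---|
| `intensity_cv` | 0.10 | replicate/biological CV of peak intensities |
| `peak_width_sigma` | 0.05 Da | Gaussian peak σ; templates are packed ≥ 4σ apart |
| `mz_jitter_sd` | 0.01 Da | per-peak mass-axis jitter |
| `baseline_amplitude`, `baseline_decay` | 30, 0.01 /Da | small vs analyte peaks (10²–10⁴) |
| `additive_noise_sd` | 3 | detector noise floor |
| `dropout_prob` | 0 | peak-loss probability |

The 0.10 CV matches the replicate reproducibility regime of clean LDI
fingerprints (single-digit to low-teens percent). Differential templates
are drawn from the embedded reference metabolites, interleaved
up/down-regulated (lactic acid ↑, creatine ↓, uric acid ↑,
dimethylglycine ↓, malondialdehyde ↑, threonine ↓, 3-hydroxybutyric
acid ↑, fucose ↓), so an 8-marker design plants four of each direction
and the annotation round trip can verify identities, not just positions.
Background metabolites are synthetic nulls placed uniformly at ≥ 4σ_mz
spacing; requesting more peaks than ~85 % of the window capacity raises
an explicit packing error.

Randomness: one master seed feeds `numpy.random.SeedSequence`; child 0
builds templates, child 1+i drives sample i (grandchildren per
replicate). The seed is recorded in the metadata.

`simulate_feature_matrix` draws the same intensity model directly as a
feature matrix, skipping spectral rendering; statistical studies
(classifier calibration, screening recovery, power) use it so planted
effects are exact and runtimes stay in seconds, while the spectral path
is exercised by the processing and round-trip tests.

**What the generator does not emulate:** isotope patterns,
fragmentation/matrix clusters, detector saturation, batch effects,
correlated metabolite modules, or covariate-linked effects (age/sex are
generated balanced and independent of intensities). Passing tests
therefore certify the *statistical machinery* under a clean, known
model — not performance on real plasma, where drift, correlation and
confounding can only degrade the printed figures.

## Processing chain

Baseline = rolling minimum (window 5 Da) followed by a rolling mean of
the same width, subtracted with a floor at 0; smoothing = Savitzky–Golay,
degree 2, 7 points. Peak detection estimates noise as 1.4826 × MAD of the
signal detrended by a 51-point rolling median, gates local maxima at
`snr_min` (default 3) times that level on the *detrended* residual, and
centroids by intensity-weighted mean over the descending flanks of the
apex; heights are read from the baseline-corrected signal so neighbouring
peaks do not bias each other. This combination holds false peaks below
5 % of grid local maxima on pure noise while centroiding clean peaks to
< 1 ppm.

Alignment sorts all peaks and packs them greedily into clusters of width
≤ `tol` (default 0.2 Da); for sorted points this greedy rule attains the
minimum possible number of width-bounded clusters, which the tests verify
against a dynamic-programming oracle. Feature m/z is the median member;
per sample the most intense member is kept; features present in fewer
than `min_presence` (default 0.1) of samples are dropped; missing entries
are 0 (absence of signal, not missingness). TIC normalization rescales
each sample to the cohort-median total — note the target is
data-dependent, so "scaling one sample leaves it unchanged" holds exactly
only when the scaling does not move the median total.

QC: per-sample cosine similarity against the leave-one-out group median
profile (reference excludes the scored sample), summarized as the
fraction above 0.85; replicate CV% = sd/mean per feature.

## Diagnosis

"Sparse learning" is L1-penalized logistic regression (scikit-learn,
liblinear). Features are standardized with discovery statistics only;
the penalty λ is chosen on a log-spaced grid (default 50 values,
10⁻³–10^1.5) by maximal mean cross-validated AUC (default 5 folds), ties
resolved toward the stronger penalty; the model is refit on full
discovery. Both the tuned CV-mean AUC (an out-of-sample estimate) and
the refit in-sample AUC are reported and must not be conflated. AUC is
the Mann–Whitney rank statistic (ties ½); CIs are stratified-bootstrap
percentiles. The operating point maximizes Youden's J on discovery
(smallest threshold on ties, so all-equal scores read sens = 1,
spec = 0); a fixed 0.5 cut is available. The permutation test reruns the
*entire* tuning procedure per permuted label vector and uses the add-one
estimate p = (1 + #{null ≥ obs})/(1 + n_perm), keeping the null
exchangeable with the observed pipeline.

## Screening and panel

Selection frequency = fraction of stratified bootstrap resamples (80 %
of the cohort, with replacement; a subsample scheme is available) in
which the feature's lasso coefficient at the tuned λ is nonzero. The
screen intersects frequency ≥ 0.90, rank-sum p < 0.05 (BH-adjusted q is
also reported but the screen uses raw p, as printed), mean normalized
abundance > 500 (same arbitrary units as the generator), and oriented
single-feature AUC > 0.7. Constant features read p = 1, AUC = 0.5, and a
fold change of exactly 1 is labelled "up" by convention. The panel model
is logistic with a tiny ridge (C = 10⁶) so separable small panels stay
finite; with a discovery/validation split it is fit and thresholded on
discovery only. Heatmaps are per-feature z-scores with samples ordered
by group then model probability.

Known behaviour worth noting: on (near-)separable cohorts the lasso
splits selection among equally separating markers, so individual
frequencies can fall below 0.9 even for true markers — stability
selection's usual failure mode under perfect separation. The recovery
guarantees quoted below are for the Δ = 1.5, n = 100/group regime where
each marker is informative but not individually separating.

## Power at a controlled FDR

From a pilot: per-feature d = mean difference / pooled sd on log1p
intensities; π₀ = min(1, 2 · frac(p > 0.5)) from the two-sample-t
p-value histogram (chosen over spline fits for determinism); optional
(default on) positive-part shrinkage d ← d·max(0, 1 − v_d/d²) with v_d
the usual sampling variance of a standardized mean difference, countering
winner's curse in small pilots. The non-null set is the (1 − π₀)m
smallest-p features. α\* solves E[FDR](α) = π₀mα / (π₀mα + Σ power_i(α))
by fixed-point iteration, capped at α\* ≤ FDR (so a π₀ = 0 pilot gives
α\* = FDR exactly); predicted power is the mean two-sided two-sample
noncentral-t power of the non-null effects at α\*. The noncentral-t tail
is computed directly from `scipy.stats.nct` because the far wrong-side
tail underflows to NaN in the usual library route at large
noncentrality; that term is < 10⁻¹⁰ and is floored at 0.

Limitation: with the histogram rule, weak-signal pilots (few non-nulls,
small m) can estimate π₀ = 1, in which case power is declared undefined
rather than extrapolated — a pilot indistinguishable from null supports
no power claim. Pilot designs in the tests use m = 200 with 20 %
non-null features, where the estimator has adequate precision.

## Annotation and enrichment

A feature matches a (metabolite, adduct) candidate when
|m/z_obs − m/z_theo| / m/z_theo ≤ 5 ppm (configurable); candidates are
ranked by |ppm error|. The embedded reference covers the eight
exacerbation markers plus glucose, with monoisotopic masses computed from
the NIST atomic-mass table at import (never hard-coded) and validated
against the stated formula to 10⁻⁴ Da. The pathway map is a small
KEGG-style table for testing; user tables are accepted and no live
database is queried. Enrichment is the one-sided hypergeometric tail
with BH adjustment across pathways.

## Diffraction utility

d = nλ/(2 sin θ) with λ defaulting to Cu Kα (0.15406 nm) — a documented
default, not a claim about any particular instrument. At 2θ = 0.46° this
gives d = 19.19 nm; a printed pairing of 0.46° with 19.0 nm is mutually
consistent only if the peak position was ≈ 0.4646° before rounding
(the inversion check in the test suite makes this explicit).

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own defaults for a single-CPU run: screening
recovery uses 900-feature cohorts at n = 100/group, Δ = 1.5 (20 seeds in
the tests, 5 in the script); binormal calibration Δ = 2 at n = 200/group;
null calibration 15-feature cohorts at n = 20–25/group; permutation
calibration n_perm = 99 over 100 null cohorts (30 in the script) with a
6-point λ grid and 3 folds; power self-consistency m = 1/d = 1/n = 24
against a 20 000-replicate Monte-Carlo, and a 200-feature pilot
(40 non-null at Δ = 1) for the recommended-n FDR check; the annotation
round trip renders 200 full spectra with instrument-noise terms off.

## Interfaces

Spectra: mzML (MS1; minimal self-contained reader/writer — the reader
accepts 32/64-bit float arrays, zlib or uncompressed; Bioconductor mzR
cross-validates the writer in the tests) and a CSV dialect (`mz` column
plus one intensity column per sample). Feature matrices: CSV with a JSON
parameter sidecar. Models and panel reports: JSON + CSV. The `fingermet`
CLI is a thin wrapper over the library; the Python API and `examples/`
are the primary surface.
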