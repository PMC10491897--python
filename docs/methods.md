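# Methods

This note documents the models, parameter choices, and numerical
conventions behind `lungraman`, and what the synthetic validation does and
does not demonstrate.

## Forward model of a measurement

Each interrogation point yields `n_repeats` laser-on frames and one
laser-off dark frame. Per pixel, the expected laser-on counts are

    E[counts] = R(p) · (S(ν(p)) + B(ν(p))) · t + d · t

where `R` is the per-pixel instrument response, `ν(p)` the true
pixel-to-wavenumber map (a gentle quadratic over 800–1700 cm⁻¹, so
calibration fitting is nontrivial), `S` the tissue Raman signal, `B` the
fluorescence background, `t` the integration time (75 ms; dark frame
50 ms), and `d` the dark rate. Shot noise is exact Poisson where the mean
is ≤ 20 counts and Gaussian with variance = mean above that (CCD regime);
read noise is additive Gaussian (sd 4 counts). Counts are clipped at zero,
as a real detector's are.

The tissue spectrum is a sum of Lorentzian bands (Gaussian selectable):
seven discrete marker bands at the canonical lung-tissue positions (852,
1037, 1080, 1156, 1449, 1549, 1657 cm⁻¹) plus seven broad, class-shared
"matrix" bands (880, 1004, 1260, 1310, 1340, 1587, 1618 cm⁻¹, fwhm up to
70 cm⁻¹) representing the band congestion of real fingerprint tissue
spectra. The matrix is not cosmetic: SNV normalization divides by the
whole-spectrum standard deviation, so without substantial shared spectral
energy any class-specific band boost bleeds into every other normalized
band and the subtle tyrosine contrast disappears. Matrix bands carry half
the biological coefficient of variation of the markers (`cv_scale 0.5`),
reflecting that a bulk compositional average fluctuates less than
individual constituents.

Class structure: cancer/necrosis tissue has amide I (1657 cm⁻¹) raised by
50% and tyrosine (852 cm⁻¹) by 45% — the tyrosine change is the subtler
one in absolute terms (0.27 vs 0.40 amplitude units). All other bands are
shared between classes. These effect sizes are generator inventions,
calibrated once so that the ten-patient, ~200-spectrum desk-scale cohort
lands in the performance regime the analysis is designed for (LOPO AUC
comfortably above 0.85 with the QF filter on); they are tunable through
`default_profiles`.

Variability: each patient draws one multiplicative log-normal factor per
band (CV 0.15, shared by both tissue classes of that patient — both are
sampled from the same subject), and each measurement draws a second
per-band factor (CV 0.05). A fraction (default 0.33) of measurements is
"degraded": their laser-on noise is multiplied by 35, emulating
low-photon-count acquisitions whose spectra show no recognizable tissue
bands. The background-to-Raman amplitude ratio (default 12) and detector
sampling (2048 pixels) were chosen together with that multiplier so that
degraded measurements genuinely fall below the QF threshold while normal
ones stay far above it; coarser sampling or a steeper background lets
baseline removal imprint smooth noise artifacts that inflate the QF of
junk spectra.

## Preprocessing chain

Order: repeat averaging → dark subtraction (scaled by the 75/50 ms
integration-time ratio; negative values retained, since clipping would
bias the baseline) → response correction (measured broadband reference
divided by the certified shape, Savitzky–Golay smoothed, window 31 px,
quadratic) → wavenumber calibration (least-squares polynomial through the
detected peaks of the calibration standard, order 2, rejected if
non-monotone) and linear resampling onto the fixed 1 cm⁻¹ grid from 800
to 1700 cm⁻¹ (901 points) → BubbleFill → SNV.

**BubbleFill.** The spectrum is rescaled so its intensity range equals its
index range (making circles meaningful), then a circular arc spanning the
full axis is grown from below until it touches the spectrum. Each touch
point splits the interval; intervals narrower than `min_bubble_width`
(default 100 cm⁻¹ — wider than any tissue band, narrower than any
fluorescence structure) are not refined further. Intervals at the axis
ends use half-bubbles of doubled radius with the apex at the edge, and a
touch at an interval endpoint shaves that point off rather than
re-splitting, which guarantees termination and lets the envelope climb
smooth rising flanks point by point. The decomposition is exact
(`baseline + raman` reproduces the input to rounding), deterministic, and
scale-equivariant. Two intrinsic approximations are worth knowing: arcs
sag between touch points, so a pure broad background leaves a residual of
up to ~11% of its amplitude at the minimum-bubble scale, and band wings
wider than the bubble width are absorbed into the baseline — a 15 cm⁻¹
peak is recovered to within ~7% of its height, but structure broader than
`min_bubble_width` is by construction treated as background.

**SNV** uses the population (1/N) standard deviation; constant spectra are
rejected as unnormalizable.

## Quality factor

`QF = Var(smooth(z))` for an SNV spectrum `z`, clipped to [0, 1], with a
Savitzky–Golay smoother (window 13 cm⁻¹, cubic). Because `Var(z) = 1`,
this is the fraction of spectral energy at scales the smoother preserves:
a noiseless multi-band tissue spectrum scores > 0.99, white noise scores
the smoother's noise-variance factor, ≈ 0.175 in expectation. The window
was set to 13 cm⁻¹ because a cubic smoother needs at least that span for
white noise to fall below 0.2 — a 9-point cubic window retains 0.255 of
noise variance and cannot separate the regimes — while remaining narrow
enough to preserve every tissue band. QF is computed on the fully
processed (post-SNV) spectrum; retention requires QF strictly greater
than the threshold (default 0.4).

In the full chain, the effective QF of signal-free spectra is ~0.25–0.35
rather than 0.175: resampling correlates neighboring noise samples and
the bubble baseline tracks smooth noise envelopes. The separation between
degraded (~0.30) and normal (~0.98) spectra is nevertheless wide, and the
rejected fraction tracks the planted degraded fraction within ±0.03.

## Feature selection and classification

Features are the 901 grid intensities minus the closed interval
1060–1100 cm⁻¹ (possible surface-blood phosphate contamination), leaving
860 columns. Ranking fits L1-penalized squared-hinge linear SVMs over 50
log-spaced penalty levels starting just above the smallest C with any
active feature; a feature's rank is the level at which its weight first
becomes nonzero, with ties broken by final |weight| then by wavenumber.
The path stops early once the requested number of features has entered.
Correlated columns of one band enter in quick succession, so selected
features are also reported grouped into contiguous bands (gap ≤ 10 cm⁻¹);
models always operate on individual wavenumbers.

The final classifier is a hinge-loss linear SVM (libsvm, tolerance 1e-8)
on the top-k features. Validation is leave-one-patient-out: all spectra
of one patient form the held-out fold and feature ranking is recomputed
from the training patients of each fold (a global-selection variant would
leak; the in-fold default is the conservative choice). The grid search
spans C ∈ {0.01, 0.05, 0.1, 0.5, 1, 2, 5} and k ∈ {5…20}, scores each
cell by pooled LOPO AUC, reuses the per-fold rankings across cells (the
path order is independent of C and k), and breaks ties toward smaller k,
then smaller C. Folds whose training partition lacks a class are skipped
and flagged.

Note that soft-margin SVM scores are *not* invariant to feature
rescaling at fixed C (regularization geometry changes); invariance holds
only in the separable hard-margin limit, and the tests check it there.

## Evaluation

ROC/AUC follows the empirical curve over all thresholds; the AUC equals
the normalized Mann–Whitney pair count with ties counted ½ (verified
against a brute-force oracle). The reported operating point maximizes
Youden's J, resolving ties toward higher sensitivity; fixed-specificity
and closest-to-corner rules are selectable. The permutation control
shuffles labels across spectra (patient ids intact; a patient-level
shuffle is available), reruns the entire LOPO pipeline — including
in-fold feature selection — at fixed hyperparameters, and summarizes N
repeats as mean ± sd; on any dataset this is centered at 0.5. Univariate
band statistics use the two-sided Wilcoxon rank-sum test at the grid
point nearest each marker band (robust to the skewed intensity
distributions typical of these data); significance stars follow the
p < 0.01 / p < 0.0001 convention on raw p-values, with a Holm-adjusted
column reported separately rather than replacing them. Cohort tallies are
pure integer arithmetic; ratios are rounded to two decimals and the
rejection rate to whole percent.

## What the synthetic validation shows — and does not

Passing tests demonstrate that the pipeline is internally consistent: the
preprocessing chain inverts the generator's forward model up to the
stated baseline approximations, the QF filter removes exactly the
low-SNR stratum, in-fold L1 selection finds the planted marker bands, the
LOPO AUC reflects the planted effect size, and the permutation control
sits at chance. The generator does not emulate biological confounders
(histology-specific sub-signatures, spatial heterogeneity within a
specimen, probe-pressure effects, cosmic-ray spikes) or real certified
reference materials — its calibration standard and broadband shape are
synthetic stand-ins. Performance numbers on synthetic cohorts therefore
characterize the algorithms, not expected clinical accuracy.

## Problem sizes and numerics

Default analyses use 10 patients × up to 20 measurements × 10 repeat
frames on a 2048-pixel detector; replicate studies use 25 seeds and the
permutation control uses 100 repeats. All randomness derives from one
integer seed through named, independent substreams (cohort, permutation),
so every artifact is bit-reproducible. Solver settings: liblinear
tolerance 1e-4 (path ranking; entry order is insensitive to it), libsvm
tolerance 1e-8 (final models), polynomial fits by numpy least squares.
Degenerate inputs fail loudly: constant spectra (SNV), single-class folds
(flagged and skipped), empty retained sets, non-monotone calibrations,
bands outside the axis.

One consequence of BubbleFill's exact affine equivariance is worth
noting: applying SNV before baseline removal and re-normalizing
afterwards reproduces the standard chain exactly, so the order of the
two stages matters only because the pipeline does not re-normalize —
the diagnostic "SNV-first" order ends at an un-normalized spectrum that
the quality module rightly refuses to score.
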