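# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the limits of what the test suite demonstrates.

## The analysis problem

A MALDI-IMS experiment yields one mass spectrum per pixel of a tissue
section. For peptide imaging of injured skeletal muscle the analysis must
(i) make spectra comparable within and across sections, (ii) assign each
pixel to a pathophysiological region — trauma core (tm) vs trauma-adjacent
tissue (tam) — without relying on histology, (iii) describe the molecular
structure without supervision, (iv) find m/z values whose intensity
distribution discriminates treated (MSC-TX) from control tissue within a
region, and (v) attach peptide/protein identities to those m/z values using
a bottom-up LC-MS/MS run on adjacent sections, since on-tissue MS/MS is
defeated by isobaric ions and chimera spectra.

## Preprocessing

*Baseline removal* (profile mode only): morphological opening — moving
minimum then moving maximum, both with a 20-point window — followed by a
20-point moving average; the result is subtracted and clipped at zero. The
opening follows linear drift exactly and removes structures narrower than
the window; a plain minimum-then-average estimator under-subtracts a sloped
baseline by slope × width/2. The window unit is profile points; a config
knob (`baseline_width_units`) records that the point-vs-Da convention of
vendor software is ambiguous.

*TIC normalization*: every spectrum is scaled to the dataset-wide mean TIC,
jointly over all sections so they stay comparable. Spectra whose TIC is
below 10% of the median TIC (background/off-tissue positions, including
all-zero spectra) are flagged and left unscaled: rescaling a near-empty
spectrum to tissue TIC amplifies noise by orders of magnitude and, measured
on synthetic data, destroys marker-image correlation (0.52 → 0.09).
Downstream statistics exclude sub-floor spectra by the same rule.

*Peak detection*: local maxima of the Gaussian-smoothed joint mean spectrum
("weak"/"medium"/"strong" = σ of 1/2/4 profile points), accepted when both
their height above the median smoothed level and their topographic
prominence exceed `snr_floor` (default 3) times a robust noise estimate
(1.4826 × MAD of the smoothing residual). Prominence prevents a nonzero
noise floor or a peak shoulder from counting as signal. Centroid data passes
through unchanged.

*Alignment*: one column per detected center with half-open interval
[c − 0.156, c + 0.156) Da; the value is the mean over profile points in the
interval, or the sum of centroids for centroid data. Overlapping intervals
merge onto the stronger center (by joint mean-spectrum intensity), logged.

## Region annotation

Tissue pixels (TIC ≥ 10% of the per-section median) are split by the
annotation marker ions, which are depressed in the trauma core. Each marker
image is denoised by a tissue-restricted normalized Gaussian convolution
(σ = 1 pixel) — ion images are spatially coherent, so this suppresses
per-pixel abundance noise without moving region boundaries — min-max
normalized, and blended 70/30 with the pixel's own normalized intensity.
The blend matters at razor-edge boundary pixels: the denoised field carries
the regional structure, while the raw term lets a decisive single-pixel
measurement win, which keeps the noise-free limit exactly equal to the
generating geometry. The averaged marker score is thresholded per section by
two-class Otsu refined with Ridler–Calvard intermeans (plain Otsu parks the
threshold at an arbitrary point of an empty histogram gap). Annotation is
refused when (a) two markers' denoised images correlate below 0.65 over
tissue (Pearson), naming the disagreeing marker, or (b) a kernel-density
estimate of the denoised marker score shows no second mode (e.g. a
single-region section). Because denoising and min-max normalization are
linear/affine, labels are invariant under positive affine rescaling of any
marker image; invariance under arbitrary monotone transforms is *not*
claimed — a rank transform would make every marginal uniform and erase the
density valley the threshold needs.

Marker acceptance is validated as in the motivating workflow: tm-vs-tam
AUC < 0.35 at rank-sum p < 0.001, with AUC oriented as P(core intensity >
adjacent intensity), so a depressed marker scores near zero.

## Unsupervised analyses

*OMP peak selection* greedily approximates the standardized, mean-centered
feature matrix by its own columns, re-orthogonalizing the residual after
each pick; standardization makes selection order reflect correlation
structure rather than intensity scale. Mutually redundant marker columns are
deliberately skipped once their structure is explained — the guarantee is
"selected early or explained by the early selection", which the tests assert
as R² ≥ 0.5 against the first `n_markers + 5` picks.

*Bisecting k-means*: recursive 2-means (scikit-learn, fixed seeds, n_init
10) on the standardized OMP-selected columns; at each level the segment with
the largest within-segment SSE splits, so level k + 1 refines level k and
trees are reproducible. Off-tissue spectra are excluded before segmentation.

*PCA*: unit-variance scaling, constant columns dropped with a warning,
components ordered by explained variance, sign fixed so each loading
vector's largest-magnitude entry is positive (score-image polarity is
otherwise arbitrary).

*PLSA*: the aspect model P(w|d) = Σ_z P(w|z) P(z|d) fitted by EM on the
nonnegative spectra × peaks matrix; P(z|d) are the component score images,
P(w|z) the peak loadings. Both factors are renormalized to simplices every
step (holds to 1e-8) and the log-likelihood trace is non-decreasing.
Initialization is deterministic NNDSVD seeding that uses *both* signs of
each singular pair beyond the first: a singular vector encodes a signed
contrast between two spectrum populations, and keeping only its dominant
side (classical NNDSVD) discards one of them — with both sides, a
bidirectional group contrast (peptides up in treated vs up in control
tissue) seeds two distinct components, and on the default batch one
component's top-decile pixels concentrate ≥ 70% in treated-adjacent tissue
and another's in control-adjacent tissue. EM stops at relative
log-likelihood change < 1e-7 or 500 iterations.

Five components are computed although four tissue states are expected
(tm/tam × treated/control); the surplus absorbs background and noise
structure rather than forcing it into the interpreted components.

## Marker discovery

AUC is the Mann-Whitney U statistic divided by n_a·n_b, computed from
midranks (ties count half). The rank-sum p-value is exact — full enumeration
of the C(n_a+n_b, n_a) group assignments of the pooled midranks, correct
under ties — when n_a + n_b ≤ 12, and otherwise uses the normal
approximation with midrank tie correction and 0.5 continuity correction;
both paths are cross-checked against independent enumeration and scipy.

Two named filter profiles exist because the thresholds differ between the
marker classes: `treatment_marker` (AUC < 0.35 or > 0.65, p < 0.01, mean
ratio > 1.2 or < 0.8) and `region_marker` (AUC gates, p < 0.001, min-max
normalized mean-intensity delta > 0.3 — the "delta" is interpreted as the
absolute difference of min-max-normalized ROI means, configurable). All raw
statistics are retained for failing columns; rows follow feature-column
order. No multiple-testing correction is applied by default — the joint
AUC + p + ratio gate is the filter — but a Benjamini–Hochberg q-value column
is available. A zero denominator makes the ratio infinite and the peak fails
the gates. Balanced subsampling (uniform without replacement, seeded)
equalizes ROI sizes; at full study scale 6000 spectra per ROI/group is the
convention, scaled to 400 in the tests.

## Identity transfer

Monoisotopic masses are summed from the standard 5-decimal residue table
plus one water (18.010565 Da), with optional methionine oxidation
(+15.994915 Da); the implementation is cross-checked against pyteomics. The
curated reference panel of 14 LC-MS/MS-identified muscle peptides (Col6a1,
Hspa8, Ca3, Myl3, Flnc, Tnc) reproduces its printed experimental neutral
masses within 0.01 Da (0.011 Da for four sequences whose second-decimal
rounding straddles the 0.005 boundary). Imaging ions convert to neutral mass
via m/z·z − z·1.007276 (MALDI peptides: z = 1). A candidate peptide matches
when its mass difference is strictly below 0.9 Da; the lowest difference
wins, ties break by ppm then lexicographic sequence (logged), and a protein
is accepted only when ≥ 2 distinct peptide sequences are matched by distinct
imaging ions. Reports follow the customary identification-table column
order with per-protein grouping.

## The synthetic study design

Each section is a grid (default 40×40) holding an elliptical tissue blob
(semi-axes 0.44 × grid) with an elliptical trauma core whose area targets
`tm_fraction` (default 0.25 — a compact core inside the section; the
realized pixel share must land within ±20% of the target or the layout is
rejected as too coarse). Two sections per group by default (configurable to
three, the full study shape, via `--paper-scale`).

The default peak panel holds 50 peaks in m/z 800–3500 with ≥ 1 Da spacing:

* 10 **region markers**, depressed in the core in both groups (factors
  0.4–0.7; the two designated annotation anchors at 0.45/0.50, emulating
  the strong alpha-actin contrast), base intensity U(100, 1000) —
  trauma broadly depletes structural muscle peptides;
* 5 **treatment markers** in the trauma-adjacent region only, ratio
  magnitudes U(1.5, 4) with direction per marker (up in treated or up in
  control), base intensity U(150, 400). Moderate abundance is both realistic
  (regulatory vs structural proteins) and bounds the crosstalk that TIC
  normalization induces on null peaks to a few percent — measured null AUCs
  stay within 0.44–0.49, far from the 0.35/0.65 gates. The markers carry
  reference-peptide identities (their m/z is the peptide's [M+H]+), ordered
  so consecutive markers complete two-peptide proteins in both directions;
* 35 **null peaks** (all factors 1).

Per pixel and peak: intensity = base × factor(region, group) ×
exp(N(0, cv)) × exp(N(0, tic_cv)), the second factor shared across a
pixel's peaks, plus additive N(0, noise_sd) clipped at zero; off-tissue
pixels carry only noise (and, in profile mode, an exponentially decaying
baseline). Defaults cv = 0.3 and tic_cv = 0.2 are stated conventions for
realistic spot-to-spot variability, not inferences; `cv` is the log-scale
σ, which for cv ≤ 0.3 is within 5% of the true coefficient of variation.
Profile mode renders Gaussian peak shapes (σ 0.15 Da on a 0.1 Da grid) and
exists for testing the profile-only operations; pipeline-scale runs use
centroid mode. All randomness derives from one master seed through named
per-stage streams, so runs are bit-identical.

What the generator does **not** emulate: isotope envelopes, detector
saturation, mass-calibration drift, spatially correlated noise, chemical
(matrix) background peaks, and partial-volume mixing at region boundaries.
Passing tests therefore demonstrate that the chain recovers planted
multiplicative region/treatment structure under log-normal noise — not that
it is robust to every artifact of real acquisitions.

## Problem sizes and determinism

The default batch (4 sections × 1600 pixels × 50 peaks) runs the whole
pipeline in a few seconds; the test suite's type-I experiment uses 100
replicates of a 20×20, 20-peak null design. These sizes were chosen so the
parameter-recovery surface (effects ≥ 1.5×, cv 0.3, ≥ 400 pixels per ROI
side) is comfortably identifiable while iteration stays fast. Reruns with
the same config reproduce every CSV byte-identically; the only
non-deterministic manifest fields are wall times.

## Known limitations

* The annotation threshold assumes a bimodal marker score; gradual
  core-to-adjacent transitions (no sharp boundary) would need a different
  region model.
* The exact rank-sum path enumerates up to n = 12; between exact and
  asymptotic regimes (n ≈ 13–20 with heavy ties) the normal approximation
  is the weakest link, though cross-checks at n = 6+6 agree within 0.02.
* PLSA component identity is data-dependent: which component captures which
  tissue state can permute between datasets; tests therefore assert
  existence of localized components, not their index.
* Identity transfer trusts the LC-MS/MS table; no FDR re-estimation is
  attempted, and a 0.9 Da tolerance cannot distinguish isobaric peptides —
  the two-peptide protein rule is the only guard.
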