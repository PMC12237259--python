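# Methods

`nmjquant` re-implements, as a tested library, the quantitative analysis
stack used for *Drosophila* larval NMJ presynapse studies: confocal punctum
quantification inside an HRP-defined neuronal mask, Pearson colocalization
with a flipped-channel control, STED-scale distance and radial-profile
analysis around active-zone (AZ) centers, electrophysiological trace metrics
up to readily-releasable-pool (RRP) back-extrapolation, and T-maze
behavioral indices with the accompanying statistical decision tree. All
stages are exercised end to end on synthetic data with known ground truth.

## Image quantification

**Containers.** `ImageStack` holds a `(c, z, y, x)` array with an in-plane
pixel pitch (default 100 nm for confocal, 20 nm for STED) and a z step
(default 0.25 µm, within the 0.2–0.3 µm optical sectioning the simulated
stacks emulate). Coordinates are 0-based `(z, y, x)` pixel indices with the
pixel-center convention; areas are pixel counts × pitch².

**Masking and cleaning.** The neuronal-membrane (HRP) channel is thresholded
(`pixels > t`) into a binary mask that restricts all measurements to the
terminal. The original protocol's manual threshold is replaced by a
configurable scalar plus logged auto-strategies (Otsu, Moments), since a
hand-picked value is irreproducible. For proteins with a muscle contribution
the mask is applied per optical slice *before* maximum projection
(`clean_stack_per_slice`), so out-of-focus muscle signal never reaches the
projection. Background subtraction is a scalar estimate (fixed, ROI mean, or
histogram mode) clamped at zero; the protocol is silent on negative pixels.
The per-slice threshold may differ from the projection threshold — both are
explicit arguments.

**Spot segmentation.** `find_maxima` reports local maxima (8-connectivity)
whose topographic prominence (height above the highest saddle to any higher
peak) exceeds the noise tolerance — a re-specification of the ImageJ
Find-Maxima rule. A plateau yields one representative point: its centroid
rounded to the nearest pixel, ties broken lexicographically. When two equal
peaks merge at their connecting saddle, the earlier (raster-order) peak
survives; for noise-free equal maxima this is undocumented in the original
tool, and tests therefore use unique-valued images where prominence is
unambiguous. The maxima seed a watershed on inverted intensity restricted to
the supra-threshold mask — the automated equivalent of hand-drawn 1-pixel
separation lines. Intensities are then measured on original gray values via
min-combination of the mask with the unmodified image. The noise tolerance
is a required parameter; no default is claimed.

**Metrics.** Per spot: area, centroid, mean and integrated intensity;
sub-cutoff labels (e.g. the 0.0202 µm² early-endosome cut-off) are removed
before any statistic. Per NMJ: unweighted mean spot area, density (count /
HRP-mask area, an exact identity), unweighted mean of per-spot mean
intensities, total count, and integrated density (sum of in-mask
intensities). NMJ length is measured by skeletonizing the HRP mask and
accumulating inter-pixel edges (diagonals √2) — a surrogate for hand-drawn
branch lines that only affects length-normalized metrics. Group values are
expressed as percent of the control mean (control ≡ 100%); the
driver-control background-subtraction variant subtracts that group's mean
first.

## Colocalization

Pearson's r is computed over in-mask pixels. Automatic thresholds follow the
Costes construction: total-least-squares (major-axis) regression of channel
2 on channel 1 gives a line along which candidate threshold pairs are
scanned from the top intensity down; the accepted pair is the highest for
which the sub-threshold pixels are uncorrelated (r ≤ 0). `Rcoloc` is r over
pixels where *either* channel exceeds its threshold (both-sub-threshold
pixels excluded, the plugin convention). The negative control mirrors
channel 2 horizontally and repeats the whole procedure; for left-right
symmetric content this control is degenerate (r = 1), a documented caveat.
Mean-intensity normalization to a maximum of 256 (exactly as stated, not
255) precedes thresholding.

## STED-scale analysis

**K-neighbor distances.** Planar AZs are analyzed in 53 × 53-px ROIs
(1.06 µm at the 20-nm default pitch; the pitch is a parameter because the
printed per-pixel area of 18.9 nm² conflicts with the stated ROI
equivalence). The BRP ring center is the intensity-weighted centroid after
subtracting the ROI minimum (subpixel); partner coordinates are integer
Find-Maxima pixels; Euclidean distances are ranked (k1…k5, NaN-padded),
counted within 400 nm, and AZs are binned by supra-threshold scaffold pixel
area into small [1, 159], middle [160, 215] and big > 215 px² (the printed
big-bin label "<215" contradicts the other edges and is implemented as
> 215). Per-animal averaging is an optional grouping key on the result
table.

**Radial profiles.** Cluster centers come from moments-preserving (Tsai)
auto-thresholding followed by prominence-filtered maxima. The Tsai threshold
is computed on a 256-bin histogram: the below-threshold fraction p₀ and two
representative levels preserving the first three gray-level moments are
solved in closed form and the threshold is the p₀-tile. Annulus-mean
intensity versus radius (bins centered on multiples of the bin width) is
computed per cluster in both channels, reduced to a per-image median, and
aggregated across images as the mean with Student-t 95% CIs (n − 1 df; the
source states only "means ± 95% confidence intervals"). "Normalized"
profiles divide each channel by its maximum bin.

## Electrophysiology

Sign convention: inward currents negative (nA), potentials positive (mV).
The 500-Hz Gaussian low-pass filter uses the half-amplitude convention
σ = √(ln 2 / 2)/(π f_c), stated explicitly because acquisition packages
differ. Miniature events are detected by the Clements–Bekkers sliding
scaled-template criterion (optimal scale + offset per window; criterion =
scale / fit standard error; default threshold 3.5), deduplicated to one
detection per 10-ms refractory window; the template is the unit-peak
difference-of-exponentials kernel (default rise 1 ms, decay 5 ms, truncated
at 15 ms — a truncation chosen so the fitted window is dominated by the
event flank rather than baseline) scaled to the expected amplitude, since no
waveform parameters are published. Event times mark template onset.

Averaged evoked responses use per-sweep pre-stimulus baselines and excise a
configurable artifact window (default 1 ms) by linear interpolation.
Kinetics: 10–90% rise time by linear interpolation of the normalized rising
phase (last 10% crossing, first subsequent 90% crossing); decay τ from a
single-exponential least-squares fit on the magnitude trace between the 60%
and 5% post-peak crossings; charge as the trapezoidal integral (1 nA·s =
1000 pC). Quantal content is |evoked| / |mini|. The paired-pulse ratio
takes A1 from the sweep baseline and A2 from the last data point before the
second stimulus artifact.

**RRP back-extrapolation.** Per-stimulus amplitudes of the 61-stimulation,
100-Hz train are extracted against the last point before each artifact,
cumulated, divided by the cell's mean mini amplitude, and the last 20
cumulative quantal contents are fit by OLS against stimulus number:
intercept = RRP (quanta), slope = refill per stimulus. For the depressing
recurrence `released_i = p·pool_i`, `pool_{i+1} = pool_i − released_i + R`,
the cumulative line is `C_i = R·i + (N0 − R/p)(1 − (1 − p)^i)`, so the
intercept estimates `N0 − R/p` — exactly `N0` when R = 0, and a documented
downward bias otherwise that is a property of the published estimator, not
of this implementation. Overlapping responses at the 10-ms ISI introduce an
additional few-percent underestimate through the pre-artifact baseline rule.

## Behavior and statistics

The choice index is `(n_avoiding − n_approaching)/total`; the performance
index averages two reciprocal runs, which algebraically cancels any fixed
arm/odor bias. Group comparisons follow the fixed route: D'Agostino–Pearson
omnibus normality per group (requires n ≥ 8; smaller groups route to the
nonparametric branch — the aggregation rule "all groups must pass" is this
package's choice, as the source is silent); all normal → unpaired two-tailed
t test (2 groups) or one-way ANOVA with Tukey HSD (> 2); otherwise
Mann–Whitney U (2) or Kruskal–Wallis (> 2, this package's extension of the
stated rules). Outliers: iterated two-sided single-Grubbs at α = 0.05,
removing at most one point per pass — the single-outlier-per-pass variant
used by common outlier calculators.

## Synthetic data

The generators are pure functions of their parameters including the seed
(identical seed → bit-identical output). Defaults describe the study
conditions: 8-bouton terminals ~25 µm long with ~150 puncta (PSF σ 0.1 µm)
at 100-nm pitch and 0.25-µm z-steps; STED tiles of 53 px at 20 nm with
annular scaffolds (radius 150 nm, σ 40 nm); 90-s miniature records at
10 kHz, ~1 Hz, 0.7-nA events with 25% amplitude CV; trains of 61 stimuli at
100 Hz from the release recurrence (N0 = 500, p = 0.3) with 2-sample
rectangular stimulus artifacts so artifact-exclusion logic is exercised;
reciprocal T-maze runs of 40–50 flies. Noise is Poisson(signal) followed by
additive Gaussian, both optional. Muscle background reuses the punctum
generator outside the HRP envelope, mimicking the muscle contribution the
cleaning workflow must remove. STED AZ centers jitter on the pixel grid so
offsets stated in whole pitch multiples land on pixel centers, keeping the
distance truth well-defined at pixel resolution.

Deliberately not emulated: optics-accurate PSFs, deconvolution, detector
nonuniformity, biological variability beyond the stated distributions,
recording drift, and seal/access artifacts. Passing recovery tests therefore
demonstrates correctness of the measurement chain on data obeying the stated
models, not robustness to every property of real recordings.

## Numerical choices and problem sizes

Thresholds and tolerances are explicit arguments throughout and logged where
the original workflow made manual choices. Watershed uses 8-connectivity;
ties in Find-Maxima are resolved deterministically (raster order). The
moments threshold bins float images into 256 levels between min and max,
which makes it exactly shift-equivariant. Decay fits seed a log-linear
estimate before the nonlinear fit. Test and acceptance runs use 10 seeds for
image recovery, 1,000 random configurations for the distance oracle, 50
seeds for the stochastic RRP median, 10 × 90-s traces for detection
performance, and 2,000 samples for the Grubbs type-I rate — sizes chosen so
the whole suite completes in well under a minute while keeping Monte-Carlo
standard errors far below the tested tolerances.

## Known limitations

* The Find-Maxima equal-peak tie rule is a specification of this package;
  other implementations may report a different representative for exactly
  tied maxima.
* The flipped-channel colocalization control is meaningless for left-right
  symmetric content.
* RRP intercepts inherit the `N0 − R/p` bias and the overlap-related
  underestimate described above.
* Skeleton length slightly overcounts at dense junctions (diagonal +
  orthogonal double edges) and differs from hand-drawn branch lines by
  end-effects of about one pixel per branch.
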