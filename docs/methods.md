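# Methods

## The measurement

The quantity of interest is the *fluorescent integration* of each
pair-rule stripe: the area under the embryo's one-dimensional AP
fluorescence profile between the stripe's boundaries, in arbitrary
intensity units times percent egg length (a.u.·%EL).  Because it is an
area, both the width and the height of a stripe enter the number; a
stripe that narrows or dims loses integration either way.  The profile is
computed only from the central band of the embryo (by default the central
10% of the dorsal–ventral extent, |v| ≤ 0.05), where the blastoderm
surface is roughly parallel to the imaging plane and stripes run
perpendicular to the AP axis.

### Geometry

The embryo mask comes from the nuclear channel: Gaussian smoothing
(σ = 2 px), Otsu global threshold, largest connected component, hole
filling.  A constant image, an empty mask, or a mask hugging more than
half the image border raises a segmentation error.  The AP/DV frame is
the principal-axis frame of the mask's second central moments; a
near-circular mask (eigenvalue ratio < 1.2) is rejected as ambiguous.
Axis *extents* — which normalize u to [0, 1] between the embryo tips —
are measured on the sub-pixel iso-contour of the smoothed nuclear channel
at the Otsu level when available, because pixel-center extremes jitter by
±0.5 px with rotation of the imaging frame, and that jitter alone moves
steep profile flanks by a visible fraction of a percent.  The 180°
ambiguity of the AP axis is resolved by metadata (`anterior: left|right`)
or, in `auto` mode, by placing the strongest stripe in the posterior half
— valid for wild-type-like patterns (stripe 7 strongest) but deliberately
not the default, since it misorients embryos whose posterior expression
is strongly reduced.

### Profile and stripe calls

Band pixels are background-subtracted by the q-th percentile rule
(default q = 5).  The percentile is taken over coarse per-bin mean
intensities (50 bins) rather than raw pixels: under additive noise the
raw-pixel percentile estimates background − ~1.6σ, which would inflate
every integration by a baseline offset; bin means estimate the same level
without the bias.  Negatives are clamped to zero.

The profile is the per-bin *mean* (not sum) of sample intensities over B
uniform u-bins (default B = 100, i.e. 1% EL), so the varying thickness of
the band across the ellipse does not weight AP positions unequally.  Each
bin's mean is located at the samples' mean u within the bin and
interpolated onto the uniform grid, which removes rasterization-induced
sub-bin distortion.  Empty bins are linearly interpolated; more than 20%
empty bins aborts.  A centered moving average (default window 3 bins)
smooths the profile.

Stripes are called on the smoothed profile: local maxima with prominence
≥ 5% of the profile maximum; boundaries between adjacent peaks at the
interpeak minimum (sub-bin position by 3-point parabolic interpolation);
outer boundaries where the profile first falls below 0.2 × the outermost
peak's height (sub-bin position by linear interpolation), or at the
profile ends.  Integration is the exact trapezoidal area of the
piecewise-linear profile between the continuous boundaries (×100 for
%EL units), which makes integration exactly additive over any partition
of a stripe's interval.  The centroid is the intensity-weighted mean u
between the boundaries; the width is the boundary distance.  When fewer
than the expected number of peaks are found and reference centers are
supplied, missing stripes are quantified in a fallback window of
half-width 2.5% EL around the reference center, clipped against
neighboring calls — so a nearly absent stripe yields a near-zero
integration instead of a missing value.  Boundary placement and the
fallback rule are this package's explicit constructions; they are
recorded in run metadata for reproducibility.

The control channel (an unaffected gene such as *eve*) can be quantified
identically for quality control; it is *not* used to normalize target
integrations, since the experiment this pipeline models treats it as an
internal staining control only.

### Group statistics

Per stripe and genotype: n, mean, sample SD (n − 1).  The genotype effect
is summarized as the ratio of group means, pct = 100·x̄ₘᵤₜ/x̄_wt, with SD
from first-order (delta-method) propagation,
pct_sd = pct·√((sₘᵤₜ/x̄ₘᵤₜ)² + (s_wt/x̄_wt)²), written in a form that stays
finite as x̄ₘᵤₜ → 0.  Inference is a two-sided Welch t-test from the group
summaries with Welch–Satterthwaite degrees of freedom; family-wise error
across the seven stripes is controlled by Holm's step-down procedure, and
significance is called at adjusted p < 0.05.  Welch and Holm are
*inferences* about the published analysis this package reproduces: that
analysis names neither its test nor its adjustment, but recomputing its
table from its own printed summaries reproduces every raw p-value (e.g.
0.564, 0.0546) only with the unequal-variance test, and every adjusted
p-value (e.g. 0.00251 × 7 = 0.0176) only with Holm — Benjamini–Hochberg
does not.  Raw-scale values (not log-transformed) reproduce the printed
numbers.  The same machinery applies unchanged to stripe widths and
centroid positions (`compare_widths_and_centers`).

## The synthetic generator

The generator emulates what the pipeline needs from a lateral-view
blastoderm HCR image and nothing more: an ellipse (default semi-axes
170 × 70 px in a 220 × 400 frame) of uniform nuclear intensity; a target
channel of background plus a sum of Gaussian stripes in u, uniform across
DV; optional additive Gaussian noise (default SD 2% of the maximum stripe
amplitude) and optional Poisson resampling (off by default — no imaging
noise model is mandated by the data being emulated, so the minimal one is
the default).  Seven stripes sit at u = 0.25 … 0.73 with σ = 0.017 egg
lengths, matching pair-rule stripes about four cells (~4% EL) wide;
default amplitudes are proportional to the published wild-type (or
mutant) per-stripe integration means.  Specs are validated: stripes must
fit inside the embryo (center ± 3σ), the ellipse inside the frame,
semi-axes above 2 px.

Ground truth per stripe is computed by applying the pipeline's own
boundary rule to a dense (20 001-point) sampling of the analytic
noiseless profile *after* the default 3% EL moving average — i.e. the
truth is the infinite-resolution limit of the full measurement rule.
Defining truth on the unsmoothed profile instead would shift asymmetric
interstripe minima (a weak stripe beside a strong one) and misattribute
~2% to the pipeline as recovery error.  Because stripe geometry is
defined in embryo coordinates, ground truth is exactly invariant under
rotation of the imaging frame.

Cohorts draw each embryo's per-stripe integration from Normal(mean, SD)
truncated at zero — integrations are nonnegative, and mean ± SD summaries
are all the emulated experiment reports, so the truncated normal is the
minimal consistent model.  One consequence worth knowing: for groups with
large CV (the mutant stripe-7 group has SD ≈ mean), truncation shifts the
realized mean well above the nominal parameter (~+27% there); for groups
with mean/SD ≳ 2.5 the shift is negligible.  Each embryo contributes one
draw per stripe (one image per embryo, no optical-section averaging);
per-embryo averaging of replicates, if desired, is a pre-processing step
on the tidy table.

### What passing tests do and do not show

The synthetic embryo is an idealization: sharp-edged ellipse, DV-uniform
stripes, flat background, stationary Gaussian noise.  Passing recovery
tests therefore demonstrates the correctness of the geometry, profiling
and integration *algorithms*, not robustness to real-image phenomena —
curvature of the blastoderm surface, nuclear texture, uneven staining,
out-of-focus light, touching embryos.  The segmentation and
background-processing steps stand in for supplementary protocols of the
emulated experiment that are not reproduced here.

## Numerical choices and problem sizes

- Defaults: B = 100 bins, smoothing window 3, background percentile 5,
  peak prominence 0.05, outer-boundary fraction 0.2, fallback half-width
  2.5% EL, band fraction 0.10, α = 0.05.  All configurable; every run's
  parameters are serialized next to its outputs.
- Degenerate inputs have defined behavior: both group SDs zero with equal
  means → p = 1 by convention (unequal means raise); empty profile with
  reference centers → seven zero-integration fallback calls; zero-SD
  cohort stripes degenerate to their mean.
- Ties in peak pruning are resolved by prominence, then AP order; the
  parabolic minimum refinement is clipped to ±half a bin.
- Test and acceptance problem sizes were chosen to exercise the methods
  at study scale while keeping runs quick: 20 synthetic embryos for
  recovery checks, 200 simulated cohorts at the published n = 6/5 for the
  Monte-Carlo behavior of the comparison, 10 000 draws for
  law-of-large-numbers checks, 200 000 for delta-method validation.

## Known limitations

- 2D only: no z-stacks, no surface curvature correction; the central-band
  restriction is the mitigation, not a cure.
- The `auto` anterior heuristic fails when posterior stripes are strongly
  reduced; supply orientation metadata for mutant-heavy datasets.
- The ratio-of-means percentage with delta-method SD is first-order; at
  group-mean CVs beyond ~0.5 the propagated SD understates the skew of
  the ratio distribution.
- Under the truncated-normal cohort model at n = 6/5, stripe 4 is the
  minimum-percentage stripe in roughly 86% of replicates (its Holm
  significance rate is ~75–80%, and no other stripe exceeds 50%): with
  five mutant embryos, the high-variance stripes 5 and 7 occasionally
  undercut it.  Single-study rankings at these group sizes are noisy even
  when the underlying effect is real.
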