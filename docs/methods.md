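# Methods

## Measurement model

A sample's isoform composition is parameterized by three fractions: the
long-fragment (acidic-cluster) share `f_long` read from the gel, and the
serine-insertion fractions `s_short` and `s_long` within the short and
long RT-PCR bands, read from each band's mixed chromatogram.  The
four-isoform profile is the product form

    A = (1 − f_long)(1 − s_short)     C = (1 − f_long)·s_short
    B = f_long(1 − s_long)            D = f_long·s_long

This assumes the two splice events combine multiplicatively *within the
measurement*: because each band is excised and sequenced separately, the
only observable association between the events is the band-level serine
fraction, so the product estimator is the maximum the data identify.  The
map (f_long, s_short, s_long) → (A, B, C, D) is a bijection on the open
cube; `band_fractions` is its inverse.  When `f_long` is 0 or 1 the serine
fraction of the absent band is unidentifiable and is simply carried
through as given, not validated.  Complements are computed by subtraction
(`A = (1 − f_long) − C`) so profiles sum to 1 exactly in floating point.

Replicate aggregation averages per-replicate isoform *fractions* (not raw
amplitudes), then renormalizes the means and reports the sample SD
(ddof = 1) per isoform; a single replicate reports SD 0.  Averaging
fractions matches how technical replicates of ratio measurements are
conventionally summarized (mean ± SD per displayed quantity).

## Trace decomposition

A mixed electropherogram downstream of an insertion junction superimposes
two reads shifted by the insert length.  Sites where the two species
predict different bases are *informative*; the default picks the first
`n_sites = 3` differing positions downstream of the junction, because
amplitude decays along the read and the earliest sites carry the most
signal.  Three sites mirror common practice of reading three nucleotide
amplitudes off a mixed profile.

**Peak amplitude reading.**  The amplitude of a channel at a called peak
is the channel's value at the peak apex after light Gaussian smoothing
(`smooth_sigma = 1.0` scans; 0 disables).  Two alternatives were rejected
after measurement: (i) the raw value at the apex is exact on noiseless
data but inherits the full scan-level noise, and (ii) a window *maximum*
around the peak — superficially closest to reading a printed profile —
is biased upward by the maximum of the noise within the window (at 5%
scan noise it pushes a true fraction of 0.10 to ≈ 0.16) and, on noiseless
data, picks up the tails of neighbouring same-base peaks at the window
edge.  Smoothing attenuates all channels by the same factor, so amplitude
ratios are unchanged; with the default peak width (sigma 1.8 scans) and
spacing (12 scans), neighbouring-peak leakage into the smoothed apex is
below 1e-7 of the base amplitude.

**Amplitude-ratio estimator.**  Per site, `f_i = a(+base) / (a(+base) +
a(-base))` using only the two predicted channels (insensitive to baseline
in the other two); the estimate is the mean of `f_i` with the sample SD
as dispersion, clamped to [0, 1].  Sites where both predicted channels
read zero are dropped with a warning; if all sites drop, the estimate is
an error rather than a guess.

**Least-squares estimator.**  Over all junction-window peaks shared by
both reads, minimize `Σ_i ‖obs_i − f·E+_i − (1 − f)·E−_i‖²` where `E±`
are one-hot expected channel patterns and `obs_i` is the observed channel
row at peak `i` *normalized to unit sum*.  Channel sums at a peak are
conserved under the mixture model (the two species' weights add to 1), so
the per-peak normalization absorbs the amplitude scale and its
exponential decay exactly; a single shared scale factor would not.  The
unconstrained minimizer is the closed-form projection
`f* = Σ⟨obs − E−, E+ − E−⟩ / Σ‖E+ − E−‖²`, clamped to [0, 1].  If the two
species agree at every peak in the window (e.g. a homopolymer junction)
the mixture is unidentifiable and the function raises.  The closed form
is validated in the tests against an exhaustive grid search of the same
objective (step 1e-3).

Reverse-primer reads are handled by explicitly reverse-complementing the
reference pair (`ReferencePair.reverse_complemented()`, CLI `--revcomp`);
strand is never inferred from the data.

## Densitometry

Lane profiles are background-subtracted (straight line through the first
and last 5% of pixels, or a rolling-minimum baseline; negatives clipped
to zero).  Each labelled band is the local maximum nearest its expected
migration position within a tolerance (default 10 px); a label with no
maximum in reach reports volume 0 rather than an error, since a missing
band is a legitimate measurement (`f_long = 0` or 1).  Conflicting label
claims on one maximum go to the nearer expected center; an exact tie
raises.

Band center and width are fitted at the apex: a Gaussian band is an exact
parabola in log intensity, so a three-point log-parabolic fit returns
subpixel center and sigma to machine precision on clean data; when the
fit is unusable (boundary peak, zero neighbours, non-negative curvature,
implausible width) the half-maximum crossing width is used instead.
Volume is the cubic-spline integral of the profile over center ± 3
half-widths (≈ ±3.53 sigma, capturing 99.96% of a Gaussian band).  The
window is deliberately *not* wider: with bands allowed as close as four
combined sigmas, a ±6-sigma window would swallow several percent of the
neighbouring band, whereas the ±3-half-width window keeps
cross-contamination below 1e-5 while the truncation bias (0.04%) cancels
in ratios of same-width bands.  Grid-trapezoid integration with half-max
widths was measured at ~1e-4 relative ratio error (subpixel band centers
shift each band's captured fraction); the apex fit plus spline quadrature
brings the noiseless 312:688 two-band ratio to within 2e-7.

`long_fraction` is the intensity ratio `V_long / (V_long + V_short)` with
*no* length correction by default — reproducing what ImageJ-style
densitometry measures on a mass-proportional stain.  An optional
per-fragment length correction (divide volumes by fragment length)
converts mass staining to molar fractions; with the default 542/500-nt
fragments the correction shifts an equal-volume lane from 0.500 to 0.480,
quantifying the bias the uncorrected ratio carries.
`normalize_to_reference` divides a target band volume by a loading-control
(e.g. GAPDH) band volume for relative-expression readouts.

## Statistics

- `t_test_unpaired`: Student's pooled-variance two-tailed t-test (Welch
  optional).  Degenerate zero-variance inputs return p = 1 (equal means)
  or p = 0 (unequal), instead of NaN.
- `f_test_variance`: F = var(x)/var(y), df (n_x−1, n_y−1); two-tailed
  p = 2·min(P(F ≤ f), P(F ≥ f)) capped at 1.  Two-tailed is the
  conservative default when no direction of the dispersion change is
  pre-specified, and makes p invariant under swapping the samples.
- `two_way_anova`: ordinary least squares with interaction and Type II
  sums of squares, valid for the unbalanced cell counts of
  three-or-four-replicate assays; empty cells raise with the cell named.
  Degenerate decompositions resolve as: zero effect SS → F = 0, p = 1;
  nonzero effect with zero residual → F = ∞, p = 0.
- α = 0.05 is reported in CLI output but never hard-gates any library
  result.

The test suite compares the t-test against an exhaustive 70-assignment
permutation oracle using the mid-p convention (half weight on tied |t|),
which is the appropriate comparison when a heavily tied discrete null is
held against a continuous reference distribution.

## Synthetic data generator

Electropherograms: for base `i` of each species, a Gaussian peak (sigma
1.8 scans) at `i × 12` scans in that base's channel, amplitude
`1000 × exp(−0.005·i)` arbitrary units, weighted by the species fraction;
optional channel crosstalk (default 0 — analyzed traces are assumed
spectrally calibrated) leaks a fraction evenly into the other channels
while conserving channel sums; i.i.d. Gaussian scan noise (default SD 50
= 5% of the base amplitude, the noise condition all robustness numbers
are quoted at) truncated at zero.  Peak calls are placed on the exact
grid; there is no mobility shift between species, since co-amplified
fragments run in one reaction.

Gel lanes: band centers follow `position = 1700 − 250·ln(length)` pixels
(log-length migration, ≈20 px between the 542- and 500-nt fragments on a
400-px lane), Gaussian bands of sigma 2 px, volume proportional to molar
abundance (`molar`) or abundance × length (`mass`), constant background
20 units and Gaussian pixel noise SD 2, truncated at zero.  A
450-nt loading-control band is included in generated datasets.

Replicate bundles derive per-replicate seeds deterministically (base seed
+ replicate index, expanded through `numpy.random.SeedSequence`), so a
truth record and seed reproduce byte-identical serialized bundles.  The
junction sequence, the 3-nt serine insert (AGC) and the 42-nt
acidic-cluster stand-in (fourteen Asp/Glu codons) are placeholders — the
real junction nucleotides are not published — and are parameters
everywhere; no estimator hard-codes them.

**What the generator does not emulate:** PCR amplification bias between
species, primer artifacts, dye blobs, base-caller miscalls, mobility
shifts, saturated peaks or bands, lane smiling/warping, and 2-D gel
geometry.  Passing tests therefore demonstrate correctness of the
*quantification* given the idealized measurement physics, not robustness
to every artifact of real capillary or gel data; on real traces the
informative-site amplitudes should be inspected (`per_site_fractions`)
before trusting the mean.

## Problem sizes

The default verification runs use 11 noiseless fractions for the
round-trip check, 100 noisy instances for the grid-search oracle, 200
replicates per fraction (0.1/0.3/0.5) for stochastic recovery, 50
Dirichlet-sampled truths × 3 technical replicates end-to-end, 200 lanes
(two bands each) for densitometry accuracy, and 10,000 null pairs for
type-I calibration — sizes at which all reported margins are stable
across seeds (e.g. end-to-end per-isoform MAE ≈ 0.005 against a 0.05
bound; recovery ≥ 99.5% against a 95% bound).

## Known limitations

- Only two-species mixtures are decomposed; chimeric or three-allele
  junctions are out of scope.
- Amplitude reading assumes called peak positions (from the file's peak
  table or the built-in spacing-constrained detector); severely
  miscalled traces will degrade both estimators.
- Band quantification assumes approximately Gaussian, non-saturated
  bands; saturation flattening defeats the apex fit and falls back to
  the less precise half-max width.
- The mass→molar length correction assumes staining strictly
  proportional to mass, which intercalating dyes only approximate.
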