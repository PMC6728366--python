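# Methods

This note documents the models, conventions, numerical choices and known
limitations of the neuropol pipeline.

## Angular conventions

Orientation of a polarity *axis* is an axial quantity, defined modulo
180° and reported on the half-open interval (−90°, 90°], measured
anticlockwise from the +x (anterior–posterior) axis in a y-up frame.
The boundary convention maps −90° to +90°, so the 90° tie in an axial
difference is always broken to +90°. Kinocilium *directions* are modulo
360° on (−180°, 180°]. Image-derived coordinates (y down) are negated at
ingestion so "anticlockwise = positive" holds for data displayed on
screen; all internal math is y-up. Bins are left-open right-closed
everywhere (histograms, quadrants), so every tie-break is deterministic
and documented.

## Concentricity

The concentricity statistic asks whether hair-cell polarity axes follow
the organ outline. Pipeline, in order:

1. **Ellipse fit.** The organ outline is estimated from the scored cells'
   centers by PCA least squares: center = centroid, rotation = first
   principal axis, semi-axes = √2 × the per-axis standard deviations
   (population, ddof 0). For points uniform in the ellipse parameter t,
   var(a·cos t) = a²/2, so the √2 scaling is exact in the dense noiseless
   limit. An algebraic direct conic fit (`fit_ellipse_direct`) is kept as
   a sensitivity check; the PCA fit is the default. The fit can
   optionally use a separate reference cell set; by default it uses the
   scored cells themselves. Near-circular fits (a/b < 1.05) carry a
   conditioning flag because the rotation is then ill-defined.
2. **Projection.** Each cell is projected to the nearest boundary point
   by minimising the squared distance over the parameter t: a 720-point
   coarse scan, bounded Brent refinement in the bracketing interval, then
   up to five safeguarded Newton steps on the stationarity condition
   (P(t) − q)·P′(t) = 0. The scan-plus-bracket stage avoids the known
   instability of pure Newton iterations for points near the evolute; the
   Newton polish removes the O(√ε) slack Brent leaves, giving distance
   agreement with a 10⁶-point brute-force scan at the 10⁻¹⁵·a level. A
   point exactly at the center is degenerate; the major-axis vertex
   (t = 0) is returned with a flag.
3. **Deviation.** The signed axial difference between the tangent at the
   projected point and the cell's polarity axis. Deviations are
   frame-free: rigid motions of the whole field (positions and angles)
   leave them unchanged, which the test suite verifies to 10⁻⁶.
4. **Test and label.** Deviations are binned into 12 equal bins on
   (−90°, 90°] and tested against uniformity with a χ² goodness-of-fit
   test (statistic Σ(Oᵢ−n/k)²/(n/k), df = k−1, upper-tail p). The field
   is labelled *Concentric* iff p < α with α = 0.01. The choice of the
   binned χ² (rather than a continuous-sample test such as Rayleigh) is
   deliberate: the histogram is the primary data display, and the same
   one-way χ² is used for the support-cell analysis, keeping a single
   uniformity criterion across the package. A strongly *radial* field is
   also non-uniform; an optional stricter criterion additionally requires
   |μ| < 30°, off by default.
5. **von Mises fit.** Axial data are doubled onto the full circle,
   the mean direction and mean resultant length R̄ are computed there,
   κ solves A(κ) = I₁(κ)/I₀(κ) = R̄ (Best–Fisher start, Newton refinement
   on exponentially scaled Bessel ratios), and μ is half the doubled mean
   direction. Angle doubling is the standard axial treatment and makes κ
   directly comparable to the generator's concentration parameter. κ is
   capped at 1000 (R̄ → 1 gives κ → ∞); capped fits carry a flag.
   Low-count fields (< 5 cells) are analysed but flagged.

Nearest-neighbour alignment (signed axial difference to the Euclidean
nearest cell, distance ties broken to the lower cell id) is reported
alongside as the geometry-free companion measurement.

## Orientation, pairs and divisions

A kinocilium line drawn from the pole opposite the kinocilium toward it
gives the cell's direction; its axial wrap gives the polarity axis. A
sibling pair is scored *opposed* when each cell's direction lies within a
tolerance (default 90°, i.e. positive inner product) of the unit vector
toward its sibling; the published per-genotype percentages rest on a
visual criterion, so the numeric tolerance here is a package construction
and is a parameter. The division angle is arccos(|u·v|/|u||v|) ∈ [0°, 90°]
between the daughter–daughter vector u and the radius vector v from the
organ center to the daughter midpoint; it is scale-, translation- and
rotation-invariant and works in 2-D and 3-D. Condition comparisons use
Welch's t-test (unequal variances) by default.

## Cortical intensity profiles

Profiles are sampled along a closed cortical contour with a 4-pixel band
normal to the contour (bilinear interpolation, band mean), assigned the
angular position of each vertex about the contour centroid, and resampled
to a uniform 1° grid (360 samples) by circular interpolation. Alignment
rolls the maximum to 0° (ties to the first in scan order, flagged); the
angular support is (−179°, 180°]. Averaging is pointwise with SEM.

The peak model is a single Gaussian on a constant baseline,
I(θ) = B + A·exp(−θ²/2σ²), fitted by bounded nonlinear least squares
initialised from the maximum, the full-width-at-half-maximum and the
minimum. Parameter errors come from 100 Monte Carlo refits on data
resampled as fit + Gaussian noise with SD equal to the residual SD of the
primary fit; empirical-residual resampling is available as an option.
The 1-σ amplitude error bars achieve the nominal ≈ 68% coverage in
simulation at 5% noise. A wrapped-Gaussian alternative is unnecessary for
the σ ≲ 60° peaks this analysis targets; beyond that the plain Gaussian
underestimates the tails. Flat profiles are reported as degenerate
(amplitude 0, σ unidentifiable) rather than fitted.

Polarity ratios average the 3 grid values nearest each anchor (0°, 90°,
180°; the anchor's point and its two neighbours), with the SE of that
mean, and propagate to the ratios r = a/b via the first-order formula
σ_r/r = √((σ_a/a)² + (σ_b/b)²).

## Support-cell shapes

Each labelled region is summarised by the ellipse with equal second
central moments (scikit-image regionprops). The reported orientation is
folded to the unsigned range [0°, 90°] against the horizontal to match
the standard histogram presentation; the signed axial angle is retained
for reuse. The regionprops orientation convention was calibrated
empirically against rendered ellipses: a region drawn at math-frame axial
angle θ satisfies θ = wrap_axial(90° + orientation). Regions under 5 px
are rejected; axis ratio < 1.05 flags a near-circular region whose
orientation is excluded from the histogram (both thresholds are package
choices to avoid meaningless orientations). The default histogram is 9
bins of 10°; the bin count is configurable and recorded in the output.
Segmentation itself is out of scope — the module consumes label images,
decoupling results from any particular segmenter.

## Synthetic data

The generator supplies fixtures with the statistical structure the
analyses assume; its distributional choices are fixtures, not biological
claims. Defaults describe a realistic neuromast-scale field: 30 cells on
the boundary band of a 40 × 30 px ellipse (cells uniform in the ellipse
parameter, band thickness 15% of the radius — rosette geometry matching
the fitted-ellipse assumption), orientation noise κ = 4 (≈ 21° axial
SD), ring profiles with amplitude 3 on baseline 1 and σ = 25°, division
centers 10–30 px from the organ center. Orientation noise is von Mises
on *doubled* angles so κ has its standard circular meaning and is
directly comparable to the fitted κ; κ ≥ 1000 is treated as the
noiseless limit. A single seed expands into fixed per-component
substreams (SeedSequence spawn keys), so adding one generator call never
shifts another's output and identical seed + config is byte-identical.

What the generator does **not** emulate: photorealistic microscopy
(PSFs, shot noise), 3-D stacks, cell-cell packing mechanics, or
primordium migration dynamics. Passing tests therefore demonstrate the
correctness of the measurement pipeline, not robustness to segmentation
or annotation errors in real images.

Division events accept an optional angle-noise parameter (default 0)
beyond the three canonical models (radial/tangential/uniform); the
noiseless limits are what the geometry tests rely on.

## Validation problem sizes

The validation runs (`scripts/acceptance.py`, mirrored in the acceptance
test suite) use: 1000 random ellipse/point pairs against a 10⁶-sample
projection scan; 720-point noiseless boundaries for fit recovery; 200
replicates of 30-cell fields for the label's type-I error (exact binomial
99% band around α = 0.01) and power (≥ 95% at κ = 4); 1000 draws for von
Mises recovery (κ within 15%, μ within 3°); full enumeration of exact
tests to n = 20; 200 truths at 5% noise for Monte Carlo coverage (90-point
grids, 100 refits each); 30-cell label-image round trips (≤ 1° RMS); and
20 random rigid motions (≤ 10⁻⁶ shifts). These sizes make the whole
validation run in about a minute on one CPU while keeping every binomial
acceptance band narrow enough to be informative.

## Known limitations

* The ellipse fit assumes cells sample the organ boundary roughly
  uniformly in parameter; strongly clustered cells bias the fitted axes.
* The χ² uniformity test with 30 cells puts 2.5 expected counts per bin,
  below the textbook rule of 5; the simulated type-I error nevertheless
  sits at the nominal 1% (the result carries a validity warning when
  expected counts drop below 1).
* The concentric label tests *non-uniformity*, not tangent alignment per
  se, matching the published criterion; use the optional |μ| < 30°
  criterion when radial patterns must be excluded.
* Pair-opposition percentages depend on the chosen angular tolerance;
  report the tolerance alongside the percentage.
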