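# neuropol

Quantification of planar cell polarity (PCP) in zebrafish lateral-line
neuromasts — and in any rosette-shaped organ where cell orientation
matters.

## The problem

Hair cells in a neuromast carry a single kinocilium whose position defines
each cell's polarity. Wild-type organs coordinate these polarities along a
body axis (anterior–posterior for primI-derived organs, dorso-ventral for
primII). Two mutant classes break this coordination in *different* ways:

* **PCP-type** (e.g. *vangl2*): polarities are randomised — the angle
  distribution is uniform;
* **Wnt-type** (e.g. *wnt11f1*): polarities become **concentric** — each
  cell aligns with the tangent of the organ outline.

Telling these apart requires more than a rose diagram: it needs a
statistic that measures alignment *relative to the organ geometry*. This
package implements that full quantitative pipeline:

1. **Axial circular statistics** (`neuropol.circstats`) — orientation
   angles are axial (mod 180°, reported on (−90, 90]); the module provides
   wrapping, 12-bin histograms, a χ² uniformity test, maximum-likelihood
   axial von Mises fits (angle doubling), the quadrant binomial test of
   A-P vs D-V axis use, and Fisher's exact comparison between genotypes.
2. **Concentricity** (`neuropol.concentric`) — fit an ellipse to the cell
   centers (PCA least squares), project each cell to the nearest boundary
   point, take the signed axial deviation of its polarity axis from the
   local tangent, test the deviations against uniformity at p < 0.01, and
   label the field *Concentric* / *Not Concentric*.
3. **Orientation & divisions** (`neuropol.orient`) — kinocilium-line
   angles, pair-opposition scoring (sibling kinocilia pointing at each
   other), and progenitor division angles relative to the organ radius,
   arccos(|u·v|/|u||v|) ∈ [0°, 90°], with a Welch t-test between
   conditions.
4. **Cortical intensity polarity** (`neuropol.profilepol`) — extract
   4-px-thick angular intensity profiles around a cell cortex, align the
   maximum to 0°, wrap to (−179°, 180°], average with SEM, fit a Gaussian
   peak I(θ) = B + A·exp(−θ²/2σ²) with Monte Carlo (100-refit) parameter
   errors, and compute 0°/90° and 0°/180° polarity ratios with first-order
   error propagation.
5. **Support-cell shape** (`neuropol.cellshape`) — per-region moment
   ellipses from label images, 0–90° orientation histograms, one-way χ²
   uniformity test.
6. **Synthetic neuromasts** (`neuropol.synthgen`) — seeded generators for
   all of the above (uniform / axis-bimodal / concentric fields, hair-cell
   pairs, label images, ring profiles, division events), so the entire
   pipeline is verifiable end-to-end without microscopy data.

The two fitted analyses follow the statsmodels model/results idiom:
`ConcentricityModel(...).fit()` and `GaussianPeakModel(...).fit()` return
results objects with estimates, uncertainties, diagnostics and a
`summary()` table.

## Worked example

Simulate a Wnt-type (concentric) field of 30 hair cells with von Mises
orientation noise κ = 4 and analyse it:

```sh
$ neuropol simulate --model concentric --n 30 --kappa 4 --seed 7 -o cells.tsv
wrote 30 cells to cells.tsv
$ neuropol concentricity cells.tsv --frame math_y_up -o result.json
Concentricity analysis
==========================================================
n cells                        30
ellipse center         (    97.561,     94.313) px
semi-axes (a, b)       (    37.676,     25.797) px
rotation theta              7.381 deg
----------------------------------------------------------
uniformity chi-square     46.8000  (df = 11)
uniformity p-value      2.334e-06  (alpha = 0.01)
von Mises mu                0.070 deg
von Mises kappa            2.4611
mean resultant length      0.7607
----------------------------------------------------------
label                  Concentric
```

The fitted organ ellipse has semi-axes ≈ 38 × 26 px. The tangent
deviations are far from uniform (χ² = 46.8 on 11 df, p = 2.3 × 10⁻⁶ <
0.01), and the axial von Mises fit concentrates at μ ≈ 0° — cells align
with the local tangent — so the field is labelled **Concentric**. The same
command on a uniform (PCP-type) field (`--model uniform`) gives p = 0.082
and **Not Concentric**.

The same analyses are available as library calls:

```python
from neuropol import ConcentricityModel, FieldConfig, simulate_field

cells = simulate_field(FieldConfig(n_cells=30, orientation_model="concentric",
                                   kappa=4.0, seed=7))
res = ConcentricityModel(cells).fit()
print(res.summary())          # same table as above
res.deviations                # per-cell signed tangent deviations (deg)
res.vm_fit.kappa              # concentration of the deviation distribution
```

Other subcommands: `orientation` (rose counts + quadrant binomial test),
`divisions` (division angles + Welch t-test), `profile` (align/average/
Gaussian-fit cortical profiles + polarity ratios), `support-cells`
(label-image orientation analysis). `--help` on each lists the options.

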