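# Methods

## The assay model

A well contains a heterogeneous cell population in which a fraction *p* of
cells carries high ALDH activity. Per-cell reporter intensity is modeled as
a two-component Gaussian mixture truncated at zero:

- background cells: Normal(µ_bg, σ_bg), defaults µ_bg = 100 a.u.,
  σ_bg = 10 a.u.;
- ALDH-high cells: Normal(µ_bg + s·σ_bg, σ_hi) with shift s = 8 by default.

Truncation at zero is done by resampling, not clipping, so the realized
moments stay close to nominal. The DEAB inhibitor control is the same
population with *p* forced to 0: the inhibitor abolishes reporter
retention, leaving only staining background.

**Choice of σ_hi (default σ_bg/2).** The separation of the two populations
is what the generators are for: the gate at 6σ above the control mean only
recovers planted fractions to binomial accuracy when essentially no
ALDH-high cell falls below the gate. With s = 8 and σ_hi = σ_bg/2 the
probability that a bright cell lands below a 6σ gate is Φ(−4) ≈ 3×10⁻⁵, so
recovery is binomial-limited; with σ_hi = σ_bg it would be Φ(−2) ≈ 2.3%, a
visible downward bias. The default therefore emulates a crisply bimodal
staining histogram, which is also the regime in which gate-based counting
is a sensible readout at all. Broader bright populations can be requested
per spec (`high_sd`), and the recovery guarantees then weaken accordingly.

## The gate

Threshold T = mean + k·SD of single-cell intensities pooled across all
DEAB wells of the plate, k = 6 by default, SD with the n−1 denominator.
Cells count as ALDH-high when strictly above T; a tie at exactly T counts
as low (conservative). Pooling is at the cell level, not an average of
per-well means — both are defensible, pooling uses every cell at equal
weight and is the package default. A QC floor of 200 pooled control cells
protects against gating on noise; below it the plate fails rather than
gates. Expected null behavior: a pure-background Gaussian well crosses a
6σ gate at per-cell rate Φ(−6) ≈ 1.0×10⁻⁹, so even 10⁵ background cells
almost never contribute a single gated cell. This is the property the
null-calibration test checks.

An empty well raises an error rather than reporting 0%: "no cells" (toxic
well) and "no ALDH-high cells" (effective compound) mean opposite things
in a screen.

## Imaging

Segmentation: Gaussian smooth (σ = 2 px) → Otsu threshold → fill holes →
distance-transform watershed seeded at h-maxima of the distance map
(h = 10% of its maximum) → area gate (defaults 30–3000 px² at 0.65 µm/px).
This is a standard, reproducible recipe for roundish nuclei; it is not
tuned to any particular instrument's software.

Measurement: per-cell reporter mean over the nucleus dilated by a 3 µm
cytoplasmic ring (the reporter product is cytoplasmic; nuclear-only
measurement would underestimate it). Ring collisions are resolved by
nearest-label assignment (`expand_labels`). Background is a single scalar
per field — the median reporter intensity outside all dilated cell regions
— subtracted and floored at 0. Synthetic fields are flat, so no
illumination-field model is included; shading correction for real images
is out of scope.

The synthetic renderer paints each cell's intensity over its nucleus plus
ring footprint before PSF blur, so the measurement region sits inside the
painted footprint and the measured mean tracks the painted value. Blur and
noise attenuate samples and controls identically, and the gate is scale
equivariant, so the image-path fraction matches the table-path fraction
within counting noise — the property the image-path test checks
end to end.

## Tumorspheres

Objects are segmented (smooth → Otsu → fill → label) and measured in µm:
equivalent circular diameter 2·√(A/π) and shape factor 4πA/P². Filters:
50 ≤ d ≤ 250 µm and shape factor ≥ 0.5, boundaries inclusive; "size" is
interpreted as a length (equivalent diameter), and the shape-factor bound
as a minimum — standard morphometric usage. Perimeter uses the Crofton
approximation: near-exact on smooth convex outlines (circles measure
within ~1% of circularity 1) but biased low on grid-aligned straight
edges, so a discrete square measures ~0.88 rather than π/4 ≈ 0.785. The
documented discretization tolerance on the shape factor is ±0.1, and
values slightly above 1.0 are possible for small circles.
Border-touching objects are excluded because their area and perimeter are
truncated. TFC = passing count / seeded count; the seeding count comes
from a Day-0 nuclear count when Day-0 images exist, otherwise from the
declared seeding density (100 or 200 cells per well).

## Screen rules

With f = per-well ALDH-high fraction and aggregates over control wells
(median by default; mean by config):

- **masking**: masked ⇔ n_cells < 0.5 · agg(neutral n_cells). Strict: a
  well at exactly half the control count is kept.
- **normalization**: effect% = 100·(f_neutral − f_well)/(f_neutral −
  f_full). Anchors map to 0/100 by construction; values outside [0, 100]
  are legitimate over-normalization and are flagged only beyond ±150.
- **hit**: not masked AND 100·(f_neutral − f_well)/f_neutral > 25,
  strict. The reduction is computed against the neutral control fraction
  directly, not on the normalized scale; both numbers are reported. In
  plate-level analysis only sample-role wells carry hit flags — control
  wells satisfy the bare rule trivially and are not nominatable.
- **fast-acting**: a hit whose 2 h effect ≥ 75% and whose post-wash-off
  effect < 25% reproduces the direct-enzyme-inhibitor pattern and is
  flagged a likely false positive. Both thresholds are configuration, not
  constants of nature; the defaults are chosen so that a compound
  reproducing the inhibitor control's near-total 2 h knockdown with a full
  rebound is flagged, while slow-acting suppressors are not.
- **robust Z′**: 1 − 3·(1.4826·MAD_pos + 1.4826·MAD_neg)/|median_pos −
  median_neg|, the standard robust form of the Z′ assay-quality factor;
  MAD (not IQR) spread. Equal medians return −∞ as a QC-failure sentinel.
- **S/B**: agg(neutral f)/agg(full-effect f), mean by default; +∞ when
  the background is exactly zero (possible on synthetic plates where the
  inhibitor control is noise-free by construction).

## Dose-response

4PL model y = bottom + (top − bottom)/(1 + (x/IC50)^hill), fitted by
bounded least squares with IC50 parameterized as log10(IC50), multistart
over IC50 at the dose quartiles × Hill ∈ {+1, −1}, bounds
bottom ∈ [−20, 50]%, top ∈ [50, 150]%, Hill ∈ [−10, 10], log10(IC50)
within the dose range ±2 decades. Fits require ≥ 4 distinct doses;
flat or near-flat solutions are flagged `non_identifiable` rather than
forced, and an IC50 outside the tested dose range is flagged.

## Synthetic plates and reproducibility

A plate spec is a 384-well layout (roles: sample, dmso, deab, lipid,
sirna_control, empty), a base mixture, per-well overrides, a compound/dose
map and a toxicity map (cell-count multipliers). Inhibitor-control roles
force p = 0. Each well draws from an independent substream
`SeedSequence((plate_seed, well_index))` with the 0-based row-major well
index, so any single well regenerates bit-identically without building
the plate. All generators are deterministic given their seed; the CLI
writes a config hash, the seed and the gate parameters into every output
CSV header.

Problem sizes used by the test suite and the acceptance script — 2,000
control cells per gate, 10⁴-cell recovery wells, 100-replicate
calibrations, a 384-well plate at 5,000 cells/well, 8-dose curves at 100
seeds — were chosen as realistic desk-scale analogues of a high-content
screen; a 384-well plate imaged at 10× yields cell counts of this order.

## What the synthetic data does and does not show

The generators emulate population structure (mixtures, control layouts,
toxicity, dose response) with Gaussian noise and idealized optics: flat
illumination, symmetric PSF, no debris in nuclear channels, no intensity
heavy tails, no spatial plate effects. Passing tests therefore demonstrate
that the statistics and rules are implemented correctly and are
well-calibrated under their own assumptions — not that the pipeline is
robust to shading, focus drift, segmentation failure modes of clumped
cultures, or non-Gaussian staining backgrounds of real instruments.
Real-data headline figures (assay-window RZ′ of a live-cell screen,
compound IC50s, FACS purities) depend on cells and chemistry and cannot be
reproduced in silico; the corresponding checks here are structural
analogues with planted ground truth.

## Known limitations

- No multi-plate batch correction, B-score/spatial detrending, or FDR
  across compounds: single-plate, rule-based hit calling by design.
- The scalar background model is wrong for vignetted real images.
- Crofton-perimeter circularity is biased for straight-edged objects;
  tumorspheres are round, so the bias is immaterial in the intended use.
- The 4PL fit reports but does not propagate parameter uncertainty.
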