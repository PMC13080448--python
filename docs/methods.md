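# Methods

## FISH focus quantification

Each three-channel frame is segmented per channel by Otsu thresholding
(a fixed threshold can be configured per channel instead; a constant
channel yields an empty labeling). Connected components in the red (*MYC*)
channel with area ≥ `min_focus_area_px` (default 2 px, suppressing
single-pixel noise) are candidate foci. A focus is classified
intrachromosomal — and removed from the extrachromosomal count — when it
shares at least one pixel with the DAPI chromosome mask or any chr8
centromere object; this is the strictest reading of "overlap", and
`dilation_px` grows both masks for sensitivity analysis. By construction
the counts conserve: extrachromosomal + removed = detected, per cell.

Chr8 features follow cytogenetic scoring practice: the *object count*
applies an area filter (≥ 5 px) so hybridization specks are not counted as
centromeres, while *total area* and *mean intensity* are computed over all
chr8-labeled pixels. The per-cell extrachromosomal count is normalized to
the expected two chr8 objects (`ec * 2 / chr8_count`); a cell with no chr8
object is reported unquantifiable rather than dividing by zero, and a
config flag (`require_expected_chr8`) restricts analysis to cells with
exactly the expected count instead of rescaling.

Cell instancing defaults to one cell per frame, the usual situation for
metaphase spread acquisitions. A `cluster` mode closes the DAPI mask with
a 20 px disk, labels the resulting clusters and assigns every focus to the
nearest cluster, for frames holding several spreads. Both the closing
radius and the mode are configuration, not code.

## Synthetic metaphase frames

The generator renders what the detector assumes: foci are isotropic
Gaussian blobs (σ = radius/2, default radius 3 px), the chromosome mass is
a union of 30 elongated ellipses confined to a central disk (dense enough
that morphological closing sees one cluster per spread, as a metaphase's
~46 chromosomes would be), centromere signals are larger blobs (radius
5 px) planted on the mass. All channels receive a Gaussian PSF blur
(σ = 0.8 px) and iid Gaussian background noise (sd 0.02 on a unit-intensity
scale) — a high-SNR confocal regime appropriate for probe signals scored
by eye. Double-minute-like foci are planted off the chromosome mass with a
clearance of two radii plus the blur scale, so a planted extrachromosomal
focus can never bleed onto the mask, and pairwise separation of 4× radius
(the contract floor is 2×); HSR-like foci are planted on the mass with the
2× floor only, since they clump in reality and are removed as a group
anyway. Placement is rejection sampling with 1000 tries per object;
exhaustion raises an error rather than silently planting fewer objects.
The truth table records every planted object and the generator hands back
the noiseless masks, so recovery, overlap classification and normalization
can be scored exactly.

What the generator does **not** emulate: focus brightness variation,
overlapping/touching double minutes, autofluorescence gradients, z-stack
blur anisotropy, or chromosomes extending outside the central cluster.
Perfect recall/precision on these frames therefore demonstrates that the
counting logic is correct, not that real microscope frames are this easy.

## Aggregate morphometry

Grayscale fields are Otsu-thresholded and hole-filled; connected
components are measured in physical units via the pixel calibration, and
objects below 40 µm equivalent diameter (single nuclei / dispersed cells)
are excluded by default. "Large" aggregates use strict inequality at the
300 µm cutoff; ties at exactly 300 µm are measure-zero in practice.
"Per unit area" is the imaged field area. Touching aggregates merge —
connected-component analysis does not split them — which matches how
area-per-field is accumulated but undercounts n in dense fields. Foam pore
(bubble) sizing reuses the same machinery with no size floor.

## Mechanics

The apparent modulus is the least-squares slope over a sliding strain
window (default width 0.10 strain, searched over 0–0.3) maximizing R²;
ties break toward the larger slope so a flat toe never wins. Windows
truncated at the search-range edge are skipped (they hold few points and
can reach spuriously high R²) unless no full-width window exists. The fit
is invariant to constant stress offsets. Under additive noise, picking the
R²-maximizing window carries a small upward bias (R² grows with the
slope-to-noise ratio, so noise-steepened windows are preferred): at
noise sd 0.2 kPa on a 22.2 kPa / 500-point curve the recovered modulus is
biased high by ≈ 2.5% with a per-curve sd of ≈ 2.4%, which is why
recovery is assessed as the mean over many curves rather than per curve.

The synthetic curve's toe ramps quadratically so slope grows 0 → E and
joins the linear branch with continuous value and slope; 500 points per
curve corresponds to a universal testing machine sampling a slow
(0.1 mm/s-scale) compression at ordinary rates.

Gibson–Ashby inversion uses the open-cell relative-density-squared law
with C = 1, n = 2 (both configurable), and relative density ≡ 1 − air
fraction, appropriate because foam and bulk share one hydrogel
composition. Air fraction comes from the foam/bulk mass deficit at equal
mold volume; an air fraction ≥ 1 or a foam outweighing the bulk is
rejected as inconsistent input.

## Expression statistics

Fold change: technical replicates are averaged per sample × gene (standard
ΔΔCt practice); ΔCt subtracts the same sample's housekeeping Ct, which
cancels per-sample loading shifts exactly; ΔΔCt subtracts the *mean* ΔCt
of the declared reference group, making the reference group's fold change
exactly 1. The reference group is a required argument, never guessed,
because the appropriate baseline (2D culture vs day-1) is a design choice
of each comparison.

Trend screen: Spearman's ρ of the values against their series position,
one-sided for increase by default. For n ≤ 8 the p-value is exact, by
enumerating all n! orderings of the observed values (vectorized rank
correlation over the permutation array); beyond that the asymptotic
approximation is used. The screen passes at ρ > 0.9 and p < 0.05; at
n = 4 only the perfectly increasing ordering passes, so the null pass rate
is exactly 1/24. No multiple-testing correction is applied by default
(`screen_trends(..., fdr=True)` switches to Benjamini–Hochberg). All-tied
series have no defined rank correlation and are reported non-passing with
a flag.

KS, t, ANOVA and Tukey HSD delegate to SciPy (exact KS p for small
samples); results carry the significance tiers \* p < 0.05, \*\* p < 0.005,
\*\*\* p < 0.0005.

## Problem sizes and numerical choices

Default synthetic frames are 256×256 px — large enough to place 80
well-separated foci around the chromosome mass, small enough that a
50-seed recovery sweep takes seconds. Stress–strain recovery uses 100
curves; the trend-screen null rate uses 10,000 draws (3-SE band ≈ ±0.6
percentage points around 1/24). All generators are deterministic per seed
(`numpy.random.default_rng`). Table output uses full-precision float repr
so written results round-trip exactly.

## Known limitations

* Focus detection has no declumping; two planted foci closer than the
  separation floor would merge (the generator never produces this by
  default).
* The chr8 channel of an HSR-like cell can merge into fewer objects than
  centromeres present; the observed count is reported as-is and
  normalization uses it (or the cell is excluded via
  `require_expected_chr8`).
* The KS test assumes continuous data; heavy ties (quantized sizes) make
  the exact p conservative.
* Gibson–Ashby constants are material idealizations; reported inherent
  moduli scale directly with 1/C.
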