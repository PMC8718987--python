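# Methods

## The measurement model

Nitrocellulose redox permanganometry (NRP) turns a sample's reductive
(total antioxidant) capacity into brown MnO₂ deposited on a nitrocellulose
membrane: KMnO₄ oxidizes the trapped sample and the insoluble reduction
product stays where the sample was applied. Everything this package does
starts from a digitized photograph of such a membrane.

The canonical in-memory object is a float64 field in [0, 1] on the
*reductive-intensity scale*: the scanned luminance is inverted (v → 1 − v)
so that larger values mean darker deposit, i.e. more reduction. Inversion is
performed exactly once and guarded against double application. RGB scans
collapse to luminance with the fixed ITU-R BT.601 weights (0.299, 0.587,
0.114); integer code spaces (8/16-bit) exist only at file boundaries, which
decouples all downstream math from the scanner's bit depth. Images are
indexed (row, column) from the top-left; "dorsoventral" always means
increasing row index.

## Dot-blot densitometry

A spot's readout is its **integrated density**

    ID = Σ_{p ∈ disk} ( I(p) − b ),

the sum of background-subtracted reductive intensity over a circular ROI.
Pixel centers at distance ≤ radius are in the disk (boundary ties included,
so the pixel count of a given geometry is deterministic). The local
background *b* is the **median** intensity over an annulus with radii
1.2×/1.8× the ROI radius; the median makes the estimate robust to bleed
from neighboring spots, and for any background that is locally linear the
point-symmetric annulus estimates the plane's value at the spot center
exactly. An annulus clipped by the image edge uses its in-bounds portion
(flagged `partial_annulus`). Negative densities are possible (spot dimmer
than background) and flagged rather than clamped.

A second, profile-based mode mirrors the gel-analysis workflow: a lane
rectangle is averaged into a 1D profile, a piecewise-linear baseline is
anchored at the local minima flanking each detected peak (peak prominence
threshold: 5% of the profile range, configurable), and above-baseline runs
are integrated. The two modes agree within a few percent on isolated spots;
the disk+annulus mode is the default because it needs no baseline anchors.
A known limitation of minima-anchored baselines: when a peak is fat
relative to its lane, the anchors sit on the peak's own tails (at roughly
3σ for a Gaussian peak) and the recovered area is biased low by ~1–2%; the
bias shrinks as the lane window grows relative to the peak width.

ROI placement is either grid-refined (each node of a known pipetting grid
is moved to the local intensity centroid within half a spacing) or blind
Laplacian-of-Gaussian blob detection; both are deterministic for a fixed
image.

## Calibration and validation

A graded series (by default ten levels, 0.01–0.1 M, 5–6 replicate spots
per level — the standard design for validating total-antioxidant-capacity
methods with sodium thiosulfate or ascorbic acid) is fitted by unweighted
OLS of integrated density on nominal concentration, all replicates entering
individually. Weighted (e.g. 1/x²) fitting is deliberately not the default
because no weighting scheme is part of the assay's definition.

Validation verdicts follow the structure of bioanalytical method-validation
guidance:

| check | statistic | default acceptance |
|---|---|---|
| accuracy | back-calculated level mean as % of nominal | within ±15% (±20% at the lowest level) |
| precision | per-level CV = 100·sd(n−1)/mean | ≤ 15% (≤ 20% at the lowest level) |
| linearity | calibration R² | ≥ 0.98 |

The lowest level plays the LLOQ role and gets the wider tolerances. All
thresholds are overridable (`ValidationThresholds`). CV uses the n−1 sample
SD — material at n = 5–6. Levels with one replicate have no CV; their
precision verdict is withheld and flagged, not failed. A constant response
is reported as R² = 0 (nothing explained), not as a perfect fit.

Two comparison statistics support benchmarking: `compare_methods` (OLS of
one readout on another, R² plus the two-sided zero-slope p), used e.g.
against a platinum redox-microelectrode series; and `compare_groups`, the
two-sided Wilcoxon rank-sum (Mann–Whitney) test, exact by enumeration for
combined n ≤ 20 and the tie-corrected normal approximation above that, with
the method used always reported.

## Ratiometric protein correction

Tissue homogenates are spotted at fixed volume, so density confounds
reductive capacity with protein loading. The correction
`corrected_i = density_i · (p_ref / p_i)` keeps values on the original
integrated-density scale (a sample loaded at exactly the reference protein
level is unchanged). It assumes signal is linear in protein content, so it
is *gated*: sample i qualifies only when |p_i − p_ref| / p_ref < 0.5, a
strict inequality — a sample exactly at 50% dispersion is excluded. The
representative value p_ref defaults to the batch median (overridable to a
named sample); the choice is recorded in the output. An OLS linearity audit
(R² of density on protein over the justified samples) is attached to every
corrected table.

## Bilateral spatial analysis

A unilateral lesion in a bilaterally symmetric tissue print is analysed
against the intact hemisphere as a within-subject control:

1. **Midline.** Estimated as the column m maximizing the Pearson
   correlation between the left block and the mirrored right block over
   their overlap (search: central third by default; ties to the smaller
   index; uniform images raise, prompting a manual midline, and a manual
   midline always wins).
2. **Mirror pairing.** The axis passes through the center of column m
   (x′ = 2m − x); column m belongs to neither side. This convention makes
   mirroring an exact involution on the integer grid. For offset d,
   ipsi(r, d) = I(r, m + d) and contra(r, d) = I(r, m − d) (ipsilateral =
   right; symmetric otherwise).
3. **Maps.** sum_map = ipsi + contra, diff_map = ipsi − contra, pixel-wise
   over the overlap. A mirror-symmetric input yields diff_map ≡ 0 — the
   analysis cannot manufacture asymmetry. Swapping the ipsilateral side
   negates diff_map exactly.
4. **Regions.** ROIs (polygons or masks) are drawn once, on the
   ipsilateral side, in source coordinates; the homologous contralateral
   sample reuses the same mask through the mirror map. Each region reports
   its pixel samples, means, the **oxidative increment**
   (contra_mean − ipsi_mean; positive = reductive capacity lost on the
   damaged side), Gaussian kernel densities of both samples, and the
   Euclidean distance from the ROI centroid to the trauma point.
   ROIs under 10 px are flagged; ROIs touching the midline are errors.
5. **Ranking.** Regions sort by trauma distance (ties alphabetically) and
   the Spearman ρ between distance and increment summarizes whether damage
   decays with distance.

Density estimation uses `scipy.stats.gaussian_kde` with Silverman's rule on
a 256-point grid spanning the pooled value range padded by three pooled
bandwidths, then renormalized by its trapezoid integral so every reported
density integrates to exactly 1 on its own grid (the Gaussian tails beyond
any finite grid would otherwise leave a deficit). Zero-variance samples
(possible on noiseless synthetic data) collapse to a unit spike at the
nearest grid node and are flagged `degenerate_density`.

## The phantom generators

Synthetic phantoms stand in for real membranes so that every stage is
testable against exact ground truth.

**Dot blot.** One concentration level per row, one replicate per column.
Spot amplitude follows a linear dose-response A(c) = a·c by default
(slope a = 8 intensity/M, keeping amplitudes in [0.08, 0.8] over
0.01–0.1 M); a saturating option A_max·(1 − e^{−kc}) exists to exercise
linearity-failure reporting. Replicate noise is multiplicative lognormal
parameterized by its CV (default 5%, the precision regime the assay
operates in); pixel noise is additive Gaussian (default σ = 0.01); a
gentle linear background plane (default 0.03 + 5·10⁻⁵ per px each way)
exercises the background correction. Spots are flat disks with a 2-px
cosine-taper rim: the taper suppresses aliasing of the disk edge while
keeping **compact support**, so the exact integrated density of every spot
is a finite sum fully captured by a measurement disk of radius
spot_radius + 2 px — on noiseless phantoms, pipeline readout equals the
truth table to ~1e-14. Values are clipped to [0, 1] and clipping is
flagged.

**Oxidation pair.** Two membranes of isoconcentrated aliquots (default
0.05 M, six replicates): untreated at A(c), treated at A(c·(1 − f)) — the
oxidized fraction f removes reductive capacity without changing the
nominal concentration.

**Brain print.** The pre-lesion field is built from elliptical structures
evaluated as functions of (row, |col − m|), hence exactly mirror-symmetric
by construction (background 0.05; brain ellipse +0.55; two off-path detail
ellipses). The lesion multiplies one hemisphere by
w(p) = 1 − δ·exp(−‖p − c‖²/2σ²) (defaults δ = 0.3, σ = 30 px). Six square
ROIs (15 px) march away from the trauma point at 20-px increments through
a region of constant pre-lesion intensity, so the true oxidative increment
of an ROI has the closed form mean(pre·δ·g) over its mask and decreases
strictly with distance — the Spearman ρ of a clean analysis is exactly −1.

All randomness flows through `numpy.random.default_rng(seed)`: identical
spec + seed reproduces every output byte-for-byte.

What the phantoms do *not* emulate: MnO₂ deposition chemistry and its
dose-response shape near saturation, diffusion blur of slice-print
transfer, uneven membrane texture, anatomical realism of the structures,
and scanner-specific artifacts. Green tests therefore demonstrate the
correctness of the quantification pipeline, not the wet-lab assay's
validity on real tissue.

## Numerical choices and degenerate inputs

- Working precision is float64 throughout; file I/O quantizes by rounding
  to the nearest 8/16-bit code (round trip within half a code step).
- The grayscale inversion is an involution up to one ulp of 1.0 in IEEE
  doubles; the mirror involution is exact (pure reindexing).
- Empty annulus, zero-width lane, out-of-range offsets, non-positive
  protein values, single-replicate CVs, zero-slope back-calculation and
  uniform-image midlines all raise typed errors (`nrpquant.errors`) rather
  than returning silent defaults; recoverable oddities (partial annulus,
  below-background spots, small ROIs, degenerate densities) are flags on
  the result objects.
- Problem sizes used by the test suite and the acceptance script — the
  standard 10×6 dot blot (~330×200 px), 220×320 brain prints, 200-seed
  slope-recovery and 400-repeat rejection-rate loops — keep a full run in
  well under a minute while leaving the stochastic checks' sampling error
  small relative to their acceptance bands.

## Known limitations

- The lane-profile baseline is an automated stand-in for manually drawn
  gel-analysis baselines and is labelled as such; its anchor-on-tail bias
  is described above.
- Midline estimation assumes approximate global mirror symmetry; heavily
  asymmetric or cropped sections need the manual override.
- Contralateral sampling assumes the mirror map lands on homologous
  tissue; no registration or atlas alignment is attempted.
- The dispersion gate and ratiometric correction address loading, not
  protein-composition differences between groups.
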