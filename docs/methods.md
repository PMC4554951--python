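# Methods

This note documents the models, estimators and numerical choices behind
`pomoct`, in the spirit of a methods appendix: what is computed, under
which assumptions, with which defaults, and what the synthetic validation
does and does not establish.

## Conventions

Arrays are `(z, y, x)`; a physical coordinate is `index × voxel_size_mm`
(index 0 ↦ 0.0 mm). Voxels are cubic; anisotropic voxel sizes are
rejected at read time. The void/vessel (foreground) phase uses
26-adjacency and the solid phase its 6-adjacent complement — the standard
complementary pair, fixed because it changes component counts. Masks
serialize as 0/255 TIFF; any nonzero voxel reads back as true.

## Tissue morphometry

**Segmentation.** A radius-1 median filter (6-connected ball footprint)
precedes a global Otsu threshold; the low-intensity phase is the void
space. The ball footprint rather than the 3×3×3 box is deliberate: the
box median erases gas structures 1–2 voxels thick and measurably biases
porosity low. Void components smaller than `min_object_vox` (default 29
voxels ≈ 3.2·10⁻⁶ mm³ at 4.8 µm voxels, the smallest void resolvable at
that resolution) are discarded as noise. Otsu always produces a split, so
two guards exist: a warning when the between-class variance share is
below 0.5 (weak bimodality), and an empty-mask return with a warning when
the class-mean contrast is below twice the summed within-class spreads —
without the latter, a single-phase noisy volume would report ~50%
porosity.

**Porosity, void counts.** Porosity is the void fraction of the ROI
(default: the full grid) in percent. The void count is the number of
26-connected components; its density uses the full analyzed volume — the
choice of denominator is documented here because either convention is
defensible.

**Fragmentation index.** (S₁−S₂)/(V₁−V₂), where S and V are void surface
area and volume before and after one single-voxel (6-neighbour) dilation,
surfaces by exposed-face counting. Convex structures close little surface
per added volume (positive index); concave, well-connected networks close
surface rapidly and can go negative. Face counting is kept here — it
overestimates absolute areas but is stable under the differencing. The
index has units mm⁻¹ and scales inversely with voxel size.

**Sphericity.** ψ = π^⅓(6V)^⅔/S per void, V from the voxel count, S from
a marching-cubes surface at iso-level 0.5. The raw binary iso-surface is
a staircase that overestimates smooth areas by ~8% (which would bias ψ of
a true sphere to ~0.92), so for components of ≥125 voxels the indicator
field is smoothed with a Gaussian (σ = 1 voxel) before surface
extraction; voxelized balls then converge to ψ = 1 in absolute error
(1.021 → 1.003 → 0.999 at radii 10/20/40). Components of 27–124 voxels
use the raw iso-surface; below 27 voxels the face-counted surface is used
and the value flagged low-confidence. The surface-model asymmetry with
the fragmentation index (marching cubes vs face counting) is intentional.

**Anisotropy.** Mean intercept length (MIL) along 128 quasi-uniform
directions (Fibonacci hemisphere; MIL is antipodally symmetric). For each
direction a bundle of parallel test lines (3-voxel spacing, half-voxel
sampling step) is traced through the grid; MIL = total in-phase length /
number of entries into the phase. An ellipsoid 1/MIL² = nᵀAn is fitted by
least squares and the anisotropy factor is 1 − λ_min/λ_max of A, which
maps total isotropy to 0 and total anisotropy to 1 (the raw degree of
anisotropy λ_max/λ_min is unbounded and would not honor that scale).
Directions without intercepts are dropped; fewer than six valid
directions is an error. Measured endpoints on 128³ grids: solid ball
0.021, thin parallel plates 0.997.

**Local thickness.** Largest-inscribed-ball diameter per voxel: candidate
ball centers are the skeleton voxels plus all local maxima of the
Euclidean distance transform (thinning alone misses some maximal-ball
centers), each carrying diameter 2·(dt − ½) voxels — the half-voxel term
because the phase boundary lies between voxel centers — and the balls are
propagated so every voxel receives the largest covering diameter. The
mean over the structure gives the mean void diameter. Validated against
through-cylinders: mean = 2r within ±1 voxel for r ∈ {3, 5, 8}.

**Cell separation.** Marker-based watershed on the negated distance
transform of the cell phase. Markers are distance-transform local maxima
with a minimum separation h; h defaults to a quarter of the expected cell
diameter (when configured) or to 0.6 × the 75th-percentile distance
value. Half a diameter — the natural first guess — measurably suppresses
true maxima in tight packings, where gas covers only part of each cell's
boundary and maxima sit off-center; a quarter diameter recovers the mean
cell diameter within 10% across 10–30% porosity. Equivalent cell diameter
is (6V/π)^⅓ per watershed label.

**Size distributions.** Voids sorted by equivalent spherical diameter;
the cumulative volume curve is the running volume fraction and the
frequency curve the running count fraction; both end at exactly 1. A void
holding half the total volume produces a 0.5-high discrete jump in the
volume curve — the signature of a single dominant connected void network.

## Whole-fruit vasculature

**Smoothing.** Perona–Malik diffusion with conductance
exp(−(|∇I|/κ)²), explicit step 1/7; iterations chosen to match a
Gaussian of the requested σ in flat regions. κ (`edge_stop`, default 30–40
on 8-bit data) sits between the noise scale and the vessel contrast, so
bundles and the fruit boundary survive (measured: step-edge gradient
fully preserved, flat-region noise reduced >3×, thin-tube contrast ≥80%).

**Region segmentation.** The air/tissue threshold is the histogram valley
between the two largest significant modes (Gaussian-smoothed, 3 bins);
when the valley is a wide flat run — the usual case for well-separated
phases — its center is used, not the noise-driven argmin, and a "valley"
that fails to dip below half the lower mode is rejected as single-mode
ripple (the caller is told to supply a manual threshold). The fruit is
the largest above-threshold component, hole-filled (two fruit-sized
components abort). Core air = interior dark components; core = core air
dilated `dilate_px` unit-ball iterations; the working cortex is the fruit
eroded by `erode_px` minus the core; the epidermis is the eroded-away
rind. `dilate_px`/`erode_px` (defaults 20/14) are resolution-specific
voxel counts and must be rescaled mm-equivalently at other voxel sizes;
the erosion must at least cover the bright-skin blur tail, or a
false-positive shell appears at the cortex boundary.

**Vessel enhancement.** White top-hat with a discrete ball structuring
element; "width 4 px" is read as the ball diameter (radius-2 ball),
configurable. Voxels with response ≥ `height` (default 4 intensity units
on 8-bit data; 16-bit inputs should be rescaled to 8-bit first) within
the working cortex form the vessel mask; sub-`min_size` components are
dropped. The transform detects bundles strictly narrower than the
element and suppresses wider features (epidermis remnants, smooth
gradients) by construction.

**Skeleton graph.** 3D thinning (Lee) to 1-voxel centerlines; skeleton
voxels with 1 or ≥3 of 26 neighbours are node voxels; 26-connected node
clusters merge into nodes at their centroid; edges are traced through
degree-2 runs with chamfer (1, √2, √3) step lengths. Local radius at a
skeleton point is (dt − ½) voxels. Thinning retracts tube ends, so each
terminal edge is corrected to the point where the mask exits along the
terminal direction minus the local tube radius (exact for rounded vessel
ends), with a ¾-voxel quantization offset; straight-tube lengths are then
within ±1% of the axis for r ∈ {2, 4, 6} and lengths 50/100 voxels.
Cycles (bundles that merge and re-split, the known annular skeleton
artifact) are preserved and logged, never cut. Pure cycles with no
junction get one artificial node.

**Pruning.** Terminal edges shorter than `min_branch` (recommended:
2 × structuring-element width) are removed iteratively; junction pairs
closer than half that scale — junctions split by thinning sit about one
tube diameter apart — are merged; degree-2 nodes are contracted with
lengths summed. Pruning never increases total length.

**Metrics and radial statistics.** Total length in m; length density =
length (cm) / fruit volume (cm³); mean radius over all skeleton points.
Branch points (degree ≥ 3) are binned by relative radius r/R (R the
equivalent fruit radius, (3V/4π)^⅓). Vessel density per spherical shell
divides the polyline length falling in each shell (edges resampled into
sub-segments far shorter than the shell width and assigned by midpoint
radius, which conserves total length exactly) by the fruit volume in the
shell; empty shells give NaN, not 0.

**Reference segmentation and comparison.** The region-growing reference
flood-fills 26-connected voxels above a threshold from picked seeds
(seeds below threshold are skipped with a warning); the automated
protocol's length underestimation is 100·(L_ref − L_auto)/L_ref.

## Phantoms

**Parenchyma.** Cell centers are uniform random points regularized by 6
Lloyd iterations; each cell is a ball whose radius — a common multiple of
the per-cell nearest-neighbour distance, solved by bisection — leaves
inter-cell gas wedges carrying a set fraction (default 60%) of the target
porosity. The remainder comes from deleting compact clusters of whole
cells (cluster size 1 + Poisson(mean−1), members by seed proximity),
mimicking lysigenous void formation in which cells die and leave
cell-sized cavities; deletion stops mid-cluster when the target is
crossed, and a residual beyond ±1 percentage point (cells too coarse) is
an error naming the achieved value. The wedge component is essential, not
cosmetic: with gas only in whole-cell voids, the solid phase has no
per-cell distance-transform structure and no watershed can recover the
cells. Rendering: two intensity levels (defaults 30/200; the contrast is
a free parameter, not calibrated to any scanner), Gaussian blur (σ = 0.5
voxels), additive Gaussian noise (SD 5), clipped to 8-bit. Thresholding
the blur- and noise-free render at mid-intensity reproduces the truth
mask exactly. Defaults: 96³ voxels at 4.8 µm, 400 cells (≈75 µm cells —
a scaled-down domain, so cells sit at the small end of the realistic
range).

**Whole fruit.** A sphere of radius 11 mm in a 160³ grid at 0.16 mm
voxels — a scaled-down fruit preserving the anatomy the pipeline
exploits: dark exterior and core air cavity, bright epidermal shell
(2 voxels), flesh at mid-gray, and ten primary bundles as meridional arcs
on a ring at 6 mm radius, each spawning a recursive branching tree toward
the skin (branch probability 0.3 mm⁻¹, 2 levels, root radius 0.3 mm,
taper 0.8/level — radii chosen below the top-hat element radius so the
enhancement step can see every bundle). Branches stop at 0.86 of the
fruit radius and are hard-clipped one epidermis thickness below the
surface; spawn points keep ≥1.5 mm spacing and ≥2.5 mm clearance to any
free end, so that true terminal segments stay above the skeleton-spur
scale — a phantom with branches below the pruning scale would be
unrecoverable by construction, by any implementation. Truth region masks
follow the same morphological recipe as the segmentation stage
(dilate 8 / erode 6 unit-ball iterations at this resolution), applied to
the noise-free analytic masks. The carpellary bundle system is
approximated by the same tree generator anchored at the core ring; exact
carpel anatomy, seeds/locules and scanner physics are out of scope.

**What phantom validation shows — and does not.** Measured on the
defaults: porosity RMSE 0.77 pp and mean-cell-diameter error ≤5.4% over
five phantoms spanning 10–30% porosity; total network length within
+3.8…+6.0% and branch-point count within ±7% of truth over three fruit
phantoms; fruit/core/cortex region Dice ≥0.99 (epidermis ≈0.92 — a
few-voxel shell whose outer boundary rides the bright-skin blur tail, so
its overlap is boundary-noise limited). These establish correctness of
the estimators under the stated image model (two-level tissue, Gaussian
blur and noise, isolated fruit in the field of view). They do not
establish robustness to beam hardening, ring artifacts, intensity
inhomogeneity across the detector, touching objects, or anatomy the
generator omits (seeds, locules, the calyx/stem indentations, partial
xylem/phloem contrast).

## Degenerate inputs and tie-breaks

Constant images are a segmentation error; single-phase noisy volumes
return an empty void mask with a warning. An empty vessel mask returns an
empty network (warning), whose metrics are (0, 0, NaN). Watershed marker
ties are resolved by `peak_local_max`'s deterministic ordering; void
sorting ties are stable. Every generator and estimator is deterministic
under a fixed seed; the MIL direction set is deterministic by
construction (Fibonacci lattice).

## Problem sizes

The validation suite uses 64³–96³ phantoms for unit tests and the
generator defaults (96³ parenchyma, 160³ fruit, five and three phantoms
respectively) for end-to-end recovery, with anisotropy endpoints on 128³
grids — sizes chosen so the full battery runs on a laptop-class single
core in a few minutes while keeping every structure several voxels above
the resolution floor.
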