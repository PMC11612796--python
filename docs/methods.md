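# Methods

This note documents the model implemented by `onspv`, the assumptions and
defaults behind it, and the numerical choices a user may want to audit or
change. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Geometrical model

**Spaces.** Every RGC carries linked coordinates in visual field (degrees),
retina (mm, fovea-centered) and optic-nerve cross-section (mm, axis-
centered). The model frame is the left eye, +x nasal and +y superior;
right-eye mode mirrors x. Retina and visual field are converted with a
constant magnification of 0.29 mm/deg — a single-number stand-in for the
mildly nonlinear human magnification curve; it is a configurable field of
`RetinaGeometry`.

**Fibers.** The nerve section is a circle of radius R_ON = 2.5 mm. Fibers
come from uniform seed pairs. Two radial maps are provided:
`area_uniform` (ρ = R√u, the default; uniform per unit area) and
`as_printed` (ρ = R·u, linear in the seed; denser toward the center).
The linear map is sometimes written as the uniform-disc map although it is
not area-uniform, so both are kept; they share the same seed ordering and
therefore the same retinotopy. An inhomogeneous axon-density variant routes
the same seeds through the 2-D inverse-transform sampler instead.

**Soma density.** No digitized cadaveric density ships with the package.
The default `DensityField` is parametric: four radial profiles (nasal,
temporal, superior, inferior; CSV files under `onspv/data/`, editable) with
a central rise to a peak of ~3·10^4 cells/mm² near 1 mm eccentricity and a
two-exponential peripheral tail, interpolated log-linearly in angle. The
profiles integrate to ~0.7 million cells, inside the human range. Users
with digitized data can substitute the CSVs; everything downstream is
agnostic to their origin.

**Optic-disc void.** The corrected density is zeroed inside the disc
ellipse (centered 4 mm nasal, axes 1.88 × 1.77 mm). The zeroed node set is
dilated by roughly one polar-grid cell (an inflated-ellipse test with
margin 2(Δρ + ρΔθ)), so every point strictly inside the ellipse lies in a
grid interval whose endpoints are both zero. Because the sampler's CDFs are
piecewise linear on those nodes, it assigns the interior exactly zero
probability: the void is absolute, not statistical, while keeping the
fiber/soma seed pairing intact (no rejection resampling).

**2-D inverse-transform sampling.** The joint PDF is the corrected density
times the polar Jacobian; θ is drawn by inverting the marginal CDF
(cumulative trapezoid on a 256-column grid), ρ by inverting the conditional
CDF obtained by blending the two neighboring columns' unnormalized
cumulatives. All inversions are exact on the piecewise-linear tabulation
(a closed-form interpolation step rather than an iterative root search).
Default grid: 421 radial × 256 angular nodes over 21 mm.

**Receptive-field displacement.** CC_soma(ρ,θ) integrates the soma density
radially per meridian. Inside the displacement zone (default radius 4 mm)
CC_RF integrates a centrally peaked exponential RF-density profile
(scale 1.2 mm) normalized so both counts agree at the zone edge; outside it
CC_RF = CC_soma. The displacement equation CC_RF(ρ_RF,θ) =
CC_soma(ρ_soma,θ) is solved by exact inversion of the monotone tabulated
CC_RF, guaranteeing ρ_RF ≤ ρ_soma inside the zone and identity outside.
Both CC functions can be replaced by user tables
(`CumulativeCounts.from_tables`). The RF radius is linear in eccentricity,
σ = 0.05 + 0.01·ρ_RF degrees by default, clamped at 0.01°; the coefficients
are explicit configuration, not hidden constants, because no authoritative
pair ships with the package.

**Species mode.** Where no cumulative-count data exist (e.g. pig, macaque),
`species_mode=True` ties the soma and receptive-field coordinates together
(identical numbers, no displacement).

**R_RET = 21 mm** is the extent of the shipped profiles, an assumption
rather than a measurement, and is configurable.

## Encoding and reconstruction

Each cell's RF image is an isotropic (in degrees) Gaussian at its
visual-field position, σ in degrees converted per raster axis, truncated at
4σ (discarded mass < 4·10⁻⁴) and normalized against the *untruncated*
discrete Gaussian mass so that an all-white scene yields exactly
FR_max = 300 Hz for any cell whose mass lies inside the raster — cells
straddling the border scale down smoothly, cells outside encode zero.
Sub-half-pixel σ is clamped to half a pixel with a warning. Encoding is the
pixelwise product-and-sum; it is linear in the scene by construction.

Reconstruction computes Σ FR_i·RF_i over living cells and divides by the
coverage Σ FR_max·RF_i of the living population, so a full-rate pattern
renders white and percepts are comparable across grids and degeneration
states. Pixels with coverage below 10⁻⁶ of the maximum are rendered black
(they carry no usable signal). Whether the original normalization was
global-max or coverage-weighted is not determinable from the printed
formula (only a proportionality); the coverage-weighted choice is explicit
and configurable.

## Electrode grids and the partition rule

Nerve arrays tile the square circumscribed to the nerve section (n×n cells
of side 2R/n). The reduced grid starts from 14×14 and merges the central
8×8 block into 4×4 double-size cells: 196 − 64 + 16 = 148 sites. The
merge factor is 2×2 because that is the only construction consistent with
the 196→148 count. The retinal array is a 6×10 tiling with 0.525 mm
spacing (device-literature value, configurable); it partitions soma
positions — an epiretinal abstraction without axon-of-passage effects.
Cells are half-open so membership is unique.

The partition rule sets all fibers of a cell to the cell's maximum natural
rate when the active fraction (FR > 0) reaches the threshold (default
30%), else zero; broken sites and out-of-grid fibers are silenced. The rule
is idempotent and never invents rates.

## Degradation operators

All operators copy the population; soma and RF coordinates are never
modified.

* **Local shuffle** swaps fiber positions: partner j of a uniformly drawn
  fiber i is chosen with probability ∝ exp(−d²ᵢⱼ/2σ²). Defaults: σ = 1/5 of
  the exact mean pairwise fiber distance (computed chunked, O(n²) time,
  O(n·chunk) memory), n_swaps = round(n/5) — 2,000 swap operations at
  n = 10⁴. The draw of i may repeat across swaps; j ≠ i within a swap. The
  swap count is interpreted as the number of swap operations (each moving
  two fibers), matching the 1/5-of-n prescription. Implemented as an index
  permutation, so the multiset of fiber coordinates is preserved exactly.
* **Global shuffle** swaps 6×6 square units tiling the square inscribed in
  the nerve section, with the same Gaussian kernel on unit-center distances
  (σ = 1/5 of mean center distance) and round(36/5) = 7 swaps. Units move
  rigidly (translation by center difference): within-unit arrangement and,
  the units being congruent, overall uniformity are preserved.
* **Shuffle correction.** The reference procedure is only sketched in the
  sources ("identify the contacts targeting each RGC group"), so it is
  concretized here. Two implementations are provided. The *remap* form
  (`correct_global_shuffle`) votes, per site, for the pre-shuffle cell most
  represented among the fibers the site now controls (lowest id on ties)
  and returns a static site→cell map; it is the identity without a shuffle
  and exactly undoes a whole-unit swap aligned with the cell tiling. The
  *least-squares* form (the default corrected path in
  `stimulate_shuffled`) gives each site the available command closest to
  the mean intended rate of its current fibers — the optimum a single
  shared command can achieve in squared rate error. Plurality voting was
  implemented first but can worsen percepts when unit and cell boundaries
  misalign (most cells then hold fibers of mixed origin and the minority
  is served badly), which is why least squares is the default. Both
  corrections remain partial by construction.
* **Broken sites** flag round(fraction·n_sites) sites inactive (default
  10%), chosen uniformly; the partition rule silences their cells.
* **Encapsulation depletion** kills fibers within a given radius (50 or
  100 μm are typical literature values for fibrotic sheaths) of any site
  center.
* **Degeneration** draws per-fiber deaths from p(ρ): constant (uniform),
  k/(1+exp(ρ−0.35·R_RET)) (foveal) or the mirrored sigmoid (peripheral),
  with ρ the soma eccentricity in mm (configurable to RF eccentricity).
  The constant is solved by monotone bisection so the population mean of
  the clipped probability equals the target fraction (default 0.5);
  infeasible targets raise with the achievable maximum.

## Biophysical fiber model

A fiber is 31 Ranvier nodes (1 μm long, active) alternating with 30
passive internodes (100× the 1 μm diameter), threaded along z at the
fiber's transverse nerve position, centered so the electrode plane z = 0
crosses mid-length. Nodal kinetics use five gates — transient sodium
(m³h), A-type potassium (a³b), persistent sodium (p³) — with the ten rate
functions implemented with removable singularities evaluated by limit and
inputs clamped to ±500 mV (rates saturate; keeps exponentials finite when
an electrode nearly touches a compartment). The persistent current uses a
(V − E_Na) driving force — the printed form without a driving term is
retained as an `as_printed` audit option, as it is not integrable as a
current density. The unusually large β_b magnitude (60 ms⁻¹) is
transcribed faithfully and exposed in configuration.

Membrane constants are configuration defaults in the range of myelinated
fiber models of this class, not asserted measurements: g_Na = 400,
g_A = 100, g_P = 2.5, g_l = 10 mS/cm²; E_Na = +50, E_K = −90 mV; nodal
capacitance 2 μF/cm²; myelin capacitance 0.05 μF/cm² and conductance
0.05 mS/cm²; axial resistivity 70 Ω·cm; rest −70 mV. The leak reversal is
balanced at initialization so the resting state is an exact equilibrium
(quiescence without drive is by construction, and verified).

Stimulation sites are point sources in an infinite homogeneous anisotropic
medium (σ_xy = 0.08, σ_z = 0.5 S/m): l = 1/(4π√(σ_xy σ_z(Δx²+Δy²) +
σ_xy²Δz²)), the standard anisotropic point-source solution; the square
root is restored relative to the commonly misprinted form, which is
dimensionally inconsistent (an `as_printed` audit mode evaluates it
anyway). Per-site currents are A_j·sin(2πf_j t); extracellular potentials
enter the cable equation through axial differences between neighboring
compartments.

Integration is backward-Euler for the voltage (tridiagonal Thomas solve
per step, vectorized across a batch of fibers and JIT-compiled when numba
is available) with exponential gate updates — stable at the default
dt = 0.1 ms over 1000 ms. Spikes are local maxima of the recording-node
(node 26 of 31, 1-based) potential above +10 mV absolute, merged within
1 ms; firing rate is count/duration. The choice of absolute potential
(rather than deviation from rest) for the 10 mV criterion is configurable.

## Synthetic stimuli

Instance scenes are depth-coded: table/indoor settings use the linear law
I = (d_min − d)/(d_max − d_min) + 1 and outdoor the quadratic
I = a·d² + b with a = 1/(d_min² − d_max²) and b = −d_max²/(d_min² − d_max²),
so that I(d_min) = 1 and I(d_max) = 0 in all settings; values are
clipped to [0,1] outside the range (the sources are silent on
out-of-range depths). Ranges: 0.3–1.5 m (table), 0.5–5 m (indoor),
1.5–16 m (outdoor). Overlaps render nearer-on-top.

The static generator emulates a segmented-and-depth-coded capture:
rectangles/ellipses with pairwise distinct depths and areas, labels from a
three-word vocabulary per setting, ground truth recorded for scoring. The
dynamic generator produces 3 s clips (default 30 fps; the frame rate is a
package choice) of gray blocks translating horizontally at distinct
velocities, each guaranteed visible in at least one frame. What these
fixtures do *not* emulate: real segmentation errors, textured objects,
occlusion ambiguity, depth-map noise and FOV misalignment — so passing
tests demonstrate the pipeline's behavior on clean inputs, not robustness
to real RGB-D capture artifacts.

## Task scoring and baselines

Count errors are ε_A = |n_true − n| and ε_R = ε_A/n_true; orderings are
compared with Kendall's τ (scipy implementation, validated in the tests
against an O(n²) pair-counting oracle), computed only when the reported
count is correct; classification error is the mislabeled fraction.
Random-answer subjects draw counts from the empirical count distribution
of the stimulus set, orderings as uniform permutations, and classification
as independent uniform target/answer over three labels (expected error
2/3). Group comparisons use Kruskal–Wallis followed, when significant at
0.05, by pairwise Dunn tests with Bonferroni correction (Dunn is
implemented directly — rank sums with tie correction — as no installed
package provides it); ties in τ cannot arise because orderings are strict
permutations.

## Problem sizes and tolerances used by the verification suite

The reference population is 10⁴ cells; goodness-of-fit checks (χ² on
12×12 polar bins at α = 0.01, KS against U(0,1)) use 10⁵ samples. Percept
comparisons run on a 320×240 raster (same 90°×65° FOV as the default
640×480; encoder calibration is checked at full size). The grid-refinement
and shuffle-correction checks use five synthetic four-object table scenes;
the refinement trend (10×10 → 14×14 → 32×32) is asserted on the mean MSE
over the scene set, since individual scenes can break monotonicity through
grid-alignment accidents while the trend is a property of the ensemble.
The biophysical compatibility check uses a compact 0.8 mm nerve section
with 50 fibers and one central site at 2000 μA/100 Hz for 500 ms —
amplitude tuned, as stimulation protocols are in practice, to recruit the
whole section; with the full 2.5 mm section a single central source cannot
recruit distant fibers (the activating function flattens at transverse
distances comparable to the modeled fiber length), which is a physical
feature, not a numerical artifact.

## Known limitations

* The RGC response is linear and static: no center-surround antagonism,
  rectification, adaptation or temporal dynamics.
* The shipped density and cumulative-count profiles are parametric
  stand-ins with the right structure and magnitudes, not digitizations of
  histological data.
* Axon trajectories between retina and nerve are not modeled; fiber
  positions in the nerve are statistical, not anatomical, so
  axon-of-passage phosphene elongation is absent.
* The volume conductor is infinite and homogeneous; no nerve sheath,
  perineurium or finite-element geometry.
* Percept normalization, σ_RF coefficients, the mm/deg conversion and all
  biophysical membrane constants are explicit assumptions; every
  population and simulation records them in its configuration output.
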