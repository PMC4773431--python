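# Methods

This note documents the models, numerical schemes and design choices behind
`embryotrack`, what the synthetic data generator does and does not emulate,
and the known limitations. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted from
memory of real data.

## Coordinate and unit conventions

Arrays are indexed `(z, y, x)`, 0-based. Physical positions are `(x, y, z)`
micrometres under the centre-of-voxel convention
`physical = (index + 0.5) × spacing`, with spacing given as `(sz, sy, sx)`
µm. All inter-centre distances are computed in physical µm, so anisotropic
voxels (common in light microscopy: z coarser than x, y) are handled
uniformly — a sigma or radius given in µm is converted per axis to voxel
units wherever a discrete kernel is built. Intensities are never rescaled
on load; thresholds are either absolute or fractions of a per-frame
maximum, and each function documents which.

The lineage forest stores mothers as a daughter → mother map. This makes
the single-mother constraint structural (in-degree > 1 is unrepresentable);
the two-daughter constraint is checked by `LineageForest.validate`, so
intermediate tracking states can carry recorded violations. Lineage files
are plain CSV (`id,t,x,y,z,mother_id,virtual`) with positions written at
six decimals — the documented round-trip precision.

## Geodesic mean curvature flow (filtering)

The continuous model is

u_t = g(|∇G_σ ∗ u|) κ |∇u| + ∇g·∇u,  g(s) = 1/(1 + K s²),

edge-stopped mean-curvature motion of the image's level sets. Discretely:

* curvature term by the standard regularized expansion
  `[Σᵢ uᵢᵢ(Q − uᵢ²) − 2Σᵢ<ⱼ uᵢuⱼuᵢⱼ]/Q` with `Q = |∇u|² + ε²`,
  `ε = 10⁻⁴ × (intensity range)`;
* advection term `∇g·∇u` upwinded on the sign of each velocity component;
* reflective (zero-flux Neumann) boundaries — chosen to avoid edge
  darkening; the boundary condition is otherwise a free choice;
* explicit time stepping with
  `τ ≤ 0.4 / (2 Σ 1/hᵢ² + Σ |v|ᵢ/hᵢ)` when no τ is given;
* a per-step min–max limiter clipping the iterate to the input range. The
  continuous flow satisfies a maximum principle; the limiter removes the
  residual overshoot of the explicit scheme so the discrete guarantee is
  exact. Instability (a wrong explicit τ) is detected as a non-finite value
  or a >10× overshoot of the input range *before* limiting, and reported
  with the advice to reduce τ.

Defaults: `K = 1` on raw gradient units (the pipeline uses `K = 0.01` for
8-bit-like dynamic ranges where gradients are tens of units per µm),
`σ_pre = 1 µm`, 5 iterations. K and σ are data-dependent by nature; they
are exposed in every interface. With `K = 0` the flow is pure mean
curvature motion, under which the volume enclosed by an isolevel of a noisy
ball shrinks — one of the phantom tests.

## FBLS centre detection

The level-set motion `V = δ + μk` is split the same way: `μ·(curvature
term)` plus `δ·|∇u|` with the Godunov upwind gradient for the sign of δ.
The sign convention makes δ < 0 erode bright superlevel sets. Defaults
`δ = −0.05`, `μ = 1`, 10 iterations: mild erosion plus curvature smoothing,
enough to merge noise maxima while nucleus humps survive. Local maxima are
voxels ≥ all 26 neighbours, above `intensity_floor × frame max`
(default 0.2 — safely above background fluctuations that sit near 5–10 % of
a typical nucleus peak, and below even a half-intensity, depth-attenuated
anaphase figure); plateaus of equal-valued connected maxima merge to one
centre at the plateau centroid. The 26-neighbourhood and plateau handling
are implementation choices made for rotational symmetry of the tests.

## DoG centre detection

Response `G_σs ∗ u − G_σl ∗ u`; voxels above `threshold_pct/100 × max
response` form 26-connected components; one centre per component at the
response-weighted centroid. The threshold is relative to the per-frame
response maximum, making detection equivariant to global intensity scaling.
A consequence of the component rule worth knowing: at threshold fraction θ
a blob's footprint has radius `σ_eff √(2 ln 1/θ)` (σ_eff² = σ² + σs²), so
two nuclei merge into a single component when closer than twice that —
about 14 µm at the defaults (σs = 2 µm, θ = 0.05). DoG is therefore the
low-density detector; the FBLS path is the default in the pipeline.

## Subjective-surface segmentation

A seeded, radially decreasing function `u₀ = 1/(1 + r/h)` (h = 5 µm)
evolves under

u_t = w_d · g · κ_ε|∇u|_ε + w_c · ∇g·∇u,

with `g` computed on the [0, 1]-normalized image (so `K` has an
intensity-independent meaning) presmoothed at 1 µm. The ε in
`|∇u|_ε = √(|∇u|² + ε²)` interpolates between curvature motion (ε → 0) and
plain edge-stopped diffusion (ε large): diffusion floods the object
interior, the advection term drags level sets toward edge minima of g from
both sides, and the function develops a plateau inside the object with a
sharp drop at its boundary — including across staining gaps, which is the
contour-completion property. The mask is the seed's connected component of
`{u ≥ iso_fraction × max u}`, hole-filled; masks touching the border are
flagged.

Defaults were fixed on the sphere phantom (R = 6 µm, SNR ≈ 60): `ε = 0.5`,
`w_c = 8`, `w_d = 1`, `K = 2000`, 400 iterations, `iso_fraction = 0.5`.
With these the phantom volume is recovered within 15 % and the boundary
within 2 voxels Hausdorff (measured in the tests; the acceptance script
reports the volume error, ≈ 13 %). A weaker edge term lets the 0.5-of-max
cut land outside the intensity edge and overestimate volume — the main
failure mode to watch on low-contrast data.

Whole-embryo segmentation first smooths the nucleus channel at the tissue
scale (default 8 µm, roughly the internuclear distance) so nuclei blur into
one region, then runs the same evolution seeded at the intensity centroid
with a wide seed profile. Cell density is the centre count inside the mask
divided by its physical volume.

## Tracking

Stage 1 — nearest neighbour: every centre at t+1 links to its nearest
centre at t within `d_max`. Daughters choose mothers, so divisions need no
special case; the raw result may violate the two-daughter limit, which is
left for annealing.

Stage 2 — simulated annealing on the link set. The cost is a weighted sum
of per-centre terms (each term has one owner, which is what makes
incremental evaluation exact):

| term | owner | form | default weight |
|---|---|---|---|
| multi-mother | — | structurally 0 (representation) | 10⁴ (hard) |
| excess daughters | mother | out-degree − 2 when > 2 | 10⁴ (hard) |
| motherless | daughter | 1 per centre at t > 0 with no mother | 10 |
| disappearance | mother | 1 per centre at t < T with no daughter | 10 |
| displacement | daughter | (d/d_max)² per link | 1 |
| division interval | mother | 1 per division with an ancestor division ≤ τ_div frames back | 5 |
| inertia | daughter | ‖v_t − v_{t−1}‖²/d_max² | 0.5 |
| sister symmetry | mother | ‖v_A − v_B‖²/d_max² at division | 0.5 |

All distance terms are normalized by `d_max` to be unit-free. The
disappearance term encodes the absence of cell death at the developmental
stages modelled; `allow_disappearance` zeroes it for other systems.
Weights are config-visible and justified solely by the oracle-equivalence
and synthetic-recovery gates.

Moves, proposed uniformly: rewire a centre's mother among its
`k_candidates` nearest predecessors; delete a link; swap the mothers of two
same-frame centres; and a compound *adopt + displace* move that attaches a
centre to a candidate mother while rewiring one existing daughter of that
mother in the same proposal. The compound move exists because some optima
are separated from the greedy solution only by an uphill intermediate
(gaining a second daughter before releasing the first); with it, the
annealer reaches the exhaustive-enumeration minimum on every tested
two-frame instance at a modest temperature (T₀ = 1, linear schedule to 0,
`min(1, exp(−Δ/T))` acceptance, strict descent at T = 0). Cost changes are
evaluated incrementally over the union of affected owners in the pre- and
post-move states, and a property test pins the incremental total to the
full recomputation. After the schedule a deterministic sweep removes any
residual excess-daughter links (farthest first) so the returned forest
always satisfies the hard constraints; determinism is per-seed.

Stage 3 — repair. Candidate edits are (a) deletion of isolated trees
spanning fewer than `L_min` (default 3) frames — spurious detections — and
(b) bridging a track that ends at t to one that starts at t+2 within
`2·d_max`, inserting a `virtual` centre at the spatial midpoint. Edits are
selected by the same annealing machinery over the edit set; bridge edits
never touch members of deletable branches, and virtual ids are drawn from a
monotone counter so toggling edits cannot collide. Deleting anything always
lowers this cost function (there is no data-fidelity reward), which is
exactly why deletion candidates are restricted to short branches.

Label propagation walks links forward from each labelled centre; conflicts
are impossible because of the single-mother constraint.

## Validation metrics

Matching is one-to-one per frame: maximum-cardinality,
minimum-total-distance assignment (Hungarian on a padded cost matrix with a
prohibitive cost for pairs beyond the radius), radius = `r_factor ×` mean
nearest-neighbour distance among the gold centres of that frame. The mean
nearest-neighbour definition and the one-to-one rule are the package's
choices where the protocol leaves room: one-to-one prevents a single
detected centre from serving two gold nuclei, and a brute-force enumeration
oracle pins the matcher on all small instances. `r_factor` defaults to 0.5,
the midpoint of the useful 0.2–0.6 window, and is exposed everywhere.

Link errors are counted over TP centres whose gold twin has a mother:
correct mother → TP; mother matched elsewhere → wrong link (WL, counted in
FP and FN); no mother → missing link (ML, FN only); FN = WL + ML. A gold
division is assessable when mother and both daughters are TP; it is TP when
the detected forest links the matched mother to both matched daughters. A
detected division whose TP mother does not correspond to such a reproduced
gold division counts FP — deliberately including the common artifact where
a nucleus is split in two and one half is itself a false-positive centre.
Centre counts conserve `TP + FN = |gold|` and `TP + FP = |detected|`;
link/mitosis categories do not, because they are restricted to TP centres.
Scoring can be limited to scope boxes (space × time windows) when the gold
standard is regional; events outside scope are ignored entirely, on both
sides. Zero denominators yield an explicit undefined marker, never 0.

## Synthetic embryo

The generator emulates the regime the pipeline targets: ~100 nuclei
(Gaussian blobs, σ = 2 µm) in a 120 × 120 × 60 µm³ box at 1.37 µm isotropic
voxels; drift (0.3, 0.2, 0) µm/frame plus a 0.8 µm random walk — per-frame
displacement ≈ 0.1 of the ≈ 12 µm mean internuclear distance; soft
repulsion below 8 µm; no cell death; division probability 0.01 per cell per
frame with a 10-frame refractory period (a cell cycle of order a hundred
frames, far from cleavage-stage synchrony); daughters placed ±1.5 σ around
the mother (≈ one nucleus diameter apart, the anaphase/telophase geometry
that makes a division detectable as two objects) and rendered at half
intensity in their birth frame; background 10, peak 200, Gaussian noise
σ = 4; signal attenuated by 0.2 % per µm of depth. Everything is
deterministic per seed; rendering windows each blob to ±4 σ.

What it does *not* emulate: chromatin texture, PSF anisotropy beyond the
per-axis sigma, scattering, bleaching, nucleus-size variation, apoptosis,
or imaging gaps longer than one frame. Passing the recovery gate (centre
sensitivity ≥ 0.99, linkage ≥ 0.95, mitosis ≥ 0.8 on this generator)
therefore demonstrates the machinery is correct and self-consistent, not
that these rates transfer to any particular real acquisition — on real
data, performance is bounded by SNR at depth and by nucleus density, and
parameters (K, σ, δ, μ, thresholds, d_max) must be chosen per dataset.

## Problem sizes

The default test and acceptance workloads were sized for a single CPU: the
full-pipeline recovery runs 30 frames of 88 × 88 × 44 voxels (~1 minute),
oracle equivalence enumerates 50 two-frame instances with ≤ 5 centres per
frame against best-of-20 annealing restarts, and the phantoms are 24³–40³
volumes. Larger volumes scale linearly in voxels for the PDE stages and
near-linearly in centres for tracking (KD-tree candidates, incremental
costs).

## Known limitations

* Explicit time stepping only; a semi-implicit scheme would allow larger τ
  for the same stability and is the natural next step for big volumes.
* The DoG component rule merges close blobs (see above); it has no
  per-component splitting.
* Per-cell SubSurf segmentation runs on the full frame per seed; cropping a
  window around each seed would make all-cell segmentation practical.
* Repair bridges only single-frame gaps; two-frame gaps remain split
  tracks.
* The quantitative fidelity of segmentation masks is gated only by
  phantoms; no manual-outline benchmark is included.
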