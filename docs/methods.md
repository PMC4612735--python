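# Methods

This note records the model implemented by `rfaseg`, the choices made where
the design was genuinely open, and what the synthetic tests do and do not
demonstrate.

## Segmentation model

The segmenter finds a closed, star-shaped (with respect to the seed)
surface around a user-supplied seed point. The search space is discretized
by a spherical template: rays from the seed towards the vertices of a
refined icosahedron, each ray sampled at `nodes_per_ray` equidistant radii
`(j+1)·Δs` with `Δs = max_radius_mm / nodes_per_ray`. A surface is a choice
of one cut level per ray, constrained so that adjacent rays (edges of the
template triangulation) differ by at most the integer smoothness parameter
Δr. Δr = 0 admits only spheres; each increment widens the family of
reachable shapes.

Node costs are `c(v) = |ref − g(v)|` with `g` trilinearly interpolated and
`ref` the pooled ablation-zone intensity (below). Costs enter the graph as
per-node *votes*: the excess `c(v) − θ`, clamped to `[−θ, +θ]`, where θ is
a classification margin. Negative votes (lesion-like nodes) become source
links, positive votes sink links, and node 0 of every ray is tied to the
source with ∞ capacity so the seed is always foreground. With the
∞-capacity intra- and inter-edges, a minimum s–t cut minimizes the total
cumulative excess

    Σ_r Σ_{j ≤ k_r} clamp(c(r, j) − θ,  −θ, +θ)

over all Δr-feasible cut vectors (k_r). Intuitively each ray's boundary
advances while sampled values stay on the lesion side of the margin and
stops where they cross it, so the surface settles at the intensity
transition. This functional is verified exactly against an independent
brute-force enumeration on small instances in the test suite.

Two properties were essential in practice and are worth stating:

* **Why a cumulative (region) functional.** A functional that charges only
  the cost *at* the cut node is minimized anywhere inside a homogeneous
  lesion; under image noise its optimum wanders to interior noise minima
  and the segmentation collapses (measured DSC ≈ 0.03 on a noisy phantom).
  The cumulative form integrates evidence along the ray and is robust:
  noise of σ well below the lesion/background contrast perturbs the
  boundary by at most about one radial step.
* **Why clamped votes.** Unbounded votes let a thin, extremely bright
  needle crossing (|c| ≈ 900 against a contrast of 70) block a ray
  permanently: the accumulated penalty can never be recovered by the
  lesion tissue behind the needle, and Δr then drags neighboring rays
  inward too. Clamping to ±θ bounds each node's influence
  (winsorization); a 2-node needle crossing costs two +θ votes, which a
  handful of lesion nodes beyond it outvote.

### Margin θ

`cost_threshold` defaults to `|ref − background| / 2`, with the background
estimated as the median gray value at the outermost in-bounds node of each
ray. The halfway margin places the boundary at the 50 % intensity point of
the partial-volume ramp — the unbiased boundary estimate under symmetric
blur. The outer-shell estimate assumes the rays extend beyond the lesion
into representative background, which is the same assumption behind the
choice of `max_radius_mm`. The margin is floored at one intensity unit so
contrast-free inputs still produce a well-defined (maximal) network.

### Tie handling

Among multiple minimum cuts the solver reports the *maximal* source side —
the complement of the set of nodes that can reach the sink in the residual
network. In a perfectly homogeneous interior all interior cuts tie; the
maximal rule resolves to the outermost optimal boundary, which matches the
intended semantics ("last nodes still bound to the seed"). The brute-force
oracle instead breaks ties to the lexicographically smallest index vector;
oracle comparisons are therefore made on objective values, not vectors.

## Reference intensity

The reference is pooled over an axis-aligned cube of 1000 mm³ (edge
≈ 10 mm, converted per axis to voxel counts, at least one voxel per axis)
centered at the seed. The default statistic is the **median**: with an
umbrella needle in place, needle voxels can occupy well over 10 % of the
cube, which shifts a mean by ~100 intensity units (enough to invert the
segmentation) while leaving the median at the lesion value. The mean
remains available (`mode="mean"`) for needle-free data. Cube bounds use an
epsilon-inclusive rounding so integer-voxel translations of the image and
seed leave the estimate unchanged.

## Sphere template

Templates start from the canonical golden-ratio icosahedron and refine by
centroid insertion: at each level the centroid of every face of the current
spherical Delaunay triangulation (convex hull) is projected onto the unit
sphere and added, and the point set is re-triangulated. Since any sphere
triangulation has F = 2V − 4, each level maps V → 3V − 4, giving exactly
12, 32, 92, 272, 812, 2432 vertices (20·3^level faces) for levels 0–5.
Re-triangulating per level keeps the direction set quasi-uniform
(nearest-neighbor angular spread within a factor 1.4 at every level) and —
critically — keeps all adjacency edges at comparable angular scale, so the
Δr bound means the same thing everywhere on the sphere. Retaining the raw
subdivision combinatorics instead would keep the original 63° icosahedron
edges at every level; measured on an off-center seed, that over-smooths
the oblique boundary badly (DSC 0.72 instead of 0.96).

## Surfaces and masks

The cut's per-ray boundary points (positions of the last source-side
nodes), triangulated by the template, form a watertight mesh by
construction. Voxelization tests each voxel center against the mesh's
cross-section at that slice's z height using an even-odd crossing count on
the raw section segments; manual slice contours are filled with the same
center-inside rule (orientation-free) and merged by union. Voxel centers
exactly on a boundary follow the half-open crossing rule and are counted
deterministically. The same center-inside convention underlies the
volumetry (voxel count × voxel size), keeping mask volume and DSC
consistent.

## Min-cut solver and numerics

Max-flow is computed with `scipy.sparse.csgraph.maximum_flow` (Dinic, C
implementation), which requires 32-bit integer capacities. Votes are
quantized at `cost_scale` capacity units per intensity unit (default 10,
i.e. 0.1-unit resolution — far below CT noise). The ∞ stand-in is
1 + (total sink-side capacity): cutting any ∞ edge then provably exceeds
the trivial all-foreground cut, so ∞ edges never appear in an optimal
unconstrained cut; a cut value ≥ ∞ is reported as mutually incompatible
boundary constraints. A guard raises before any capacity or the total sink
capacity could overflow 32 bits, naming `cost_scale` as the remedy.
Out-of-bounds nodes (rays leaving the volume) are flagged and given a
penalty cost of twice the largest in-bounds cost, making them definite
background relative to any in-bounds node.

Boundary constraints pin the nearest ray: every node up to the constraint
radius receives an ∞ source link and the next node an ∞ sink link; the Δr
inter-edges propagate the restriction to neighboring rays.

## Phantom generator

Phantoms emulate post-interventional RFA CT at the descriptive level: a
dark ellipsoidal lesion (default 40) in brighter parenchyma (110), an
optional thin hyper-enhancing rim (160), an optional umbrella needle —
cylindrical shaft entering the lesion plus tines fanning from a hub at a
fixed opening angle, all far brighter (1000) — and additive Gaussian noise
with a seeded generator. Ground truth is the analytic ellipsoid sampled at
voxel centers; needle voxels are excluded from the truth, the rim is
excluded by default but can be included to study rim-adaptation effects.
An optional low-order radial perturbation (`bump_amplitude`) provides
non-spherical stress shapes. `paper_case_suite` draws reproducible case
collections with 512×512 matrices, 0.679–0.777 mm pixels, 1–3 mm slice
spacing, lesion volumes log-uniform over ≈6–123 cm³ and a needle in every
second case.

What the phantoms do **not** emulate: beam-hardening and streak artifacts
around metal, spatially correlated reconstruction noise, intensity
inhomogeneity inside real necrosis, liver anatomy (vessels, capsule,
neighboring organs) and contrast-phase effects. Passing the phantom tests
therefore demonstrates the correctness and noise/outlier robustness of the
optimization machinery, not clinical-grade accuracy; on real data the
achievable agreement is bounded by exactly these unmodeled effects.

## Parameters and problem sizes

| parameter | default | meaning / guidance |
| --- | --- | --- |
| `delta_r` | 2 | smoothness in radial steps per adjacency edge; 0 = sphere |
| `nodes_per_ray` | 40 | radial samples; boundary resolution = `max_radius/nodes` |
| `max_radius_mm` | 40 | ray length; use ≈ 2× the expected lesion radius so rays reach representative background without wasting radial resolution |
| `template_level` | 4 (812 rays) | angular resolution; 5 (2432) costs ~3× |
| `cost_scale` | 10 | capacity units per intensity unit |
| `cost_threshold` | derived | classification margin θ; override for known contrast |
| reference mode | median | use mean only for needle-free data |

The surface passes through the last sampled node inside the lesion, so
reported volumes carry a small negative bias of up to one radial step
(0.75 mm at the defaults used in the examples); finer steps shrink it.

Test and example phantoms use a 97×97×41 grid at 0.7×0.7×2.0 mm with a
15 mm lesion and 30 mm rays; oracle comparisons use 12-ray templates with
6–8 nodes, where exhaustive enumeration is exact and fast. These sizes
exercise every code path at full angular resolution (812 rays × 40 nodes
for the pipeline runs) while keeping the whole suite quick to re-run.

## Known limitations

* Star-shaped surfaces only: the boundary is single-valued per ray, so
  strongly concave or multi-lobed zones are out of reach by construction.
* Axis-aligned volumes only (no direction cosines); DICOM support is a
  best-effort series read.
* The θ margin assumes the rays' outer ends sample representative
  background; lesions larger than `max_radius_mm` or seeds placed outside
  the lesion violate the model (the interactive workflow — move the seed,
  re-run — is the intended remedy, as is adding border constraints).
* Volumes are biased low by up to one radial step (see above).
* The 2432-ray template works but is ~3× slower; the defaults favor
  interactive re-running over maximal angular resolution.
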