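"""Ray-template graph construction and Δr-constrained min-cut.

The segmentation graph has one column of nodes per template ray.  Node ``j``
of a ray sits at radius ``(j+1) * max_radius_mm / nodes_per_ray`` from the
seed.  Each node carries a cost ``c(v) = |reference - gray(v)|``.  Three
families of edges are built:

* **intra-edges** — ∞-capacity arcs from node ``j`` to ``j-1`` along each
  ray, so the source-side set of any finite cut is a contiguous prefix
  (the segmented interior is a closed set around the seed);
* **inter-edges** — ∞-capacity arcs between adjacent rays (edges of the
  template triangulation) from ``(r, j)`` to ``(r', max(0, j - Δr))`` and
  symmetrically, bounding the per-ray cut-level difference by the integer
  smoothness parameter Δr (Δr = 0 forces a sphere);
* **terminal edges** — one per node, from the excess of its cost over a
  classification margin θ: a node with ``c(v) < θ`` (lesion-like) gets a
  source link of capacity ``θ - c(v)``, any other node a sink link of
  capacity ``c(v) - θ``.  Node 0 is additionally tied to the source with ∞
  capacity so the seed is always foreground.  θ defaults to half the
  contrast between the reference value and a background estimate (the
  median gray value at the outermost in-bounds node of each ray), keeping
  the method free of per-scanner intensity settings.

The per-node excess ``c(v) - θ`` is clamped to ``[-θ, +θ]`` before it
becomes a capacity, bounding the influence of any single node: a thin
bright needle crossing a ray contributes a few ``+θ`` votes that the lesion
nodes beyond it can outvote, instead of an arbitrarily large cost that
would freeze the boundary in front of the needle.

Cutting a ray between nodes ``k`` and ``k+1`` severs the sink links of the
included nodes and the source links of the excluded ones, so up to a
constant the cut pays the cumulative excess cost
``E(r, k) = Σ_{j<=k} clamp(c(r, j) - θ)``.  A minimum s-t cut therefore
selects exactly the Δr-feasible per-ray cut-index vector minimizing
``Σ_r E(r, k_r)`` (verified against the brute-force oracle in the test
suite): each ray's boundary advances while the sampled gray values stay on
the lesion side of the margin and stops where they cross it, which places
the surface at the intensity transition and is robust to image noise.
Among multiple minimum cuts the *maximal* source side is reported — the
complement of the set of nodes that can still reach the sink in the
residual network — so that exact cost ties resolve to the outermost
optimal boundary.

Capacities are quantized to integers (``cost_scale`` capacity units per
intensity unit) because the underlying solver,
:func:`scipy.sparse.csgraph.maximum_flow`, works on 32-bit integer
capacities; an explicit guard rejects networks that would overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .errors import (
    InfeasibleConstraintError,
    InvalidParameterError,
    SizeGuardError,
    SolverError,
    StructuralError,
    UnreachableConstraintError,
)
from .template import MAX_LEVEL, RayTemplate
from .volume import ImageVolume, SeedPoint

__all__ = [
    "GraphCutParams",
    "NodeGrid",
    "FlowNetwork",
    "CutResult",
    "BoundaryConstraint",
    "sample_node_grid",
    "build_flow_network",
    "solve_min_cut",
    "brute_force_cut",
    "apply_boundary_constraints",
]

_INT32_MAX = 2**31 - 1


@dataclass(frozen=True)
class GraphCutParams:
    """Tunable parameters of the graph construction.

    Attributes
    ----------
    delta_r : int
        Smoothness bound on the cut-level difference between adjacent rays;
        0 forces a spherical result.
    nodes_per_ray : int
        Number of sampled nodes per ray (2..40).
    max_radius_mm : float
        Length of every ray; the radial step is ``max_radius_mm / nodes_per_ray``.
    template_level : int
        Sphere-template refinement level (0..5 → 12..2432 rays); default 4
        (812 rays).
    cost_scale : float
        Integer capacity units per intensity unit (quantization of costs).
    cost_threshold : float or None
        Classification margin θ separating lesion-like from background-like
        node costs; None (default) derives it from the data as half the
        reference-to-background contrast.
    """

    delta_r: int = 2
    nodes_per_ray: int = 40
    max_radius_mm: float = 40.0
    template_level: int = 4
    cost_scale: float = 10.0
    cost_threshold: float | None = None

    def __post_init__(self) -> None:
        if not 2 <= self.nodes_per_ray <= 40:
            raise InvalidParameterError(
                f"nodes_per_ray must be in 2..40, got {self.nodes_per_ray}"
            )
        if self.delta_r < 0 or self.delta_r >= self.nodes_per_ray:
            raise InvalidParameterError(
                f"delta_r must satisfy 0 <= delta_r < nodes_per_ray, got {self.delta_r}"
            )
        if not self.max_radius_mm > 0:
            raise InvalidParameterError(
                f"max_radius_mm must be positive, got {self.max_radius_mm}"
            )
        if not 0 <= self.template_level <= MAX_LEVEL:
            raise InvalidParameterError(
                f"template_level must be in 0..{MAX_LEVEL}, got {self.template_level}"
            )
        if not self.cost_scale > 0:
            raise InvalidParameterError("cost_scale must be positive")
        if self.cost_threshold is not None and not self.cost_threshold > 0:
            raise InvalidParameterError("cost_threshold must be positive")

    @property
    def step_mm(self) -> float:
        return self.max_radius_mm / self.nodes_per_ray


@dataclass
class NodeGrid:
    """Sampled node positions, gray values and costs (rays × nodes)."""

    positions: np.ndarray  # (rays, nodes, 3) world mm
    radii: np.ndarray  # (nodes,) distance from seed, mm
    gray: np.ndarray  # (rays, nodes)
    cost: np.ndarray  # (rays, nodes), >= 0
    in_bounds: np.ndarray  # (rays, nodes) bool
    seed_world: np.ndarray  # (3,)
    reference_value: float

    @property
    def n_rays(self) -> int:
        return self.cost.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.cost.shape[1]


@dataclass
class FlowNetwork:
    """Directed capacitated s-t network over the ray/node grid.

    Node ``(r, j)`` has id ``r * nodes + j``; the two virtual terminals are
    ``source = rays * nodes`` and ``sink = rays * nodes + 1``.  ``infinity``
    is the finite stand-in for ∞: strictly larger than the total sink-side
    terminal capacity, hence provably never part of a minimum cut of an
    unconstrained problem.
    """

    rays: int
    nodes: int
    infinity: int
    cost_scale: float
    cost_threshold: float
    edges_u: np.ndarray
    edges_v: np.ndarray
    edges_cap: np.ndarray  # int64 capacities
    excess_int: np.ndarray  # (rays, nodes) cumulative quantized excess cost
    source_slack: int  # Σ of source-link capacities (cut-value offset)
    positions: np.ndarray  # (rays, nodes, 3)
    seed_world: np.ndarray
    adjacency_pairs: np.ndarray  # (n_edges, 2) ray adjacency
    delta_r: int
    n_constraints: int = 0

    @property
    def source(self) -> int:
        return self.rays * self.nodes

    @property
    def sink(self) -> int:
        return self.rays * self.nodes + 1

    @property
    def n_graph_nodes(self) -> int:
        return self.rays * self.nodes + 2

    def node_id(self, ray: int, index: int) -> int:
        return ray * self.nodes + index

    def with_extra_edges(self, u, v, cap) -> "FlowNetwork":
        """A copy of the network with additional directed edges."""
        return replace(
            self,
            edges_u=np.concatenate([self.edges_u, np.asarray(u, dtype=np.int64)]),
            edges_v=np.concatenate([self.edges_v, np.asarray(v, dtype=np.int64)]),
            edges_cap=np.concatenate([self.edges_cap, np.asarray(cap, dtype=np.int64)]),
        )


@dataclass
class CutResult:
    """Per-ray cut indices (last node on the source side) and diagnostics."""

    cut_index: np.ndarray  # (rays,) int
    flow_value: float  # min-cut capacity, intensity units
    boundary_points: np.ndarray  # (rays, 3) world mm
    boundary_cost: float  # Σ_r Σ_{j<=k_r} (c(r,j) - θ), intensity units
    delta_r: int
    feasible: bool  # |cut_index[r] - cut_index[r']| <= delta_r on adjacency


@dataclass(frozen=True)
class BoundaryConstraint:
    """A user-placed point on the lesion border (world mm)."""

    point: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", tuple(float(p) for p in self.point))


# ---------------------------------------------------------------------------
# node sampling
# ---------------------------------------------------------------------------

def sample_node_grid(
    volume: ImageVolume,
    seed: SeedPoint,
    template: RayTemplate,
    params: GraphCutParams,
    reference_value: float,
) -> NodeGrid:
    """Sample gray values and costs along every template ray.

    Node ``j`` of each ray lies at radius ``(j+1) * step`` from the seed
    (the seed voxel itself is represented by the always-foreground node 0).
    Gray values are trilinearly interpolated; nodes outside the volume are
    flagged and given a penalty cost of twice the largest in-bounds cost,
    which makes them definite background relative to any in-bounds node.
    """
    seed_world = seed.to_world(volume)
    step = params.step_mm
    radii = step * np.arange(1, params.nodes_per_ray + 1)
    # (rays, nodes, 3)
    positions = (
        seed_world[None, None, :]
        + template.directions[:, None, :] * radii[None, :, None]
    )
    vox = (positions - np.asarray(volume.origin)) / np.asarray(volume.spacing)
    shape = np.array(volume.shape)
    in_bounds = np.all((vox >= 0) & (vox <= shape - 1), axis=2)
    coords = np.moveaxis(vox, 2, 0)  # (3, rays, nodes)
    gray = map_coordinates(volume.values, coords, order=1, mode="nearest")
    cost = np.abs(float(reference_value) - gray)
    if np.any(in_bounds):
        penalty = 2.0 * (cost[in_bounds].max() + 1.0)
    else:
        penalty = 1.0
    cost = np.where(in_bounds, cost, penalty)
    return NodeGrid(
        positions=positions,
        radii=radii,
        gray=gray,
        cost=cost,
        in_bounds=in_bounds,
        seed_world=seed_world,
        reference_value=float(reference_value),
    )


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def node_excess(cost: np.ndarray, theta: float) -> np.ndarray:
    """Per-node boundary vote: ``c - θ`` clamped to ``[-θ, +θ]``.

    The clamp bounds the influence of any single node (winsorized cost), so
    isolated extreme outliers such as needle voxels cannot dominate the
    cumulative objective of a whole ray.
    """
    return np.clip(np.asarray(cost, dtype=float) - theta, -theta, theta)


def derive_cost_threshold(grid: NodeGrid) -> float:
    """Data-derived classification margin θ.

    Half the absolute contrast between the reference value and a background
    estimate — the median gray value over the outermost in-bounds node of
    each ray.  Floored at 1 intensity unit so a degenerate (contrast-free)
    volume still yields a well-defined network.
    """
    R, N = grid.n_rays, grid.n_nodes
    outer = np.full(R, np.nan)
    for r in range(R):
        idx = np.nonzero(grid.in_bounds[r])[0]
        if len(idx):
            outer[r] = grid.gray[r, idx[-1]]
    outer = outer[np.isfinite(outer)]
    if len(outer) == 0:
        return 1.0
    background = float(np.median(outer))
    return max(abs(grid.reference_value - background) / 2.0, 1.0)


def build_flow_network(
    grid: NodeGrid, template: RayTemplate, params: GraphCutParams
) -> FlowNetwork:
    """Assemble intra-, inter- and terminal edges into an s-t network."""
    R, N = grid.n_rays, grid.n_nodes
    if R != template.n_rays:
        raise StructuralError(
            f"grid has {R} rays but template has {template.n_rays}"
        )
    if params.delta_r >= N:
        raise InvalidParameterError("delta_r must be smaller than nodes per ray")

    theta = (
        params.cost_threshold
        if params.cost_threshold is not None
        else derive_cost_threshold(grid)
    )
    if np.any(grid.cost < 0):
        raise StructuralError("negative node cost")
    # per-node excess over the margin, clamped and quantized to capacities
    w = np.round(node_excess(grid.cost, theta) * params.cost_scale).astype(np.int64)

    node_ids = np.arange(R * N, dtype=np.int64).reshape(R, N)
    source = R * N
    sink = R * N + 1

    sink_total = int(w[w > 0].sum())
    source_slack = int(-w[w < 0].sum())
    infinity = sink_total + 1
    if infinity > _INT32_MAX or source_slack > _INT32_MAX:
        raise SolverError(
            f"total capacity {max(infinity, source_slack)} exceeds the "
            "32-bit solver limit; reduce cost_scale"
        )

    us, vs, caps = [], [], []

    # one terminal edge per node, by the sign of its excess cost
    rr, jj = np.nonzero(w > 0)
    us.append(node_ids[rr, jj])
    vs.append(np.full(rr.shape, sink, dtype=np.int64))
    caps.append(w[rr, jj])
    rr, jj = np.nonzero(w < 0)
    us.append(np.full(rr.shape, source, dtype=np.int64))
    vs.append(node_ids[rr, jj])
    caps.append(-w[rr, jj])
    # node 0 of every ray: forced foreground
    us.append(np.full(R, source, dtype=np.int64))
    vs.append(node_ids[:, 0])
    caps.append(np.full(R, infinity, dtype=np.int64))

    # intra-edges j -> j-1
    intra_u = node_ids[:, 1:].ravel()
    intra_v = node_ids[:, :-1].ravel()
    us.append(intra_u)
    vs.append(intra_v)
    caps.append(np.full(intra_u.shape, infinity, dtype=np.int64))

    # inter-edges along the template triangulation
    pairs = template.adjacency_pairs()
    j = np.arange(N)
    tj = np.maximum(0, j - params.delta_r)
    a = pairs[:, 0][:, None]
    b = pairs[:, 1][:, None]
    for src_ray, dst_ray in ((a, b), (b, a)):
        eu = node_ids[src_ray, j[None, :]].ravel()
        ev = node_ids[dst_ray, tj[None, :]].ravel()
        us.append(eu)
        vs.append(ev)
        caps.append(np.full(eu.shape, infinity, dtype=np.int64))

    return FlowNetwork(
        rays=R,
        nodes=N,
        infinity=infinity,
        cost_scale=params.cost_scale,
        cost_threshold=float(theta),
        edges_u=np.concatenate(us),
        edges_v=np.concatenate(vs),
        edges_cap=np.concatenate(caps),
        excess_int=np.cumsum(w, axis=1),
        source_slack=source_slack,
        positions=grid.positions,
        seed_world=grid.seed_world,
        adjacency_pairs=pairs,
        delta_r=params.delta_r,
    )


# ---------------------------------------------------------------------------
# min-cut solve
# ---------------------------------------------------------------------------

def solve_min_cut(network: FlowNetwork) -> CutResult:
    """Solve the s-t max-flow and read off the per-ray cut indices.

    The source side is the *maximal* minimum cut: the complement of the set
    of nodes that can reach the sink in the residual network.  The cut index
    of a ray is the largest node index on the source side; the construction
    guarantees the source-side nodes of each ray form a contiguous prefix.

    Raises
    ------
    InfeasibleConstraintError
        If the minimum cut severs an ∞ edge (conflicting boundary
        constraints under the Δr bound).
    SolverError
        On capacity overflow or a malformed network.
    """
    n = network.n_graph_nodes
    cap = csr_matrix(
        (network.edges_cap, (network.edges_u, network.edges_v)),
        shape=(n, n),
        dtype=np.int64,
    )
    cap.sum_duplicates()
    # parallel ∞ edges may have been merged by summation; clamp back
    np.minimum(cap.data, network.infinity, out=cap.data)
    if cap.data.max(initial=0) > _INT32_MAX:
        raise SolverError("edge capacity exceeds the 32-bit solver limit")
    sink_in = int(cap[:, network.sink].sum())
    if sink_in > _INT32_MAX:
        raise SolverError(
            "total sink capacity exceeds the 32-bit solver limit; reduce cost_scale"
        )
    cap32 = cap.astype(np.int32)
    res = maximum_flow(cap32, network.source, network.sink)
    if res.flow_value >= network.infinity:
        raise InfeasibleConstraintError(
            "minimum cut severs an infinite edge: boundary constraints are "
            f"mutually incompatible under delta_r={network.delta_r}"
        )

    residual = cap32 - res.flow
    residual.data[residual.data < 0] = 0
    residual.eliminate_zeros()
    # nodes that can still reach t: BFS from t over reversed residual arcs
    order = breadth_first_order(
        residual.T.tocsr(), network.sink, directed=True, return_predecessors=False
    )
    reaches_sink = np.zeros(n, dtype=bool)
    reaches_sink[order] = True
    if reaches_sink[network.source]:
        raise SolverError("augmenting path remains after max-flow")
    source_side = ~reaches_sink
    node_side = source_side[: network.rays * network.nodes].reshape(
        network.rays, network.nodes
    )

    prefix_len = node_side.sum(axis=1)
    expected = np.zeros_like(node_side)
    for r in range(network.rays):
        expected[r, : prefix_len[r]] = True
    if not np.array_equal(expected, node_side):
        raise SolverError("source side is not a per-ray prefix")
    if np.any(prefix_len == 0):
        raise SolverError("node 0 left the source side despite its forced link")

    cut_index = (prefix_len - 1).astype(np.int64)
    d = np.abs(
        cut_index[network.adjacency_pairs[:, 0]]
        - cut_index[network.adjacency_pairs[:, 1]]
    )
    feasible = bool(np.all(d <= network.delta_r)) if len(d) else True
    boundary_points = network.positions[np.arange(network.rays), cut_index]
    boundary_cost = (
        float(network.excess_int[np.arange(network.rays), cut_index].sum())
        / network.cost_scale
    )
    return CutResult(
        cut_index=cut_index,
        flow_value=float(res.flow_value) / network.cost_scale,
        boundary_points=boundary_points,
        boundary_cost=boundary_cost,
        delta_r=network.delta_r,
        feasible=feasible,
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_cut(
    grid: NodeGrid,
    template: RayTemplate,
    delta_r: int,
    cost_threshold: float | None = None,
) -> CutResult:
    """Exhaustively find the Δr-feasible cut minimizing the excess cost.

    Independent test oracle for :func:`solve_min_cut`: minimizes the same
    functional ``Σ_r Σ_{j<=k_r} (c(r,j) - θ)`` by depth-first
    branch-and-bound over per-ray cut indices, pruned with per-ray minimum
    completions.  Ties resolve to the lexicographically smallest index
    vector.  Guarded to small instances (≤ 12 rays).
    """
    costs = grid.cost
    R = costs.shape[0]
    if R != template.n_rays:
        raise StructuralError("grid/template ray count mismatch")
    if R > 12:
        raise SizeGuardError(f"brute force limited to 12 rays, got {R}")
    theta = (
        cost_threshold if cost_threshold is not None else derive_cost_threshold(grid)
    )
    excess = np.cumsum(node_excess(costs, theta), axis=1)
    cut, total = _exact_min_boundary(excess, template.adjacency_pairs(), delta_r)
    boundary_points = grid.positions[np.arange(R), cut]
    return CutResult(
        cut_index=cut,
        flow_value=float("nan"),
        boundary_points=boundary_points,
        boundary_cost=float(total),
        delta_r=int(delta_r),
        feasible=True,
    )


def _exact_min_boundary(
    costs: np.ndarray, pairs: np.ndarray, delta_r: int
) -> tuple[np.ndarray, float]:
    """Exact minimizer of Σ_r costs[r, k_r] s.t. |k_r - k_r'| <= delta_r on pairs.

    ``costs`` is any per-ray, per-level objective matrix (here: cumulative
    excess costs); entries may be negative.
    """
    costs = np.asarray(costs, dtype=np.float64)
    R, N = costs.shape
    if delta_r < 0:
        raise InvalidParameterError("delta_r must be non-negative")
    prev_nbrs: list[list[int]] = [[] for _ in range(R)]
    for a, b in pairs:
        a, b = int(a), int(b)
        lo, hi = (a, b) if a < b else (b, a)
        prev_nbrs[hi].append(lo)

    # feasible incumbent: best uniform cut level
    col = costs.sum(axis=0)
    k0 = int(np.argmin(col))
    best_cost = float(col[k0])
    best_vec = np.full(R, k0, dtype=np.int64)

    ray_min = costs.min(axis=1)
    suffix = np.zeros(R + 1)
    suffix[:R] = np.cumsum(ray_min[::-1])[::-1]

    assign = np.zeros(R, dtype=np.int64)

    def dfs(r: int, acc: float) -> None:
        nonlocal best_cost, best_vec
        if r == R:
            if acc < best_cost or (
                acc == best_cost and tuple(assign) < tuple(best_vec)
            ):
                best_cost = acc
                best_vec = assign.copy()
            return
        lo, hi = 0, N - 1
        for nb in prev_nbrs[r]:
            lo = max(lo, int(assign[nb]) - delta_r)
            hi = min(hi, int(assign[nb]) + delta_r)
        if lo > hi:
            return
        for k in range(lo, hi + 1):
            c = acc + costs[r, k]
            if c + suffix[r + 1] > best_cost:
                continue
            assign[r] = k
            dfs(r + 1, c)

    dfs(0, 0.0)
    return best_vec, best_cost


# ---------------------------------------------------------------------------
# boundary constraints
# ---------------------------------------------------------------------------

def apply_boundary_constraints(
    network: FlowNetwork,
    grid: NodeGrid,
    constraints: list[BoundaryConstraint],
) -> FlowNetwork:
    """Pin the cut to user-placed border points.

    For the ray nearest each constraint point, all nodes at radius up to the
    constraint's receive ∞ source links and the next node an ∞ sink link,
    which fixes that ray's cut index; the Δr inter-edges propagate the
    influence to neighboring rays.  Conflicting constraints surface as an
    :class:`InfeasibleConstraintError` at solve time.
    """
    if not constraints:
        return network
    INF = network.infinity
    us: list[int] = []
    vs: list[int] = []
    for con in constraints:
        p = np.asarray(con.point, dtype=float)
        radius = float(np.linalg.norm(p - grid.seed_world))
        max_reach = float(grid.radii[-1]) + 0.5 * float(
            grid.radii[1] - grid.radii[0] if len(grid.radii) > 1 else grid.radii[0]
        )
        if radius > max_reach:
            raise UnreachableConstraintError(
                f"constraint at {tuple(p)} lies {radius:.1f} mm from the seed, "
                f"beyond the ray length {grid.radii[-1]:.1f} mm"
            )
        d2 = np.sum((grid.positions - p[None, None, :]) ** 2, axis=2)
        r, j = np.unravel_index(int(np.argmin(d2)), d2.shape)
        for jj in range(j + 1):
            us.append(network.source)
            vs.append(network.node_id(r, jj))
        if j + 1 < network.nodes:
            us.append(network.node_id(r, j + 1))
            vs.append(network.sink)
    caps = np.full(len(us), INF, dtype=np.int64)
    out = network.with_extra_edges(us, vs, caps)
    out.n_constraints = network.n_constraints + len(constraints)
    return out
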