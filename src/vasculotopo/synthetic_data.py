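"""Synthetic vascular phantoms and reference random graphs.

Real cerebrovascular light-sheet data is not bundled with this package, so
every downstream stage is exercised against generated inputs with known
ground truth:

* **Tube phantoms** — spatial networks of cylindrical tubes on an anisotropic
  voxel grid. The *healthy-like* preset emulates a hierarchical
  arterio-venous branching scheme interwoven with a capillary mesh (bifurcating
  trees with Murray-law radius tapering plus nearest-neighbour capillary
  closures); roughly 11% of its nodes are vessel endpoints (degree k = 1), the
  share reported for healthy murine brain vasculature. The *tumor-like* preset
  is fragmented and endpoint-rich (~20% endpoints, matching full glioblastoma
  xenograft networks): capillary closures are sparser, random segments are
  deleted, blind-ended sprouts are inserted, and segments meander more.
* **Pure graph generators** — Erdős–Rényi G(n, m) null models, the
  deterministic Ravasz–Barabási hierarchical network (a C(k) ~ 1/k oracle),
  and configuration-model graphs with power-law degree sequences (oracles for
  degree-exponent recovery).

Every generator is a pure function of its spec and seed; there is no global
random state.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .volume_preprocess import DEFAULT_SPACING_UM, BinaryVolume


class InfeasibleDensityError(ValueError):
    """Requested vessel density cannot be realised in the given domain."""


@dataclass(frozen=True)
class NoiseSpec:
    """Segmentation-artefact model applied by :func:`corrupt`.

    ``speck_count`` isolated small foreground bunches (below the 6-um-sphere
    cleanup threshold), ``hole_count`` enclosed interior cavities ("hollow"
    vessels), and surface-voxel flips with probability ``boundary_fuzz_prob``.
    """

    speck_count: int = 0
    speck_radius_um: float = 4.0
    hole_count: int = 0
    boundary_fuzz_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.speck_count < 0 or self.hole_count < 0:
            raise ValueError("noise counts must be >= 0")
        if not 0.0 <= self.boundary_fuzz_prob <= 1.0:
            raise ValueError("boundary_fuzz_prob must be in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of a tube phantom.

    Sizes are physical micrometres in (z, y, x) axis order, matching the voxel
    grid. Defaults reflect a desk-scale tissue block at the acquisition grid
    of 3.25 x 3.25 um in-plane and 5 um between planes.
    """

    domain_size_um: tuple = (500.0, 650.0, 650.0)
    voxel_spacing_um: tuple = DEFAULT_SPACING_UM
    mode: str = "healthy_like"
    n_seed_trees: int = 4
    bifurcation_levels: int = 4
    capillary_mesh_density: float = 980.0  # total length per volume, mm/mm^3
    radius_range_um: tuple = (4.0, 11.0)
    endpoint_fraction_target: float = 0.11
    endpoint_tolerance: float = 0.05
    tortuosity_amplitude: float = 0.04
    edge_deletion_fraction: float = 0.0
    loop_insertion_fraction: float = 0.0  # triangle closures (angiogenic loops)
    sprout_length_um: tuple = (30.0, 70.0)
    closure_max_um: float = 120.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in {"healthy_like", "tumor_like", "custom"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(s <= 0 for s in self.domain_size_um) or any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError("physical sizes must be positive")
        if not 0.0 <= self.endpoint_fraction_target <= 1.0:
            raise ValueError("endpoint_fraction_target must be in [0, 1]")
        if self.radius_range_um[0] <= 0 or self.radius_range_um[1] < self.radius_range_um[0]:
            raise ValueError("invalid radius range")
        if self.tortuosity_amplitude < 0:
            raise ValueError("tortuosity_amplitude must be >= 0")

    @property
    def volume_mm3(self) -> float:
        return float(np.prod(self.domain_size_um)) * 1e-9

    @property
    def grid_shape(self) -> tuple:
        return tuple(
            int(math.ceil(d / s)) for d, s in zip(self.domain_size_um, self.voxel_spacing_um)
        )


def healthy_like(seed: int = 0, **overrides) -> PhantomSpec:
    """Preset emulating healthy cerebral microvasculature signatures."""
    return PhantomSpec(mode="healthy_like", seed=seed, **overrides)


def tumor_like(seed: int = 0, **overrides) -> PhantomSpec:
    """Preset emulating full glioblastoma xenograft network signatures:
    sparser, endpoint-rich, more tortuous, fragmented mesh."""
    defaults = dict(
        mode="tumor_like",
        n_seed_trees=2,
        bifurcation_levels=3,
        capillary_mesh_density=730.0,
        radius_range_um=(4.0, 9.0),
        endpoint_fraction_target=0.20,
        tortuosity_amplitude=0.10,
        edge_deletion_fraction=0.08,
        loop_insertion_fraction=0.12,
        sprout_length_um=(18.0, 42.0),
        closure_max_um=75.0,
        seed=seed,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@dataclass
class GroundTruthGraph:
    """True topology and geometry of a generated phantom.

    Wraps an undirected spatial multigraph whose node attribute ``pos_um``
    gives physical coordinates and whose edge attributes carry the centerline
    ``polyline`` (N x 3, um) and tube ``radius_um``.
    """

    graph: nx.MultiGraph
    spec: PhantomSpec

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_multiset(self):
        return sorted(d for _, d in self.graph.degree())

    def endpoint_fraction(self) -> float:
        degs = [d for _, d in self.graph.degree()]
        return float(sum(d == 1 for d in degs) / len(degs)) if degs else 0.0

    def segment_lengths_um(self) -> np.ndarray:
        out = []
        for _, _, d in self.graph.edges(data=True):
            pts = np.asarray(d["polyline"], float)
            out.append(float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()))
        return np.asarray(out)

    def tortuosities(self) -> np.ndarray:
        out = []
        for _, _, d in self.graph.edges(data=True):
            pts = np.asarray(d["polyline"], float)
            arc = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
            chord = float(np.linalg.norm(pts[-1] - pts[0]))
            if chord > 0:
                out.append(arc / chord)
        return np.asarray(out)

    def total_length_um(self) -> float:
        return float(self.segment_lengths_um().sum())

    def length_density(self) -> float:
        """Total centerline length per volume in mm/mm^3."""
        return self.total_length_um() * 1e-3 / self.spec.volume_mm3

    def validate(self) -> None:
        for n, deg in self.graph.degree():
            assert deg == len(list(self.graph.edges(n, keys=True))) or deg >= 0
        for u, v, d in self.graph.edges(data=True):
            pts = np.asarray(d["polyline"], float)
            pu = self.graph.nodes[u]["pos_um"]
            pv = self.graph.nodes[v]["pos_um"]
            ok_fwd = np.allclose(pts[0], pu) and np.allclose(pts[-1], pv)
            ok_rev = np.allclose(pts[0], pv) and np.allclose(pts[-1], pu)
            assert ok_fwd or ok_rev, "polyline must join its node positions"
            assert d["radius_um"] >= min(self.spec.voxel_spacing_um) / 2


# ---------------------------------------------------------------------------
# tube phantom generation
# ---------------------------------------------------------------------------

def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _perp(d, rng):
    """A unit vector perpendicular to d with random azimuth."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    a = _unit(np.cross(d, ref))
    b = _unit(np.cross(d, a))
    phi = rng.uniform(0, 2 * np.pi)
    return math.cos(phi) * a + math.sin(phi) * b


def _polyline(p, q, amplitude_frac, rng, step_um=3.0):
    """Centerline from p to q: straight chord plus an optional single-period
    sinusoidal lateral displacement (the tortuosity perturbation)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    chord = float(np.linalg.norm(q - p))
    n = max(2, int(math.ceil(chord / step_um)) + 1)
    t = np.linspace(0.0, 1.0, n)
    pts = p[None, :] + t[:, None] * (q - p)[None, :]
    if amplitude_frac > 0 and chord > 0 and n > 2:
        d = _unit(q - p)
        lateral = _perp(d, rng)
        amp = amplitude_frac * chord
        pts = pts + np.sin(np.pi * t)[:, None] * amp * lateral[None, :]
        pts[0], pts[-1] = p, q
    return pts


class _Builder:
    def __init__(self, spec: PhantomSpec, rng):
        self.spec = spec
        self.rng = rng
        self.G = nx.MultiGraph()
        self._next = 0
        self.total_length_um = 0.0

    def add_node(self, pos):
        nid = self._next
        self._next += 1
        self.G.add_node(nid, pos_um=np.asarray(pos, float))
        return nid

    def connect(self, u, v, radius, amplitude=None):
        amp = self.spec.tortuosity_amplitude if amplitude is None else amplitude
        pts = _polyline(self.G.nodes[u]["pos_um"], self.G.nodes[v]["pos_um"], amp, self.rng)
        self.G.add_edge(u, v, polyline=pts, radius_um=float(radius))
        self.total_length_um += float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def clamp(self, pos, margin):
        lo = np.full(3, margin, float)
        hi = np.asarray(self.spec.domain_size_um, float) - margin
        return np.clip(pos, lo, hi)


def _grow_tree(b: _Builder, root_pos, direction, levels, trunk_len, r0, r_min, branch_angle_deg=38.0):
    """Recursive bifurcating tree with Murray-law tapering r -> r * 2^(-1/3)."""
    margin = 3 * r0
    root = b.add_node(b.clamp(root_pos, margin))
    leaves = []

    def grow(parent, direction, length, radius, level):
        d = _unit(direction)
        pos = b.clamp(b.G.nodes[parent]["pos_um"] + d * length, margin)
        child = b.add_node(pos)
        b.connect(parent, child, radius)
        if level == 0:
            leaves.append(child)
            return
        r_child = max(radius * 2.0 ** (-1.0 / 3.0), r_min)
        perp = _perp(d, b.rng)
        ang = math.radians(branch_angle_deg + b.rng.uniform(-6, 6))
        for s in (1.0, -1.0):
            nd = math.cos(ang) * d + s * math.sin(ang) * perp
            grow(child, nd, length * 0.78, r_child, level - 1)

    grow(root, direction, trunk_len, r0, levels)
    return root, leaves


def _tree_scaffold(b: _Builder, spec: PhantomSpec):
    """Place the seed trees with roots on the domain boundary, aimed inward."""
    dom = np.asarray(spec.domain_size_um, float)
    trunk = float(dom.min()) / 3.2
    r0 = spec.radius_range_um[1]
    for _ in range(spec.n_seed_trees):
        face = b.rng.integers(0, 6)
        pos = b.rng.uniform(0.15, 0.85, 3) * dom
        pos[face // 2] = 0.0 if face % 2 == 0 else dom[face // 2]
        inward = (dom / 2 - pos) + b.rng.normal(0, dom.min() / 6, 3)
        _grow_tree(
            b, pos, inward, spec.bifurcation_levels, trunk, r0, spec.radius_range_um[0]
        )


def _endpoints(G):
    return [n for n, d in G.degree() if d == 1]


def _nearest_other(G, n, candidates, min_um=15.0, max_um=120.0):
    p = G.nodes[n]["pos_um"]
    neighbors = set(G.neighbors(n))
    cand = [c for c in candidates if c != n and c not in neighbors]
    if not cand:
        return None
    pos = np.array([G.nodes[c]["pos_um"] for c in cand])
    dist = np.linalg.norm(pos - p, axis=1)
    ok = (dist >= min_um) & (dist <= max_um)
    if not ok.any():
        return None
    return cand[int(np.argmin(np.where(ok, dist, np.inf)))]


def generate_network(spec: PhantomSpec) -> GroundTruthGraph:
    """Generate the ground-truth spatial graph of a tube phantom.

    ``custom`` mode builds the bare bifurcating tree(s) only (no capillary
    mesh, no calibration) — a combinatorial oracle. The healthy/tumor presets
    add a capillary mesh until the target length density is met, apply the
    preset's degradations, and finally calibrate the endpoint (k = 1) node
    fraction to ``endpoint_fraction_target`` by closing endpoint pairs into
    capillary loops (fraction too high) or inserting blind sprouts (too low).

    Deterministic given ``spec`` (including its seed). Raises
    :class:`InfeasibleDensityError` when the requested mesh density cannot fit
    the domain at the given calibres.
    """
    rng = np.random.default_rng(spec.seed)
    b = _Builder(spec, rng)

    # feasibility: implied fractional vessel volume must stay clearly below 1
    r_mean = float(np.mean(spec.radius_range_um))
    implied_fvv = spec.capillary_mesh_density * np.pi * (r_mean * 1e-3) ** 2
    if spec.mode != "custom" and implied_fvv > 0.45:
        raise InfeasibleDensityError(
            f"mesh density {spec.capillary_mesh_density} mm/mm^3 at mean radius "
            f"{r_mean} um implies fVV ~ {implied_fvv:.2f}"
        )

    _tree_scaffold(b, spec)
    G = b.G
    if spec.mode == "custom":
        return GroundTruthGraph(G, spec)

    r_cap = spec.radius_range_um[0]
    target_len = spec.capillary_mesh_density * spec.volume_mm3 * 1e3  # um
    dom = np.asarray(spec.domain_size_um, float)

    # capillary mesh: preferentially close endpoint pairs, otherwise sprout
    # short capillaries from random nodes, until the length budget is used
    s_lo, s_hi = spec.sprout_length_um
    guard = 0
    while b.total_length_um < target_len and guard < 200000:
        guard += 1
        eps = _endpoints(G)
        frac = len(eps) / max(G.number_of_nodes(), 1)
        nodes = list(G.nodes)
        if eps and frac > spec.endpoint_fraction_target and rng.random() < 0.7:
            n = eps[rng.integers(0, len(eps))]
            other = _nearest_other(G, n, eps, max_um=spec.closure_max_um) or _nearest_other(
                G, n, nodes, max_um=spec.closure_max_um
            )
            if other is not None:
                b.connect(n, other, r_cap)
                continue
        # sprout a new capillary from a random node
        n = nodes[rng.integers(0, len(nodes))]
        d = _unit(rng.normal(size=3))
        pos = b.clamp(G.nodes[n]["pos_um"] + d * rng.uniform(s_lo, s_hi), 3 * r_cap)
        if np.linalg.norm(pos - G.nodes[n]["pos_um"]) < 10:
            continue
        m = b.add_node(pos)
        b.connect(n, m, r_cap)

    if spec.mode == "tumor_like" and spec.edge_deletion_fraction > 0:
        edges = list(G.edges(keys=True))
        n_del = int(spec.edge_deletion_fraction * len(edges))
        for i in rng.choice(len(edges), size=n_del, replace=False):
            G.remove_edge(*edges[i])
        G.remove_nodes_from([n for n, d in G.degree() if d == 0])

    # angiogenic loop closures: link two neighbours of a common node,
    # producing the local three-edge vessel loops that raise clustering
    if spec.loop_insertion_fraction > 0:
        n_loops = int(spec.loop_insertion_fraction * G.number_of_nodes())
        for _ in range(20 * n_loops):
            if n_loops <= 0:
                break
            nodes = list(G.nodes)
            n = nodes[rng.integers(0, len(nodes))]
            nbrs = list(set(G.neighbors(n)) - {n})
            if len(nbrs) < 2:
                continue
            u, w = rng.choice(len(nbrs), size=2, replace=False)
            u, w = nbrs[u], nbrs[w]
            if G.has_edge(u, w):
                continue
            sep = np.linalg.norm(G.nodes[u]["pos_um"] - G.nodes[w]["pos_um"])
            if sep < 10 or sep > spec.closure_max_um:
                continue
            b.connect(u, w, r_cap)
            n_loops -= 1

    # endpoint-fraction calibration
    for _ in range(5 * G.number_of_nodes()):
        frac = len(_endpoints(G)) / G.number_of_nodes()
        if abs(frac - spec.endpoint_fraction_target) <= spec.endpoint_tolerance / 2:
            break
        if frac > spec.endpoint_fraction_target:
            eps = _endpoints(G)
            n = eps[rng.integers(0, len(eps))]
            other = _nearest_other(G, n, eps, max_um=spec.closure_max_um) or _nearest_other(
                G, n, list(G.nodes), max_um=spec.closure_max_um
            )
            if other is None:
                break
            b.connect(n, other, r_cap)
        else:
            nodes = list(G.nodes)
            n = nodes[rng.integers(0, len(nodes))]
            d = _unit(rng.normal(size=3))
            pos = b.clamp(G.nodes[n]["pos_um"] + d * rng.uniform(20, 45), 3 * r_cap)
            m = b.add_node(pos)
            b.connect(n, m, r_cap, amplitude=0.0)

    return GroundTruthGraph(G, spec)


# ---------------------------------------------------------------------------
# voxelization and corruption
# ---------------------------------------------------------------------------

def _stamp_ball(grid, center_um, r_um, spacing):
    lo = np.maximum(0, np.floor((center_um - r_um) / spacing)).astype(int)
    hi = np.minimum(np.array(grid.shape) - 1, np.ceil((center_um + r_um) / spacing)).astype(int)
    if np.any(lo > hi):
        return
    sl = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
    axes = np.ogrid[sl]
    d2 = sum(((ax * s - c) ** 2 for ax, s, c in zip(axes, spacing, center_um)))
    grid[sl] |= d2 <= r_um**2


def _box_polyline_dist2(lo, box_shape, poly, reach_um, spacing):
    """Squared distance from voxel centers of a box to a polyline.

    Box voxels start at index ``lo``; per polyline segment only the sub-box
    within ``reach_um`` of the segment is updated, which keeps the cost
    proportional to tube volume rather than bounding-box volume.
    """
    d2 = np.full(box_shape, np.inf)
    axes = [np.arange(l, l + n) * s for l, n, s in zip(lo, box_shape, spacing)]
    for i in range(len(poly) - 1):
        a, b = poly[i], poly[i + 1]
        slo = np.floor((np.minimum(a, b) - reach_um) / spacing).astype(int) - lo
        shi = np.ceil((np.maximum(a, b) + reach_um) / spacing).astype(int) - lo
        slo = np.maximum(slo, 0)
        shi = np.minimum(shi, np.array(box_shape) - 1)
        if np.any(slo > shi):
            continue
        sub = tuple(slice(l, h + 1) for l, h in zip(slo, shi))
        zz = axes[0][sub[0]][:, None, None]
        yy = axes[1][sub[1]][None, :, None]
        xx = axes[2][sub[2]][None, None, :]
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            cand = (zz - a[0]) ** 2 + (yy - a[1]) ** 2 + (xx - a[2]) ** 2
        else:
            t = ((zz - a[0]) * ab[0] + (yy - a[1]) * ab[1] + (xx - a[2]) * ab[2]) / denom
            np.clip(t, 0.0, 1.0, out=t)
            cand = (
                (zz - a[0] - t * ab[0]) ** 2
                + (yy - a[1] - t * ab[1]) ** 2
                + (xx - a[2] - t * ab[2]) ** 2
            )
        np.minimum(d2[sub], cand, out=d2[sub])
    return d2


def _polyline_dist2(pts, poly):
    """Squared distance from each point in ``pts`` (n, 3) to the polyline."""
    d2 = np.full(len(pts), np.inf)
    for i in range(len(poly) - 1):
        a, b = poly[i], poly[i + 1]
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            cand = ((pts - a) ** 2).sum(-1)
        else:
            t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
            nearest = a + t[:, None] * ab
            cand = ((pts - nearest) ** 2).sum(-1)
        np.minimum(d2, cand, out=d2)
    return d2


def _stamp_tube(grid, poly, r_um, spacing):
    """Mark voxels at least half-covered by the tube swept along ``poly``.

    Coverage is approximated with 2x2x2 subvoxel quadrature (voxel center
    +/- spacing/4, majority vote), applied only within the borderline shell —
    far less grid-alignment bias than a center-point rule when the radius is
    comparable to the voxel pitch.
    """
    margin = float(np.linalg.norm(spacing)) / 4.0  # subvoxel point reach
    lo_um = poly.min(axis=0) - r_um - spacing
    hi_um = poly.max(axis=0) + r_um + spacing
    lo = np.maximum(0, np.floor(lo_um / spacing)).astype(int)
    hi = np.minimum(np.array(grid.shape) - 1, np.ceil(hi_um / spacing)).astype(int)
    if np.any(lo > hi):
        return
    sl = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
    box_shape = tuple(h - l + 1 for l, h in zip(lo, hi))
    d2c = _box_polyline_dist2(lo, box_shape, poly, r_um + 2 * margin, spacing)
    sure = d2c <= max(r_um - margin, 0.0) ** 2
    border = (d2c <= (r_um + margin) ** 2) & ~sure
    out = sure
    if border.any():
        bidx = np.argwhere(border)
        bpts = (bidx + lo) * spacing
        offsets = np.array(
            [[dz, dy, dx] for dz in (-0.25, 0.25) for dy in (-0.25, 0.25) for dx in (-0.25, 0.25)]
        ) * spacing
        stacked = (bpts[None, :, :] + offsets[:, None, :]).reshape(-1, 3)
        inside = (_polyline_dist2(stacked, poly) <= r_um**2).reshape(8, -1)
        out = sure.copy()
        out[tuple(bidx.T)] = inside.sum(axis=0) >= 4
    grid[sl] |= out


def voxelize(truth: GroundTruthGraph, spacing_um=None) -> BinaryVolume:
    """Rasterise the tube network onto an anisotropic voxel grid.

    The foreground is the union of spheres of each segment's radius swept
    along its centerline (overlapping tubes simply merge, as touching vessels
    do in real segmentations); every voxel traversed by a centerline is
    guaranteed foreground. Segments whose radius falls below half the largest
    spacing component are flagged ``under_resolved`` and trigger a warning.
    """
    spec = truth.spec
    spacing = np.asarray(spacing_um if spacing_um is not None else spec.voxel_spacing_um, float)
    shape = tuple(int(math.ceil(d / s)) for d, s in zip(spec.domain_size_um, spacing))
    grid = np.zeros(shape, bool)
    guard = float(spacing.max()) / 2.0
    n_flagged = 0
    for u, v, k, d in truth.graph.edges(keys=True, data=True):
        r = float(d["radius_um"])
        if r < guard:
            d["under_resolved"] = True
            n_flagged += 1
        pts = np.asarray(d["polyline"], float)
        _stamp_tube(grid, pts, r, spacing)
        # guarantee every voxel traversed by the centerline is foreground
        step = float(spacing.min()) / 2.0
        for i in range(len(pts) - 1):
            seg = float(np.linalg.norm(pts[i + 1] - pts[i]))
            n = max(2, int(math.ceil(seg / step)) + 1)
            samples = pts[i] + np.linspace(0.0, 1.0, n)[:, None] * (pts[i + 1] - pts[i])
            vox = np.clip(
                np.round(samples / spacing).astype(int), 0, np.array(shape) - 1
            )
            grid[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    if n_flagged:
        warnings.warn(
            f"{n_flagged} segment(s) thinner than the resolvability guard "
            f"({guard:.2f} um); flagged under_resolved"
        )
    return BinaryVolume(grid, spacing)


def corrupt(vol: BinaryVolume, noise: NoiseSpec) -> BinaryVolume:
    """Apply segmentation-like artefacts to a clean volume (see NoiseSpec).

    Specks are placed disjointly from the vasculature and from each other;
    holes are carved strictly inside the foreground so they remain enclosed
    cavities. Deterministic given ``noise.seed``.
    """
    from scipy import ndimage

    rng = np.random.default_rng(noise.seed)
    grid = vol.grid.copy()
    spacing = vol.spacing_um

    if noise.speck_count > 0:
        clearance = ndimage.binary_dilation(
            grid, ndimage.generate_binary_structure(3, 3),
            iterations=max(1, int(math.ceil(2 * noise.speck_radius_um / spacing.min()))),
        )
        free = np.argwhere(~clearance)
        placed = 0
        attempts = 0
        while placed < noise.speck_count and attempts < 50 * noise.speck_count and len(free):
            attempts += 1
            v = free[rng.integers(0, len(free))]
            c = v * spacing
            probe = np.zeros_like(grid)
            _stamp_ball(probe, c, noise.speck_radius_um, spacing)
            near = ndimage.binary_dilation(probe, ndimage.generate_binary_structure(3, 3))
            if (near & grid).any():
                continue
            grid |= probe
            placed += 1
        if placed < noise.speck_count:
            warnings.warn(f"placed only {placed}/{noise.speck_count} specks")

    if noise.hole_count > 0:
        interior = ndimage.binary_erosion(grid, np.ones((3, 3, 3)))
        iv = np.argwhere(interior)
        if len(iv):
            take = rng.choice(len(iv), size=min(noise.hole_count, len(iv)), replace=False)
            for i in np.atleast_1d(take):
                z, y, x = iv[i]
                grid[z, y, x] = False
        else:
            warnings.warn("no strict interior voxels; holes not carved")

    if noise.boundary_fuzz_prob > 0:
        s6 = ndimage.generate_binary_structure(3, 1)
        surface = grid & ~ndimage.binary_erosion(grid, s6)
        halo = ndimage.binary_dilation(grid, s6) & ~grid
        flips = (surface | halo) & (rng.random(grid.shape) < noise.boundary_fuzz_prob)
        grid ^= flips

    return vol.with_grid(grid)


# ---------------------------------------------------------------------------
# reference graph generators
# ---------------------------------------------------------------------------

def min_intersegment_clearance(truth: GroundTruthGraph) -> float:
    """Smallest surface-to-surface gap between non-adjacent segments (um).

    Edges sharing a node are skipped (they legitimately meet there). The
    exact skeleton round-trip contract requires this clearance to be at
    least ~4 voxels; phantoms below that may merge tubes on voxelization.
    """
    from scipy.spatial import cKDTree

    edges = []
    for u, v, k, d in truth.graph.edges(keys=True, data=True):
        pts = np.asarray(d["polyline"], float)
        edges.append(({u, v}, pts, float(d["radius_um"])))
    best = np.inf
    for i in range(len(edges)):
        nodes_i, pts_i, r_i = edges[i]
        tree = cKDTree(pts_i)
        for j in range(i + 1, len(edges)):
            nodes_j, pts_j, r_j = edges[j]
            if nodes_i & nodes_j:
                continue
            gap = tree.query(pts_j)[0].min() - r_i - r_j
            best = min(best, gap)
    return float(best)


def clearance_tree_phantom(
    seed: int = 0,
    min_clearance_voxels: float = 4.0,
    max_tries: int = 64,
    **spec_overrides,
) -> GroundTruthGraph:
    """A bifurcating-tree phantom that certifiably satisfies the exact
    round-trip preconditions (radius >= 1.5 voxels, stated clearance).

    Tree layout is random, so a given seed may place branches too close;
    seeds are advanced deterministically until the clearance holds.
    """
    defaults = dict(
        mode="custom",
        n_seed_trees=1,
        bifurcation_levels=3,
        domain_size_um=(600.0, 800.0, 800.0),
        radius_range_um=(8.0, 14.0),
    )
    defaults.update(spec_overrides)
    need = min_clearance_voxels * max(defaults.get("voxel_spacing_um", DEFAULT_SPACING_UM))
    for s in range(seed, seed + max_tries):
        truth = generate_network(PhantomSpec(seed=s, **defaults))
        if min_intersegment_clearance(truth) >= need:
            return truth
    raise RuntimeError("no clearance-compliant phantom found")


def generate_er_graph(n: int, m: int, seed: int = 0) -> nx.Graph:
    """Uniform simple G(n, m) random graph with exactly n nodes, m edges."""
    if m > n * (n - 1) // 2:
        raise ValueError("m exceeds the number of possible edges")
    return nx.gnm_random_graph(n, m, seed=seed)


def generate_hierarchical_graph(levels: int) -> nx.Graph:
    """Deterministic hierarchical (Ravasz–Barabási) network on 5**levels nodes.

    Starts from a 5-clique; at each iteration four replicas are attached and
    all their peripheral nodes are wired to the central hub. The clustering
    coefficient of this model scales as C(k) ~ 1/k, the hallmark value for
    hierarchical organisation.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    G = nx.complete_graph(5)
    center = 0
    peripheral = [1, 2, 3, 4]
    for _ in range(levels - 1):
        n = G.number_of_nodes()
        new_peripheral = []
        base = nx.Graph(G)
        for c in range(1, 5):
            offset = c * n
            G.add_edges_from((u + offset, v + offset) for u, v in base.edges)
            new_peripheral.extend(p + offset for p in peripheral)
        G.add_edges_from((p, center) for p in new_peripheral)
        peripheral = new_peripheral
    return G


def sample_powerlaw_degrees(
    n: int, gamma: float, rng, k_min: int = 5, k_max: int | None = None
) -> np.ndarray:
    """Degree sequence from a truncated discrete power law P(k) ~ k^-gamma on
    [k_min, k_max], with the sum adjusted to be even."""
    if k_max is None:
        k_max = max(k_min + 2, int(round(math.sqrt(n))))
    ks = np.arange(k_min, k_max + 1)
    p = ks.astype(float) ** (-gamma)
    p /= p.sum()
    degrees = rng.choice(ks, size=n, p=p)
    if degrees.sum() % 2:
        degrees[rng.integers(0, n)] += 1
    return degrees


def generate_powerlaw_graph(
    n: int, gamma: float, seed: int = 0, k_min: int = 5, k_max: int | None = None
) -> nx.MultiGraph:
    """Configuration-model multigraph with a truncated power-law degree
    sequence of exponent ``gamma`` (oracle for degree-exponent recovery)."""
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    if n < 100:
        raise ValueError("n must be >= 100")
    rng = np.random.default_rng(seed)
    degrees = sample_powerlaw_degrees(n, gamma, rng, k_min=k_min, k_max=k_max)
    return nx.configuration_model(degrees.tolist(), seed=seed)


def write_ground_truth(truth: GroundTruthGraph, graphml_path, csv_path=None) -> None:
    """Export ground truth as GraphML (x/y/z um node attrs; per-edge length
    and radius) and optionally a CSV edge table."""
    import pandas as pd

    g = nx.MultiGraph()
    for nid, d in truth.graph.nodes(data=True):
        z, y, x = (float(v) for v in d["pos_um"])
        g.add_node(nid, x=x, y=y, z=z)
    rows = []
    for u, v, k, d in truth.graph.edges(keys=True, data=True):
        pts = np.asarray(d["polyline"], float)
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        g.add_edge(u, v, key=k, length_um=length, radius_um=float(d["radius_um"]))
        rows.append({"node_a": u, "node_b": v, "key": k, "length_um": length,
                     "radius_um": float(d["radius_um"])})
    nx.write_graphml(g, graphml_path)
    if csv_path is not None:
        pd.DataFrame(rows).to_csv(csv_path, index=False)
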