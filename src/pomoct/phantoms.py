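"""Synthetic tomographic phantoms with exact ground truth.

Two generators emulate the two kinds of scan the pipeline quantifies:

* :func:`make_parenchyma` — porous fruit flesh at micrometre voxels: a
  packing of rounded cells (Lloyd-relaxed centers, overlapping balls) with
  gas wedges intertwined between the cells, plus larger voids formed by
  deleting connected clusters of whole cells (mimicking lysigenous void
  formation, where voids arise by cell death and have cell-sized
  diameters), rendered with Gaussian blur and additive noise.
* :func:`make_fruit` — a whole fruit at coarser voxels: a spheroid with a
  dark central air cavity, a bright epidermal shell, and a branching tree of
  bright vascular bundles rooted on a meridional ring of primary bundles
  around the core, ramifying toward the skin.

Both return a :class:`PhantomTruth` carrying the exact void inventory /
centerline network so estimator error can be measured directly.  Analytic
test shapes (ball, tube, parallel plates) are provided as oracles for the
morphometric estimators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from pomoct.io import LabelMap, Mask, Volume

logger = logging.getLogger(__name__)

_CROSS = ndimage.generate_binary_structure(3, 1)  # 6-connected unit ball
_FULL = np.ones((3, 3, 3), bool)  # 26-connectivity


# ---------------------------------------------------------------------------
# analytic shapes

def make_ball(radius_vox: float, shape: tuple[int, int, int], voxel_size_mm: float = 1.0) -> Mask:
    """Voxelized solid ball centered in the grid.

    A voxel is set iff its center lies within ``radius_vox`` of the grid
    center ``((n-1)/2, ...)``.  Raises if the ball does not fit.
    """
    shape = tuple(int(s) for s in shape)
    if any(radius_vox > (s - 1) / 2 for s in shape):
        raise ValueError(f"ball of radius {radius_vox} does not fit in shape {shape}")
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    c = [(s - 1) / 2 for s in shape]
    d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
    return Mask(d2 <= radius_vox**2, voxel_size_mm)


def make_tube(
    p0_mm: tuple[float, float, float],
    p1_mm: tuple[float, float, float],
    radius_mm: float,
    shape: tuple[int, int, int],
    voxel_size_mm: float,
) -> Mask:
    """Voxelized straight cylinder (capsule) between two points.

    A voxel is set iff its center is within ``radius_mm`` of the segment
    ``p0—p1`` (coordinates in mm, (z, y, x) order).
    """
    p0 = np.asarray(p0_mm, float)
    p1 = np.asarray(p1_mm, float)
    if np.allclose(p0, p1):
        raise ValueError("degenerate tube: p0 == p1")
    zz, yy, xx = np.meshgrid(*[np.arange(s) * voxel_size_mm for s in shape], indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    d = p1 - p0
    t = np.clip(((pts - p0) @ d) / (d @ d), 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    return Mask(dist2 <= radius_mm**2, voxel_size_mm)


def make_plates(
    spacing_vox: int, thickness_vox: int, shape: tuple[int, int, int], voxel_size_mm: float = 1.0
) -> Mask:
    """Parallel slabs normal to z spanning the full x-y extent.

    Slab k occupies z in ``[k*spacing, k*spacing + thickness)``.  A fully
    solid (degenerate) result when ``thickness == spacing`` only warns.
    """
    if not (spacing_vox >= thickness_vox >= 1):
        raise ValueError("require spacing >= thickness >= 1")
    if spacing_vox == thickness_vox:
        warnings.warn("thickness == spacing: plates degenerate to a solid block")
    z = np.arange(shape[0])
    slab = (z % spacing_vox) < thickness_vox
    vox = np.zeros(shape, bool)
    vox[slab, :, :] = True
    return Mask(vox, voxel_size_mm)


# ---------------------------------------------------------------------------
# ground truth container

@dataclass
class PhantomTruth:
    """Exact ground truth attached to a generated phantom."""

    true_porosity: Optional[float] = None
    #: list of (void id, volume mm^3) for 26-connected void components
    void_inventory: list = field(default_factory=list)
    #: remaining (non-deleted) Voronoi cell volumes, mm^3
    cell_volumes_mm3: Optional[np.ndarray] = None
    cell_labels: Optional[LabelMap] = None
    true_network: Optional[object] = None  # VesselNetwork
    true_total_length_m: Optional[float] = None
    n_branch_points: Optional[int] = None
    #: named region masks: core_air / core / cortex / epidermis / fruit
    region_masks: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# parenchyma phantom

@dataclass
class ParenchymaSpec:
    """Parameters of the porous-parenchyma phantom.

    Defaults emulate cortex tissue imaged at ~5 µm voxels: roundish cells
    ~16 voxels (75 µm) across packed with gas wedges intertwined between
    them, target porosity in the 10-30% range, mild blur and noise.
    ``intercellular_fraction`` is the share of the target porosity carried
    by the inter-cell gas (pore space between the rounded cells, present at
    essentially every cell junction); the remainder is produced by deleting
    compact clusters of whole cells (lysigenous, cell-sized voids).
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: float = 0.0048
    target_porosity: float = 0.25
    n_cells: int = 400
    void_cluster_size: float = 3.0  # mean cells deleted per void event
    intercellular_fraction: float = 0.6
    lloyd_iterations: int = 6
    blur_sigma_vox: float = 0.5
    noise_sd: float = 5.0  # 8-bit intensity units
    seed: int = 0
    cell_intensity: int = 200
    void_intensity: int = 30

    def validate(self) -> None:
        if not (0.0 < self.target_porosity < 0.5):
            raise ValueError("target_porosity must be in (0, 0.5)")
        if self.n_cells < 8:
            raise ValueError("n_cells must be >= 8")
        if not (0.0 <= self.intercellular_fraction < 1.0):
            raise ValueError("intercellular_fraction must be in [0, 1)")


def _render(binary_low: np.ndarray, low: int, high: int, blur: float, noise_sd: float,
            rng: np.random.Generator) -> np.ndarray:
    img = np.where(binary_low, float(low), float(high))
    if blur > 0:
        img = ndimage.gaussian_filter(img, blur)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def make_parenchyma(spec: ParenchymaSpec) -> tuple[Volume, Mask, PhantomTruth]:
    """Generate a parenchyma phantom: rendered volume, truth void mask, truth.

    Cell centers are seeded-random points regularized by Lloyd
    (centroidal-Voronoi) iterations; each cell is a ball around its center
    whose radius (a common fraction of the nearest-neighbour distance,
    solved by bisection) is chosen so the gas wedges intertwined between
    the packed cells carry ``intercellular_fraction`` of the target
    porosity.  The remaining porosity is produced by deleting spatially
    compact clusters of whole cells (cluster sizes
    ~ 1 + Poisson(void_cluster_size − 1)) — the lysigenous mechanism in
    which voids arise by cell death and are therefore cell-sized; deletion
    stops mid-cluster once the target is crossed.  Raises if the achieved
    porosity misses the target by more than one percentage point.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    n_vox = int(np.prod(shape))
    n = spec.n_cells
    vox3 = spec.voxel_size_mm**3

    seeds = rng.uniform(0, 1, size=(n, 3)) * np.array(shape)
    grid = np.stack(
        np.meshgrid(*[np.arange(s) + 0.5 for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    for _ in range(spec.lloyd_iterations):
        _, assign = cKDTree(seeds).query(grid, k=1)
        for ax in range(3):
            sums = np.bincount(assign, weights=grid[:, ax], minlength=n)
            cnts = np.bincount(assign, minlength=n)
            nz = cnts > 0
            seeds[nz, ax] = sums[nz] / cnts[nz]
    tree = cKDTree(seeds)
    d_nn = tree.query(seeds, k=2)[0][:, 1]

    # per-voxel distances to the 8 nearest cell centers: enough to decide
    # ball-union membership at the overlap depths used here
    dd, ii = tree.query(grid, k=8)

    # bisect the common overlap factor so the packing porosity alone is
    # intercellular_fraction x target
    base = spec.target_porosity * spec.intercellular_fraction
    lo, hi = 0.55, 1.2
    for _ in range(30):
        ov = 0.5 * (lo + hi)
        gas_frac = 1.0 - np.mean((dd <= (ov * d_nn)[ii]).any(axis=1))
        if gas_frac > base:
            lo = ov
        else:
            hi = ov
    radii = ov * d_nn
    cover_n = (dd <= radii[ii]).sum(axis=1).astype(np.int8)

    # greedy deletion of compact whole-cell clusters until target porosity
    alive = np.ones(n, bool)
    porosity = float(np.mean(cover_n == 0))
    target = spec.target_porosity
    order = rng.permutation(n)
    oi = 0
    while porosity < target and oi < n:
        c = int(order[oi])
        oi += 1
        if not alive[c]:
            continue
        k = 1 + int(rng.poisson(max(spec.void_cluster_size - 1.0, 0.0)))
        _, idx = tree.query(seeds[c], k=min(4 * k + 8, n))
        cluster = [c]
        for j in np.atleast_1d(idx):
            j = int(j)
            if j != c and alive[j]:
                cluster.append(j)
            if len(cluster) >= k:
                break
        for cell in cluster:
            if porosity >= target:
                break
            alive[cell] = False
            cover_n = cover_n - ((ii == cell) & (dd <= radii[cell])).sum(axis=1).astype(np.int8)
            porosity = float(np.mean(cover_n == 0))
    if abs(porosity - target) > 0.01:
        raise ValueError(
            f"target porosity {target:.3f} unreachable with n_cells={n}: "
            f"achieved {porosity:.3f}"
        )

    void_mask = (cover_n == 0).reshape(shape)
    voids = Mask(void_mask, spec.voxel_size_mm)

    vol = Volume(
        _render(void_mask, spec.void_intensity, spec.cell_intensity,
                spec.blur_sigma_vox, spec.noise_sd, rng),
        spec.voxel_size_mm,
    )

    comp, ncomp = ndimage.label(void_mask, structure=_FULL)
    inv = [(i, float(n) * vox3) for i, n in
           enumerate(np.bincount(comp.ravel())[1:], start=1)]

    # truth cell identity: solid voxels claimed by their nearest alive seed
    alive_ids = np.flatnonzero(alive)
    alive_tree = cKDTree(seeds[alive_ids])
    solid_idx = np.flatnonzero(~void_mask.ravel())
    _, owner = alive_tree.query(grid[solid_idx], k=1)
    labels = np.zeros(n_vox, np.int32)
    labels[solid_idx] = owner + 1
    labels = labels.reshape(shape)
    cell_counts = np.bincount(labels.ravel())[1:]

    truth = PhantomTruth(
        true_porosity=float(void_mask.sum()) / n_vox,
        void_inventory=inv,
        cell_volumes_mm3=cell_counts[cell_counts > 0] * vox3,
        cell_labels=LabelMap(labels, spec.voxel_size_mm),
    )
    logger.info("parenchyma phantom: porosity %.3f (target %.3f), %d voids",
                truth.true_porosity, target, ncomp)
    return vol, voids, truth


# ---------------------------------------------------------------------------
# whole-fruit phantom

@dataclass
class FruitSpec:
    """Parameters of the whole-fruit phantom.

    The default geometry is a scaled-down fruit (radius 11 mm at 0.16 mm
    voxels in a 160³ grid) preserving the anatomy the pipeline exploits:
    ten primary (sepal and petal) vascular bundles on a meridional ring
    around the core, branching toward the skin, a dark core air cavity and
    a thin bright epidermis.
    """

    shape: tuple[int, int, int] = (160, 160, 160)
    voxel_size_mm: float = 0.16
    fruit_radius_mm: float = 11.0
    core_radius_mm: float = 6.0  # radius of the primary-bundle ring
    core_air_radius_mm: float = 2.0
    n_primary_bundles: int = 10
    branch_levels: int = 2
    branch_prob_per_mm: float = 0.3
    # branches only spawn with this much room left before the growth stops,
    # and at least this far apart along a parent, so that true terminal
    # segments stay well above the skeleton-spur scale
    min_branch_clearance_mm: float = 2.5
    min_branch_spacing_mm: float = 1.5
    radius_root_mm: float = 0.30
    radius_taper: float = 0.8  # per-level radius multiplier
    epidermis_thickness_vox: int = 2
    blur_sigma_vox: float = 0.8
    noise_sd: float = 4.0
    seed: int = 0
    # resolution-specific morphology used to define the truth regions
    region_dilate_vox: int = 8
    region_erode_vox: int = 6
    # intensities (8-bit)
    air_intensity: int = 10
    flesh_intensity: int = 120
    vessel_intensity: int = 230
    skin_intensity: int = 230

    def validate(self) -> None:
        if not (self.core_air_radius_mm < self.core_radius_mm < self.fruit_radius_mm):
            raise ValueError("require core_air_radius < core_radius < fruit_radius")
        if self.n_primary_bundles < 1:
            raise ValueError("n_primary_bundles must be >= 1")
        if not (0 < self.radius_taper <= 1):
            raise ValueError("radius_taper must be in (0, 1]")
        half_extent = min(self.shape) / 2 * self.voxel_size_mm
        if self.fruit_radius_mm >= half_extent:
            raise ValueError("fruit does not fit in the field of view")


def _sph(r: float, theta: float, phi: float) -> np.ndarray:
    """(z, y, x) point from spherical coordinates (z is the fruit axis)."""
    return np.array([r * np.cos(theta),
                     r * np.sin(theta) * np.sin(phi),
                     r * np.sin(theta) * np.cos(phi)])


class _TreeBuilder:
    """Accumulates polylines/nodes while growing the vascular tree."""

    def __init__(self, spec: FruitSpec, center: np.ndarray, rng: np.random.Generator):
        self.spec = spec
        self.center = center
        self.rng = rng
        self.nodes: list[dict] = []
        self.edges: list[dict] = []
        self.stop_r = 0.86 * spec.fruit_radius_mm
        # hard clip one epidermis thickness below the surface
        self.clip_r = spec.fruit_radius_mm - (spec.epidermis_thickness_vox + 1) * spec.voxel_size_mm

    def add_node(self, pos: np.ndarray, radius: float) -> int:
        self.nodes.append({"pos": pos.copy(), "radius": radius})
        return len(self.nodes) - 1

    def add_edge(self, a: int, b: int, poly: np.ndarray, radius: float) -> None:
        seg = np.diff(poly, axis=0)
        length = float(np.sum(np.sqrt(np.sum(seg**2, axis=1))))
        self.edges.append({
            "a": a, "b": b, "polyline_mm": poly,
            "radii_mm": np.full(len(poly), radius), "length_mm": length,
        })

    def grow_branch(self, start: np.ndarray, direction: np.ndarray, level: int,
                    start_node: int) -> None:
        """Grow one branch outward from `start`, possibly spawning children."""
        spec = self.spec
        radius = spec.radius_root_mm * spec.radius_taper**level
        ds = 2.0 * spec.voxel_size_mm
        pos = start.copy()
        d = direction / np.linalg.norm(direction)
        pts = [pos.copy()]
        prev_node = start_node
        since_spawn = 0.0
        while True:
            rel = pos - self.center
            r = np.linalg.norm(rel)
            if r >= min(self.stop_r, self.clip_r):
                if r > self.clip_r:
                    logger.info("branch clipped below the epidermis at r=%.2f mm", r)
                break
            # outward bias plus seeded angular jitter
            outward = rel / max(r, 1e-9)
            d = d + 0.35 * outward + 0.25 * self.rng.normal(size=3)
            d /= np.linalg.norm(d)
            pos = pos + d * ds
            pts.append(pos.copy())
            since_spawn += ds
            if (level < spec.branch_levels
                    and self.rng.uniform() < spec.branch_prob_per_mm * ds
                    and since_spawn >= spec.min_branch_spacing_mm
                    and self.stop_r - r >= spec.min_branch_clearance_mm
                    and len(pts) > 3):
                node = self.add_node(pos, radius)
                self.add_edge(prev_node, node, np.array(pts), radius)
                pts = [pos.copy()]
                prev_node = node
                since_spawn = 0.0
                child_dir = d + 0.9 * self.rng.normal(size=3)
                self.grow_branch(pos, child_dir, level + 1, node)
        end = self.add_node(pos, radius)
        if len(pts) >= 2:
            self.add_edge(prev_node, end, np.array(pts), radius)


def make_fruit(spec: FruitSpec) -> tuple[Volume, PhantomTruth]:
    """Generate a whole-fruit phantom and its exact vascular ground truth.

    The truth region masks follow the same morphological recipe the
    segmentation stage uses (core = core-air dilated ``region_dilate_vox``
    unit-ball iterations; epidermis = fruit minus fruit eroded
    ``region_erode_vox``), applied to the noise-free analytic masks.
    """
    # local import: vasculature depends on io only, no cycle at runtime
    from pomoct.vasculature import VesselNetwork
    import networkx as nx

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    vs = spec.voxel_size_mm
    center = (np.array(shape) - 1) / 2 * vs

    zz, yy, xx = np.meshgrid(*[np.arange(s) * vs for s in shape], indexing="ij")
    r_mm = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    fruit = r_mm <= spec.fruit_radius_mm
    core_air = r_mm <= spec.core_air_radius_mm
    eroded = ndimage.binary_erosion(fruit, _CROSS, iterations=spec.region_erode_vox)
    epidermis_region = fruit & ~eroded
    core = ndimage.binary_dilation(core_air, _CROSS, iterations=spec.region_dilate_vox) & fruit
    cortex = eroded & ~core

    # ---- vascular tree -----------------------------------------------------
    tb = _TreeBuilder(spec, center, rng)
    for b in range(spec.n_primary_bundles):
        phi = 2 * np.pi * b / spec.n_primary_bundles + rng.normal(0, 0.05)
        thetas = np.arange(0.18 * np.pi, 0.82 * np.pi, 1.2 * vs / spec.core_radius_mm)
        arc = np.array([center + _sph(spec.core_radius_mm, t, phi) for t in thetas])
        start_node = tb.add_node(arc[0], spec.radius_root_mm)
        ds_arc = spec.core_radius_mm * (thetas[1] - thetas[0])
        prev_node, pts = start_node, [arc[0]]
        # the arc start is a free end: leave a full clearance before the
        # first junction, then ordinary spacing between junctions
        since_spawn = spec.min_branch_spacing_mm - spec.min_branch_clearance_mm
        for j, p in enumerate(arc[1:]):
            pts.append(p)
            since_spawn += ds_arc
            remaining = (len(arc) - 2 - j) * ds_arc
            if (spec.branch_levels > 0
                    and rng.uniform() < spec.branch_prob_per_mm * ds_arc
                    and since_spawn >= spec.min_branch_spacing_mm
                    and remaining >= spec.min_branch_clearance_mm
                    and len(pts) > 3):
                node = tb.add_node(p, spec.radius_root_mm)
                tb.add_edge(prev_node, node, np.array(pts), spec.radius_root_mm)
                pts = [p.copy()]
                prev_node = node
                since_spawn = 0.0
                outward = (p - center) / np.linalg.norm(p - center)
                tb.grow_branch(p, outward + 0.4 * rng.normal(size=3), 1, node)
        end = tb.add_node(arc[-1], spec.radius_root_mm)
        if len(pts) >= 2:
            tb.add_edge(prev_node, end, np.array(pts), spec.radius_root_mm)

    g = nx.MultiGraph()
    for i, nd in enumerate(tb.nodes):
        g.add_node(i, pos_mm=nd["pos"], radius_mm=nd["radius"])
    for e in tb.edges:
        g.add_edge(e["a"], e["b"], polyline_mm=e["polyline_mm"],
                   radii_mm=e["radii_mm"], length_mm=e["length_mm"])
    net = VesselNetwork(graph=g)

    # ---- rasterize and render ---------------------------------------------
    img = np.full(shape, float(spec.air_intensity))
    img[fruit] = spec.flesh_intensity
    img[epidermis_shell(fruit, spec.epidermis_thickness_vox)] = spec.skin_intensity
    img[core_air] = spec.air_intensity
    vessel_mask = _rasterize_tubes(tb.edges, shape, vs)
    vessel_mask &= eroded  # bundles live in the flesh, never in the skin
    img[vessel_mask] = spec.vessel_intensity

    rendered = img
    if spec.blur_sigma_vox > 0:
        rendered = ndimage.gaussian_filter(rendered, spec.blur_sigma_vox)
    if spec.noise_sd > 0:
        rendered = rendered + rng.normal(0, spec.noise_sd, size=shape)
    vol = Volume(np.clip(rendered, 0, 255).astype(np.uint8), vs)

    truth = PhantomTruth(
        true_network=net,
        true_total_length_m=net.total_length_m,
        n_branch_points=len(net.branch_points),
        region_masks={
            "fruit": Mask(fruit, vs),
            "core_air": Mask(core_air, vs),
            "core": Mask(core, vs),
            "cortex": Mask(cortex, vs),
            "epidermis": Mask(epidermis_region, vs),
            "vessels": Mask(vessel_mask, vs),
        },
    )
    logger.info("fruit phantom: %d nodes, %d edges, total length %.3f m, %d branch points",
                g.number_of_nodes(), g.number_of_edges(),
                net.total_length_m, truth.n_branch_points)
    return vol, truth


def epidermis_shell(fruit: np.ndarray, thickness_vox: int) -> np.ndarray:
    """The outermost `thickness_vox` voxel layers of a solid mask."""
    return fruit & ~ndimage.binary_erosion(fruit, _CROSS, iterations=thickness_vox)


def _rasterize_tubes(edges: list[dict], shape: tuple[int, int, int], vs: float) -> np.ndarray:
    """Stamp tube polylines into a boolean grid (ball per sample point)."""
    mask = np.zeros(shape, bool)
    ball_cache: dict[int, np.ndarray] = {}
    for e in edges:
        poly = np.asarray(e["polyline_mm"])
        radius = float(e["radii_mm"][0])
        r_vox = max(radius / vs, 0.6)
        key = int(round(r_vox * 4))
        if key not in ball_cache:
            rr = key / 4
            n = int(np.ceil(rr))
            zz, yy, xx = np.mgrid[-n : n + 1, -n : n + 1, -n : n + 1]
            ball_cache[key] = (zz**2 + yy**2 + xx**2) <= rr**2
        ball = ball_cache[key]
        n = ball.shape[0] // 2
        # resample polyline at <= half-voxel spacing for gap-free tubes
        seg = np.diff(poly, axis=0)
        seglen = np.sqrt(np.sum(seg**2, axis=1))
        cum = np.concatenate([[0], np.cumsum(seglen)])
        total = cum[-1]
        if total == 0:
            continue
        s = np.arange(0, total, 0.4 * vs)
        pts = np.empty((len(s), 3))
        for ax in range(3):
            pts[:, ax] = np.interp(s, cum, poly[:, ax])
        idx = np.round(pts / vs).astype(int)
        for p in idx:
            z0, y0, x0 = p
            zl, zh = max(z0 - n, 0), min(z0 + n + 1, shape[0])
            yl, yh = max(y0 - n, 0), min(y0 + n + 1, shape[1])
            xl, xh = max(x0 - n, 0), min(x0 + n + 1, shape[2])
            if zl >= zh or yl >= yh or xl >= xh:
                continue
            mask[zl:zh, yl:yh, xl:xh] |= ball[
                zl - (z0 - n) : zh - (z0 - n),
                yl - (y0 - n) : yh - (y0 - n),
                xl - (x0 - n) : xh - (x0 - n),
            ]
    return mask
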