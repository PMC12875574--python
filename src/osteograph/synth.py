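"""Seed-reproducible synthetic osteocyte-network scenes.

The generator emulates 2-D confocal scans of phalloidin-stained osteocyte
networks in cortical bone: bright elliptical cell bodies connected by thin
(1.5-3 px at 150 nm/px) curvilinear dendritic processes, imaged through a
diffraction-limited optic (~450 nm, i.e. a ~1.5 px Gaussian PSF), with
additive sensor noise, a slow illumination fall-off across the field, and
optional unlabelled distractors (transiting blood vessels, shrunken
apoptotic osteocytes).  Every scene carries its ground-truth graph and
3-class mask, and is a pure function of ``(SceneParams, seed)``.

The default parameters reproduce the young-bone regime of the imaging
protocol the package targets (500x500 px field at 150 nm/px, ~7 osteocytes
per field, ~21 dead-end dendrites and ~3.8 inter-osteocyte connections per
cell); :func:`aged_params` applies the degeneration measured in aged bone
(osteocyte density down ~38%, connectivity down ~40-55%, shorter dendrites,
more dead ends).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.draw import ellipse as draw_ellipse

from .errors import GenerationError, ValidationError
from .io import DENDRITE, OSTEOCYTE, GreyImage, SegmentationMask

__all__ = [
    "SceneParams",
    "GTNode",
    "GTEdge",
    "GTDeadEnd",
    "GroundTruthGraph",
    "SyntheticScene",
    "sample_network",
    "render_scene",
    "make_scene",
    "generate_cohort",
    "young_params",
    "aged_params",
    "low_noise_params",
    "recovery_params",
    "ground_truth_metrics",
]


@dataclass(frozen=True)
class SceneParams:
    """All knobs of the scene generator; identical params + seed give
    byte-identical scenes.

    ``n_osteocytes`` is an exact count when ``n_jitter="fixed"`` and a
    Poisson mean when ``n_jitter="poisson"`` (used by the cohort presets so
    per-image cell counts vary as they do across real fields of view).
    ``well_separated`` turns on clearance enforcement between structures so
    that the rendered true mask maps back onto the ground-truth graph
    exactly (used for oracle scenes).
    """

    image_size: int = 500
    pixel_size_nm: float = 150.0
    n_osteocytes: float = 7
    n_jitter: str = "fixed"  # "fixed" | "poisson"
    body_axes_px: tuple[float, float] = (20.0, 40.0)  # semi-major axis range
    body_aspect: tuple[float, float] = (0.55, 0.85)  # semi-minor / semi-major
    dendrite_width_px: tuple[float, float] = (1.5, 3.0)
    connection_prob: float = 0.9
    connection_radius_px: float = 300.0
    deadend_rate: float = 20.9
    deadend_len_px: tuple[float, float] = (25.0, 90.0)
    blur_sigma_px: float = 1.5
    noise_sd: float = 8.0
    illum_gradient: float = 0.2
    blood_vessel: bool = False
    shrunken_osteocyte: bool = False
    seed: int = 0
    background: float = 12.0
    body_intensity: float = 210.0
    dendrite_intensity: float = 90.0
    min_separation_factor: float = 2.0
    well_separated: bool = False
    clearance_px: float = 6.0

    def validate(self) -> None:
        if self.image_size < 8:
            raise ValidationError("image_size must be >= 8")
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be positive")
        if self.n_osteocytes < 0 or self.deadend_rate < 0 or self.noise_sd < 0:
            raise ValidationError("counts, rates and noise_sd must be >= 0")
        if self.n_jitter not in ("fixed", "poisson"):
            raise ValidationError("n_jitter must be 'fixed' or 'poisson'")
        if self.n_jitter == "fixed" and self.n_osteocytes != int(self.n_osteocytes):
            raise ValidationError("n_osteocytes must be an integer when n_jitter='fixed'")
        if not (0.0 <= self.connection_prob <= 1.0):
            raise ValidationError("connection_prob must lie in [0, 1]")
        if not (0.0 <= self.illum_gradient <= 1.0):
            raise ValidationError("illum_gradient must lie in [0, 1]")
        for name in ("body_axes_px", "dendrite_width_px", "deadend_len_px", "body_aspect"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must be a positive (lo, hi) range")
        if self.blur_sigma_px < 0:
            raise ValidationError("blur_sigma_px must be >= 0")


@dataclass
class GTNode:
    id: int
    centroid: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (major, minor)
    angle: float  # radians, orientation of the major axis
    area_px2: float  # analytic ellipse area pi*a*b


@dataclass
class GTEdge:
    node_a: int
    node_b: int
    path: np.ndarray  # (N, 2) float (row, col) samples along the centreline
    length_um: float
    width_px: float


@dataclass
class GTDeadEnd:
    node: int
    path: np.ndarray
    length_um: float
    width_px: float


@dataclass
class GroundTruthGraph:
    """Ground truth of one scene: osteocytes (nodes), inter-osteocyte
    dendrites (edges) and dead-end dendrites attached to a single cell."""

    nodes: list[GTNode] = field(default_factory=list)
    edges: list[GTEdge] = field(default_factory=list)
    deadends: list[GTDeadEnd] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {n.id for n in self.nodes}
        for e in self.edges:
            if e.node_a == e.node_b:
                raise ValidationError("self-edges are not allowed")
            if e.node_a not in ids or e.node_b not in ids:
                raise ValidationError("edge endpoint references a missing node")

    def deadend_count(self, node_id: int) -> int:
        return sum(1 for d in self.deadends if d.node == node_id)


@dataclass
class SyntheticScene:
    graph: GroundTruthGraph
    image: Optional[GreyImage]
    mask: Optional[SegmentationMask]
    params: SceneParams


# ---------------------------------------------------------------------------
# geometry helpers


def _catmull_rom(points: np.ndarray, step: float = 0.5) -> np.ndarray:
    """Sample a uniform Catmull-Rom spline through ``points`` at roughly
    ``step`` px spacing (endpoints duplicated, so the curve interpolates
    the first and last control point)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return pts
    ext = np.vstack([pts[0], pts, pts[-1]])
    out = [pts[0][None, :]]
    for i in range(len(pts) - 1):
        p0, p1, p2, p3 = ext[i], ext[i + 1], ext[i + 2], ext[i + 3]
        seg_len = np.linalg.norm(p2 - p1)
        n = max(int(np.ceil(seg_len / step)), 2)
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        out.append(
            0.5
            * (
                (2 * p1)
                + (-p0 + p2) * t
                + (2 * p0 - 5 * p1 + 4 * p2 - p3) * t**2
                + (-p0 + 3 * p1 - 3 * p2 + p3) * t**3
            )
        )
    return np.vstack(out)


def _arc_length(path: np.ndarray) -> float:
    d = np.diff(path, axis=0)
    return float(np.sqrt((d**2).sum(axis=1)).sum())


def _outside(path: np.ndarray, node: GTNode) -> np.ndarray:
    """Boolean per path point: outside the node's ellipse."""
    a, b = node.semi_axes
    u = np.array([np.cos(node.angle), np.sin(node.angle)])
    v = np.array([-np.sin(node.angle), np.cos(node.angle)])
    rel = path - np.asarray(node.centroid)
    return (rel @ u / a) ** 2 + (rel @ v / b) ** 2 > 1.0


def _dendrite_length(path: np.ndarray, bodies: list[GTNode]) -> float:
    """Arc length of the path portion outside the attached cell bodies
    (the dendrite proper; anchors sit slightly inside the body)."""
    out = np.ones(len(path), dtype=bool)
    for n in bodies:
        out &= _outside(path, n)
    d = np.sqrt((np.diff(path, axis=0) ** 2).sum(axis=1))
    keep = out[:-1] & out[1:]
    return float(d[keep].sum())


def _ellipse_radius(node: GTNode, direction: np.ndarray) -> float:
    """Distance from the ellipse centre to its boundary along ``direction``."""
    a, b = node.semi_axes
    u = np.array([np.cos(node.angle), np.sin(node.angle)])
    v = np.array([-np.sin(node.angle), np.cos(node.angle)])
    d = direction / np.linalg.norm(direction)
    return 1.0 / np.sqrt((d @ u / a) ** 2 + (d @ v / b) ** 2)


def _boundary_point(node: GTNode, angle: float, inset: float = 1.5) -> np.ndarray:
    """Point on (or, with ``inset``, just inside) the ellipse boundary along
    ``angle``; the inset guarantees a rasterised dendrite stroke overlaps
    its cell body."""
    d = np.array([np.sin(angle), np.cos(angle)])  # (row, col)
    c = np.asarray(node.centroid)
    return c + d * max(_ellipse_radius(node, d) - inset, 0.0)


class _Clearance:
    """Incremental clearance bookkeeping for well-separated scenes."""

    def __init__(self, params: SceneParams):
        self.params = params
        self._points: list[np.ndarray] = []
        self._tree: Optional[cKDTree] = None

    def blocked(self, path: np.ndarray, width: float, nodes: list[GTNode], own: set[int]) -> bool:
        p = self.params
        margin = p.clearance_px + width / 2 + p.dendrite_width_px[1] / 2
        if self._points:
            if self._tree is None:
                self._tree = cKDTree(np.vstack(self._points))
            if (self._tree.query(path, k=1)[0] < margin).any():
                return True
        for node in nodes:
            if node.id in own:
                continue
            reach = max(node.semi_axes) + p.clearance_px + width / 2
            if (np.linalg.norm(path - np.asarray(node.centroid), axis=1) < reach).any():
                return True
        return False

    def commit(self, path: np.ndarray) -> None:
        self._points.append(path)
        self._tree = None


def _in_bounds(path: np.ndarray, size: int, pad: float) -> bool:
    return bool((path >= pad).all() and (path <= size - 1 - pad).all())


# ---------------------------------------------------------------------------
# network sampling


def _place_bodies(rng: np.random.Generator, params: SceneParams) -> list[GTNode]:
    if params.n_jitter == "poisson":
        n = int(rng.poisson(params.n_osteocytes))
    else:
        n = int(params.n_osteocytes)
    a_lo, a_hi = params.body_axes_px
    min_sep = params.min_separation_factor * a_hi
    margin = a_hi + 2.0
    lo, hi = margin, params.image_size - 1 - margin
    if n > 0 and hi <= lo:
        raise GenerationError("field too small for the requested body size")
    nodes: list[GTNode] = []
    attempts, max_attempts = 0, 400 * max(n, 1)
    while len(nodes) < n:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {n} osteocytes with separation {min_sep:.0f} px "
                f"in a {params.image_size} px field after {max_attempts} attempts"
            )
        c = rng.uniform(lo, hi, size=2)
        if any(np.linalg.norm(c - np.asarray(m.centroid)) < min_sep for m in nodes):
            continue
        a = rng.uniform(a_lo, a_hi)
        b = a * rng.uniform(*params.body_aspect)
        angle = rng.uniform(0, np.pi)
        nodes.append(
            GTNode(
                id=len(nodes),
                centroid=(float(c[0]), float(c[1])),
                semi_axes=(float(a), float(b)),
                angle=float(angle),
                area_px2=float(np.pi * a * b),
            )
        )
    return nodes


def _edge_path(
    rng: np.random.Generator, na: GTNode, nb: GTNode, params: SceneParams, wobble: float
) -> np.ndarray:
    ca, cb = np.asarray(na.centroid), np.asarray(nb.centroid)
    dr, dc = cb - ca
    ang_ab = np.arctan2(dr, dc)  # direction basis: (row, col) = (sin, cos)
    jitter = rng.uniform(-0.35, 0.35, size=2)
    p0 = _boundary_point(na, ang_ab + jitter[0])
    p1 = _boundary_point(nb, ang_ab + np.pi + jitter[1])
    chord = np.linalg.norm(p1 - p0)
    n_ctrl = int(rng.integers(1, 3))  # 1-2 interior control points (3-4 total)
    ts = np.sort(rng.uniform(0.25, 0.75, size=n_ctrl))
    perp = np.array([-(p1 - p0)[1], (p1 - p0)[0]])
    perp = perp / max(np.linalg.norm(perp), 1e-9)
    ctrl = [p0 + t * (p1 - p0) + perp * rng.uniform(-wobble, wobble) * chord for t in ts]
    return _catmull_rom(np.vstack([p0, *ctrl, p1]))


def _deadend_path(
    rng: np.random.Generator, node: GTNode, params: SceneParams, wobble: float
) -> np.ndarray:
    angle = rng.uniform(0, 2 * np.pi)
    p0 = _boundary_point(node, angle)
    length = rng.uniform(*params.deadend_len_px)
    d = np.array([np.sin(angle), np.cos(angle)])
    perp = np.array([-d[1], d[0]])
    t_mid = rng.uniform(0.35, 0.65)
    mid = p0 + d * length * t_mid + perp * rng.uniform(-wobble, wobble) * length
    p1 = p0 + d * length + perp * rng.uniform(-wobble, wobble) * length
    return _catmull_rom(np.vstack([p0, mid, p1]))


def sample_network(params: SceneParams) -> GroundTruthGraph:
    """Sample the ground-truth graph of one scene (bodies, connections,
    dead ends), fully determined by ``params`` (including its seed).

    Osteocyte centres keep a minimum separation of
    ``min_separation_factor x max semi-axis``; connections are drawn only
    between pairs closer than ``connection_radius_px``; each node receives
    ``Poisson(deadend_rate)`` dead-end dendrites.  With
    ``well_separated=True`` candidate dendrite paths that come within
    ``clearance_px`` of unrelated structures are re-drawn and eventually
    dropped, so the rendered mask decomposes into exactly the recorded
    components.
    """
    params.validate()
    rng = np.random.default_rng([params.seed, 0])
    nodes = _place_bodies(rng, params)
    graph = GroundTruthGraph(nodes=nodes)
    um = params.pixel_size_nm / 1000.0
    clear = _Clearance(params) if params.well_separated else None
    wobble = 0.10

    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            dist = np.linalg.norm(np.asarray(nodes[i].centroid) - np.asarray(nodes[j].centroid))
            if dist > params.connection_radius_px:
                continue
            if rng.random() >= params.connection_prob:
                continue
            width = float(rng.uniform(*params.dendrite_width_px))
            path = None
            for attempt in range(8):
                w = wobble if attempt < 6 else 0.0  # last resorts: straight line
                cand = _edge_path(rng, nodes[i], nodes[j], params, w)
                if not _in_bounds(cand, params.image_size, pad=2.0):
                    continue
                if clear is not None and clear.blocked(cand, width, nodes, {i, j}):
                    continue
                path = cand
                break
            if path is None:
                continue
            if clear is not None:
                clear.commit(path)
            graph.edges.append(
                GTEdge(
                    i, j, path,
                    length_um=_dendrite_length(path, [nodes[i], nodes[j]]) * um,
                    width_px=width,
                )
            )

    for node in nodes:
        k = int(rng.poisson(params.deadend_rate))
        for _ in range(k):
            width = float(rng.uniform(*params.dendrite_width_px))
            path = None
            for _attempt in range(8):
                cand = _deadend_path(rng, node, params, wobble)
                if not _in_bounds(cand, params.image_size, pad=2.0):
                    continue
                if clear is not None and clear.blocked(cand, width, nodes, {node.id}):
                    continue
                path = cand
                break
            if path is None:
                continue
            if clear is not None:
                clear.commit(path)
            graph.deadends.append(
                GTDeadEnd(
                    node.id, path,
                    length_um=_dendrite_length(path, [node]) * um,
                    width_px=width,
                )
            )
    return graph


# ---------------------------------------------------------------------------
# rendering


def _stamp_path(canvas: np.ndarray, path: np.ndarray, width: float) -> None:
    """Mark every pixel whose centre lies within ``width/2`` of the polyline
    (the 0.5-coverage threshold of an anti-aliased round-capped stroke)."""
    r = width / 2.0
    # densify so consecutive samples are < 0.25 px apart
    d = np.sqrt((np.diff(path, axis=0) ** 2).sum(axis=1))
    if (d > 0.25).any():
        pieces = [path[:1]]
        for k in range(len(path) - 1):
            n = int(np.ceil(d[k] / 0.25))
            t = np.linspace(0, 1, n + 1)[1:, None]
            pieces.append(path[k] + t * (path[k + 1] - path[k]))
        pts = np.vstack(pieces)
    else:
        pts = path
    h, w_ = canvas.shape
    base = np.floor(pts).astype(int)
    m = int(np.ceil(r)) + 1
    for dy in range(-m, m + 1):
        for dx in range(-m, m + 1):
            py = base[:, 0] + dy
            px = base[:, 1] + dx
            dist2 = (py - pts[:, 0]) ** 2 + (px - pts[:, 1]) ** 2
            sel = (dist2 <= r * r) & (py >= 0) & (py < h) & (px >= 0) & (px < w_)
            canvas[py[sel], px[sel]] = True


def _draw_bodies(shape: tuple[int, int], nodes: list[GTNode]) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for n in nodes:
        rr, cc = draw_ellipse(
            n.centroid[0], n.centroid[1], n.semi_axes[0], n.semi_axes[1],
            shape=shape, rotation=n.angle,
        )
        out[rr, cc] = True
    return out


def render_scene(graph: GroundTruthGraph, params: SceneParams) -> tuple[GreyImage, SegmentationMask]:
    """Rasterise a ground-truth graph into a (GreyImage, SegmentationMask)
    pair.

    The mask is the pre-blur geometry: filled ellipses (class 1) over
    stroked dendrite polylines (class 2, body pixels win ties).  The image
    is the clean render scaled by the illumination field, convolved with a
    Gaussian PSF of ``blur_sigma_px``, plus Gaussian noise, clipped to
    [0, 255].  Distractor artefacts (blood vessel, shrunken osteocyte) are
    drawn into the image only and stay class 0 in the mask.
    """
    params.validate()
    size = params.image_size
    shape = (size, size)
    dend = np.zeros(shape, dtype=bool)
    for e in graph.edges:
        _stamp_path(dend, e.path, e.width_px)
    for d in graph.deadends:
        _stamp_path(dend, d.path, d.width_px)
    body = _draw_bodies(shape, graph.nodes)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[dend] = DENDRITE
    labels[body] = OSTEOCYTE  # bodies win ties
    mask = SegmentationMask(labels, pixel_size_nm=params.pixel_size_nm)

    clean = np.full(shape, params.background, dtype=float)
    clean[labels == DENDRITE] = params.dendrite_intensity
    clean[labels == OSTEOCYTE] = params.body_intensity

    rng = np.random.default_rng([params.seed, 1])
    if params.blood_vessel:
        vessel = np.zeros(shape, dtype=bool)
        x0 = rng.uniform(0.2, 0.8) * size
        ang = rng.uniform(0, np.pi)
        d = np.array([np.sin(ang), np.cos(ang)])
        p0 = np.array([size / 2, x0]) - d * size
        path = p0 + np.linspace(0, 2 * size, 200)[:, None] * d
        _stamp_path(vessel, path, width=float(rng.uniform(14, 22)))
        clean[vessel & (labels == 0)] = 120.0
    if params.shrunken_osteocyte:
        blob = np.zeros(shape, dtype=bool)
        for _ in range(int(rng.integers(1, 3))):
            cy, cx = rng.uniform(0.1, 0.9, size=2) * size
            rr, cc = draw_ellipse(cy, cx, rng.uniform(4, 7), rng.uniform(3, 5), shape=shape)
            blob[rr, cc] = True
        clean[blob & (labels == 0)] = 95.0

    if params.illum_gradient > 0:
        ramp = 1.0 - params.illum_gradient * (np.arange(size) / max(size - 1, 1))
        clean = clean * ramp[None, :]
    if params.blur_sigma_px > 0:
        clean = ndi.gaussian_filter(clean, params.blur_sigma_px, mode="reflect")
    if params.noise_sd > 0:
        clean = clean + rng.normal(0.0, params.noise_sd, size=shape)
    pixels = np.clip(np.round(clean), 0, 255).astype(np.uint8)
    return GreyImage(pixels, pixel_size_nm=params.pixel_size_nm), mask


def make_scene(params: SceneParams, render: bool = True) -> SyntheticScene:
    """Sample a network and (optionally) render it."""
    graph = sample_network(params)
    if render:
        image, mask = render_scene(graph, params)
        return SyntheticScene(graph, image, mask, params)
    return SyntheticScene(graph, None, None, params)


def _derive_seed(master_seed: int, group: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), group, index])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    params_a: SceneParams,
    params_b: SceneParams,
    n_per_group: int,
    seed: int,
    render: bool = True,
) -> tuple[list[SyntheticScene], list[SyntheticScene]]:
    """Generate two groups of scenes with per-scene seeds derived
    deterministically from ``seed``.  With ``render=False`` only the
    ground-truth graphs are produced (fast path for statistical studies)."""
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    groups = []
    for g, params in enumerate((params_a, params_b)):
        scenes = []
        for i in range(n_per_group):
            p = dataclasses.replace(params, seed=_derive_seed(seed, g, i))
            scenes.append(make_scene(p, render=render))
        groups.append(scenes)
    return groups[0], groups[1]


# ---------------------------------------------------------------------------
# presets


def young_params(**overrides) -> SceneParams:
    """Young-bone preset: the generator defaults with Poisson-varying cell
    counts (~7 osteocytes per 500x500 field)."""
    return SceneParams(**{"n_jitter": "poisson", **overrides})


def aged_params(**overrides) -> SceneParams:
    """Aged-bone preset: osteocyte density reduced by 38%, shorter
    connection reach (fewer/shorter connections; connectivity per cell falls
    ~45-55% through the density drop plus the reach cut) and ~25% more
    dead-end dendrites."""
    base = dict(
        n_osteocytes=7 * (1 - 0.3803),
        n_jitter="poisson",
        connection_radius_px=260.0,
        deadend_rate=26.0,
        deadend_len_px=(20.0, 70.0),
    )
    base.update(overrides)
    return SceneParams(**base)


def low_noise_params(**overrides) -> SceneParams:
    """Young preset under favourable imaging (low noise, nearly flat
    illumination); used to probe the ceiling of the threshold pipelines."""
    base = dict(n_jitter="poisson", noise_sd=3.0, illum_gradient=0.05)
    base.update(overrides)
    return SceneParams(**base)


def recovery_params(**overrides) -> SceneParams:
    """Sparse, clean, well-separated preset whose true masks decompose into
    exactly the recorded graph (oracle scenes for the connectomics module)."""
    base = dict(
        n_osteocytes=5,
        n_jitter="fixed",
        connection_prob=0.7,
        deadend_rate=2.0,
        deadend_len_px=(25.0, 60.0),
        noise_sd=0.0,
        illum_gradient=0.0,
        well_separated=True,
        min_separation_factor=3.0,  # boundary gaps stay wide: no stub connections
    )
    base.update(overrides)
    return SceneParams(**base)


def ground_truth_metrics(graph: GroundTruthGraph, pixel_size_nm: float = 150.0):
    """Network summary metrics computed directly from a ground-truth graph
    (same six quantities as the mask-based connectomics pipeline)."""
    from .connectomics import ConnectomicsMetrics

    n = len(graph.nodes)
    if n == 0:
        return ConnectomicsMetrics(0, 0.0, 0.0, 0.0, 0.0, 0.0)
    um = pixel_size_nm / 1000.0
    all_widths = [e.width_px for e in graph.edges] + [d.width_px for d in graph.deadends]
    return ConnectomicsMetrics(
        n_nodes=n,
        deadends_per_node=len(graph.deadends) / n,
        connections_per_node=2 * len(graph.edges) / n,
        mean_connection_length_um=float(np.mean([e.length_um for e in graph.edges]))
        if graph.edges
        else 0.0,
        mean_connection_diameter_um=float(np.mean([e.width_px for e in graph.edges])) * um
        if graph.edges
        else 0.0,
        mean_network_diameter_um=float(np.mean(all_widths)) * um if all_widths else 0.0,
    )
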