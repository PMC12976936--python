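"""Parametric synthetic aortic anatomies.

Generates seeded, structured quad-shell surface meshes of an idealized
thoracic aorta (ascending limb, arch with 0-2 supra-aortic branches,
descending limb) that stand in for image-derived porcine anatomies.  The
patient frame is right-handed with +x = anatomical Left, +y = Anterior,
+z = Superior; all coordinates are in millimetres.

Tubes are lofted along centerlines using rotation-minimizing frames
(double-reflection propagation), which avoids the twist flips Frenet frames
exhibit at inflection points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np


class GeometryError(ValueError):
    """Invalid or degenerate geometric input."""


# ---------------------------------------------------------------------------
# core containers


@dataclass
class Centerline:
    """Ordered 3-D polyline with per-point lumen radius.

    Attributes
    ----------
    points : (P, 3) float array, mm
    radii : (P,) float array, mm, all > 0
    arclength : (P,) float array, cumulative arc length starting at 0
    """

    points: np.ndarray
    radii: np.ndarray
    arclength: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise GeometryError("centerline needs >= 2 3-D points")
        if len(self.radii) != len(self.points):
            raise GeometryError("radii/points length mismatch")
        if np.any(self.radii <= 0):
            raise GeometryError("centerline radii must be positive")
        if self.arclength is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.arclength = np.concatenate([[0.0], np.cumsum(seg)])
        else:
            self.arclength = np.asarray(self.arclength, dtype=float)
        if np.any(np.diff(self.arclength) <= 0):
            raise GeometryError("arclength must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def resample(self, n: int) -> "Centerline":
        """Resample to ``n`` stations uniformly spaced in arclength."""
        s = np.linspace(0.0, self.length, n)
        pts = np.column_stack([
            np.interp(s, self.arclength, self.points[:, k]) for k in range(3)
        ])
        rad = np.interp(s, self.arclength, self.radii)
        return Centerline(pts, rad, s)

    def point_at(self, s: float) -> np.ndarray:
        return np.array([np.interp(s, self.arclength, self.points[:, k])
                         for k in range(3)])

    def radius_at(self, s: float) -> float:
        return float(np.interp(s, self.arclength, self.radii))

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent by central differencing of the interpolated polyline."""
        h = max(1e-4 * self.length, 1e-6)
        a = self.point_at(max(s - h, 0.0))
        b = self.point_at(min(s + h, self.length))
        t = b - a
        n = np.linalg.norm(t)
        if n == 0:
            raise GeometryError("degenerate tangent")
        return t / n


@dataclass
class TubeStructure:
    """Structured-ring bookkeeping for a lofted tube part.

    rings[i, j] is the node id of ring i, circumferential station j; rings are
    ordered proximal to distal along ``arclength``.
    """

    rings: np.ndarray            # (n_rings, n_circ) int
    arclength: np.ndarray        # (n_rings,) float, mm along the part centerline
    parent: Optional[str] = None           # part this tube branches off
    attach_arclength: Optional[float] = None  # takeoff station on the parent


@dataclass
class VesselModel:
    """Tagged quad-shell surface mesh of a vessel tree.

    ``region_tags`` labels every element (AAo / arch / DAo / branch_i / TEVG);
    ``boundary_loops`` are named, ordered, closed node cycles (first node not
    repeated).  ``structure`` keeps the structured-ring layout per lofted part,
    which downstream resection and lumen profiling exploit.
    """

    nodes: np.ndarray                       # (N, 3) mm
    quads: np.ndarray                       # (M, 4) int
    region_tags: np.ndarray                 # (M,) str
    boundary_loops: dict                    # name -> (k,) int node ids
    thickness: float = 1.5                  # wall thickness, mm
    centerline: Optional[Centerline] = None
    structure: dict = field(default_factory=dict)  # part -> TubeStructure
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.quads = np.asarray(self.quads, dtype=int)
        if len(self.quads) and (self.quads.min() < 0 or self.quads.max() >= len(self.nodes)):
            raise GeometryError("quad connectivity references invalid nodes")
        if len(self.region_tags) != len(self.quads):
            raise GeometryError("one region tag per element required")
        for name, loop in self.boundary_loops.items():
            loop = np.asarray(loop, dtype=int)
            if len(np.unique(loop)) != len(loop):
                raise GeometryError(f"boundary loop {name!r} is not a simple cycle")
            self.boundary_loops[name] = loop

    # -- basic queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.quads)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.quads].mean(axis=1)

    def triangles(self) -> np.ndarray:
        """(2M, 3) triangulation splitting each quad 0-1-2 / 0-2-3."""
        q = self.quads
        return np.concatenate([q[:, [0, 1, 2]], q[:, [0, 2, 3]]], axis=0)

    def loop_centroid(self, name: str) -> np.ndarray:
        return self.nodes[self.boundary_loops[name]].mean(axis=0)

    def copy(self) -> "VesselModel":
        return VesselModel(
            nodes=self.nodes.copy(),
            quads=self.quads.copy(),
            region_tags=self.region_tags.copy(),
            boundary_loops={k: v.copy() for k, v in self.boundary_loops.items()},
            thickness=self.thickness,
            centerline=None if self.centerline is None else Centerline(
                self.centerline.points.copy(), self.centerline.radii.copy(),
                self.centerline.arclength.copy()),
            structure={k: TubeStructure(v.rings.copy(), v.arclength.copy(),
                                        v.parent, v.attach_arclength)
                       for k, v in self.structure.items()},
            flags=list(self.flags),
        )

    def to_trimesh(self):
        """Triangulated open surface as a ``trimesh.Trimesh`` (no caps)."""
        import trimesh
        return trimesh.Trimesh(vertices=self.nodes.copy(),
                               faces=self.triangles(), process=False)


@dataclass
class AnatomyConfig:
    """Parameters of the synthetic aorta generator.

    The default dimensions are configurable placeholders sized for a young
    20-30 kg pig (proximal aortic radius ~10 mm, arch radius ~20 mm); they are
    not literature-calibrated measurements.  ``growth_scale`` is the uniform
    expansion applied at design time to account for somatic growth between
    imaging and implantation (default +5%).
    """

    arch_radius_mm: float = 20.0
    radius_profile: Sequence[float] = (10.0, 10.0)   # lumen radius vs normalized arclength
    asc_length_mm: float = 30.0
    desc_length_mm: float = 60.0
    branch_count: int = 1
    branch_radii_mm: Sequence[float] = (4.0, 3.5)
    branch_length_mm: float = 20.0
    branch_arch_fractions: Sequence[float] = (0.35, 0.65)  # takeoff position along the arch
    n_circumferential: int = 16
    n_axial: int = 48
    branch_n_axial: int = 10
    thickness_mm: float = 1.5
    seed: int = 0
    noise_amplitude_mm: float = 0.0
    growth_scale: float = 1.05

    def __post_init__(self):
        if self.n_circumferential < 8:
            raise GeometryError("n_circumferential must be >= 8")
        if self.branch_count not in (0, 1, 2):
            raise GeometryError("branch_count must be 0, 1 or 2")
        if self.growth_scale <= 0:
            raise GeometryError("growth_scale must be positive")
        if np.any(np.asarray(self.radius_profile, dtype=float) <= 0):
            raise GeometryError("radius profile must be strictly positive")


# ---------------------------------------------------------------------------
# rotation-minimizing frames and lofting


def _rotation_minimizing_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tangent + two normal fields along a polyline via double reflection."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    tan = np.zeros((n, 3))
    tan[1:-1] = pts[2:] - pts[:-2]
    tan[0] = pts[1] - pts[0]
    tan[-1] = pts[-1] - pts[-2]
    norms = np.linalg.norm(tan, axis=1)
    if np.any(norms == 0):
        raise GeometryError("repeated centerline points")
    tan /= norms[:, None]

    # initial normal: least-aligned global axis
    t0 = tan[0]
    ref = np.eye(3)[np.argmin(np.abs(t0))]
    e1 = np.zeros((n, 3))
    e1[0] = ref - np.dot(ref, t0) * t0
    e1[0] /= np.linalg.norm(e1[0])
    for i in range(n - 1):
        # double reflection (Wang et al. RMF)
        v1 = pts[i + 1] - pts[i]
        c1 = np.dot(v1, v1)
        rl = e1[i] - (2.0 / c1) * np.dot(v1, e1[i]) * v1
        tl = tan[i] - (2.0 / c1) * np.dot(v1, tan[i]) * v1
        v2 = tan[i + 1] - tl
        c2 = np.dot(v2, v2)
        if c2 < 1e-30:
            e1[i + 1] = rl
        else:
            e1[i + 1] = rl - (2.0 / c2) * np.dot(v2, rl) * v2
        e1[i + 1] -= np.dot(e1[i + 1], tan[i + 1]) * tan[i + 1]
        e1[i + 1] /= np.linalg.norm(e1[i + 1])
    e2 = np.cross(tan, e1)
    return tan, e1, e2


def loft_surface(centerline: Centerline, n_circ: int, n_axial: int,
                 thickness: float = 1.5,
                 radial_noise: Optional[np.ndarray] = None,
                 part_name: str = "main",
                 inlet_name: str = "inlet",
                 outlet_name: str = "outlet") -> VesselModel:
    """Loft a structured quad tube along a centerline.

    Rings carry ``n_circ`` nodes each at ``n_axial + 1`` stations uniformly
    spaced in arclength; the open tube therefore has ``n_circ * n_axial``
    quads.  Element winding gives outward normals.  A loft whose radius
    exceeds the local centerline curvature radius would self-intersect; it is
    flagged (``model.flags``) and warned about, not rejected.
    """
    if n_circ < 3 or n_axial < 1:
        raise GeometryError("need n_circ >= 3 and n_axial >= 1")
    cl = centerline.resample(n_axial + 1)
    tan, e1, e2 = _rotation_minimizing_frames(cl.points)

    flags: list[str] = []
    # curvature check on the resampled polyline
    if n_axial >= 2:
        d1 = np.gradient(cl.points, cl.arclength, axis=0)
        d2 = np.gradient(d1, cl.arclength, axis=0)
        kappa = np.linalg.norm(np.cross(d1, d2), axis=1) / \
            np.maximum(np.linalg.norm(d1, axis=1) ** 3, 1e-30)
        with np.errstate(divide="ignore"):
            if np.any(kappa * cl.radii > 1.0 + 1e-9):
                flags.append("self_intersecting_loft")
                warnings.warn("loft radius exceeds local curvature radius; "
                              "surface self-intersects", stacklevel=2)

    theta = 2.0 * np.pi * np.arange(n_circ) / n_circ
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    radii = cl.radii[:, None]
    if radial_noise is not None:
        radii = radii + radial_noise
        if np.any(radii <= 0):
            raise GeometryError("radial noise makes radius non-positive")
    nodes = (cl.points[:, None, :]
             + radii[..., None] * (cos_t[None, :, None] * e1[:, None, :]
                                   + sin_t[None, :, None] * e2[:, None, :]))
    nodes = nodes.reshape(-1, 3)

    n_rings = n_axial + 1
    ring_ids = np.arange(n_rings * n_circ).reshape(n_rings, n_circ)
    i = np.repeat(np.arange(n_axial), n_circ)
    j = np.tile(np.arange(n_circ), n_axial)
    jp = (j + 1) % n_circ
    quads = np.column_stack([ring_ids[i, j], ring_ids[i, jp],
                             ring_ids[i + 1, jp], ring_ids[i + 1, j]])

    model = VesselModel(
        nodes=nodes,
        quads=quads,
        region_tags=np.array(["tube"] * len(quads)),
        boundary_loops={inlet_name: ring_ids[0].copy(),
                        outlet_name: ring_ids[-1].copy()},
        thickness=thickness,
        centerline=cl,
        structure={part_name: TubeStructure(ring_ids, cl.arclength.copy())},
        flags=flags,
    )
    return model


# ---------------------------------------------------------------------------
# aorta generation


def _aorta_centerline(cfg: AnatomyConfig, n_pts: int = 400) -> Centerline:
    """Candy-cane centerline: ascending (+z), arch semicircle in the x-z
    plane, descending (-z).  arch_radius_mm == 0 degenerates to a straight
    segment along +z."""
    la, ld, ra = cfg.asc_length_mm, cfg.desc_length_mm, cfg.arch_radius_mm
    arch_len = np.pi * ra
    total = la + arch_len + ld
    s = np.linspace(0.0, total, n_pts)
    pts = np.zeros((n_pts, 3))
    for k, sk in enumerate(s):
        if sk <= la or ra == 0.0:
            pts[k] = (0.0, 0.0, sk)
        elif sk <= la + arch_len:
            phi = np.pi - (sk - la) / ra     # pi -> 0
            pts[k] = (ra * (1.0 + np.cos(phi)), 0.0, la + ra * np.sin(phi))
        else:
            pts[k] = (2.0 * ra, 0.0, la - (sk - la - arch_len))
    prof = np.asarray(cfg.radius_profile, dtype=float)
    radii = np.interp(s / total, np.linspace(0, 1, len(prof)), prof)
    return Centerline(pts, radii, s)


def _branch_takeoff_arclengths(cfg: AnatomyConfig) -> list[float]:
    la, ra = cfg.asc_length_mm, cfg.arch_radius_mm
    return [la + f * np.pi * ra for f in cfg.branch_arch_fractions[:cfg.branch_count]]


def _smooth_radial_noise(rng: np.random.Generator, n_rings: int, n_circ: int,
                         amplitude: float) -> np.ndarray:
    """Band-limited random radial perturbation (a few Fourier modes)."""
    s = np.linspace(0, 2 * np.pi, n_rings)
    th = 2 * np.pi * np.arange(n_circ) / n_circ
    out = np.zeros((n_rings, n_circ))
    for ka in (1, 2):
        for kc in (0, 1, 2):
            amp = rng.normal(scale=amplitude / 3.0)
            pa, pc = rng.uniform(0, 2 * np.pi, size=2)
            out += amp * np.sin(ka * s / 2 + pa)[:, None] * np.cos(kc * th + pc)[None, :]
    return out


def generate_aorta(config: AnatomyConfig) -> VesselModel:
    """Generate a synthetic aorta shell mesh from a config.

    The main tube is tagged AAo / arch / DAo by element arclength; each
    supra-aortic branch is a separate lofted tube rooted on the arch surface
    (tagged ``branch_i``), with boundary loops named ``inlet``,
    ``outlet_DAo``, ``outlet_branch_i`` and ``branch_i_root``.  Branch
    junctions are not watertight stitched unions; the root loop is left as a
    named boundary loop.  Fully deterministic for a fixed seed.
    """
    cl = _aorta_centerline(config)
    rng = np.random.default_rng(config.seed)
    noise = None
    if config.noise_amplitude_mm > 0:
        noise = _smooth_radial_noise(rng, config.n_axial + 1,
                                     config.n_circumferential,
                                     config.noise_amplitude_mm)
    model = loft_surface(cl, config.n_circumferential, config.n_axial,
                         thickness=config.thickness_mm, radial_noise=noise,
                         part_name="main", inlet_name="inlet",
                         outlet_name="outlet_DAo")

    # region tags from element mid-arclength
    main = model.structure["main"]
    ring_s = main.arclength
    elem_ring = np.repeat(np.arange(config.n_axial), config.n_circumferential)
    mid_s = 0.5 * (ring_s[elem_ring] + ring_s[elem_ring + 1])
    la = config.asc_length_mm
    arch_end = la + np.pi * config.arch_radius_mm
    tags = np.where(mid_s < la, "AAo", np.where(mid_s < arch_end, "arch", "DAo"))
    if config.arch_radius_mm == 0.0:
        tags = np.where(mid_s < la, "AAo", "DAo")
    model.region_tags = tags.astype(object).astype(str)

    # branches
    for b, s_b in enumerate(_branch_takeoff_arclengths(config), start=1):
        r_b = float(config.branch_radii_mm[b - 1])
        c = cl.point_at(s_b)
        t = cl.tangent_at(s_b)
        up = np.array([0.0, 0.0, 1.0])
        n_hat = up - np.dot(up, t) * t
        nn = np.linalg.norm(n_hat)
        n_hat = np.array([0.0, 1.0, 0.0]) if nn < 1e-9 else n_hat / nn
        r_main = cl.radius_at(s_b)
        p0 = c + r_main * n_hat
        p1 = c + (r_main + config.branch_length_mm) * n_hat
        bcl = Centerline(np.array([p0, p1]), np.array([r_b, r_b]))
        btube = loft_surface(bcl, config.n_circumferential, config.branch_n_axial,
                             thickness=config.thickness_mm,
                             part_name=f"branch_{b}",
                             inlet_name=f"branch_{b}_root",
                             outlet_name=f"outlet_branch_{b}")
        offset = model.n_nodes
        bs = btube.structure[f"branch_{b}"]
        model.nodes = np.vstack([model.nodes, btube.nodes])
        model.quads = np.vstack([model.quads, btube.quads + offset])
        model.region_tags = np.concatenate(
            [model.region_tags, np.array([f"branch_{b}"] * btube.n_elements)])
        for name, loop in btube.boundary_loops.items():
            model.boundary_loops[name] = loop + offset
        model.structure[f"branch_{b}"] = TubeStructure(
            bs.rings + offset, bs.arclength.copy(),
            parent="main", attach_arclength=s_b)
    return model


def scale_uniform(model: VesselModel, factor: float) -> VesselModel:
    """Uniformly scale a model about its node centroid (growth adjustment).

    Topology, tags and loops are untouched; wall thickness is kept (it is a
    shell property, not a lumen dimension).
    """
    if factor <= 0:
        raise GeometryError("scale factor must be positive")
    out = model.copy()
    centroid = model.nodes.mean(axis=0)
    out.nodes = centroid + factor * (model.nodes - centroid)
    if out.centerline is not None:
        cl = out.centerline
        out.centerline = Centerline(centroid + factor * (cl.points - centroid),
                                    factor * cl.radii, factor * cl.arclength)
    for st in out.structure.values():
        st.arclength = factor * st.arclength
        if st.attach_arclength is not None:
            st.attach_arclength = factor * st.attach_arclength
    return out
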