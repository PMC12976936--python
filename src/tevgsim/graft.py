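"""Virtual resection and graft construction.

Places clamp/anastomosis planes perpendicular to the aortic centerline,
partitions the shell mesh into a native remnant and a resected segment,
lofts a replacement graft whose edge loops carry the same node counts as
the native cut loops (the equal-node suturing contract), and applies
controlled placement deviations.

Deviation semantics follow the virtual-study rules: L-R translations move
both the graft and the anastomosis plane (shifting the resection site);
A-P and I-S translations move only the graft; rotations (right-hand rule)
move both; size scaling is applied about the proximal anastomosis center so
it does not double as a translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .anatomy import (Centerline, GeometryError, TubeStructure, VesselModel)

AXIS_NAMES = ("L-R", "A-P", "I-S")


@dataclass
class CutPlane:
    """Oriented plane: origin on the centerline, normal along the local
    tangent, two in-plane axes completing a right-handed orthonormal triple
    (u x v = normal)."""

    origin: np.ndarray
    normal: np.ndarray
    in_plane_axes: np.ndarray            # (2, 3), rows u and v
    station_arclength: Optional[float] = None   # bookkeeping, mm

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        self.in_plane_axes = np.asarray(self.in_plane_axes, dtype=float).reshape(2, 3)
        triple = np.vstack([self.in_plane_axes, self.normal])
        if not np.allclose(triple @ triple.T, np.eye(3), atol=1e-9):
            raise GeometryError("plane axes and normal must be orthonormal")
        if np.dot(np.cross(self.in_plane_axes[0], self.in_plane_axes[1]),
                  self.normal) < 0:
            raise GeometryError("plane triple must be right-handed")

    @classmethod
    def from_origin_normal(cls, origin, normal, station_arclength=None) -> "CutPlane":
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
        ref = np.eye(3)[np.argmin(np.abs(n))]
        u = ref - np.dot(ref, n) * n
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return cls(origin, n, np.vstack([u, v]), station_arclength)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.origin) @ self.normal


@dataclass
class DeviationSpec:
    """Rigid + size perturbation of the graft relative to its designed pose.

    ``translation_mm`` along (L-R, A-P, I-S); ``rotation_deg`` about the same
    axes by the right-hand rule, composed intrinsically in that order;
    ``scale`` is the uniform size factor (scale < 1 = undersized graft).
    """

    translation_mm: Sequence[float] = (0.0, 0.0, 0.0)
    rotation_deg: Sequence[float] = (0.0, 0.0, 0.0)
    scale: float = 1.0

    def __post_init__(self):
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(3)
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float).reshape(3)
        if self.scale <= 0:
            raise GeometryError("deviation scale must be positive")

    @property
    def is_identity(self) -> bool:
        return (not self.translation_mm.any() and not self.rotation_deg.any()
                and self.scale == 1.0)

    def to_dict(self) -> dict:
        return {"translation_mm": self.translation_mm.tolist(),
                "rotation_deg": self.rotation_deg.tolist(),
                "scale": float(self.scale)}

    @classmethod
    def from_dict(cls, d: dict) -> "DeviationSpec":
        return cls(d.get("translation_mm", (0, 0, 0)),
                   d.get("rotation_deg", (0, 0, 0)), d.get("scale", 1.0))


@dataclass
class GraftModel:
    """Designed TEVG: a shell surface whose named edge loops mate with the
    native cut loops (equal node counts).  ``design_pose`` accumulates the
    affine transform applied since design (identity at design time)."""

    surface: VesselModel
    proximal_loop: str = "prox"
    distal_loop: str = "dist"
    branch_loop: Optional[str] = None
    design_pose: np.ndarray = field(default_factory=lambda: np.eye(4))

    def loop_names(self) -> list:
        names = [self.proximal_loop, self.distal_loop]
        if self.branch_loop:
            names.append(self.branch_loop)
        return names


# ---------------------------------------------------------------------------
# plane placement and resection


def _branch_parts(aorta: VesselModel) -> dict:
    return {k: v for k, v in aorta.structure.items() if v.parent == "main"}


def place_resection_planes(aorta: VesselModel, s_prox: float,
                           s_dist: float) -> tuple[CutPlane, CutPlane]:
    """Clamp/cut planes perpendicular to the centerline at two stations.

    Rejects stations outside the vessel and planes that would slice through
    a branch ostium (within one branch radius of a takeoff).
    """
    cl = aorta.centerline
    if cl is None:
        raise GeometryError("aorta has no centerline")
    if not (0.0 < s_prox < s_dist < cl.length):
        raise GeometryError("require 0 < s_prox < s_dist < total arclength")
    for name, st in _branch_parts(aorta).items():
        root = aorta.nodes[aorta.structure[name].rings[0]]
        r_branch = np.linalg.norm(root - root.mean(axis=0), axis=1).mean()
        for s in (s_prox, s_dist):
            if abs(st.attach_arclength - s) <= r_branch:
                raise GeometryError(
                    f"cut plane at s={s:.1f} mm intersects ostium of {name}")
    planes = tuple(
        CutPlane.from_origin_normal(cl.point_at(s), cl.tangent_at(s), s)
        for s in (s_prox, s_dist))
    return planes


def _plane_station(aorta: VesselModel, plane: CutPlane) -> float:
    if plane.station_arclength is not None:
        return float(plane.station_arclength)
    cl = aorta.centerline
    d = np.linalg.norm(cl.points - plane.origin, axis=1)
    return float(cl.arclength[np.argmin(d)])


def _extract_submodel(model: VesselModel, elem_mask: np.ndarray,
                      ring_slices: dict, new_loops: dict) -> VesselModel:
    """Compact the elements selected by ``elem_mask`` into a standalone
    model.  ``ring_slices``: part name -> (source part, ring index slice);
    ``new_loops``: loop name -> original node id array."""
    quads = model.quads[elem_mask]
    used = np.unique(quads)
    remap = -np.ones(model.n_nodes, dtype=int)
    remap[used] = np.arange(len(used))
    loops = {}
    for name, loop in model.boundary_loops.items():
        if np.all(np.isin(loop, used)):
            loops[name] = remap[loop]
    for name, loop in new_loops.items():
        loops[name] = remap[np.asarray(loop, dtype=int)]
    structure = {}
    for new_name, (src, sl) in ring_slices.items():
        st = model.structure[src]
        rings = st.rings[sl]
        if rings.size and np.all(np.isin(rings.ravel(), used)):
            structure[new_name] = TubeStructure(
                remap[rings], st.arclength[sl].copy(), st.parent,
                st.attach_arclength)
    return VesselModel(
        nodes=model.nodes[used].copy(),
        quads=remap[quads],
        region_tags=model.region_tags[elem_mask].copy(),
        boundary_loops=loops,
        thickness=model.thickness,
        centerline=None,
        structure=structure,
        flags=list(model.flags),
    )


def resect(aorta: VesselModel,
           planes: tuple[CutPlane, CutPlane]) -> tuple[VesselModel, VesselModel]:
    """Partition the aorta into (native remnant, resected segment).

    Cut-band re-meshing is done by projecting the mesh ring nearest each
    plane onto that plane, so element counts are conserved exactly and the
    mating loops on the two parts share the same node count by construction.
    Branches whose takeoff lies inside the resected interval are cut at half
    their length, leaving a native branch stump in the remnant (this yields
    the four-part implantation model: AAo, DAo, branch, graft).
    """
    if "main" not in aorta.structure:
        raise GeometryError("resect requires a structured main tube")
    model = aorta.copy()
    main = model.structure["main"]
    n_rings, n_circ = main.rings.shape
    p_prox, p_dist = planes
    s_cut = [_plane_station(model, p) for p in (p_prox, p_dist)]
    if s_cut[0] >= s_cut[1]:
        raise GeometryError("proximal plane must precede distal plane")
    idx = []
    for s, plane in zip(s_cut, (p_prox, p_dist)):
        i = int(np.argmin(np.abs(main.arclength - s)))
        if i <= 0 or i >= n_rings - 1:
            raise GeometryError("cut plane lies outside the mesh interior")
        ring_nodes = main.rings[i]
        d = plane.signed_distance(model.nodes[ring_nodes])
        model.nodes[ring_nodes] -= d[:, None] * plane.normal
        main.arclength[i] = s
        idx.append(i)
    i_p, i_d = idx
    if i_p >= i_d:
        raise GeometryError("resection interval collapsed to zero rings")

    elem_ring = np.full(model.n_elements, -1)
    n_main_elems = (n_rings - 1) * n_circ
    elem_ring[:n_main_elems] = np.repeat(np.arange(n_rings - 1), n_circ)
    resected_mask = (elem_ring >= i_p) & (elem_ring < i_d)

    rem_slices = {"AAo": ("main", slice(0, i_p + 1)),
                  "DAo": ("main", slice(i_d, n_rings))}
    res_slices = {"main": ("main", slice(i_p, i_d + 1))}
    rem_loops = {"cut_prox": main.rings[i_p], "cut_dist": main.rings[i_d]}
    res_loops = {"prox": main.rings[i_p], "dist": main.rings[i_d]}

    # branch assignment / cutting
    elem_part = np.array(["main"] * model.n_elements, dtype=object)
    for name, st in _branch_parts(model).items():
        part_elems = model.region_tags == name
        elem_part[part_elems] = name
        inside = s_cut[0] < st.attach_arclength < s_cut[1]
        nb = st.rings.shape[0]
        if inside:
            j = nb // 2
            br_ring = np.repeat(np.arange(nb - 1), n_circ)
            e_idx = np.where(part_elems)[0]
            resected_mask[e_idx[br_ring < j]] = True
            res_slices[name] = (name, slice(0, j + 1))
            rem_slices[name] = (name, slice(j, nb))
            res_loops[f"{name}_cut"] = st.rings[j]
            rem_loops[f"cut_{name}"] = st.rings[j]
        else:
            side_resected = False  # takeoff outside interval stays native
            if side_resected:
                resected_mask[part_elems] = True
            else:
                rem_slices[name] = (name, slice(0, nb))

    if not resected_mask.any():
        raise GeometryError("empty resected set")

    remnant = _extract_submodel(model, ~resected_mask, rem_slices, rem_loops)
    resected = _extract_submodel(model, resected_mask, res_slices, res_loops)
    remnant.centerline = model.centerline
    if model.centerline is not None:
        cl = model.centerline
        keep = (cl.arclength >= s_cut[0] - 1e-9) & (cl.arclength <= s_cut[1] + 1e-9)
        pts = cl.points[keep]
        rad = cl.radii[keep]
        if len(pts) >= 2:
            resected.centerline = Centerline(pts, rad)
    return remnant, resected


# ---------------------------------------------------------------------------
# graft construction


def design_graft(resected: VesselModel, diameter_scale: float = 1.0,
                 branched: bool = False,
                 native_remnant: Optional[VesselModel] = None) -> GraftModel:
    """Loft the replacement graft over the resected region.

    The graft reuses the resected segment's structured rings with every ring
    dilated radially about its own centroid by ``diameter_scale``, so the
    design centerline is preserved and loop node counts match the native cut
    loops.  ``branched`` keeps the branch stub (third loop) if the resected
    segment carries one.
    """
    if resected.n_elements == 0:
        raise GeometryError("resected segment is empty")
    if diameter_scale <= 0:
        raise GeometryError("diameter_scale must be positive")
    surf = resected.copy()
    branch_names = [n for n in surf.structure if n.startswith("branch")]
    branch_loop = None
    if branched:
        if not branch_names:
            raise GeometryError("branched graft requested but the resected "
                                "segment has no branch stub")
        branch_loop = f"{branch_names[0]}_cut"
    else:
        for name in branch_names:
            mask = surf.region_tags != name
            keep_loops = {k: v for k, v in surf.boundary_loops.items()
                          if not k.startswith(name) and k != f"{name}_cut"}
            surf = _extract_submodel(
                surf, mask,
                {k: (k, slice(None)) for k in surf.structure if k != name},
                {})
            surf.boundary_loops = {k: surf.boundary_loops[k]
                                   for k in keep_loops if k in surf.boundary_loops}
            surf.centerline = resected.centerline

    if diameter_scale != 1.0:
        for st in surf.structure.values():
            for ring in st.rings:
                c = surf.nodes[ring].mean(axis=0)
                surf.nodes[ring] = c + diameter_scale * (surf.nodes[ring] - c)
        if surf.centerline is not None:
            surf.centerline = Centerline(surf.centerline.points,
                                         diameter_scale * surf.centerline.radii,
                                         surf.centerline.arclength)

    surf.region_tags = np.where(
        np.char.startswith(surf.region_tags.astype(str), "branch"),
        "TEVG_branch", "TEVG").astype(object).astype(str)

    graft = GraftModel(surface=surf, proximal_loop="prox", distal_loop="dist",
                       branch_loop=branch_loop)
    if native_remnant is not None:
        mates = {"prox": "cut_prox", "dist": "cut_dist"}
        if branch_loop:
            mates[branch_loop] = "cut_" + branch_loop.replace("_cut", "")
        for g_loop, n_loop in mates.items():
            ng = len(surf.boundary_loops[g_loop])
            nn = len(native_remnant.boundary_loops[n_loop])
            if ng != nn:
                raise GeometryError(
                    f"equal-node contract violated on {g_loop}: {ng} vs {nn}")
    return graft


# ---------------------------------------------------------------------------
# deviations


def deviation_rotation(dev: DeviationSpec) -> np.ndarray:
    """Rotation matrix of a deviation: intrinsic rotations about L-R, then
    A-P, then I-S (right-hand rule)."""
    return Rotation.from_euler("XYZ", dev.rotation_deg, degrees=True).as_matrix()


def apply_deviation(graft: GraftModel, plane: CutPlane,
                    dev: DeviationSpec) -> tuple[GraftModel, CutPlane]:
    """Transform the graft (and, where applicable, the anastomosis plane).

    The graft is rotated about the proximal anastomosis-loop centroid,
    scaled uniformly about the same point, then translated.  The returned
    plane is co-transformed for rotations and for the L-R translation
    component only; A-P and I-S translation components leave the plane in
    place (they do not change the resection site).
    """
    if dev.is_identity:
        return graft, plane
    surf = graft.surface.copy()
    c = surf.nodes[surf.boundary_loops[graft.proximal_loop]].mean(axis=0)
    r = deviation_rotation(dev)
    t = dev.translation_mm
    s = dev.scale

    def xform(points):
        return c + s * ((points - c) @ r.T) + t

    surf.nodes = xform(surf.nodes)
    if surf.centerline is not None:
        cl = surf.centerline
        surf.centerline = Centerline(xform(cl.points), s * cl.radii,
                                     s * cl.arclength)
    for st in surf.structure.values():
        st.arclength = s * st.arclength

    t_lr = np.array([t[0], 0.0, 0.0])
    new_plane = CutPlane(
        origin=c + (plane.origin - c) @ r.T + t_lr,
        normal=plane.normal @ r.T,
        in_plane_axes=plane.in_plane_axes @ r.T,
        station_arclength=plane.station_arclength,
    )
    m = np.eye(4)
    m[:3, :3] = s * r
    m[:3, 3] = c - s * (r @ c) + t
    return (GraftModel(surface=surf, proximal_loop=graft.proximal_loop,
                       distal_loop=graft.distal_loop,
                       branch_loop=graft.branch_loop,
                       design_pose=m @ graft.design_pose),
            new_plane)


def sample_deviation_thresholds(observed: Sequence[DeviationSpec]) -> dict:
    """Per-axis deviation ranges: mean +- 2 x sample SD of the observations
    (the coverage rule used to bound the virtual sweeps)."""
    if len(observed) < 2:
        raise GeometryError("need at least 2 observations per axis")
    trans = np.array([d.translation_mm for d in observed])
    rot = np.array([d.rotation_deg for d in observed])
    scales = np.array([d.scale for d in observed])

    def rng(x):
        m, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        return (m - 2.0 * sd, m + 2.0 * sd)

    return {
        "translation_mm": {ax: rng(trans[:, k]) for k, ax in enumerate(AXIS_NAMES)},
        "rotation_deg": {ax: rng(rot[:, k]) for k, ax in enumerate(AXIS_NAMES)},
        "scale": rng(scales),
    }
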