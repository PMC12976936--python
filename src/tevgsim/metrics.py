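"""Placement and shape-agreement metrics.

Quantifies how far an implanted graft ended up from its designed pose
(rigid registration, anatomical-frame translation/rotation decomposition,
volume ratio) and how far two aortic surfaces are from each other
(Hausdorff and mean surface distance).

Conventions: the anatomical frame axes are the global patient axes
(+x = Left, +y = Anterior, +z = Superior) translated to the center of the
designed anastomosis plane.  Rotations are decomposed as intrinsic Euler
angles in the order L-R, then A-P, then I-S (right-hand rule); near gimbal
lock (middle angle at +-90 deg) the per-axis split is convention-dependent
and the report is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .anatomy import GeometryError, VesselModel

EULER_ORDER = "XYZ"  # intrinsic: L-R (x), then A-P (y), then I-S (z)


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise GeometryError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise GeometryError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal frame at the designed anastomosis center."""

    origin: np.ndarray
    axes: np.ndarray  # columns: L-R, A-P, I-S unit vectors

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=1e-9):
            raise GeometryError("frame axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise GeometryError("frame must be right-handed")


@dataclass
class DeviationReport:
    translation_mm: np.ndarray      # components along (L-R, A-P, I-S)
    rotation_deg: np.ndarray        # angles about (L-R, A-P, I-S)
    volume_ratio: float             # designed / postop
    gimbal_degenerate: bool = False

    def __post_init__(self):
        if self.volume_ratio <= 0:
            raise GeometryError("volume ratio must be positive")


@dataclass
class DistanceReport:
    hausdorff_mm: float
    mean_surface_distance_mm: float
    directed_max_ab: float
    directed_max_ba: float
    directed_mean_ab: float
    directed_mean_ba: float


# ---------------------------------------------------------------------------
# rigid registration


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    h = (source - sc).T @ (target - tc)
    u, sv, vt = np.linalg.svd(h)
    # degenerate if the points carry less than 2 independent directions
    scale = max(sv[0], 1e-30)
    if sv[1] / scale < 1e-9:
        raise GeometryError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, tc - r @ sc)


def register_rigid(source_points: np.ndarray, target_points: np.ndarray,
                   correspondence: str = "known",
                   initial: Optional[RigidTransform] = None,
                   max_iterations: int = 100,
                   tol_mm: float = 1e-6) -> RigidTransform:
    """Least-squares rigid alignment of source onto target.

    ``correspondence="known"`` solves the orthogonal Procrustes problem in
    closed form (Kabsch/SVD).  ``correspondence="unknown"`` runs
    iterative-closest-point refinement from ``initial`` (identity if omitted),
    converging when the mean closest-point distance changes by < ``tol_mm``.
    """
    source = np.asarray(source_points, dtype=float)
    target = np.asarray(target_points, dtype=float)
    if len(source) < 3 or len(target) < 3:
        raise GeometryError("need at least 3 points")
    if correspondence == "known":
        if len(source) != len(target):
            raise GeometryError("known correspondence requires equal counts")
        return _kabsch(source, target)
    if correspondence != "unknown":
        raise ValueError("correspondence must be 'known' or 'unknown'")

    transform = initial or RigidTransform.identity()
    tree = cKDTree(target)
    prev = np.inf
    for _ in range(max_iterations):
        moved = transform.apply(source)
        dist, idx = tree.query(moved)
        transform = _kabsch(source, target[idx])
        mean_d = float(dist.mean())
        if abs(prev - mean_d) < tol_mm:
            break
        prev = mean_d
    return transform


def build_frame(plane=None, patient_axes: Optional[np.ndarray] = None,
                loop_points: Optional[np.ndarray] = None) -> AnatomicalFrame:
    """Anatomical frame at the anastomosis center.

    The origin is the centroid of the anastomosis loop (``loop_points``) if
    given, else the plane origin; the axes are the global patient axes, not
    plane-aligned ones, because deviations are reported along anatomical
    directions.
    """
    if loop_points is not None:
        origin = np.asarray(loop_points, dtype=float).mean(axis=0)
    elif plane is not None:
        origin = np.asarray(plane.origin, dtype=float)
    else:
        raise GeometryError("provide a plane or loop points")
    axes = np.eye(3) if patient_axes is None else np.asarray(patient_axes, float)
    return AnatomicalFrame(origin, axes)


def decompose_deviation(transform: RigidTransform, frame: AnatomicalFrame,
                        designed_volume: float, postop_volume: float) -> DeviationReport:
    """Split a rigid motion into anatomical translation and rotation parts.

    Translation is the displacement of the frame origin under the transform,
    expressed along the frame axes.  Rotation angles are intrinsic Euler
    angles (L-R, A-P, I-S order) of the rotation expressed in the frame.
    """
    if designed_volume <= 0 or postop_volume <= 0:
        raise GeometryError("volumes must be positive")
    a = frame.axes
    disp = transform.apply(frame.origin) - frame.origin
    r_frame = a.T @ transform.rotation @ a
    gimbal = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        angles = Rotation.from_matrix(r_frame).as_euler(EULER_ORDER, degrees=True)
        gimbal = any("imbal" in str(w.message) for w in caught)
    return DeviationReport(translation_mm=a.T @ disp,
                           rotation_deg=np.asarray(angles),
                           volume_ratio=designed_volume / postop_volume,
                           gimbal_degenerate=gimbal)


# ---------------------------------------------------------------------------
# volume


def _cap_triangles(model: VesselModel) -> tuple[np.ndarray, np.ndarray]:
    """Planar cap fans over every boundary loop, oriented to close the
    outward-oriented shell.  Returns (extra_vertices, triangles into the
    concatenated [nodes, extra] array)."""
    tris = model.triangles()
    # directed boundary edges: appear in exactly one triangle
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    keys = edges[:, 0].astype(np.int64) * model.n_nodes + edges[:, 1]
    rkeys = edges[:, 1].astype(np.int64) * model.n_nodes + edges[:, 0]
    interior = np.isin(keys, rkeys)
    boundary = edges[~interior]

    extra, cap_tris = [], []
    loop_sets = {name: set(loop.tolist()) for name, loop in model.boundary_loops.items()}
    b_in_loop = {name: [] for name in loop_sets}
    for a, b in boundary:
        for name, s in loop_sets.items():
            if a in s and b in s:
                b_in_loop[name].append((a, b))
                break
    for k, (name, loop) in enumerate(model.boundary_loops.items()):
        c_id = model.n_nodes + k
        extra.append(model.nodes[loop].mean(axis=0))
        for a, b in b_in_loop[name]:
            cap_tris.append((c_id, b, a))  # reversed edge closes orientation
    if not extra:
        return np.zeros((0, 3)), tris
    return np.asarray(extra), np.vstack([tris, np.asarray(cap_tris, dtype=int)])


def enclosed_volume(surface: VesselModel) -> float:
    """Divergence-theorem volume of the shell closed by flat virtual caps on
    its boundary loops (the caps are not added to the mesh).  Rejects
    inconsistently oriented (non-orientable) input."""
    extra, tris = _cap_triangles(surface)
    verts = np.vstack([surface.nodes, extra])
    # orientability: every directed edge of the closed surface must be unique
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    keys = edges[:, 0].astype(np.int64) * len(verts) + edges[:, 1]
    if len(np.unique(keys)) != len(keys):
        raise GeometryError("surface is not consistently oriented")
    v = verts[tris]
    vol = np.einsum("ij,ij->", v[:, 0], np.cross(v[:, 1], v[:, 2])) / 6.0
    return abs(float(vol))


# ---------------------------------------------------------------------------
# surface distance


def _point_triangle_distance(points: np.ndarray, tri_v: np.ndarray) -> np.ndarray:
    """Exact distances between points[i] and triangles tri_v[i] (batched)."""
    a, b, c = tri_v[:, 0], tri_v[:, 1], tri_v[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        closest[m] = value[m]
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)                       # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)                      # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)                      # vertex C
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge AB
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge AC
    va = d3 * d6 - d5 * d4
    num = d4 - d3
    den = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(den != 0, num / den, 0.0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           b + w_bc[:, None] * (c - b))                    # edge BC
    denom = np.where(va + vb + vc != 0, va + vb + vc, 1.0)
    v_in = (vb / denom)[:, None]
    w_in = (vc / denom)[:, None]
    assign(np.ones(len(points), dtype=bool), a + v_in * ab + w_in * ac)  # face
    return np.linalg.norm(points - closest, axis=1)


def _points_to_surface(points: np.ndarray, surface: VesselModel,
                       n_candidates: int = 48) -> np.ndarray:
    """Point-to-triangle distances with a centroid KD-tree candidate
    prefilter (exact among the candidate set)."""
    tris = surface.triangles()
    tv = surface.nodes[tris]
    centroids = tv.mean(axis=1)
    k = min(n_candidates, len(tris))
    _, idx = cKDTree(centroids).query(points, k=k)
    idx = np.atleast_2d(idx.T).T if idx.ndim == 1 else idx
    best = np.full(len(points), np.inf)
    for col in range(idx.shape[1]):
        d = _point_triangle_distance(points, tv[idx[:, col]])
        best = np.minimum(best, d)
    return best


def surface_distance(a: VesselModel, b: VesselModel, n_samples: int = 10000,
                     seed: int = 0, mode: str = "sampled") -> DistanceReport:
    """Symmetric surface distances between two shell meshes.

    ``mode="sampled"``: seeded area-weighted point samples of each surface,
    distances measured point-to-triangle against the other surface.
    ``mode="vertex"``: exact point-to-point distances between the vertex
    sets (the brute-force-checkable variant).

    Hausdorff = max of the two directed maxima; the mean surface distance is
    the mean of the two directed means.
    """
    if a.n_elements == 0 or b.n_elements == 0:
        raise GeometryError("empty surface")
    if mode == "vertex":
        d_ab, _ = cKDTree(b.nodes).query(a.nodes)
        d_ba, _ = cKDTree(a.nodes).query(b.nodes)
    elif mode == "sampled":
        from trimesh.sample import sample_surface
        ta, tb = a.to_trimesh(), b.to_trimesh()
        pa, _ = sample_surface(ta, n_samples, seed=seed)
        pb, _ = sample_surface(tb, n_samples, seed=seed + 1)
        d_ab = _points_to_surface(np.asarray(pa), b)
        d_ba = _points_to_surface(np.asarray(pb), a)
    else:
        raise ValueError("mode must be 'sampled' or 'vertex'")
    return DistanceReport(
        hausdorff_mm=float(max(d_ab.max(), d_ba.max())),
        mean_surface_distance_mm=float(0.5 * (d_ab.mean() + d_ba.mean())),
        directed_max_ab=float(d_ab.max()),
        directed_max_ba=float(d_ba.max()),
        directed_mean_ab=float(d_ab.mean()),
        directed_mean_ba=float(d_ba.mean()),
    )
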