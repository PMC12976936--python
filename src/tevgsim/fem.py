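"""Hyperelastic membrane finite elements and anastomosis coupling.

The implantation is simulated as a static equilibrium of quadrilateral
membrane elements (4-node, 2x2 Gauss quadrature, no bending stiffness)
with an incompressible Yeoh strain-energy density

    W = C10 (I1 - 3) + C20 (I1 - 3)^2 + C30 (I1 - 3)^3

where I1 is the first invariant of the right Cauchy-Green tensor and the
thickness stretch is eliminated analytically through plane-stress
incompressibility, lam3 = 1/(lam1 lam2).

Suturing is modeled by node-to-node multi-point constraints: for each
paired (native, graft) edge node the native displacement is tied to the
graft displacement minus the initial gap,

    u_native = u_graft - (X_native - X_graft),

so paired nodes coincide exactly after deformation.  The constraints are
imposed by exact slave-DOF elimination (not penalties), with the gap offset
ramped linearly over the load steps; closure is therefore machine-precision.
Equilibrium at each step is found by damped Newton iteration on the total
strain energy with an analytic gradient and Hessian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .anatomy import GeometryError, VesselModel

logger = logging.getLogger(__name__)

_SQ3 = 1.0 / np.sqrt(3.0)
_GAUSS_PTS = [(-_SQ3, -_SQ3), (_SQ3, -_SQ3), (_SQ3, _SQ3), (-_SQ3, _SQ3)]
_XI_I = np.array([-1.0, 1.0, 1.0, -1.0])
_ETA_I = np.array([-1.0, -1.0, 1.0, 1.0])


def _shape_gradients() -> np.ndarray:
    """dN[g, n, a]: bilinear shape-function derivatives at the Gauss points."""
    dn = np.zeros((4, 4, 2))
    for g, (xi, eta) in enumerate(_GAUSS_PTS):
        dn[g, :, 0] = 0.25 * _XI_I * (1.0 + eta * _ETA_I)
        dn[g, :, 1] = 0.25 * _ETA_I * (1.0 + xi * _XI_I)
    return dn


_DN = _shape_gradients()


class FEMError(RuntimeError):
    pass


class ElementInversionError(FEMError):
    def __init__(self, element_id: int):
        super().__init__(f"element {element_id} inverted (non-positive metric)")
        self.element_id = element_id


# ---------------------------------------------------------------------------
# material


@dataclass
class YeohMaterial:
    """Yeoh coefficients (kPa), shell thickness (mm) and a global stiffness
    multiplier (the graft wall is modeled 2.5x stiffer than native tissue by
    scaling all coefficients).

    The default coefficients are configurable placeholders of the right
    order of magnitude for porcine thoracic aorta; they are not fitted
    values.
    """

    C10: float = 30.0
    C20: float = 150.0
    C30: float = 1000.0
    thickness: float = 1.5
    stiffness_multiplier: float = 1.0

    def __post_init__(self):
        if self.C10 <= 0:
            raise GeometryError("C10 must be positive")
        if self.thickness <= 0:
            raise GeometryError("thickness must be positive")
        if self.stiffness_multiplier <= 0:
            raise GeometryError("stiffness multiplier must be positive")

    def scaled(self, multiplier: float) -> "YeohMaterial":
        return YeohMaterial(self.C10, self.C20, self.C30, self.thickness,
                            self.stiffness_multiplier * multiplier)


def yeoh_energy_density(i1: float, mat: YeohMaterial, tol: float = 1e-9) -> float:
    """Strain-energy density W(I1) in kPa (stiffness multiplier applied)."""
    x = np.asarray(i1, dtype=float) - 3.0
    if np.any(x < -tol):
        raise GeometryError("I1 < 3 is not attainable for incompressible "
                            "membrane kinematics")
    x = np.maximum(x, 0.0)
    w = mat.C10 * x + mat.C20 * x ** 2 + mat.C30 * x ** 3
    return mat.stiffness_multiplier * w


def membrane_stress(lam1: float, lam2: float, mat: YeohMaterial) -> np.ndarray:
    """Principal Cauchy stresses (kPa) of the incompressible plane-stress
    membrane at principal stretches (lam1, lam2):
    sigma_i = 2 (lam_i^2 - lam3^2) dW/dI1, lam3 = 1/(lam1 lam2)."""
    lam1 = np.asarray(lam1, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)
    if np.any(lam1 <= 0) or np.any(lam2 <= 0):
        raise GeometryError("stretches must be positive")
    lam3sq = 1.0 / (lam1 * lam2) ** 2
    i1 = lam1 ** 2 + lam2 ** 2 + lam3sq
    x = i1 - 3.0
    wp = mat.stiffness_multiplier * (mat.C10 + 2.0 * mat.C20 * x
                                     + 3.0 * mat.C30 * x ** 2)
    return np.stack([2.0 * (lam1 ** 2 - lam3sq) * wp,
                     2.0 * (lam2 ** 2 - lam3sq) * wp], axis=-1)


# ---------------------------------------------------------------------------
# pairing and constraints


@dataclass
class NodePairing:
    """Bijective suture pairing between a graft edge loop and a native edge
    loop (equal cardinality)."""

    pairs: np.ndarray                # (k, 2) int: (graft_node_id, native_node_id)
    loop_name: str = ""
    cyclic_offset: int = 0
    orientation: int = 1             # +1 same winding, -1 reversed
    total_angle: float = 0.0         # summed angular mismatch, radians

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int)
        for col in (0, 1):
            if len(np.unique(self.pairs[:, col])) != len(self.pairs):
                raise GeometryError("pairing must be bijective")


def _loop_angle_cost(gdir: np.ndarray, ndir: np.ndarray) -> float:
    dots = np.clip(np.einsum("ij,ij->i", gdir, ndir), -1.0, 1.0)
    return float(np.arccos(dots).sum())


def pair_nodes(graft_loop: Sequence[int], native_loop: Sequence[int],
               graft_coords: np.ndarray, native_coords: np.ndarray,
               loop_name: str = "") -> NodePairing:
    """Pair the nodes of two closed edge loops for suturing.

    For every cyclic offset and both winding orientations, the candidate
    bijection's cost is the summed angle between the loop-centroid direction
    vectors of matched nodes; the minimizing assignment is returned (ties
    broken by smallest offset, same-winding first).
    """
    g_ids = np.asarray(graft_loop, dtype=int)
    n_ids = np.asarray(native_loop, dtype=int)
    if len(g_ids) != len(n_ids):
        raise GeometryError("anastomosis loops must carry an equal number "
                            "of nodes")
    k = len(g_ids)
    gp = np.asarray(graft_coords, dtype=float)[g_ids]
    npts = np.asarray(native_coords, dtype=float)[n_ids]

    def unit_dirs(pts):
        d = pts - pts.mean(axis=0)
        norms = np.linalg.norm(d, axis=1)
        if np.any(norms < 1e-12):
            raise GeometryError("loop node coincides with loop centroid")
        return d / norms[:, None]

    gdir, ndir = unit_dirs(gp), unit_dirs(npts)
    best = None
    for orientation in (1, -1):
        nd = ndir if orientation == 1 else ndir[::-1]
        nid = n_ids if orientation == 1 else n_ids[::-1]
        for off in range(k):
            cost = _loop_angle_cost(gdir, np.roll(nd, -off, axis=0))
            if best is None or cost < best[0] - 1e-12:
                best = (cost, off, orientation,
                        np.column_stack([g_ids, np.roll(nid, -off)]))
    cost, off, orientation, pairs = best
    return NodePairing(pairs=pairs, loop_name=loop_name, cyclic_offset=off,
                       orientation=orientation, total_angle=cost)


@dataclass
class MPCConstraint:
    """One suture constraint: u_slave = u_master + offset, with
    offset = -(X_native - X_graft) so final positions coincide."""

    slave_node: int      # native node
    master_node: int     # graft node
    offset: np.ndarray   # (3,) mm

    def __post_init__(self):
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.offset)):
            raise GeometryError("MPC offset must be finite")
        if self.slave_node == self.master_node:
            raise GeometryError("MPC slave and master must differ")


def build_mpcs(pairing: NodePairing, nodes: np.ndarray) -> list:
    """One constraint per suture pair against a shared node array."""
    nodes = np.asarray(nodes, dtype=float)
    out = []
    for g, n in pairing.pairs:
        out.append(MPCConstraint(slave_node=int(n), master_node=int(g),
                                 offset=-(nodes[n] - nodes[g])))
    return out


# ---------------------------------------------------------------------------
# assembly


@dataclass
class FEAssembly:
    """A meshed implantation scenario ready to solve.

    ``model`` holds every part (native remnant pieces and graft) in one node
    array; ``materials`` maps each region tag to its wall model;
    ``constraints`` are the suture MPCs; ``fixed_nodes`` get zero
    displacement (vessel tethering).
    """

    model: VesselModel
    materials: dict
    constraints: list
    fixed_nodes: np.ndarray
    load_steps: int = 10
    residual_rtol: float = 1e-8
    increment_tol_mm: float = 1e-10
    max_newton_iterations: int = 50
    # Weak edge-spring regularization standing in for the wall's neglected
    # bending rigidity; stabilizes compressive wrinkling modes.  Expressed
    # as a fraction of the local membrane stiffness C10 * thickness.
    stabilization: float = 0.1

    def __post_init__(self):
        self.fixed_nodes = np.unique(np.asarray(self.fixed_nodes, dtype=int))
        n = self.model.n_nodes
        if self.load_steps < 1:
            raise GeometryError("need at least one load step")
        if len(self.fixed_nodes) == 0:
            raise GeometryError("at least one fixed node is required")
        if self.fixed_nodes.min() < 0 or self.fixed_nodes.max() >= n:
            raise GeometryError("fixed node out of range")
        slaves = [c.slave_node for c in self.constraints]
        if len(set(slaves)) != len(slaves):
            raise GeometryError("a node may be slave of only one constraint")
        for c in self.constraints:
            if c.slave_node >= n or c.master_node >= n:
                raise GeometryError("constrained node out of range")
        missing = set(self.model.region_tags) - set(self.materials)
        if missing:
            raise GeometryError(f"no material for regions {sorted(missing)}")

    def region_parts(self) -> list:
        return sorted(set(self.model.region_tags))


@dataclass
class SolveReport:
    deformed: VesselModel
    max_pair_gap: float
    newton_iterations: list
    converged: bool
    strain_energy: float                 # mJ
    step_energies: list = field(default_factory=list)   # mJ per load step
    energy_by_region: dict = field(default_factory=dict)  # mJ
    displacement: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)


class _MembraneKernel:
    """Vectorized energy/gradient/Hessian of the assembled membrane."""

    def __init__(self, assembly: FEAssembly):
        model = assembly.model
        self.quads = model.quads
        self.X = model.nodes[self.quads]                     # (E,4,3)
        e = len(self.quads)
        c10 = np.empty(e)
        c20 = np.empty(e)
        c30 = np.empty(e)
        thick = np.empty(e)
        for tag, mat in assembly.materials.items():
            m = model.region_tags == tag
            mult = mat.stiffness_multiplier
            c10[m], c20[m], c30[m] = mult * mat.C10, mult * mat.C20, mult * mat.C30
            thick[m] = mat.thickness
        self.c10, self.c20, self.c30 = c10, c20, c30
        self.region_tags = model.region_tags

        # reference metric per Gauss point
        self.a_ref = np.einsum("gna,enk->egak", _DN, self.X)     # (E,4,2,3)
        amet = np.einsum("egak,egbk->egab", self.a_ref, self.a_ref)
        det_a = amet[..., 0, 0] * amet[..., 1, 1] - amet[..., 0, 1] * amet[..., 1, 0]
        if np.any(det_a <= 0):
            raise ElementInversionError(int(np.argwhere(det_a <= 0)[0][0]))
        self.ref_inv = self._inv22(amet, det_a)
        self.det_ref = det_a
        self.darea = np.sqrt(det_a) * thick[:, None]             # (E,4) weight*1

        # sparse assembly index pattern (12x12 per element)
        dof = (3 * self.quads[:, :, None] + np.arange(3)).reshape(e, 12)
        self.h_rows = np.repeat(dof, 12, axis=1).ravel()
        self.h_cols = np.tile(dof, (1, 12)).ravel()
        self.n_dof = 3 * model.n_nodes
        self.k_stab = self._stabilization_matrix(assembly, thick)

    def _stabilization_matrix(self, assembly: FEAssembly,
                              thick: np.ndarray) -> sp.csr_matrix:
        """Graph-Laplacian edge springs, k_e = stabilization * C10 * t,
        acting on relative nodal displacements (bending surrogate)."""
        factor = assembly.stabilization
        if factor <= 0:
            return sp.csr_matrix((self.n_dof, self.n_dof))
        q = self.quads
        k_elem = factor * self.c10 * thick          # kPa*mm per edge
        rows, cols, vals = [], [], []
        for a, b in ((0, 1), (1, 2), (2, 3), (3, 0)):
            for k in range(3):
                ia, ib = 3 * q[:, a] + k, 3 * q[:, b] + k
                rows += [ia, ib, ia, ib]
                cols += [ia, ib, ib, ia]
                vals += [k_elem, k_elem, -k_elem, -k_elem]
        mat = sp.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_dof, self.n_dof))
        return mat.tocsr()

    @staticmethod
    def _inv22(m: np.ndarray, det: np.ndarray) -> np.ndarray:
        inv = np.empty_like(m)
        inv[..., 0, 0] = m[..., 1, 1]
        inv[..., 1, 1] = m[..., 0, 0]
        inv[..., 0, 1] = -m[..., 0, 1]
        inv[..., 1, 0] = -m[..., 1, 0]
        return inv / det[..., None, None]

    def _state(self, u_full: np.ndarray):
        x = self.X + u_full.reshape(-1, 3)[self.quads]
        a_cur = np.einsum("gna,enk->egak", _DN, x)               # (E,4,2,3)
        amet = np.einsum("egak,egbk->egab", a_cur, a_cur)
        det_c = amet[..., 0, 0] * amet[..., 1, 1] - amet[..., 0, 1] * amet[..., 1, 0]
        return a_cur, amet, det_c

    def energy(self, u_full: np.ndarray, per_region: bool = False):
        _, amet, det_c = self._state(u_full)
        if np.any(det_c <= 0):
            return (np.inf, {}) if per_region else np.inf
        j2 = det_c / self.det_ref
        i1 = np.einsum("egab,egab->eg", self.ref_inv, amet) + 1.0 / j2
        xg = i1 - 3.0
        w = (self.c10[:, None] * xg + self.c20[:, None] * xg ** 2
             + self.c30[:, None] * xg ** 3)
        e_elem = (w * self.darea).sum(axis=1)
        e_stab = 0.5 * float(u_full @ (self.k_stab @ u_full))
        total = float(e_elem.sum()) + e_stab
        if not per_region:
            return total
        by_region = {str(tag): float(e_elem[self.region_tags == tag].sum())
                     for tag in np.unique(self.region_tags)}
        by_region["_stabilization"] = e_stab
        return total, by_region

    def gradient(self, u_full: np.ndarray) -> np.ndarray:
        a_cur, amet, det_c = self._state(u_full)
        if np.any(det_c <= 0):
            raise ElementInversionError(int(np.argwhere(det_c <= 0)[0][0]))
        j2 = det_c / self.det_ref
        cur_inv = self._inv22(amet, det_c)
        i1 = np.einsum("egab,egab->eg", self.ref_inv, amet) + 1.0 / j2
        xg = i1 - 3.0
        wp = (self.c10[:, None] + 2.0 * self.c20[:, None] * xg
              + 3.0 * self.c30[:, None] * xg ** 2)
        s = self.ref_inv - cur_inv / j2[..., None, None]
        ge = 2.0 * np.einsum("eg,egab,gna,egbk->enk",
                             wp * self.darea, s, _DN, a_cur)
        grad = np.zeros(self.n_dof)
        np.add.at(grad, (3 * self.quads[:, :, None] + np.arange(3)).ravel(),
                  ge.ravel())
        return grad + self.k_stab @ u_full

    def hessian(self, u_full: np.ndarray) -> sp.csr_matrix:
        a_cur, amet, det_c = self._state(u_full)
        if np.any(det_c <= 0):
            raise ElementInversionError(int(np.argwhere(det_c <= 0)[0][0]))
        j2 = det_c / self.det_ref
        cur_inv = self._inv22(amet, det_c)
        i1 = np.einsum("egab,egab->eg", self.ref_inv, amet) + 1.0 / j2
        xg = i1 - 3.0
        wp = (self.c10[:, None] + 2.0 * self.c20[:, None] * xg
              + 3.0 * self.c30[:, None] * xg ** 2)
        wpp = 2.0 * self.c20[:, None] + 6.0 * self.c30[:, None] * xg
        s = self.ref_inv - cur_inv / j2[..., None, None]

        e = len(self.quads)
        h = np.zeros((e, 4, 3, 4, 3))
        for g in range(4):
            dn = _DN[g]                                   # (4,2)
            ac = a_cur[:, g]                              # (E,2,3)
            sg = s[:, g]                                  # (E,2,2)
            ci = cur_inv[:, g]
            da = self.darea[:, g]                         # (E,)
            wpg, wppg = wp[:, g], wpp[:, g]
            j2g = j2[:, g]

            p = np.einsum("eab,na,ebk->enk", sg, dn, ac)  # (E,4,3)
            # material part: 4 Wpp dA P x P
            h += 4.0 * (wppg * da)[:, None, None, None, None] * \
                np.einsum("enk,eml->enkml", p, p)
            # geometric part 1: 2 Wp dA (S_ab dN_na dN_mb) delta_kl
            geo = np.einsum("eab,na,mb->enm", sg, dn, dn)
            h += 2.0 * (wpg * da)[:, None, None, None, None] * \
                np.einsum("enm,kl->enkml", geo, np.eye(3))
            # geometric part 2: variation of S through the current metric
            t2 = (np.einsum("mc,edl->emlcd", dn, ac)
                  + np.einsum("md,ecl->emlcd", dn, ac))   # (E,4,3,2,2)
            tr1 = np.einsum("ecd,emlcd->eml", ci, t2)
            ama = np.einsum("eac,emlcd,edb->emlab", ci, t2, ci)
            ds = (np.einsum("eab,eml->emlab", ci, tr1) + ama) / \
                j2g[:, None, None, None, None]
            h += 2.0 * (wpg * da)[:, None, None, None, None] * \
                np.einsum("emlab,na,ebk->enkml", ds, dn, ac)

        vals = h.reshape(e, 12, 12).ravel()
        mat = sp.coo_matrix((vals, (self.h_rows, self.h_cols)),
                            shape=(self.n_dof, self.n_dof))
        return mat.tocsr() + self.k_stab


def _reduction_operator(assembly: FEAssembly):
    """Build T and d such that u_full = T @ u_red + alpha * d.

    Free DOFs are all except fixed nodes and constraint slaves; slave rows
    copy their master's column and carry the ramped gap offset in d."""
    n = assembly.model.n_nodes
    fixed = set(assembly.fixed_nodes.tolist())
    slaves = {c.slave_node: c for c in assembly.constraints}
    for s in slaves:
        if s in fixed:
            raise GeometryError(f"node {s} is both fixed and a slave")
    free_nodes = [i for i in range(n) if i not in fixed and i not in slaves]
    col_of = {node: j for j, node in enumerate(free_nodes)}

    rows, cols, vals = [], [], []
    d = np.zeros(3 * n)
    free_rows = np.empty(3 * len(free_nodes), dtype=int)
    for node, j in col_of.items():
        for k in range(3):
            rows.append(3 * node + k)
            cols.append(3 * j + k)
            vals.append(1.0)
            free_rows[3 * j + k] = 3 * node + k
    for s_node, c in slaves.items():
        m_node = c.master_node
        if m_node in slaves:
            raise GeometryError("chained MPCs are not supported")
        d[3 * s_node:3 * s_node + 3] = c.offset
        if m_node in fixed:
            continue
        jm = col_of[m_node]
        for k in range(3):
            rows.append(3 * s_node + k)
            cols.append(3 * jm + k)
            vals.append(1.0)
    t = sp.coo_matrix((vals, (rows, cols)),
                      shape=(3 * n, 3 * len(free_nodes))).tocsr()
    return t, d, free_rows


def max_pair_gap(assembly: FEAssembly, u_full: np.ndarray) -> float:
    """Largest residual distance between paired nodes in the deformed state."""
    if not assembly.constraints:
        return 0.0
    x = assembly.model.nodes + u_full.reshape(-1, 3)
    gaps = [np.linalg.norm(x[c.slave_node] - x[c.master_node])
            for c in assembly.constraints]
    return float(max(gaps))


def solve_implantation(assembly: FEAssembly,
                       initial_displacement: Optional[np.ndarray] = None
                       ) -> SolveReport:
    """Quasi-static anastomosis solve.

    The suture gap offsets are ramped linearly over ``load_steps``; each step
    is equilibrated by damped Newton iteration (analytic gradient and
    Hessian on the reduced, constraint-eliminated DOF set) with an energy
    line search and adaptive Tikhonov damping for indefinite states.

    ``initial_displacement`` (full (N, 3) field, e.g. from a neighbouring
    case) warm-starts the free DOFs; with ``load_steps=1`` this turns the
    solve into a cheap continuation step.
    """
    kern = _MembraneKernel(assembly)
    t_op, d_vec, free_rows = _reduction_operator(assembly)
    n_red = t_op.shape[1]
    u_red = np.zeros(n_red)
    if initial_displacement is not None:
        u0 = np.asarray(initial_displacement, dtype=float).reshape(-1)
        if u0.shape[0] != 3 * assembly.model.n_nodes:
            raise GeometryError("initial displacement has wrong size")
        u_red = u0[free_rows].copy()
    iterations, step_energies = [], []
    converged_all = True
    diagnostics = {}

    for step in range(1, assembly.load_steps + 1):
        alpha = step / assembly.load_steps
        g_vec = alpha * d_vec

        def full(ur):
            return t_op @ ur + g_vec

        r0 = None
        damping = 0.0
        step_converged = False
        n_iter = 0
        for it in range(1, assembly.max_newton_iterations + 1):
            n_iter = it
            grad_full = kern.gradient(full(u_red))
            r = t_op.T @ grad_full
            rnorm = float(np.linalg.norm(r))
            if r0 is None:
                r0 = rnorm
            if rnorm <= max(assembly.residual_rtol * r0, 1e-12):
                step_converged = True
                break
            h_full = kern.hessian(full(u_red))
            h_red = (t_op.T @ h_full @ t_op).tocsc()
            e_now = kern.energy(full(u_red))
            accepted = False
            for _attempt in range(12):
                h_try = h_red if damping == 0.0 else \
                    h_red + damping * sp.identity(n_red, format="csc")
                try:
                    delta = spla.spsolve(h_try, -r)
                except Exception:
                    delta = None
                if delta is not None and np.all(np.isfinite(delta)):
                    beta = 1.0
                    for _ls in range(10):
                        e_new = kern.energy(full(u_red + beta * delta))
                        if e_new <= e_now + 1e-10 * (abs(e_now) + 1.0):
                            u_red = u_red + beta * delta
                            accepted = True
                            break
                        beta *= 0.5
                if accepted:
                    damping = max(damping / 10.0, 0.0) if damping > 1e-8 else 0.0
                    break
                damping = 10.0 * damping if damping > 0 else 1e-4 * \
                    max(abs(h_red.diagonal()).max(), 1.0)
            if not accepted:
                break
            if float(np.linalg.norm(delta) * beta) < assembly.increment_tol_mm:
                # stalled at displacement resolution: accept the state
                step_converged = True
                n_iter += 1
                break
        iterations.append(n_iter)
        e_step = kern.energy(full(u_red))
        step_energies.append(e_step * 1e-3)  # kPa*mm^3 (uJ) -> mJ
        logger.debug("load step %d/%d: %d Newton iterations, energy %.6g mJ",
                     step, assembly.load_steps, n_iter, e_step * 1e-3)
        if not step_converged:
            converged_all = False
            diagnostics = {"failed_step": step,
                           "residual": float(np.linalg.norm(r)),
                           "initial_residual": r0}
            logger.warning("Newton did not converge at load step %d "
                           "(residual %.3g)", step, diagnostics["residual"])
            break

    u_full = t_op @ u_red + alpha * d_vec
    total_e, by_region = kern.energy(u_full, per_region=True)
    membrane_e = total_e - by_region.get("_stabilization", 0.0)

    deformed = assembly.model.copy()
    deformed.nodes = assembly.model.nodes + u_full.reshape(-1, 3)
    gap = max_pair_gap(assembly, u_full)
    return SolveReport(
        deformed=deformed,
        max_pair_gap=gap,
        newton_iterations=iterations,
        converged=converged_all,
        strain_energy=membrane_e * 1e-3,
        step_energies=step_energies,
        energy_by_region={k: v * 1e-3 for k, v in by_region.items()},
        displacement=u_full.reshape(-1, 3),
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# implantation assembly construction


def assemble_implant(remnant: VesselModel, graft, materials: dict,
                     load_steps: int = 10,
                     graft_fixation: str = "edges") -> FEAssembly:
    """Merge a native remnant and a graft into one constrained assembly.

    Native cut loops are paired with the graft's mating loops (minimum
    angular mismatch); native edge nodes become MPC slaves of their graft
    masters.  All non-cut native boundary loops (inlet, distal outlets) are
    fixed, mimicking tethering of the aorta to surrounding tissue.
    ``materials`` maps region tags of both parts to their wall models.

    ``graft_fixation="edges"`` (default) additionally holds the graft's
    sutured edge nodes at their placed positions, so the suture constraints
    prescribe the native edge displacements: the graft stays where it was
    implanted and the (more compliant) native tissue accommodates.  Without
    this, a rigidly misplaced free graft would simply slide back to its
    designed pose at equilibrium and every rigid deviation would relax
    away.  ``graft_fixation="free"`` keeps the symmetric coupling (both
    sides share the gap closure), which is the right setting for studying
    the suture mechanics itself.
    """
    surf = graft.surface
    offset = remnant.n_nodes
    nodes = np.vstack([remnant.nodes, surf.nodes])
    quads = np.vstack([remnant.quads, surf.quads + offset])
    tags = np.concatenate([remnant.region_tags, surf.region_tags])
    loops = {f"native:{k}": v for k, v in remnant.boundary_loops.items()}
    loops.update({f"graft:{k}": v + offset for k, v in surf.boundary_loops.items()})
    from .anatomy import TubeStructure
    structure = {f"native:{k}": TubeStructure(v.rings.copy(), v.arclength.copy(),
                                              v.parent, v.attach_arclength)
                 for k, v in remnant.structure.items()}
    structure.update({
        f"graft:{k}": TubeStructure(v.rings + offset, v.arclength.copy(),
                                    v.parent, v.attach_arclength)
        for k, v in surf.structure.items()})
    merged = VesselModel(nodes=nodes, quads=quads, region_tags=tags,
                         boundary_loops=loops, thickness=remnant.thickness,
                         structure=structure)

    mates = [("cut_prox", graft.proximal_loop), ("cut_dist", graft.distal_loop)]
    if graft.branch_loop is not None:
        native_branch = "cut_" + graft.branch_loop.replace("_cut", "")
        mates.append((native_branch, graft.branch_loop))
    constraints = []
    for native_name, graft_name in mates:
        n_loop = loops[f"native:{native_name}"]
        g_loop = loops[f"graft:{graft_name}"]
        pairing = pair_nodes(g_loop, n_loop, nodes, nodes, loop_name=graft_name)
        constraints.extend(build_mpcs(pairing, nodes))

    cut_names = {f"native:{n}" for n, _ in mates}
    fixed_sets = [v for k, v in loops.items()
                  if k.startswith("native:") and k not in cut_names]
    if graft_fixation == "edges":
        fixed_sets += [loops[f"graft:{g}"] for _, g in mates]
    elif graft_fixation != "free":
        raise ValueError("graft_fixation must be 'edges' or 'free'")
    return FEAssembly(model=merged, materials=materials,
                      constraints=constraints,
                      fixed_nodes=np.concatenate(fixed_sets),
                      load_steps=load_steps)
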