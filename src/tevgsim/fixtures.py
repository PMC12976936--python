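"""Canonical synthetic benchmark fixtures.

Small, fully parametric scenarios used throughout the test suite and the
reproduction script: a straight-cylinder vessel, the classic two-coaxial-
cylinder anastomosis gap problem, and a reduced-size implantation study
case.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .anatomy import AnatomyConfig, Centerline, VesselModel, generate_aorta, loft_surface
from .fem import FEAssembly, YeohMaterial, build_mpcs, pair_nodes


def straight_cylinder(radius: float = 10.0, length: float = 100.0,
                      n_circ: int = 32, n_axial: int = 40,
                      branch_count: int = 0) -> VesselModel:
    """Straight-tube vessel along +z (zero arch curvature)."""
    cfg = AnatomyConfig(arch_radius_mm=0.0, radius_profile=(radius,),
                        asc_length_mm=0.4 * length,
                        desc_length_mm=0.6 * length,
                        branch_count=branch_count,
                        n_circumferential=n_circ, n_axial=n_axial)
    return generate_aorta(cfg)


def two_cylinder_assembly(gap: float = 2.0, radius: float = 10.0,
                          length: float = 30.0, n_circ: int = 16,
                          n_axial: int = 8,
                          native_material: Optional[YeohMaterial] = None,
                          graft_multiplier: float = 2.5,
                          load_steps: int = 10,
                          axis: np.ndarray = (0.0, 0.0, 1.0)) -> FEAssembly:
    """Two coaxial open cylinders separated by an axial gap, sutured by MPCs
    across the gap, outer ends fixed.  The canonical anastomosis mechanics
    problem: a converged solve must close every paired-node gap exactly.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    mat = native_material or YeohMaterial()

    def tube(z0, part, name_in, name_out):
        cl = Centerline(np.array([z0 * axis, (z0 + length) * axis]),
                        np.array([radius, radius]))
        return loft_surface(cl, n_circ, n_axial, thickness=mat.thickness,
                            part_name=part, inlet_name=name_in,
                            outlet_name=name_out)

    native = tube(0.0, "native", "fixed_native", "cut")
    graft = tube(length + gap, "graft", "prox", "fixed_graft")
    off = native.n_nodes
    nodes = np.vstack([native.nodes, graft.nodes])
    quads = np.vstack([native.quads, graft.quads + off])
    tags = np.array(["native"] * native.n_elements
                    + ["graft"] * graft.n_elements)
    loops = {"fixed_native": native.boundary_loops["fixed_native"],
             "cut": native.boundary_loops["cut"],
             "prox": graft.boundary_loops["prox"] + off,
             "fixed_graft": graft.boundary_loops["fixed_graft"] + off}
    from .anatomy import TubeStructure
    structure = {"native": native.structure["native"]}
    gs = graft.structure["graft"]
    structure["graft"] = TubeStructure(gs.rings + off, gs.arclength.copy())
    model = VesselModel(nodes=nodes, quads=quads, region_tags=tags,
                        boundary_loops=loops, thickness=mat.thickness,
                        structure=structure)
    pairing = pair_nodes(loops["prox"], loops["cut"], nodes, nodes,
                         loop_name="anastomosis")
    constraints = build_mpcs(pairing, nodes)
    fixed = np.concatenate([loops["fixed_native"], loops["fixed_graft"]])
    return FEAssembly(model=model,
                      materials={"native": mat,
                                 "graft": mat.scaled(graft_multiplier)},
                      constraints=constraints, fixed_nodes=fixed,
                      load_steps=load_steps)


def small_study_case(**overrides):
    """Reduced-mesh branched implantation case for fast tests."""
    from .pipeline import build_study_case

    anatomy = overrides.pop("anatomy", None) or AnatomyConfig(
        radius_profile=(8.0, 6.0), n_axial=32, branch_n_axial=8)
    return build_study_case(anatomy=anatomy, **overrides)


def narrowed_cylinder(radius: float = 10.0, dip_radius: float = 6.0,
                      length: float = 100.0, n_circ: int = 32,
                      n_axial: int = 100) -> VesselModel:
    """Straight tube with a smooth mid-length narrowing (cosine dip over
    the central 30% of the length)."""
    n_pts = 201
    s = np.linspace(0.0, length, n_pts)
    radii = np.full(n_pts, radius)
    half_w = 0.15 * length
    mask = np.abs(s - length / 2) < half_w
    radii[mask] = radius - (radius - dip_radius) * 0.5 * (
        1.0 + np.cos(np.pi * (s[mask] - length / 2) / half_w))
    pts = np.column_stack([np.zeros(n_pts), np.zeros(n_pts), s])
    cl = Centerline(pts, radii, s)
    return loft_surface(cl, n_circ, n_axial)
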