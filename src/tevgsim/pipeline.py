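"""End-to-end virtual implantation studies and tolerance mapping.

Builds a baseline case (synthetic aorta -> resection -> graft design),
sweeps placement deviations one factor at a time (1-mm translations,
5-degree rotations, 5% size steps), runs the implantation FE solve and the
0-D hemodynamic surrogate for every grid point, converts the metrics to
percentage differences from baseline, classifies hemodynamic safety
(PSPD < 20 mmHg, 0.4 Pa < TAWSS < 15 Pa), and extracts the per-direction
allowable deviation ranges (the contiguous safe interval containing the
designed pose).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .anatomy import AnatomyConfig, GeometryError, VesselModel, generate_aorta
from .fem import (FEAssembly, SolveReport, YeohMaterial, assemble_implant,
                  solve_implantation)
from .graft import (AXIS_NAMES, CutPlane, DeviationSpec, GraftModel,
                    apply_deviation, design_graft, place_resection_planes,
                    resect)
from .hemo import (BloodProperties, FlowWaveform, WindkesselParams,
                   build_network, compute_pspd, compute_tawss,
                   extract_lumen_profile, simulate, tawss_field_min)
from .metrics import DistanceReport, surface_distance

logger = logging.getLogger(__name__)


def percent_diff(value: float, baseline: float) -> float:
    """Percentage difference 100 * (value - baseline) / baseline."""
    if baseline == 0:
        raise GeometryError("percent difference undefined for zero baseline")
    return 100.0 * (value - baseline) / baseline


@dataclass
class SafeLimits:
    """Hemodynamically safe limits: PSPD below ``pspd_max`` and every
    station TAWSS strictly inside (tawss_min, tawss_max)."""

    pspd_max: float = 20.0    # mmHg; above: stenosis / reintervention marker
    tawss_min: float = 0.4    # Pa; below: atherosclerosis susceptibility
    tawss_max: float = 15.0   # Pa; above: thrombosis risk

    def __post_init__(self):
        if not (0 < self.tawss_min < self.tawss_max):
            raise GeometryError("need 0 < tawss_min < tawss_max")
        if self.pspd_max <= 0:
            raise GeometryError("pspd_max must be positive")


def classify_safe(pspd: float, tawss_max: float, tawss_min: float,
                  limits: SafeLimits) -> bool:
    """Strict-inequality safety test of one simulated case."""
    return (pspd < limits.pspd_max
            and tawss_min > limits.tawss_min
            and tawss_max < limits.tawss_max)


@dataclass
class SweepGrid:
    """One-factor-at-a-time deviation grid (always contains the baseline)."""

    translation_steps: dict      # axis -> sorted array of mm values incl. 0
    rotation_steps: dict         # axis -> sorted array of deg values incl. 0
    size_steps: np.ndarray       # sorted scale values incl. 1.0

    def __post_init__(self):
        for ax in AXIS_NAMES:
            t = np.asarray(self.translation_steps[ax], dtype=float)
            r = np.asarray(self.rotation_steps[ax], dtype=float)
            if 0.0 not in t or 0.0 not in r:
                raise GeometryError("grids must include the zero deviation")
            self.translation_steps[ax] = np.sort(t)
            self.rotation_steps[ax] = np.sort(r)
        self.size_steps = np.sort(np.asarray(self.size_steps, dtype=float))
        if 1.0 not in self.size_steps:
            raise GeometryError("size grid must include scale 1.0")

    @classmethod
    def from_ranges(cls, translation_mm: float = 5.0,
                    rotation_deg: float = 20.0,
                    size_min: float = 0.8, size_max: float = 1.2,
                    translation_step: float = 1.0,
                    rotation_step: float = 5.0,
                    size_step: float = 0.05) -> "SweepGrid":
        def sym(limit, step):
            k = int(round(limit / step))
            return step * np.arange(-k, k + 1)

        n_lo = int(round((1.0 - size_min) / size_step))
        n_hi = int(round((size_max - 1.0) / size_step))
        sizes = 1.0 + size_step * np.arange(-n_lo, n_hi + 1)
        return cls(
            translation_steps={ax: sym(translation_mm, translation_step)
                               for ax in AXIS_NAMES},
            rotation_steps={ax: sym(rotation_deg, rotation_step)
                            for ax in AXIS_NAMES},
            size_steps=sizes,
        )

    @classmethod
    def from_thresholds(cls, thresholds: dict,
                        translation_step: float = 1.0,
                        rotation_step: float = 5.0,
                        size_step: float = 0.05) -> "SweepGrid":
        """Grid spanning per-axis observation thresholds (as produced by
        ``sample_deviation_thresholds``: mean +- 2 SD per axis), snapped
        outward to the standard increments and always containing zero."""
        def span(lo, hi, step, zero=0.0):
            lo_n = -step * int(np.ceil(max(zero - lo, 0.0) / step))
            hi_n = step * int(np.ceil(max(hi - zero, 0.0) / step))
            return zero + np.arange(lo_n, hi_n + step / 2, step)

        trans = {ax: span(*thresholds["translation_mm"][ax], translation_step)
                 for ax in AXIS_NAMES}
        rot = {ax: span(*thresholds["rotation_deg"][ax], rotation_step)
               for ax in AXIS_NAMES}
        sizes = span(*thresholds["scale"], size_step, zero=1.0)
        return cls(translation_steps=trans, rotation_steps=rot,
                   size_steps=sizes)

    def deviations(self):
        """Yield (kind, axis, value, DeviationSpec) including one baseline."""
        yield ("baseline", "", 0.0, DeviationSpec())
        for k, ax in enumerate(AXIS_NAMES):
            for v in self.translation_steps[ax]:
                if v != 0.0:
                    t = np.zeros(3)
                    t[k] = v
                    yield ("translation", ax, float(v), DeviationSpec(translation_mm=t))
            for v in self.rotation_steps[ax]:
                if v != 0.0:
                    r = np.zeros(3)
                    r[k] = v
                    yield ("rotation", ax, float(v), DeviationSpec(rotation_deg=r))
        for v in self.size_steps:
            if v != 1.0:
                yield ("size", "scale", float(v), DeviationSpec(scale=v))


@dataclass
class ToleranceMap:
    """Sweep results table plus per-direction allowable deviation ranges."""

    records: pd.DataFrame
    limits: SafeLimits
    baseline_pspd: float
    baseline_tawss_max: float
    allowable_ranges: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# baseline case construction


@dataclass
class StudyCase:
    """A fully configured implantation scenario (geometry, materials,
    hemodynamic boundary conditions) ready to sweep."""

    remnant: VesselModel
    graft: GraftModel
    plane: CutPlane
    materials: dict
    load_steps: int = 10
    blood: BloodProperties = field(default_factory=BloodProperties)
    waveform: FlowWaveform = field(default_factory=FlowWaveform.half_sine)
    windkessel: dict = field(default_factory=dict)
    n_stations: int = 40
    dt: float = 2e-3
    max_cycles: int = 10
    pspd_definition: str = "peak_inflow"
    graft_fixation: str = "edges"


def default_windkessel(mean_flow_ml_s: float = 63.7,
                       mean_pressure_mmhg: float = 90.0,
                       branch_flow_fraction: float = 0.25,
                       n_branches: int = 1,
                       time_constant_s: float = 1.2) -> dict:
    """RCR parameter placeholders sized from target mean flow/pressure:
    total peripheral resistance split between descending aorta and the
    supra-aortic branches, ~10% proximal, compliance from the decay time
    constant."""
    r_total = mean_pressure_mmhg / mean_flow_ml_s
    out = {}
    dao_r = r_total / (1.0 - branch_flow_fraction)
    out["outlet_DAo"] = WindkesselParams(Rp=0.1 * dao_r, C=time_constant_s / dao_r,
                                         Rd=0.9 * dao_r)
    if n_branches:
        br_r = r_total / (branch_flow_fraction / n_branches)
        for b in range(1, n_branches + 1):
            out[f"outlet_branch_{b}"] = WindkesselParams(
                Rp=0.1 * br_r, C=time_constant_s / br_r, Rd=0.9 * br_r)
    return out


def build_study_case(anatomy: Optional[AnatomyConfig] = None,
                     s_prox: float = 40.0, s_dist: float = 70.0,
                     diameter_scale: float = 1.0,
                     branched: bool = True,
                     native_material: Optional[YeohMaterial] = None,
                     graft_stiffness_multiplier: float = 2.5,
                     graft_thickness_mm: float = 1.0,
                     load_steps: int = 10,
                     apply_growth: bool = True,
                     **case_kwargs) -> StudyCase:
    """Generate the baseline virtual-implantation scenario.

    The native aorta is expanded uniformly by the growth scale before graft
    design (anticipating somatic growth), resected between ``s_prox`` and
    ``s_dist``, and replaced by a graft whose wall is
    ``graft_stiffness_multiplier`` times stiffer than native tissue.
    """
    from .anatomy import scale_uniform

    cfg = anatomy or AnatomyConfig(radius_profile=(8.0, 6.0))
    aorta = generate_aorta(cfg)
    if apply_growth and cfg.growth_scale != 1.0:
        aorta = scale_uniform(aorta, cfg.growth_scale)
        s_prox *= cfg.growth_scale
        s_dist *= cfg.growth_scale
    planes = place_resection_planes(aorta, s_prox, s_dist)
    remnant, resected = resect(aorta, planes)
    graft = design_graft(resected, diameter_scale=diameter_scale,
                         branched=branched, native_remnant=remnant)

    native = native_material or YeohMaterial(thickness=cfg.thickness_mm)
    graft_mat = YeohMaterial(native.C10, native.C20, native.C30,
                             thickness=graft_thickness_mm,
                             stiffness_multiplier=native.stiffness_multiplier
                             * graft_stiffness_multiplier)
    materials = {"AAo": native, "arch": native, "DAo": native,
                 "branch_1": native, "branch_2": native,
                 "TEVG": graft_mat, "TEVG_branch": graft_mat}
    materials = {k: v for k, v in materials.items()}

    case_kwargs.setdefault(
        "windkessel", default_windkessel(n_branches=cfg.branch_count))
    return StudyCase(remnant=remnant, graft=graft, plane=planes[0],
                     materials=materials, load_steps=load_steps,
                     **case_kwargs)


# ---------------------------------------------------------------------------
# single-case evaluation


def evaluate_case(case: StudyCase, dev: DeviationSpec,
                  initial_displacement=None,
                  load_steps: Optional[int] = None) -> dict:
    """Apply one deviation, solve the implantation, run the surrogate and
    return the hemodynamic metrics (or the failure reason).

    ``initial_displacement`` warm-starts the FE solve (continuation from a
    neighbouring deviation); it falls back to a cold full-ramp solve if the
    warm-started one fails to converge.
    """
    graft_dev, _plane_dev = apply_deviation(case.graft, case.plane, dev)
    assembly = assemble_implant(case.remnant, graft_dev, case.materials,
                                load_steps=load_steps or case.load_steps,
                                graft_fixation=case.graft_fixation)
    report = solve_implantation(assembly,
                                initial_displacement=initial_displacement)
    if not report.converged and initial_displacement is not None:
        assembly.load_steps = case.load_steps
        report = solve_implantation(assembly)
    if not report.converged:
        return {"evaluated": False, "reason": "fem_not_converged",
                "fem_report": report}
    profile = extract_lumen_profile(report.deformed, case.n_stations)
    network = build_network(profile, case.windkessel, case.blood)
    result = simulate(network, case.waveform, dt=case.dt,
                      max_cycles=case.max_cycles)
    pspd = compute_pspd(result, definition=case.pspd_definition)
    _, tawss_max = compute_tawss(result)
    return {
        "evaluated": True,
        "reason": "",
        "pspd": pspd,
        "tawss_max": tawss_max,
        "tawss_min": tawss_field_min(result),
        "fem_report": report,
        "hemo_result": result,
        "max_pair_gap": report.max_pair_gap,
    }


# ---------------------------------------------------------------------------
# sweeps


def _allowable_range(values: np.ndarray, safe: np.ndarray,
                     evaluated: np.ndarray, zero: float) -> tuple:
    """Maximal contiguous safe interval containing the baseline value."""
    order = np.argsort(values)
    v, s, e = values[order], safe[order], evaluated[order]
    i0 = int(np.argmin(np.abs(v - zero)))
    if not (e[i0] and s[i0]):
        return (zero, zero)
    lo = hi = i0
    while lo > 0 and e[lo - 1] and s[lo - 1]:
        lo -= 1
    while hi < len(v) - 1 and e[hi + 1] and s[hi + 1]:
        hi += 1
    return (float(v[lo]), float(v[hi]))


def run_sweep(case: StudyCase, grid: SweepGrid,
              limits: Optional[SafeLimits] = None,
              progress: Optional[Callable[[str], None]] = None) -> ToleranceMap:
    """One-factor-at-a-time tolerance sweep.

    Every grid point is solved independently of sweep order; failed FE
    solves are recorded as unevaluated, never dropped.  Percentage
    differences are relative to the zero-deviation baseline, which is
    always evaluated first.
    """
    limits = limits or SafeLimits()
    base = evaluate_case(case, DeviationSpec())
    if not base["evaluated"]:
        raise GeometryError("baseline case failed to solve: "
                            + base["reason"])
    b_pspd, b_tawss = base["pspd"], base["tawss_max"]

    # Evaluate wings walking outward from the baseline so each solve can
    # warm-start from its inner neighbour (continuation).
    results = {}
    all_points = [(kind, axis, value, dev)
                  for kind, axis, value, dev in grid.deviations()
                  if kind != "baseline"]
    wings: dict = {}
    for kind, axis, value, dev in all_points:
        zero = 1.0 if kind == "size" else 0.0
        wing = (kind, axis, value > zero)
        wings.setdefault(wing, []).append((abs(value - zero), value, dev))
    for wing, points in wings.items():
        last_disp = base["fem_report"].displacement
        for _, value, dev in sorted(points):
            if progress:
                progress(f"{wing[0]} {wing[1]} {value:+g}")
            res = evaluate_case(case, dev, initial_displacement=last_disp,
                                load_steps=2)
            results[(wing[0], wing[1], value)] = res
            if res["evaluated"]:
                last_disp = res["fem_report"].displacement

    rows = []
    for kind, axis, value, dev in grid.deviations():
        if kind == "baseline":
            res = base
        else:
            res = results[(kind, axis, value)]
        row = {"kind": kind, "axis": axis, "value": value,
               "evaluated": bool(res["evaluated"]), "reason": res["reason"]}
        if res["evaluated"]:
            safe = classify_safe(res["pspd"], res["tawss_max"],
                                 res["tawss_min"], limits)
            row.update({
                "pspd_mmhg": res["pspd"],
                "tawss_max_pa": res["tawss_max"],
                "tawss_min_pa": res["tawss_min"],
                "pct_dpspd": percent_diff(res["pspd"], b_pspd)
                if b_pspd != 0 else 0.0,
                "pct_dtawss": percent_diff(res["tawss_max"], b_tawss),
                "safe": bool(safe),
                "max_pair_gap_mm": res["max_pair_gap"],
            })
        else:
            row.update({"pspd_mmhg": np.nan, "tawss_max_pa": np.nan,
                        "tawss_min_pa": np.nan, "pct_dpspd": np.nan,
                        "pct_dtawss": np.nan, "safe": False,
                        "max_pair_gap_mm": np.nan})
        rows.append(row)
    records = pd.DataFrame(rows)

    ranges = {}
    for kind, zero in (("translation", 0.0), ("rotation", 0.0)):
        for ax in AXIS_NAMES:
            sel = records[((records.kind == kind) & (records.axis == ax))
                          | (records.kind == "baseline")]
            vals = np.where(sel.kind == "baseline", zero, sel.value.to_numpy())
            ranges[f"{kind}:{ax}"] = _allowable_range(
                vals, sel.safe.to_numpy(dtype=bool),
                sel.evaluated.to_numpy(dtype=bool), zero)
    sel = records[(records.kind == "size") | (records.kind == "baseline")]
    vals = np.where(sel.kind == "baseline", 1.0, sel.value.to_numpy())
    ranges["size:scale"] = _allowable_range(
        vals, sel.safe.to_numpy(dtype=bool),
        sel.evaluated.to_numpy(dtype=bool), 1.0)

    return ToleranceMap(records=records, limits=limits,
                        baseline_pspd=b_pspd, baseline_tawss_max=b_tawss,
                        allowable_ranges=ranges)


# ---------------------------------------------------------------------------
# shape-validation protocol


@dataclass
class ShapeValidationResult:
    report_designed: DistanceReport     # original design vs postop
    report_predicted: DistanceReport    # FE-informed prediction vs postop
    improvement_percent: float


def _merged_surface(remnant: VesselModel, graft: GraftModel) -> VesselModel:
    """Plain geometric union of remnant and graft (no solve)."""
    surf = graft.surface
    nodes = np.vstack([remnant.nodes, surf.nodes])
    quads = np.vstack([remnant.quads, surf.quads + remnant.n_nodes])
    tags = np.concatenate([remnant.region_tags, surf.region_tags])
    return VesselModel(nodes=nodes, quads=quads, region_tags=tags,
                       boundary_loops={}, thickness=remnant.thickness)


def run_shape_validation(case: StudyCase, observed_deviation: DeviationSpec,
                         reference_postop: VesselModel,
                         n_samples: int = 4000,
                         seed: int = 0) -> ShapeValidationResult:
    """Does simulating the observed misplacement improve the shape
    prediction?

    Report A compares the original (undeviated, unsolved) design to the
    reference postoperative shape; report B compares the FE-deformed,
    deviation-transformed design to the same reference.  The improvement is
    100 * (A_mean - B_mean) / A_mean.
    """
    designed = _merged_surface(case.remnant, case.graft)
    report_a = surface_distance(designed, reference_postop,
                                n_samples=n_samples, seed=seed)
    if observed_deviation.is_identity:
        report_b = report_a
    else:
        res = evaluate_case(case, observed_deviation)
        if not res["evaluated"]:
            raise GeometryError("FE solve failed in shape validation: "
                                + res["reason"])
        report_b = surface_distance(res["fem_report"].deformed,
                                    reference_postop,
                                    n_samples=n_samples, seed=seed)
    a_mean = report_a.mean_surface_distance_mm
    improvement = 0.0 if a_mean == 0 else 100.0 * (
        a_mean - report_b.mean_surface_distance_mm) / a_mean
    return ShapeValidationResult(report_designed=report_a,
                                 report_predicted=report_b,
                                 improvement_percent=improvement)


def synthesize_postop(case_factory: Callable[..., StudyCase],
                      observed_deviation: DeviationSpec,
                      refine: int = 2, **factory_kwargs) -> VesselModel:
    """Synthetic ground-truth postoperative shape: the observed deviation
    applied and FE-solved on a mesh ``refine`` times denser than the study
    case (so predictions are compared against an independent
    discretization)."""
    kwargs = copy.deepcopy(factory_kwargs)
    anatomy = kwargs.pop("anatomy", None) or AnatomyConfig(radius_profile=(8.0, 6.0))
    fine = copy.deepcopy(anatomy)
    fine.n_axial = anatomy.n_axial * refine
    fine.branch_n_axial = anatomy.branch_n_axial * refine
    fine_case = case_factory(anatomy=fine, **kwargs)
    res = evaluate_case(fine_case, observed_deviation)
    if not res["evaluated"]:
        raise GeometryError("ground-truth FE solve failed")
    return res["fem_report"].deformed
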