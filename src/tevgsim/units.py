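"""Unit conventions and conversion constants.

Geometry is in millimetres, flows in mL/s, pressures in mmHg, wall shear
stress in Pa, stress-like material coefficients in kPa.  Strain energy is
accumulated in kPa*mm^3 (= microjoule) and reported in millijoule.
"""

MMHG_PER_PA = 1.0 / 133.322
PA_PER_MMHG = 133.322

M_PER_MM = 1e-3
M3_PER_ML = 1e-6

UJ_PER_MJ = 1e3  # microjoule per millijoule


def poiseuille_resistance_mmhg_s_ml(viscosity_pa_s: float, length_mm: float,
                                    radius_mm: float) -> float:
    """Hagen-Poiseuille resistance 8*mu*L/(pi*r^4) of a straight segment,
    converted to mmHg*s/mL."""
    import math
    r = radius_mm * M_PER_MM
    length = length_mm * M_PER_MM
    r_pa_s_m3 = 8.0 * viscosity_pa_s * length / (math.pi * r ** 4)
    # Pa*s/m^3 -> mmHg*s/mL
    return r_pa_s_m3 * MMHG_PER_PA * M3_PER_ML


def wall_shear_pa(viscosity_pa_s: float, flow_ml_s: float, radius_mm: float) -> float:
    """Poiseuille wall shear stress 4*mu*Q/(pi*r^3) in Pa."""
    import math
    q = abs(flow_ml_s) * M3_PER_ML
    r = radius_mm * M_PER_MM
    return 4.0 * viscosity_pa_s * q / (math.pi * r ** 3)
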