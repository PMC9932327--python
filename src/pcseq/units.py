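"""Unit conventions and centralized conversions.

The package-wide unit contract:

==================  =========
quantity            unit
==================  =========
voltage             mV
time                ms
length              um
capacitance         uF/cm^2
conductance (area)  mS/cm^2
axial resistivity   Ohm*cm
injected current    nA
current density     uA/cm^2
calcium             uM
==================  =========

These combine consistently: (mS/cm^2)*(mV) = uA/cm^2 and
(uF/cm^2)*(mV/ms) = uA/cm^2, so the membrane ODE needs no hidden factors.
"""

import math

#: Faraday constant, C/mol.
FARADAY = 96485.33212

UM_PER_CM = 1.0e4


def um_to_cm(x_um: float) -> float:
    return x_um / UM_PER_CM


def cylinder_area_cm2(length_um: float, radius_um: float) -> float:
    """Lateral membrane area of a cylindrical compartment, cm^2."""
    return 2.0 * math.pi * um_to_cm(radius_um) * um_to_cm(length_um)


def cross_section_cm2(radius_um: float) -> float:
    return math.pi * um_to_cm(radius_um) ** 2


def axial_conductance_uS(r_axial_ohm_cm: float,
                         length_a_um: float, radius_a_um: float,
                         length_b_um: float, radius_b_um: float) -> float:
    """Coupling conductance between two adjacent compartments, uS.

    Series combination of each compartment's half-length axial resistance
    R * (L/2) / (pi a^2); the standard compartmental-model coupling for a
    non-uniform cable, which reduces to pi a^2 / (R dx) on a uniform one.
    """
    r_half_a = r_axial_ohm_cm * um_to_cm(length_a_um) / 2.0 / cross_section_cm2(radius_a_um)
    r_half_b = r_axial_ohm_cm * um_to_cm(length_b_um) / 2.0 / cross_section_cm2(radius_b_um)
    return 1.0e6 / (r_half_a + r_half_b)


def nA_to_uA_per_cm2(i_nA: float, area_cm2: float) -> float:
    """Convert an absolute injected current to a membrane current density."""
    return i_nA * 1.0e-3 / area_cm2


def ca_influx_scale(shell_depth_um: float) -> float:
    """Concentration rate per unit inward Ca current density.

    For a submembrane shell of depth d, an inward current density i
    (uA/cm^2) raises [Ca] at i / (2 F d) after unit conversion; the
    returned scale has units uM * cm^2 / (uA * ms), i.e.
    d[Ca]/dt (uM/ms) = scale * |i| for inward i.

    i uA/cm^2 = 1e-12 C/(ms cm^2); /(2F) mol/(ms cm^2); /(d cm) mol/(ms cm^3)
    = 1e3 mol/(ms L); *1e6 uM.
    """
    d_cm = um_to_cm(shell_depth_um)
    return 1.0e-12 / (2.0 * FARADAY * d_cm) * 1.0e3 * 1.0e6
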