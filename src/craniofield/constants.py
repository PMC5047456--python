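"""Physical constants, tissue property tables and unit conventions.

Unit conventions used throughout the package:

* geometry (node coordinates, radii, diameters) — millimetres
* electric potential — volts
* electric field magnitude — V/m (gradients taken in mm are rescaled)
* current — amperes; current density — A/m^2
* conductivity — S/m; diffusivity — mm^2/s
* SAR — W/kg; mass density — kg/m^3

All mm <-> m conversions happen through the factors below; nothing else in
the package converts units ad hoc.
"""

from __future__ import annotations

from enum import IntEnum

MM_PER_M = 1000.0
#: multiply a V/mm gradient by this to get V/m
V_PER_MM_TO_V_PER_M = MM_PER_M
#: multiply an area in mm^2 by this to get m^2
MM2_TO_M2 = 1e-6
#: multiply a volume in mm^3 by this to get m^3
MM3_TO_M3 = 1e-9


class Tissue(IntEnum):
    """Tissue / region codes carried as per-element labels (and as Gmsh
    physical tags on export)."""

    SCALP = 1
    SKULL = 2
    CSF = 3
    GM = 4
    WM = 5
    TUMOR = 6


#: isotropic conductivities (S/m) at a 200 kHz-representative operating point
ISOTROPIC_CONDUCTIVITY = {
    Tissue.CSF: 1.654,
    Tissue.SCALP: 0.465,
    Tissue.SKULL: 0.010,
}

#: literature conductivity targets (S/m) used to calibrate the
#: diffusion-to-conductivity mapping slope
LITERATURE_CONDUCTIVITY = {
    Tissue.GM: 0.275,
    Tissue.WM: 0.126,
}

#: mass densities (kg/m^3) for SAR
DEFAULT_DENSITY = {
    Tissue.SCALP: 1109.0,
    Tissue.SKULL: 1908.0,
    Tissue.CSF: 1007.0,
    Tissue.GM: 1045.0,
    Tissue.WM: 1045.0,
    Tissue.TUMOR: 1045.0,
}

#: peak injected current per active electrode pair (A).  The device drives a
#: 1.8 A peak-to-peak sinusoid through each pair; one static solve represents
#: the instant of peak amplitude, i.e. 0.9 A.
DEFAULT_PEAK_CURRENT = 0.9
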