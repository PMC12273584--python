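"""Physical constants and unit conversions shared across the package.

Internal concentration conventions:

* reaction–diffusion and titration work uses nM;
* radial profiles carry an explicit unit tag, one of ``per_confocal``
  (particles per confocal detection volume), ``per_um3`` (particles/μm³)
  or ``nM``;
* 1 nM corresponds to 0.6022 particles/μm³.
"""

from __future__ import annotations

AVOGADRO = 6.022e23
"""Particles per mole (matches the 0.6022 particles/(μm³·nM) shorthand)."""

PARTICLES_PER_UM3_PER_NM = 0.6022
"""Particles per μm³ in a 1 nM solution: 1e-9 mol/L · N_A · 1e-15 L/μm³."""

DEFAULT_CONFOCAL_VOLUME_UM3 = 0.16
"""Default confocal detection volume used for particle↔molar conversions."""

CONC_UNITS = ("per_confocal", "per_um3", "nM")
DIFFUSIVITY_UNIT = "um2_per_s"


def nm_to_per_um3(c_nM: float) -> float:
    """Convert a concentration in nM to particles/μm³."""
    return c_nM * PARTICLES_PER_UM3_PER_NM


def per_um3_to_nm(c: float) -> float:
    """Convert particles/μm³ to nM."""
    return c / PARTICLES_PER_UM3_PER_NM
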