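"""Unit conventions and physical constants.

All energies, frequencies, spectral densities and line widths are in
wavenumbers (cm^-1); all times in picoseconds; all lengths in Angstrom;
all charges in units of the elementary charge.  A golden-rule expression
assembled purely from cm^-1 quantities yields an energy in cm^-1 and is
converted to an angular rate in ps^-1 by multiplying with ``2*pi*c``.
"""

import numpy as np

#: 2*pi*c in rad ps^-1 per cm^-1: converts an energy (cm^-1) to an angular rate.
CM_TO_RAD_PER_PS = 0.188365

#: Boltzmann constant in cm^-1 per Kelvin (k_B*300 K = 208.5 cm^-1).
KB_CM = 0.6950348

#: Coulomb constant e^2/(4*pi*eps0) in cm^-1 * Angstrom (= 14.3996 eV*A).
COULOMB_CM_ANGSTROM = 116140.0

#: Conversion between wavelength (nm) and wavenumber (cm^-1): nm = 1e7 / cm^-1.
NM_PER_CM = 1.0e7

#: 1 Debye in e*Angstrom.
DEBYE_E_ANGSTROM = 0.2081943


def thermal_energy(temperature: float) -> float:
    """k_B * T in cm^-1."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_CM * temperature


def boltzmann_factor(gap: float, temperature: float) -> float:
    """exp(-gap / k_B T) for a gap in cm^-1 (may be negative)."""
    return float(np.exp(-gap / thermal_energy(temperature)))


def wavenumber_to_nm(wavenumber):
    """Convert cm^-1 to nm (vacuum)."""
    return NM_PER_CM / np.asarray(wavenumber, dtype=float)
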