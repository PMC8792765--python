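"""Single-carotenoid spectra: linear absorption, two-photon (S0->S1)
lineshape, and the pump-probe difference spectrum.

Every vibronic line is dressed with an area-normalized Voigt profile
(Gaussian convolved with Lorentzian) whose widths are set per optical
band in the parameter set.  The difference spectrum is assembled as

    dA(w, t) = ESA(w, t) - SE(w, t) - GSB(w, t)

with excited-state absorption from S1 -> Sn, stimulated emission from
the populated levels of dipole-allowed bands, and ground-state bleach
proportional to the depletion of each S0 level relative to thermal
equilibrium.
"""

from __future__ import annotations

import numpy as np
from scipy.special import voigt_profile

from .basis import VibronicBasis
from .dynamics import PopulationTrajectory, thermal_ground_state
from .params import VERAParameterSet, pair_key


def voigt_line(omega_grid: np.ndarray, center: float, gauss_sigma: float, lor_gamma: float) -> np.ndarray:
    """Area-normalized Voigt line at ``center`` (all cm^-1)."""
    return voigt_profile(omega_grid - center, gauss_sigma, lor_gamma)


def _band_sticks(
    basis: VibronicBasis,
    lo: str,
    hi: str,
    level_weights_lo: np.ndarray | dict[tuple[int, int], float],
) -> tuple[np.ndarray, np.ndarray]:
    """Stick spectrum (positions, intensities) for lo(a) -> hi(b) transitions.

    ``level_weights_lo`` gives the population/weight of each initial
    (a1, a2) level on the lower state; intensities carry the squared FC
    product of both modes.
    """
    f1, f2 = basis.fc_tables[pair_key(lo, hi)]
    amax = basis.a_max
    pos, inten = [], []
    for a1 in range(amax + 1):
        for a2 in range(amax + 1):
            if isinstance(level_weights_lo, dict):
                w0 = level_weights_lo.get((a1, a2), 0.0)
            else:
                w0 = level_weights_lo[basis.index(lo, a1, a2)]
            if w0 == 0.0:
                continue
            e_lo = basis.energies[basis.index(lo, a1, a2)]
            for b1 in range(amax + 1):
                for b2 in range(amax + 1):
                    fc2 = f1[a1, b1] ** 2 * f2[a2, b2] ** 2
                    if fc2 == 0.0:
                        continue
                    pos.append(basis.energies[basis.index(hi, b1, b2)] - e_lo)
                    inten.append(w0 * fc2)
    return np.asarray(pos), np.asarray(inten)


def _dress(omega_grid: np.ndarray, pos: np.ndarray, inten: np.ndarray,
           gauss: float, lor: float) -> np.ndarray:
    if len(pos) == 0:
        return np.zeros_like(omega_grid, dtype=float)
    scale = np.abs(inten).max()
    if scale == 0.0:
        return np.zeros_like(omega_grid, dtype=float)
    keep = np.abs(inten) > 1e-10 * scale
    pos, inten = np.asarray(pos)[keep], np.asarray(inten)[keep]
    prof = voigt_profile(omega_grid[None, :] - pos[:, None], gauss, lor)
    return inten @ prof


def linear_absorption(
    params: VERAParameterSet,
    basis: VibronicBasis,
    omega_grid: np.ndarray,
    fluence: float = 1.0,
) -> np.ndarray:
    """Steady-state S0 -> S2 absorption from thermally populated S0 levels."""
    omega_grid = np.asarray(omega_grid, dtype=float)
    if omega_grid.size == 0:
        raise ValueError("empty wavenumber grid")
    n0 = thermal_ground_state(basis, params.temperature)
    pos, inten = _band_sticks(basis, "S0", "S2", n0)
    g, l = params.band_widths("S0", "S2")
    return fluence * params.strength("S0", "S2") * _dress(omega_grid, pos, inten, g, l)


def tpe_lineshape(
    params: VERAParameterSet,
    basis: VibronicBasis,
    omega_grid: np.ndarray,
    solvent_shift: float = 150.0,
) -> np.ndarray:
    """S0 -> S1 vibronic profile (two-photon excitation lineshape).

    The S0->S1 band is one-photon forbidden, so the profile is built from
    Franck-Condon structure alone.  ``solvent_shift`` rigidly blue-shifts
    the output (default +150 cm^-1, the octanol-vs-pyridine offset); it
    is applied at output only and does not touch the parameter set.
    """
    omega_grid = np.asarray(omega_grid, dtype=float)
    if omega_grid.size == 0:
        raise ValueError("empty wavenumber grid")
    n0 = thermal_ground_state(basis, params.temperature)
    pos, inten = _band_sticks(basis, "S0", "S1", n0)
    g, l = params.band_widths("S0", "S1")
    return _dress(omega_grid, pos + solvent_shift, inten, g, l)


def ta_difference_spectrum(
    traj: PopulationTrajectory,
    params: VERAParameterSet,
    basis: VibronicBasis,
    omega_grid: np.ndarray,
    delays: np.ndarray,
) -> np.ndarray:
    """dA(w, t) matrix, shape (len(omega_grid), len(delays)).

    ESA: S1(a) -> Sn(b), weighted by instantaneous S1 populations.
    SE: emission hi -> S0 for each dipole-allowed band (S2->S0; S1->S0
    carries zero strength by default since S1 is dark).
    GSB: thermal-equilibrium minus instantaneous S0 populations, dressed
    with the ground-state absorption band.  With full ground-state
    recovery dA -> 0 everywhere.
    """
    omega_grid = np.asarray(omega_grid, dtype=float)
    delays = np.atleast_1d(np.asarray(delays, dtype=float))
    if omega_grid.size == 0:
        raise ValueError("empty wavenumber grid")
    n_eq = thermal_ground_state(basis, params.temperature)
    out = np.zeros((omega_grid.size, delays.size))
    esa_g, esa_l = params.band_widths("S1", "Sn")
    la_g, la_l = params.band_widths("S0", "S2")
    for j, t in enumerate(delays):
        n = traj.at(t)
        dA = np.zeros_like(omega_grid)
        # ESA: S1 -> Sn
        s1_weights = np.where(basis.state_mask("S1"), n, 0.0)
        if s1_weights.any():
            pos, inten = _band_sticks(basis, "S1", "Sn", s1_weights)
            dA += params.strength("S1", "Sn") * _dress(omega_grid, pos, inten, esa_g, esa_l)
        # SE: S2 -> S0 (and S1 -> S0 if given strength)
        for hi in ("S2", "S1"):
            strength = params.strength("S0", hi)
            if strength == 0.0:
                continue
            hi_weights = np.where(basis.state_mask(hi), n, 0.0)
            if not hi_weights.any():
                continue
            g, l = params.band_widths("S0", hi)
            # emission sticks: reverse of absorption, FC table transposed
            f1, f2 = basis.fc_tables[pair_key("S0", hi)]
            amax = basis.a_max
            pos, inten = [], []
            for a1 in range(amax + 1):
                for a2 in range(amax + 1):
                    w0 = hi_weights[basis.index(hi, a1, a2)]
                    if w0 == 0.0:
                        continue
                    e_hi = basis.energies[basis.index(hi, a1, a2)]
                    for b1 in range(amax + 1):
                        for b2 in range(amax + 1):
                            fc2 = f1[b1, a1] ** 2 * f2[b2, a2] ** 2
                            if fc2 == 0.0:
                                continue
                            pos.append(e_hi - basis.energies[basis.index("S0", b1, b2)])
                            inten.append(w0 * fc2)
            dA -= strength * _dress(omega_grid, np.asarray(pos), np.asarray(inten), g, l)
        # GSB: depletion of each S0 level, dressed with its absorption lines
        depletion = np.where(basis.state_mask("S0"), n_eq - n, 0.0)
        if np.abs(depletion).max() > 0.0:
            pos, inten = _band_sticks(basis, "S0", "S2", depletion)
            dA -= params.strength("S0", "S2") * _dress(omega_grid, pos, inten, la_g, la_l)
        out[:, j] = dA
    return out
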