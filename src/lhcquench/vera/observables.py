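"""Scalar observables extracted from simulated vibronic dynamics:
electronic-state lifetimes, intra-state vibrational relaxation times and
the position of the S1 excited-state absorption."""

from __future__ import annotations

import numpy as np

from .basis import VibronicBasis
from .dynamics import PopulationTrajectory, propagate_populations
from .params import VERAParameterSet
from .spectra import _band_sticks, _dress


def electronic_population(traj: PopulationTrajectory, state: str) -> np.ndarray:
    """Total population of one electronic state along the trajectory."""
    return traj.total(state)


def fit_exponential_lifetime(times: np.ndarray, signal: np.ndarray) -> float:
    """Time constant (ps) of a near mono-exponential decay.

    Weighted log-linear regression over the window where the signal
    exceeds 1e-3 of its maximum; weights proportional to the signal so
    the tail does not dominate.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(signal, dtype=float)
    ymax = y.max()
    if ymax <= 0:
        raise ValueError("signal must be positive somewhere to fit a decay")
    mask = y > 1e-3 * ymax
    t, y = times[mask], y[mask]
    if len(t) < 3:
        raise ValueError("too few points above threshold for a lifetime fit")
    w = y / y.sum()
    x = t - np.average(t, weights=w)
    z = np.log(y)
    slope = np.sum(w * x * (z - np.average(z, weights=w))) / np.sum(w * x * x)
    if slope >= 0:
        raise ValueError("signal does not decay over the fitted window")
    return float(-1.0 / slope)


def _decay_window(traj: PopulationTrajectory, state: str) -> tuple[np.ndarray, np.ndarray]:
    pop = traj.total(state)
    k_peak = int(np.argmax(pop))
    return traj.times[k_peak:], pop[k_peak:]


def s1_lifetime(traj: PopulationTrajectory, tail_start: float | None = None) -> float:
    """Mono-exponential S1 decay constant (ps), fitted after the S1 maximum.

    ``tail_start`` optionally restricts the fit to t >= tail_start so the
    early vibrational-relaxation transient is excluded.
    """
    t, pop = _decay_window(traj, "S1")
    if tail_start is not None:
        mask = t >= tail_start
        t, pop = t[mask], pop[mask]
    return fit_exponential_lifetime(t, pop)


def s2_lifetime(traj: PopulationTrajectory) -> float:
    """S2 decay constant (ps) after the S2 maximum (~100 fs scale)."""
    t, pop = _decay_window(traj, "S2")
    return fit_exponential_lifetime(t, pop)


def s1_vibrational_relaxation_time(
    basis: VibronicBasis,
    rate_matrix: np.ndarray,
    t_max: float = 6.0,
    n_t: int = 400,
) -> float:
    """Intramolecular vibrational relaxation time on S1 (ps).

    Delta-excites |S1, 1, 0> (one quantum of the C-C stretch) and fits
    the decay of the excess vibrational energy on S1 towards its thermal
    value.  Internal conversion also depletes S1 but is an order of
    magnitude slower, so the fitted constant reflects IVR.
    """
    n0 = np.zeros(basis.n_levels)
    n0[basis.index("S1", 1, 0)] = 1.0
    t_grid = np.linspace(0.0, t_max, n_t)
    traj = propagate_populations(rate_matrix, n0, t_grid, basis)
    mask = basis.state_mask("S1")
    e_vib = basis.energies[mask] - basis.energies[basis.index("S1", 0, 0)]
    s1_pop = traj.populations[:, mask]
    tot = s1_pop.sum(axis=1)
    mean_evib = (s1_pop @ e_vib) / np.maximum(tot, 1e-300)
    excess = mean_evib - mean_evib[-1]
    keep = excess > 1e-3 * excess.max()
    return fit_exponential_lifetime(traj.times[keep], excess[keep])


def esa_peak_position(
    params: VERAParameterSet,
    basis: VibronicBasis,
    omega_grid: np.ndarray | None = None,
    populations: np.ndarray | None = None,
) -> float:
    """Probe wavenumber (cm^-1) of the S1 -> Sn ESA maximum.

    By default the band is evaluated for a vibrationally relaxed S1
    (all population in |S1, 0, 0>), as probed at delays long after the
    ~1 ps IVR but before full S1 decay.
    """
    if omega_grid is None:
        gap = params.electronic_energies["Sn"] - params.electronic_energies["S1"]
        omega_grid = np.arange(gap - 4000.0, gap + 6000.0, 2.0)
    if populations is None:
        populations = np.zeros(basis.n_levels)
        populations[basis.index("S1", 0, 0)] = 1.0
    weights = np.where(basis.state_mask("S1"), populations, 0.0)
    pos, inten = _band_sticks(basis, "S1", "Sn", weights)
    g, l = params.band_widths("S1", "Sn")
    spec = _dress(np.asarray(omega_grid, dtype=float), pos, inten, g, l)
    k = int(np.argmax(spec))
    if 0 < k < len(omega_grid) - 1:
        # parabolic refinement around the grid maximum
        y0, y1, y2 = spec[k - 1], spec[k], spec[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            return float(omega_grid[k] + 0.5 * (y0 - y2) / denom * (omega_grid[1] - omega_grid[0]))
    return float(omega_grid[k])
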