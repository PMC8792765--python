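"""Population dynamics of the vibronic master equation.

``dn/dt = K n (+ pump)`` with K the probability-conserving generator from
:func:`build_vera_rate_matrix`.  Two propagators are provided: stepwise
matrix exponentials (exact for a constant generator) and adaptive ODE
integration (required when a pump source is present); their agreement is
an internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from ..units import thermal_energy
from .basis import VibronicBasis
from .params import STATES, STATE_INDEX, pair_key


class ModelError(RuntimeError):
    """Raised for singular or non-generator rate matrices."""


@dataclass
class PumpPulse:
    """Gaussian excitation pulse.

    The spectral width is taken as transform limited for the given
    duration (time-bandwidth product 0.441 for Gaussians).
    """

    center_time: float = 0.0        # ps
    duration_fwhm: float = 0.1      # ps
    center_wavenumber: float = 21000.0  # cm^-1
    fluence: float = 1.0            # dimensionless scale

    def __post_init__(self) -> None:
        if self.duration_fwhm <= 0:
            raise ValueError(f"pump duration must be positive, got {self.duration_fwhm}")

    def envelope(self, t) -> np.ndarray:
        """Unit-peak temporal intensity envelope."""
        t = np.asarray(t, dtype=float)
        return np.exp(-4.0 * np.log(2.0) * (t - self.center_time) ** 2 / self.duration_fwhm**2)

    @property
    def spectral_fwhm(self) -> float:
        """Transform-limited spectral FWHM in cm^-1 (0.441/dt, c = 0.0299793 cm/ps)."""
        return 0.441 / self.duration_fwhm / 0.0299792458

    def spectral_weight(self, wavenumber) -> np.ndarray:
        """Unit-peak Gaussian spectral profile at the given transition energies."""
        sig = self.spectral_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        w = np.asarray(wavenumber, dtype=float)
        return np.exp(-0.5 * ((w - self.center_wavenumber) / sig) ** 2)


@dataclass
class PopulationTrajectory:
    """Time-resolved vibronic populations n[i, a1, a2](t)."""

    times: np.ndarray          # (n_t,), ps, increasing
    populations: np.ndarray    # (n_t, n_levels)
    basis: VibronicBasis

    def total(self, state: str) -> np.ndarray:
        """Total population on one electronic state vs time."""
        mask = self.basis.state_mask(state)
        return self.populations[:, mask].sum(axis=1)

    def level(self, state: str, a1: int, a2: int) -> np.ndarray:
        return self.populations[:, self.basis.index(state, a1, a2)]

    def at(self, t: float) -> np.ndarray:
        """Populations linearly interpolated at delay t (ps)."""
        if t < self.times[0] - 1e-12 or t > self.times[-1] + 1e-12:
            raise ValueError(f"delay {t} ps outside trajectory range [{self.times[0]}, {self.times[-1]}]")
        out = np.empty(self.populations.shape[1])
        for j in range(self.populations.shape[1]):
            out[j] = np.interp(t, self.times, self.populations[:, j])
        return out


def thermal_ground_state(basis: VibronicBasis, temperature: float | None = None) -> np.ndarray:
    """Boltzmann-populated S0 vibronic levels, zero elsewhere (sums to 1)."""
    if temperature is None:
        temperature = basis.params.temperature
    kt = thermal_energy(temperature)
    n = np.zeros(basis.n_levels)
    mask = basis.state_mask("S0")
    e = basis.energies[mask]
    w = np.exp(-(e - e.min()) / kt)
    n[mask] = w / w.sum()
    return n


def pump_transfer_matrix(basis: VibronicBasis, pump: PumpPulse) -> np.ndarray:
    """Population-conserving S0 -> S2 pumping generator (unit envelope).

    Each S0 level is depleted into S2 levels at a rate proportional to
    the squared Franck-Condon factors of the transition and the pump
    spectral weight at the transition energy; scaled by the pulse
    fluence.  Multiply by ``pump.envelope(t)`` for the instantaneous
    generator.
    """
    n = basis.n_levels
    W = np.zeros((n, n))
    f1, f2 = basis.fc_tables[pair_key("S0", "S2")]
    amax = basis.a_max
    for a1 in range(amax + 1):
        for a2 in range(amax + 1):
            i0 = basis.index("S0", a1, a2)
            e0 = basis.energies[i0]
            for b1 in range(amax + 1):
                for b2 in range(amax + 1):
                    i2 = basis.index("S2", b1, b2)
                    fc2 = f1[a1, b1] ** 2 * f2[a2, b2] ** 2
                    if fc2 == 0.0:
                        continue
                    wt = pump.spectral_weight(basis.energies[i2] - e0)
                    W[i2, i0] += pump.fluence * fc2 * wt
    np.fill_diagonal(W, -W.sum(axis=0))
    return W


def propagate_populations(
    rate_matrix: np.ndarray,
    initial: np.ndarray | PumpPulse,
    t_grid: np.ndarray,
    basis: VibronicBasis,
    method: str = "auto",
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> PopulationTrajectory:
    """Solve the master equation on the given time grid.

    ``initial`` is either an explicit population vector or a
    :class:`PumpPulse`; the latter starts from the thermal ground state
    and sources S2 levels through the pulse (``basis`` required).
    ``method``: "expm" (stepwise matrix exponential, constant generator
    only), "ode" (adaptive LSODA), or "auto".
    """
    K = np.asarray(rate_matrix, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D array")
    if not np.all(np.isfinite(K)):
        raise ModelError("rate matrix contains non-finite entries")
    offdiag = K - np.diag(np.diag(K))
    if np.any(offdiag < -1e-12):
        raise ModelError("rate matrix has negative off-diagonal entries")

    pump = None
    if isinstance(initial, PumpPulse):
        pump = initial
        n0 = thermal_ground_state(basis)
        W = pump_transfer_matrix(basis, pump)
    else:
        n0 = np.asarray(initial, dtype=float)
        if n0.shape != (K.shape[0],):
            raise ValueError(f"initial vector has shape {n0.shape}, expected ({K.shape[0]},)")

    if method == "auto":
        method = "ode" if pump is not None else "expm"
    if method == "expm":
        if pump is not None:
            raise ValueError("expm propagation does not support a time-dependent pump")
        pops = np.empty((len(t_grid), len(n0)))
        n = n0.copy()
        t_prev = t_grid[0]
        pops[0] = n
        for k, t in enumerate(t_grid[1:], start=1):
            n = expm(K * (t - t_prev)) @ n
            t_prev = t
            pops[k] = n
    elif method == "ode":
        if pump is None:
            def rhs(t, y):
                return K @ y
        else:
            def rhs(t, y):
                return (K + pump.envelope(t) * W) @ y
        sol = solve_ivp(
            rhs, (t_grid[0], t_grid[-1]), n0, t_eval=t_grid,
            method="LSODA", rtol=rtol, atol=atol,
            max_step=(pump.duration_fwhm / 4 if pump is not None else np.inf),
        )
        if not sol.success:
            raise ModelError(f"ODE propagation failed: {sol.message}")
        pops = sol.y.T
    else:
        raise ValueError(f"unknown propagation method {method!r}")

    return PopulationTrajectory(times=t_grid, populations=pops, basis=basis)
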