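"""Relaxation rate constants and the vibronic rate (master-equation) matrix.

Both bath channels use an overdamped Drude spectral density
``C''(w) = 2*lam*gam*w / (w**2 + gam**2)`` (an odd function of w) and
second-order golden-rule rates evaluated at the level gap:

    k(Delta) = 2*pi*c * C''(Delta) * (coth(Delta / 2 kT) + 1) / 2

With the odd extension of C'' this single expression covers downhill
(Delta > 0) and uphill (Delta < 0) transfer and satisfies detailed
balance k(Delta)/k(-Delta) = exp(Delta / kT) identically.  IVR moves one
quantum of one mode within an electronic state, with the harmonic
ladder-operator scaling (a for emission out of level a, a+1 for
absorption); IC between electronic states carries the product of the
squared Franck-Condon overlaps of both modes.
"""

from __future__ import annotations

import numpy as np

from ..units import CM_TO_RAD_PER_PS, thermal_energy
from .basis import VibronicBasis
from .params import STATES, STATE_INDEX, ParameterError, VERAParameterSet, pair_key


def drude_spectral_density(omega, lam: float, gam: float):
    """Overdamped Drude C''(w) = 2*lam*gam*w/(w^2+gam^2), odd in w (cm^-1)."""
    w = np.asarray(omega, dtype=float)
    return 2.0 * lam * gam * w / (w * w + gam * gam)


def relaxation_rate(delta: float, lam: float, gam: float, temperature: float) -> float:
    """Golden-rule rate (ps^-1) for a transition releasing energy ``delta``.

    ``delta > 0`` is downhill (bath absorbs the gap), ``delta < 0`` uphill.
    The ``delta -> 0`` limit is finite: 2*pi*c * lam * kT / gam.
    """
    kt = thermal_energy(temperature)
    if lam == 0.0:
        return 0.0
    if abs(delta) < 1e-8:
        # w->0 limit of C''(w) * (coth(w/2kT)+1)/2 = (2 lam w / gam) * (kT/w)
        return CM_TO_RAD_PER_PS * 2.0 * lam * kt / gam
    mag = abs(delta)
    # (coth(w/2kT)+1)/2 = 1/(1 - exp(-w/kT)) = n(w) + 1
    downhill = CM_TO_RAD_PER_PS * drude_spectral_density(mag, lam, gam) / (1.0 - np.exp(-mag / kt))
    if delta >= 0:
        return float(downhill)
    # uphill as downhill * Boltzmann: detailed balance exact by construction
    return float(downhill * np.exp(-mag / kt))


def build_vera_rate_matrix(basis: VibronicBasis, params: VERAParameterSet | None = None) -> np.ndarray:
    """Probability-conserving generator K over the full vibronic level set.

    ``K[to, from]`` holds the transition rate (ps^-1); diagonal entries
    close each column to zero, so ``dn/dt = K @ n`` conserves the total
    population over all levels (ground-state levels included).
    """
    if params is None:
        params = basis.params
    if params.a_max != basis.a_max or params.mode_frequencies != basis.params.mode_frequencies:
        raise ParameterError("basis and parameter set are inconsistent")
    n = basis.n_levels
    amax = params.a_max
    w = params.mode_frequencies
    T = params.temperature
    K = np.zeros((n, n))

    # --- IVR: adjacent quanta of one mode, within one electronic state ---
    for s in STATES:
        per_mode = params.ivr_spectral_params.get(s)
        if per_mode is None:
            continue
        for alpha in (0, 1):
            lam, gam = per_mode[alpha]
            if lam == 0.0:
                continue
            k_down = relaxation_rate(w[alpha], lam, gam, T)   # per-quantum emission
            k_up = relaxation_rate(-w[alpha], lam, gam, T)    # per-quantum absorption
            for a1 in range(amax + 1):
                for a2 in range(amax + 1):
                    q = [a1, a2]
                    if q[alpha] >= 1:
                        lo = list(q)
                        lo[alpha] -= 1
                        i_hi = basis.index(s, a1, a2)
                        i_lo = basis.index(s, lo[0], lo[1])
                        K[i_lo, i_hi] += q[alpha] * k_down
                        K[i_hi, i_lo] += q[alpha] * k_up

    # --- IC: between electronic states, FC^2-weighted ---
    for lo, hi in params.ic_channels():
        lam, gam = params.ic_spectral_params[pair_key(lo, hi)]
        if lam == 0.0:
            continue
        f1, f2 = basis.fc_tables[pair_key(lo, hi)]
        for a1 in range(amax + 1):
            for a2 in range(amax + 1):
                i_hi = basis.index(hi, a1, a2)
                e_hi = basis.energies[i_hi]
                for b1 in range(amax + 1):
                    fc1 = f1[b1, a1] ** 2
                    if fc1 == 0.0:
                        continue
                    for b2 in range(amax + 1):
                        fc2 = fc1 * f2[b2, a2] ** 2
                        if fc2 == 0.0:
                            continue
                        i_lo = basis.index(lo, b1, b2)
                        delta = e_hi - basis.energies[i_lo]
                        K[i_lo, i_hi] += fc2 * relaxation_rate(delta, lam, gam, T)
                        K[i_hi, i_lo] += fc2 * relaxation_rate(-delta, lam, gam, T)

    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(K, -K.sum(axis=0))
    return K


def s1_decay_rates(basis: VibronicBasis, params: VERAParameterSet | None = None) -> np.ndarray:
    """Total IC depopulation rate (ps^-1) of each S1 vibronic level to S0.

    Indexed by (a1, a2) flattened in the same order as the S1 block of the
    basis.  Used by the combined chlorophyll-lutein model, where S1 decay
    acts as an untracked sink.
    """
    if params is None:
        params = basis.params
    key = pair_key("S0", "S1")
    if key not in params.ic_spectral_params:
        raise ParameterError("no S1->S0 internal-conversion channel configured")
    lam, gam = params.ic_spectral_params[key]
    f1, f2 = basis.fc_tables[key]
    amax = params.a_max
    T = params.temperature
    out = np.zeros((amax + 1) ** 2)
    k = 0
    for a1 in range(amax + 1):
        for a2 in range(amax + 1):
            e_hi = basis.energies[basis.index("S1", a1, a2)]
            tot = 0.0
            for b1 in range(amax + 1):
                for b2 in range(amax + 1):
                    fc2 = f1[b1, a1] ** 2 * f2[b2, a2] ** 2
                    if fc2 == 0.0:
                        continue
                    delta = e_hi - basis.energies[basis.index("S0", b1, b2)]
                    tot += fc2 * relaxation_rate(delta, lam, gam, T)
            out[k] = tot
            k += 1
    return out
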