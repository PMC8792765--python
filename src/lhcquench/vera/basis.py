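"""Vibronic basis enumeration and Franck-Condon factors.

The vibronic levels are |i, a1, a2> where i indexes the electronic state
and a1, a2 are the quantum numbers of the two optically coupled modes.
With mode frequencies independent of the electronic state (no Duschinsky
rotation), the vibrational overlaps between two electronic surfaces are
those of equal-frequency harmonic oscillators displaced by a
dimensionless d, for which closed forms exist in terms of associated
Laguerre polynomials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_genlaguerre, gammaln

from .params import STATES, STATE_INDEX, VERAParameterSet, pair_key


def franck_condon_overlap(d: float, a: int, b: int) -> float:
    """Overlap <a|b'> of harmonic-oscillator states displaced by dimensionless d.

    Both oscillators share one frequency; the Huang-Rhys factor is
    S = d^2/2 so that ``franck_condon_overlap(d, 0, 0)**2 == exp(-d**2/2)``.
    The sign convention follows the coherent-state displacement operator:
    flipping the sign of d changes the overlap by (-1)^(a-b); squared
    overlaps are invariant.
    """
    if a < 0 or b < 0:
        raise ValueError("vibrational quantum numbers must be non-negative")
    alpha = d / np.sqrt(2.0)  # coherent-state displacement
    if a >= b:
        m, n, sign = a, b, 1.0
    else:
        m, n, sign = b, a, (-1.0) ** (b - a)
    if m == n == 0:
        return float(np.exp(-alpha * alpha / 2.0))
    # <m|D(alpha)|n> = e^{-a^2/2} sqrt(n!/m!) alpha^{m-n} L_n^{(m-n)}(alpha^2)
    log_pref = 0.5 * (gammaln(n + 1) - gammaln(m + 1))
    lag = eval_genlaguerre(n, m - n, alpha * alpha)
    val = np.exp(-alpha * alpha / 2.0 + log_pref) * alpha ** (m - n) * lag
    if alpha == 0.0:
        val = 1.0 if m == n else 0.0
    return float(sign * val)


def fc_matrix(d: float, a_max: int) -> np.ndarray:
    """Table F[a, b] of overlaps up to a_max quanta on each surface."""
    n = a_max + 1
    out = np.empty((n, n))
    for a in range(n):
        for b in range(n):
            out[a, b] = franck_condon_overlap(d, a, b)
    return out


@dataclass
class VibronicBasis:
    """Enumerated vibronic levels of the four-state, two-mode model.

    Attributes
    ----------
    states:
        Electronic-state index per level (into :data:`STATES`).
    quanta:
        (n_levels, 2) integer array of (a1, a2) per level.
    energies:
        Level energies eps_i + (a1 + 1/2) w1 + (a2 + 1/2) w2 (cm^-1),
        zero-point terms included.
    fc_tables:
        Per state-pair key, a pair of FC tables (one per mode):
        ``fc_tables["S0-S1"][alpha][a, b]`` with row quanta on the lower
        state of the pair and column quanta on the upper.
    """

    params: VERAParameterSet
    states: np.ndarray
    quanta: np.ndarray
    energies: np.ndarray
    fc_tables: dict[str, tuple[np.ndarray, np.ndarray]]
    _index: dict[tuple[int, int, int], int]

    @property
    def n_levels(self) -> int:
        return len(self.energies)

    @property
    def a_max(self) -> int:
        return self.params.a_max

    def index(self, state: str, a1: int, a2: int) -> int:
        """Flat index of level |state, a1, a2>."""
        return self._index[(STATE_INDEX[state], a1, a2)]

    def level_label(self, k: int) -> str:
        i = self.states[k]
        a1, a2 = self.quanta[k]
        return f"{STATES[i]}({a1},{a2})"

    def state_mask(self, state: str) -> np.ndarray:
        return self.states == STATE_INDEX[state]

    def fc_product(self, lo: str, hi: str, a: tuple[int, int], b: tuple[int, int]) -> float:
        """Product of the two single-mode FC overlaps between |lo, a> and |hi, b>."""
        f1, f2 = self.fc_tables[pair_key(lo, hi)]
        return float(f1[a[0], b[0]] * f2[a[1], b[1]])


def build_vibronic_basis(params: VERAParameterSet) -> VibronicBasis:
    """Enumerate all 4*(a_max+1)^2 vibronic levels and their FC tables."""
    amax = params.a_max
    w1, w2 = params.mode_frequencies
    states, quanta, energies = [], [], []
    index: dict[tuple[int, int, int], int] = {}
    for i, s in enumerate(STATES):
        eps = params.electronic_energies[s]
        for a1 in range(amax + 1):
            for a2 in range(amax + 1):
                index[(i, a1, a2)] = len(states)
                states.append(i)
                quanta.append((a1, a2))
                energies.append(eps + (a1 + 0.5) * w1 + (a2 + 0.5) * w2)
    fc_tables: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ia, sa in enumerate(STATES):
        for sb in STATES[ia + 1:]:
            key = pair_key(sa, sb)
            d1, d2 = params.displacement(sa, sb)
            fc_tables[key] = (fc_matrix(d1, amax), fc_matrix(d2, amax))
    return VibronicBasis(
        params=params,
        states=np.asarray(states, dtype=int),
        quanta=np.asarray(quanta, dtype=int),
        energies=np.asarray(energies, dtype=float),
        fc_tables=fc_tables,
        _index=index,
    )
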