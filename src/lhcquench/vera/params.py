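"""Parameter container for the carotenoid vibronic relaxation model.

The model describes four singlet electronic states (S0, S1, S2, Sn) each
dressed by two optically coupled intramolecular stretching modes (the C-C
and C=C stretches of the conjugated backbone).  Relaxation is driven by
two kinds of system-bath coupling, each parameterized by an overdamped
Drude spectral density C''(w) = 2*lam*gam*w / (w^2 + gam^2):

* IVR terms move single vibrational quanta within one electronic state
  (one (lam, gam) pair per electronic state and mode);
* IC terms transfer population between electronic states, weighted by
  Franck-Condon factors (one (lam, gam) pair per coupled state pair).

All energies are in cm^-1, temperature in K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

#: Electronic states in ascending energetic order.
STATES = ("S0", "S1", "S2", "Sn")

STATE_INDEX = {s: i for i, s in enumerate(STATES)}


def pair_key(i: str, j: str) -> str:
    """Canonical unordered key for an electronic-state pair, e.g. ``"S0-S1"``."""
    if i not in STATE_INDEX or j not in STATE_INDEX:
        raise ValueError(f"unknown electronic state in pair ({i}, {j})")
    if i == j:
        raise ValueError(f"state pair must involve two distinct states, got ({i}, {j})")
    a, b = sorted((i, j), key=STATE_INDEX.__getitem__)
    return f"{a}-{b}"


class ParameterError(ValueError):
    """Raised when a parameter set violates its physical invariants."""


@dataclass
class VERAParameterSet:
    """All electronic, vibrational, bath and lineshape parameters.

    Parameters
    ----------
    electronic_energies:
        Phononless electronic energies eps_i (cm^-1); ``S0`` is the zero of
        energy by convention.
    mode_frequencies:
        (w1, w2) of the two optically coupled modes (cm^-1); w1 is the
        C-C stretch (~1100 cm^-1), w2 the C=C stretch (~1520 cm^-1).
    displacements:
        Dimensionless displacements (d1, d2) per electronic-state pair,
        keyed by :func:`pair_key`.  The Huang-Rhys factor of mode alpha is
        d_alpha^2 / 2.  Pairs absent from the mapping are undisplaced.
    ivr_spectral_params:
        Per electronic state, a pair of (lam, gam) Drude parameters
        (cm^-1), one per mode, controlling vibrational relaxation.
    ic_spectral_params:
        (lam, gam) Drude parameters per coupled state pair (keyed by
        :func:`pair_key`).  Only pairs listed here have an internal
        conversion channel; Sn deliberately has none by default.
    lineshape_widths:
        Per optical band (state-pair key): ``{"gaussian": sig,
        "lorentzian": gam}`` Voigt components in cm^-1.
    transition_strengths:
        Relative electronic transition dipole strengths per band.  S0-S1
        is dipole-forbidden (strength 0) but still carries Franck-Condon
        structure for the two-photon lineshape.
    temperature:
        Bath temperature (K).
    a_max:
        Highest vibrational quantum retained per mode (default 4; at
        least 2 for converged spectra, 1 only for cheap test fixtures).
    """

    electronic_energies: dict[str, float]
    mode_frequencies: tuple[float, float]
    displacements: dict[str, tuple[float, float]]
    ivr_spectral_params: dict[str, tuple[tuple[float, float], tuple[float, float]]]
    ic_spectral_params: dict[str, tuple[float, float]]
    lineshape_widths: dict[str, dict[str, float]] = field(default_factory=dict)
    transition_strengths: dict[str, float] = field(default_factory=dict)
    temperature: float = 300.0
    a_max: int = 4

    def __post_init__(self) -> None:
        self.mode_frequencies = tuple(float(w) for w in self.mode_frequencies)  # type: ignore[assignment]
        self.displacements = {k: tuple(map(float, v)) for k, v in self.displacements.items()}  # type: ignore[assignment]
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        ee = self.electronic_energies
        missing = [s for s in STATES if s not in ee]
        if missing:
            raise ParameterError(f"missing electronic energies for {missing}")
        if abs(ee["S0"]) > 1e-9:
            raise ParameterError("S0 energy must be the zero of energy")
        if not (ee["S1"] < ee["S2"] < ee["Sn"]):
            raise ParameterError(
                "electronic energies must be ordered S1 < S2 < Sn, got "
                f"{ee['S1']}, {ee['S2']}, {ee['Sn']}"
            )
        if len(self.mode_frequencies) != 2 or any(w <= 0 for w in self.mode_frequencies):
            raise ParameterError(f"mode frequencies must be two positive values, got {self.mode_frequencies}")
        for key, (d1, d2) in self.displacements.items():
            pair_key(*key.split("-"))  # validates the key
        for state, per_mode in self.ivr_spectral_params.items():
            if state not in STATE_INDEX:
                raise ParameterError(f"IVR parameters given for unknown state {state!r}")
            if len(per_mode) != 2:
                raise ParameterError(f"IVR parameters for {state} must cover both modes")
            for lam, gam in per_mode:
                if lam < 0 or gam <= 0:
                    raise ParameterError(f"IVR (lam, gam) must be >= 0 / > 0, got ({lam}, {gam}) for {state}")
        for key, (lam, gam) in self.ic_spectral_params.items():
            pair_key(*key.split("-"))
            if lam < 0 or gam <= 0:
                raise ParameterError(f"IC (lam, gam) must be >= 0 / > 0, got ({lam}, {gam}) for {key}")
        for key, widths in self.lineshape_widths.items():
            pair_key(*key.split("-"))
            if widths.get("gaussian", 0.0) < 0 or widths.get("lorentzian", 0.0) < 0:
                raise ParameterError(f"lineshape widths must be non-negative for {key}")
            if widths.get("gaussian", 0.0) == 0 and widths.get("lorentzian", 0.0) == 0:
                raise ParameterError(f"band {key} needs a nonzero Gaussian or Lorentzian width")
        if self.temperature <= 0:
            raise ParameterError(f"temperature must be positive, got {self.temperature}")
        if self.a_max < 1:
            raise ParameterError(f"a_max must be at least 1, got {self.a_max}")

    # ------------------------------------------------------------------
    def displacement(self, i: str, j: str) -> tuple[float, float]:
        """Dimensionless displacements (d1, d2) between states i and j (0 if unset)."""
        return self.displacements.get(pair_key(i, j), (0.0, 0.0))

    def band_widths(self, i: str, j: str) -> tuple[float, float]:
        """(gaussian sigma, lorentzian gamma) for the i-j optical band."""
        w = self.lineshape_widths.get(pair_key(i, j))
        if w is None:
            raise ParameterError(f"no lineshape widths configured for band {pair_key(i, j)}")
        return float(w.get("gaussian", 0.0)), float(w.get("lorentzian", 0.0))

    def strength(self, i: str, j: str) -> float:
        return float(self.transition_strengths.get(pair_key(i, j), 0.0))

    def ic_channels(self) -> list[tuple[str, str]]:
        """IC-coupled state pairs as (lower, upper) tuples."""
        out = []
        for key in self.ic_spectral_params:
            a, b = key.split("-")
            out.append((a, b))
        return out

    def replace(self, **changes) -> "VERAParameterSet":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def with_electronic_energy(self, state: str, value: float) -> "VERAParameterSet":
        ee = dict(self.electronic_energies)
        ee[state] = float(value)
        return self.replace(electronic_energies=ee)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "units": {"energy": "cm^-1", "temperature": "K"},
            "electronic_energies": dict(self.electronic_energies),
            "mode_frequencies": list(self.mode_frequencies),
            "displacements": {k: list(v) for k, v in self.displacements.items()},
            "ivr_spectral_params": {k: [list(p) for p in v] for k, v in self.ivr_spectral_params.items()},
            "ic_spectral_params": {k: list(v) for k, v in self.ic_spectral_params.items()},
            "lineshape_widths": {k: dict(v) for k, v in self.lineshape_widths.items()},
            "transition_strengths": dict(self.transition_strengths),
            "temperature": self.temperature,
            "a_max": self.a_max,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VERAParameterSet":
        return cls(
            electronic_energies={k: float(v) for k, v in d["electronic_energies"].items()},
            mode_frequencies=tuple(d["mode_frequencies"]),
            displacements={k: tuple(v) for k, v in d.get("displacements", {}).items()},
            ivr_spectral_params={
                k: tuple(tuple(map(float, p)) for p in v)
                for k, v in d.get("ivr_spectral_params", {}).items()
            },
            ic_spectral_params={k: tuple(map(float, v)) for k, v in d.get("ic_spectral_params", {}).items()},
            lineshape_widths={k: dict(v) for k, v in d.get("lineshape_widths", {}).items()},
            transition_strengths={k: float(v) for k, v in d.get("transition_strengths", {}).items()},
            temperature=float(d.get("temperature", 300.0)),
            a_max=int(d.get("a_max", 4)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "VERAParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def lutein_pyridine_params(a_max: int = 4, temperature: float = 300.0) -> VERAParameterSet:
    """Synthetic reference parameter set for lutein in pyridine.

    A stand-in parameterization of the vibronic model, calibrated once
    against the published solution-phase observables for lutein: the
    phononless S1 energy (14,050 cm^-1), the S1-Sn excited-state
    absorption gap (~17,900 cm^-1), a near mono-exponential S1 lifetime
    of ~14 ps, S2 internal conversion on the ~100 fs scale, and
    vibrational relaxation on S1 of ~1 ps with a ~1100 cm^-1 C-C
    progression.  The bath (lam, gam) values below are this package's own
    calibration; they are not fitted to any specific measured surface.
    """
    return VERAParameterSet(
        electronic_energies={"S0": 0.0, "S1": 14050.0, "S2": 20600.0, "Sn": 31950.0},
        mode_frequencies=(1100.0, 1520.0),
        displacements={
            "S0-S1": (1.10, 1.20),
            "S0-S2": (0.90, 1.00),
            "S1-S2": (0.70, 0.80),
            "S1-Sn": (0.50, 0.60),
        },
        ivr_spectral_params={
            "S0": ((60.0, 50.0), (60.0, 50.0)),
            "S1": ((60.0, 50.0), (60.0, 50.0)),
            "S2": ((60.0, 50.0), (60.0, 50.0)),
            "Sn": ((60.0, 50.0), (60.0, 50.0)),
        },
        ic_spectral_params={
            # calibrated: S2->S1 ~100 fs, S1->S0 ~14 ps (see docs/methods.md)
            "S1-S2": (490.0, 300.0),
            "S0-S1": (82.0, 28.0),
        },
        lineshape_widths={
            "S0-S2": {"gaussian": 380.0, "lorentzian": 120.0},
            "S0-S1": {"gaussian": 380.0, "lorentzian": 100.0},
            "S1-Sn": {"gaussian": 350.0, "lorentzian": 150.0},
        },
        transition_strengths={"S0-S2": 1.0, "S0-S1": 0.0, "S1-Sn": 1.0},
        temperature=temperature,
        a_max=a_max,
    )
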