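"""Global fitting of the vibronic model to transient-absorption surfaces.

The residual stacks the pointwise difference between the simulated and
measured dA(w, t) surface with an optional weighted linear-absorption
block, so the fit cannot repair the TA at the expense of the LA.
Optimization is bounded trust-region nonlinear least squares with a
configurable number of jittered restarts (the fit surface is known to be
degenerate: the S1 energy trades off against the S0-S1 displacements and
the Sn energy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.optimize import least_squares

from .vera.basis import build_vibronic_basis
from .vera.dynamics import PumpPulse, propagate_populations
from .vera.params import VERAParameterSet
from .vera.rates import build_vera_rate_matrix
from .vera.spectra import linear_absorption, ta_difference_spectrum


@dataclass
class TADataset:
    """A transient-absorption surface dA(w, t).

    ``da`` has shape (n_wavenumbers, n_delays); delays must be strictly
    increasing.  ``noise_sigma`` optionally holds per-point noise.
    """

    delays: np.ndarray          # ps
    wavenumbers: np.ndarray     # cm^-1
    da: np.ndarray              # (n_w, n_t)
    noise_sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.da = np.asarray(self.da, dtype=float)
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if self.da.shape != (self.wavenumbers.size, self.delays.size):
            raise ValueError(
                f"dA matrix shape {self.da.shape} does not match axes "
                f"({self.wavenumbers.size}, {self.delays.size})"
            )


@dataclass
class FitResult:
    """Outcome of a TA fit."""

    params: VERAParameterSet
    frozen: tuple[str, ...]
    free: tuple[str, ...]
    uncertainties: dict[str, float]
    residual_norm: float       # normalized by the dataset's peak |dA|
    converged: bool
    n_evaluations: int
    message: str = ""


# ---------------------------------------------------------------------------
# named-parameter registry (value accessors + physical bounds)
# ---------------------------------------------------------------------------

def _get_energy(state):
    return lambda p: p.electronic_energies[state]


def _set_energy(state):
    def setter(p, v):
        return p.with_electronic_energy(state, v)
    return setter


def _get_disp(pair, mode):
    return lambda p: p.displacements.get(pair, (0.0, 0.0))[mode]


def _set_disp(pair, mode):
    def setter(p, v):
        d = dict(p.displacements)
        cur = list(d.get(pair, (0.0, 0.0)))
        cur[mode] = float(v)
        d[pair] = tuple(cur)
        return p.replace(displacements=d)
    return setter


#: name -> (getter, setter, bound_kind); energy bounds are +-3000 cm^-1
#: around the starting value, displacements are confined to [0, 2].
PARAM_REGISTRY = {
    "eps_S1": (_get_energy("S1"), _set_energy("S1"), "energy"),
    "eps_S2": (_get_energy("S2"), _set_energy("S2"), "energy"),
    "eps_Sn": (_get_energy("Sn"), _set_energy("Sn"), "energy"),
    "d1_S0S1": (_get_disp("S0-S1", 0), _set_disp("S0-S1", 0), "displacement"),
    "d2_S0S1": (_get_disp("S0-S1", 1), _set_disp("S0-S1", 1), "displacement"),
    "d1_S0S2": (_get_disp("S0-S2", 0), _set_disp("S0-S2", 0), "displacement"),
    "d2_S0S2": (_get_disp("S0-S2", 1), _set_disp("S0-S2", 1), "displacement"),
    "d1_S1S2": (_get_disp("S1-S2", 0), _set_disp("S1-S2", 0), "displacement"),
    "d2_S1S2": (_get_disp("S1-S2", 1), _set_disp("S1-S2", 1), "displacement"),
    "d1_S1Sn": (_get_disp("S1-Sn", 0), _set_disp("S1-Sn", 0), "displacement"),
    "d2_S1Sn": (_get_disp("S1-Sn", 1), _set_disp("S1-Sn", 1), "displacement"),
}

DEFAULT_FREE = ("eps_S2", "eps_Sn", "d1_S0S1", "d2_S0S1", "d1_S0S2", "d2_S0S2")


def apply_parameters(params: VERAParameterSet, names: tuple[str, ...], values: np.ndarray) -> VERAParameterSet:
    for name, v in zip(names, values):
        _, setter, _ = PARAM_REGISTRY[name]
        params = setter(params, float(v))
    return params


def extract_parameters(params: VERAParameterSet, names: tuple[str, ...]) -> np.ndarray:
    return np.array([PARAM_REGISTRY[name][0](params) for name in names])


# ---------------------------------------------------------------------------
# forward model and residual
# ---------------------------------------------------------------------------

def default_pump(params: VERAParameterSet) -> PumpPulse:
    """100 fs pulse resonant with the S2 0-0 line.

    A transform-limited 100 fs Gaussian has a ~150 cm^-1 spectral FWHM,
    much narrower than the vibronic spacing, so centering on the 0-0
    line pumps essentially only |S2, 0, 0>.
    """
    return PumpPulse(
        center_time=0.0, duration_fwhm=0.1,
        center_wavenumber=params.electronic_energies["S2"],
        fluence=0.5,
    )


def simulate_ta(
    params: VERAParameterSet,
    delays: np.ndarray,
    wavenumbers: np.ndarray,
    pump: PumpPulse | None = None,
) -> np.ndarray:
    """Forward dA(w, t) surface for the given parameters (no noise)."""
    delays = np.asarray(delays, dtype=float)
    if pump is None:
        pump = default_pump(params)
    basis = build_vibronic_basis(params)
    K = build_vera_rate_matrix(basis, params)
    t0 = min(pump.center_time - 2.0 * pump.duration_fwhm, delays[0])
    t_grid = np.union1d(np.linspace(t0, delays[-1], 200), delays)
    traj = propagate_populations(K, pump, t_grid, basis, rtol=1e-8, atol=1e-12)
    return ta_difference_spectrum(traj, params, basis, wavenumbers, delays)


def residual(
    params: VERAParameterSet,
    dataset: TADataset,
    la_reference: tuple[np.ndarray, np.ndarray] | None = None,
    la_weight: float = 1.0,
    subps_weight: float = 0.3,
    pump: PumpPulse | None = None,
) -> np.ndarray:
    """Stacked (model - data) residual over the TA surface and optional LA block.

    Sub-picosecond delays are down-weighted by ``subps_weight`` (they are
    dominated by the pump overlap and matter least for the S1 channel).
    ``la_reference = (omega_grid, la_values)`` appends a weighted
    linear-absorption constraint.
    """
    model = simulate_ta(params, dataset.delays, dataset.wavenumbers, pump=pump)
    weights = np.where(dataset.delays < 1.0, subps_weight, 1.0)[None, :]
    res = ((model - dataset.da) * weights).ravel()
    if la_reference is not None:
        grid, ref = la_reference
        basis = build_vibronic_basis(params)
        la = linear_absorption(params, basis, np.asarray(grid, dtype=float))
        scale = np.abs(ref).max()
        res = np.concatenate([res, la_weight * (la - ref).ravel() / (scale if scale > 0 else 1.0)])
    return res


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_ta(
    dataset: TADataset,
    initial: VERAParameterSet,
    frozen: tuple[str, ...] = ("eps_S1",),
    free: tuple[str, ...] | None = None,
    la_reference: tuple[np.ndarray, np.ndarray] | None = None,
    la_weight: float = 1.0,
    subps_weight: float = 0.3,
    pump: PumpPulse | None = None,
    n_restarts: int = 8,
    jitter: float = 0.02,
    seed: int = 0,
    max_nfev: int = 200,
) -> FitResult:
    """Bounded nonlinear least squares over the named free parameters.

    ``free`` defaults to the standard S2/Sn energy + ground-state
    displacement set minus anything in ``frozen``; frozen parameters are
    returned verbatim.  Restarts jitter the start point multiplicatively
    by ``jitter`` (fixed ``seed``); the lowest residual wins.
    Non-convergence is reported through ``converged``, never raised.
    """
    if free is None:
        free = tuple(n for n in DEFAULT_FREE if n not in frozen)
    else:
        free = tuple(n for n in free if n not in frozen)
    for name in free + tuple(frozen):
        if name not in PARAM_REGISTRY:
            raise KeyError(f"unknown fit parameter {name!r}")
    x0 = extract_parameters(initial, free)
    lo = np.empty_like(x0)
    hi = np.empty_like(x0)
    x_scale = np.empty_like(x0)
    diff_step = np.empty_like(x0)
    for k, name in enumerate(free):
        kind = PARAM_REGISTRY[name][2]
        if kind == "energy":
            lo[k], hi[k] = x0[k] - 3000.0, x0[k] + 3000.0
            x_scale[k] = 1000.0
            diff_step[k] = 1e-4       # a few cm^-1 finite-difference step
        else:
            lo[k], hi[k] = 0.0, 2.0
            x_scale[k] = 0.3
            diff_step[k] = 1e-2

    # normalize so the optimizer's gtol/ftol act on O(1) residuals
    data_scale = float(np.abs(dataset.da).max()) or 1.0

    def fun(x):
        p = apply_parameters(initial, free, x)
        return residual(p, dataset, la_reference=la_reference, la_weight=la_weight,
                        subps_weight=subps_weight, pump=pump) / data_scale

    rng = np.random.default_rng(seed)
    best_sol = None
    best_norm = np.inf
    n_eval = 0
    last_error = ""
    for trial in range(max(1, n_restarts)):
        if trial == 0:
            start = x0.copy()
        else:
            start = np.clip(x0 * (1.0 + jitter * rng.standard_normal(x0.shape)), lo, hi)
        try:
            sol = least_squares(fun, start, bounds=(lo, hi), method="trf",
                                x_scale=x_scale, diff_step=diff_step,
                                max_nfev=max_nfev, xtol=1e-10, ftol=1e-10)
        except Exception as exc:  # report as a flagged result, never raise
            last_error = str(exc)
            continue
        n_eval += sol.nfev
        norm = float(np.linalg.norm(sol.fun))
        if norm < best_norm:
            best_norm, best_sol = norm, sol
    if best_sol is None:
        return _failed_result(initial, frozen, free, last_error or "no trials ran")
    norm, sol = best_norm, best_sol
    fitted = apply_parameters(initial, free, sol.x)
    # 1-sigma uncertainties from the Gauss-Newton approximation
    unc: dict[str, float] = {}
    try:
        jtj = sol.jac.T @ sol.jac
        dof = max(1, sol.fun.size - sol.x.size)
        cov = np.linalg.pinv(jtj) * (norm**2 / dof)
        for k, name in enumerate(free):
            unc[name] = float(np.sqrt(max(cov[k, k], 0.0)))
    except Exception:
        unc = {name: float("nan") for name in free}
    return FitResult(
        params=fitted, frozen=tuple(frozen), free=free, uncertainties=unc,
        residual_norm=norm, converged=bool(sol.status > 0), n_evaluations=n_eval,
        message=sol.message,
    )


def _failed_result(initial, frozen, free, msg) -> FitResult:
    return FitResult(
        params=initial, frozen=tuple(frozen), free=tuple(free),
        uncertainties={n: float("nan") for n in free},
        residual_norm=float("inf"), converged=False, n_evaluations=0, message=msg,
    )
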