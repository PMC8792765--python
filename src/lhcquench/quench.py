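"""Combined chlorophyll-exciton / lutein-vibronic quenching kinetics.

The chlorophyll manifold and each lutein S1 vibronic ladder are treated
as weakly interacting subsystems exchanging population incoherently.
Cross rates follow the Fermi golden rule: squared exciton-basis coupling
times squared Franck-Condon factors times the spectral overlap of the
area-normalized donor fluorescence line and an acceptor vibronic
Gaussian of width 1070 cm^-1.  Uphill rates carry Boltzmann factors so
every pair satisfies detailed balance.  Ground states are not tracked:
chlorophyll excitons decay with the intrinsic rate Gamma_Chl and each S1
level decays with its internal-conversion rate into an untracked sink,
assuming instantaneous vibrational relaxation on the ground state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .exciton import (
    ExcitonBasis,
    PigmentGeometry,
    SnapshotEnsemble,
    SpectralDensity,
    build_site_hamiltonian,
    coulomb_coupling,
    diagonalize,
    redfield_rates,
)
from .units import CM_TO_RAD_PER_PS, thermal_energy
from .vera.basis import fc_matrix
from .vera.params import VERAParameterSet, lutein_pyridine_params
from .vera.rates import relaxation_rate

#: Intrinsic (unquenched) chlorophyll decay rate, ps^-1 (4 ns lifetime).
GAMMA_CHL_DEFAULT = 1.0 / 4000.0


@dataclass
class LutSiteConfig:
    """Per-lutein parameters of the quenching channel.

    ``site_couplings`` are the electronic couplings J_n,Lut (cm^-1)
    between each chlorophyll site transition and the lutein S1 0-0
    transition; they may instead be computed from geometry by the
    ensemble helpers.  ``delta_omega10`` is the FWHM of the acceptor
    vibronic Gaussian lineshape (cm^-1); the energetic-resonance
    behaviour of the quenching pathway hinges on this width being the
    full width, not the standard deviation.
    """

    lut_id: str = "LUT1"
    eps_s1: float = 14050.0
    delta_omega10: float = 1070.0
    site_couplings: np.ndarray | None = None
    decay_rates: np.ndarray | None = None  # optional per-level sink override (ps^-1)

    def __post_init__(self) -> None:
        if self.delta_omega10 <= 0:
            raise ValueError(f"acceptor vibronic width must be positive, got {self.delta_omega10}")
        if self.site_couplings is not None:
            self.site_couplings = np.asarray(self.site_couplings, dtype=float)

    def with_eps_s1(self, eps: float) -> "LutSiteConfig":
        return LutSiteConfig(
            lut_id=self.lut_id,
            eps_s1=float(eps),
            delta_omega10=self.delta_omega10,
            site_couplings=None if self.site_couplings is None else self.site_couplings.copy(),
            decay_rates=None if self.decay_rates is None else self.decay_rates.copy(),
        )


@dataclass
class CombinedRateModel:
    """Joint rate model over Chl excitons and Lut S1 vibronic levels.

    ``generator[to, from]`` holds transition rates (ps^-1); diagonal
    entries include the decay sinks, so columns sum to minus the total
    loss out of the tracked manifold.
    """

    generator: np.ndarray
    initial: np.ndarray
    labels: list[str]
    n_excitons: int
    lut_slices: dict[str, slice]
    lut_sink_rates: dict[str, np.ndarray]
    gamma_chl: float
    temperature: float

    @property
    def n_states(self) -> int:
        return len(self.initial)


class DivergenceError(RuntimeError):
    """Raised when the generator is not strictly dissipative."""


# ---------------------------------------------------------------------------
# couplings and golden-rule rates
# ---------------------------------------------------------------------------

def exciton_lut_coupling(basis: ExcitonBasis, site_couplings: np.ndarray) -> np.ndarray:
    """Rotate site-basis Chl-Lut couplings into the exciton basis.

    J_i = sum_n c_ni J_n; the coupling norm sum_i J_i^2 = sum_n J_n^2 is
    preserved exactly (orthonormal rotation).
    """
    site_couplings = np.asarray(site_couplings, dtype=float)
    if site_couplings.shape != (basis.coefficients.shape[0],):
        raise ValueError(
            f"site coupling vector has shape {site_couplings.shape}, expected "
            f"({basis.coefficients.shape[0]},)"
        )
    return basis.coefficients.T @ site_couplings


def gaussian_overlap(center_a: float, sigma_a: float, center_b: float, sigma_b: float) -> float:
    """Overlap integral of two area-normalized Gaussians (units 1/cm^-1)."""
    var = sigma_a**2 + sigma_b**2
    return float(np.exp(-0.5 * (center_a - center_b) ** 2 / var) / np.sqrt(2.0 * np.pi * var))


def fgr_transfer_rate(
    coupling: float,
    fc_product_sq: float,
    donor_center: float,
    donor_sigma: float,
    acceptor_center: float,
    acceptor_sigma: float,
    temperature: float = 300.0,
    level_gap: float | None = None,
) -> tuple[float, float]:
    """Forward and backward golden-rule rates (ps^-1) for one channel.

    ``coupling`` is the exciton-basis electronic coupling (cm^-1),
    ``fc_product_sq`` the squared two-mode Franck-Condon product, the
    lineshapes are area-normalized Gaussians.  ``level_gap`` (donor
    zero-phonon energy minus acceptor vibronic energy, cm^-1; defaults
    to center difference) sets the detailed-balance Boltzmann factor on
    the uphill member of the pair.
    """
    if donor_sigma <= 0 or acceptor_sigma <= 0:
        raise ValueError("lineshape widths must be positive")
    if coupling == 0.0 or fc_product_sq == 0.0:
        return 0.0, 0.0
    overlap = gaussian_overlap(donor_center, donor_sigma, acceptor_center, acceptor_sigma)
    base = CM_TO_RAD_PER_PS * 2.0 * np.pi * fc_product_sq * coupling**2 * overlap
    gap = donor_center - acceptor_center if level_gap is None else level_gap
    kt = thermal_energy(temperature)
    if gap >= 0:                       # forward is downhill
        return base, base * float(np.exp(-gap / kt))
    return base * float(np.exp(gap / kt)), base


def s1_sink_rates(params: VERAParameterSet, eps_s1: float) -> np.ndarray:
    """Internal-conversion decay rate (ps^-1) of each S1 level to the ground sink.

    Uses the S1->S0 Drude channel and Franck-Condon tables of ``params``
    with the phononless S1 energy replaced by ``eps_s1``; the final S0
    vibrational levels are summed over (and not tracked afterwards).
    """
    lam, gam = params.ic_spectral_params["S0-S1"]
    d1, d2 = params.displacement("S0", "S1")
    amax = params.a_max
    w1, w2 = params.mode_frequencies
    f1, f2 = fc_matrix(d1, amax), fc_matrix(d2, amax)
    out = np.zeros((amax + 1) ** 2)
    k = 0
    for a1 in range(amax + 1):
        for a2 in range(amax + 1):
            tot = 0.0
            for b1 in range(amax + 1):
                for b2 in range(amax + 1):
                    fc2 = f1[b1, a1] ** 2 * f2[b2, a2] ** 2
                    if fc2 == 0.0:
                        continue
                    delta = eps_s1 + (a1 - b1) * w1 + (a2 - b2) * w2
                    tot += fc2 * relaxation_rate(delta, lam, gam, params.temperature)
            out[k] = tot
            k += 1
    return out


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def build_combined_model(
    basis: ExcitonBasis,
    luts: list[LutSiteConfig],
    vera_params: VERAParameterSet | None = None,
    redfield: np.ndarray | None = None,
    spectral_density: SpectralDensity | None = None,
    gamma_chl: float = GAMMA_CHL_DEFAULT,
    temperature: float = 300.0,
    donor_sigma: float = 120.0,
    reorganization: float = 37.0,
) -> CombinedRateModel:
    """Assemble the joint rate matrix with decay sinks.

    Block structure: excitons first, then one S1 vibronic ladder per
    lutein (luteins are mutually uncoupled).  The initial vector is
    normalized over excitons proportionally to their oscillator
    strengths.
    """
    if vera_params is None:
        vera_params = lutein_pyridine_params(temperature=temperature)
    if spectral_density is None:
        spectral_density = SpectralDensity()
    if redfield is None:
        redfield = redfield_rates(basis, spectral_density, temperature)
    n_exc = basis.n_excitons
    amax = vera_params.a_max
    n_vib = (amax + 1) ** 2
    w1, w2 = vera_params.mode_frequencies
    d1, d2 = vera_params.displacement("S0", "S1")
    f1, f2 = fc_matrix(d1, amax), fc_matrix(d2, amax)

    n_tot = n_exc + len(luts) * n_vib
    A = np.zeros((n_tot, n_tot))
    A[:n_exc, :n_exc] = redfield - np.diag(np.diag(redfield))

    labels = [f"exc{i}" for i in range(n_exc)]
    lut_slices: dict[str, slice] = {}
    lut_sink: dict[str, np.ndarray] = {}
    sinks = np.zeros(n_tot)
    sinks[:n_exc] = gamma_chl

    # effective reorganization shift of each exciton fluorescence line
    pr4 = (basis.coefficients**4).sum(axis=0)
    lam_i = reorganization * pr4

    kt = thermal_energy(temperature)
    ivr = vera_params.ivr_spectral_params.get("S1")

    for ell, lut in enumerate(luts):
        if lut.site_couplings is None:
            raise ValueError(f"lutein {lut.lut_id} has no site couplings configured")
        off = n_exc + ell * n_vib
        sl = slice(off, off + n_vib)
        lut_slices[lut.lut_id] = sl
        j_exc = exciton_lut_coupling(basis, lut.site_couplings)

        decay = lut.decay_rates if lut.decay_rates is not None else s1_sink_rates(vera_params, lut.eps_s1)
        if decay.shape != (n_vib,):
            raise ValueError(f"lutein {lut.lut_id} decay rates have wrong shape {decay.shape}")
        lut_sink[lut.lut_id] = np.asarray(decay, dtype=float)
        sinks[sl] = decay

        # level bookkeeping within the ladder
        level_index = {}
        k = 0
        for b1 in range(amax + 1):
            for b2 in range(amax + 1):
                level_index[(b1, b2)] = off + k
                labels.append(f"{lut.lut_id}:S1({b1},{b2})")
                k += 1

        # intra-S1 IVR (retains the |1_10> <-> |1_00> bottleneck)
        if ivr is not None:
            for alpha, w in ((0, w1), (1, w2)):
                lam, gam = ivr[alpha]
                if lam == 0.0:
                    continue
                k_dn = relaxation_rate(w, lam, gam, temperature)
                k_up = relaxation_rate(-w, lam, gam, temperature)
                for b1 in range(amax + 1):
                    for b2 in range(amax + 1):
                        q = [b1, b2]
                        if q[alpha] >= 1:
                            lo = list(q)
                            lo[alpha] -= 1
                            hi_idx = level_index[(b1, b2)]
                            lo_idx = level_index[(lo[0], lo[1])]
                            A[lo_idx, hi_idx] += q[alpha] * k_dn
                            A[hi_idx, lo_idx] += q[alpha] * k_up

        # FGR cross rates between every exciton and every S1 level
        acceptor_sigma = lut.delta_omega10 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        for i in range(n_exc):
            donor_center = basis.energies[i] - lam_i[i]
            for (b1, b2), idx in level_index.items():
                acc_center = lut.eps_s1 + b1 * w1 + b2 * w2
                fc2 = (f1[0, b1] * f2[0, b2]) ** 2
                gap = basis.energies[i] - acc_center
                k_f, k_b = fgr_transfer_rate(
                    j_exc[i], fc2, donor_center, donor_sigma, acc_center,
                    acceptor_sigma, temperature, level_gap=gap,
                )
                A[idx, i] += k_f
                A[i, idx] += k_b

    if np.any(A - np.diag(np.diag(A)) < -1e-12):
        raise ValueError("combined model construction produced a negative off-diagonal rate")

    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(A, -(A.sum(axis=0) + sinks))

    p0 = np.zeros(n_tot)
    f = basis.oscillator_strengths
    p0[:n_exc] = f / f.sum() if f.sum() > 0 else 1.0 / n_exc
    return CombinedRateModel(
        generator=A,
        initial=p0,
        labels=labels,
        n_excitons=n_exc,
        lut_slices=lut_slices,
        lut_sink_rates=lut_sink,
        gamma_chl=gamma_chl,
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# lifetimes and experiments
# ---------------------------------------------------------------------------

def mean_excitation_lifetime(model: CombinedRateModel, method: str = "inverse") -> float:
    """Population-integrated excitation lifetime tau (ps).

    tau = int_0^inf P_exc(t) dt / P_exc(0) with P_exc the total tracked
    population; in closed form tau = 1^T (-A)^-1 p0.  ``method="ode"``
    integrates the kinetics in the time domain instead (cross-check).
    """
    A, p0 = model.generator, model.initial
    if method == "inverse":
        try:
            x = np.linalg.solve(-A, p0)
        except np.linalg.LinAlgError as exc:
            raise DivergenceError("generator is singular; model is not dissipative") from exc
        tau = float(x.sum() / p0.sum())
        if not np.isfinite(tau) or tau <= 0:
            raise DivergenceError(f"non-dissipative generator produced tau = {tau}")
        return tau
    if method == "ode":
        # adaptive quadrature of P_exc(t) via stepwise matrix exponentials
        tau_inv = mean_excitation_lifetime(model, method="inverse")
        t_end = 12.0 * tau_inv
        n_steps = 3000
        ts = np.linspace(0.0, t_end, n_steps + 1)
        P = expm(A * (ts[1] - ts[0]))
        n = p0.copy()
        pops = np.empty(n_steps + 1)
        pops[0] = n.sum()
        for k in range(1, n_steps + 1):
            n = P @ n
            pops[k] = n.sum()
        return float(np.trapezoid(pops, ts) / p0.sum())
    raise ValueError(f"unknown method {method!r}")


def lut_population_shares(model: CombinedRateModel, t_upto: float | None = None) -> dict[str, float]:
    """Fraction of dissipated population routed through each lutein sink.

    Cumulative sink flux up to ``t_upto`` (default: the mean excitation
    lifetime), normalized by the total population dissipated by then.
    """
    A, p0 = model.generator, model.initial
    if t_upto is None:
        t_upto = mean_excitation_lifetime(model)
    n_t = expm(A * t_upto) @ p0
    x = np.linalg.solve(-A, p0 - n_t)      # integral of n(t) over [0, t_upto]
    dissipated = p0.sum() - n_t.sum()
    shares = {}
    for lut_id, sl in model.lut_slices.items():
        flux = float(model.lut_sink_rates[lut_id] @ x[sl])
        shares[lut_id] = flux / dissipated if dissipated > 0 else 0.0
    return shares


@dataclass
class LifetimeResult:
    """Per-snapshot lifetimes of an ensemble and their summary."""

    lifetimes: np.ndarray                     # (n_snapshots,), ps
    mean: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    lut_shares: list[dict[str, float]] = field(default_factory=list)


def _couplings_from_snapshot(
    snapshot: list[PigmentGeometry], lut_id: str, eps_r: float
) -> np.ndarray:
    chls = [p for p in snapshot if p.pigment_type != "LUT"]
    lut = next((p for p in snapshot if p.pigment_id == lut_id), None)
    if lut is None:
        raise KeyError(f"snapshot has no pigment {lut_id}")
    return np.array(
        [coulomb_coupling(c, lut, eps_r=eps_r, transition_m="qy", transition_n="s1") for c in chls]
    )


def model_from_snapshot(
    snapshot: list[PigmentGeometry],
    luts: list[LutSiteConfig],
    site_energies: dict[str, float] | None = None,
    eps_r: float = 2.0,
    vera_params: VERAParameterSet | None = None,
    **model_kwargs,
) -> CombinedRateModel:
    """Diagonalize one snapshot and couple it to its luteins.

    Lutein site couplings are recomputed from the snapshot geometry for
    configs that do not carry explicit couplings.
    """
    H = build_site_hamiltonian(snapshot, site_energies=site_energies, eps_r=eps_r)
    basis = diagonalize(H, snapshot)
    resolved = []
    for lut in luts:
        if lut.site_couplings is None:
            j_site = _couplings_from_snapshot(snapshot, lut.lut_id, eps_r)
            lut = LutSiteConfig(
                lut_id=lut.lut_id, eps_s1=lut.eps_s1, delta_omega10=lut.delta_omega10,
                site_couplings=j_site, decay_rates=lut.decay_rates,
            )
        resolved.append(lut)
    return build_combined_model(basis, resolved, vera_params=vera_params, **model_kwargs)


def snapshot_lifetime_distribution(
    ensemble: SnapshotEnsemble | list[list[PigmentGeometry]],
    luts: list[LutSiteConfig],
    site_energies: dict[str, float] | None = None,
    eps_r: float = 2.0,
    vera_params: VERAParameterSet | None = None,
    with_shares: bool = False,
    **model_kwargs,
) -> LifetimeResult:
    """Per-snapshot mean excitation lifetimes with a Freedman-Diaconis histogram.

    Couplings are recomputed per snapshot; only relative comparisons
    between ensembles are contractually meaningful.
    """
    snapshots = list(ensemble)
    if not snapshots:
        raise ValueError("ensemble is empty")
    taus = np.empty(len(snapshots))
    shares: list[dict[str, float]] = []
    for k, snap in enumerate(snapshots):
        model = model_from_snapshot(
            snap, luts, site_energies=site_energies, eps_r=eps_r,
            vera_params=vera_params, **model_kwargs,
        )
        taus[k] = mean_excitation_lifetime(model)
        if with_shares:
            shares.append(lut_population_shares(model))
    spread = np.ptp(taus)
    if spread < 1e-9:
        edges = np.array([taus[0] - 1.0, taus[0] + 1.0])
    else:
        iqr = np.subtract(*np.percentile(taus, [75, 25]))
        width = 2.0 * iqr / len(taus) ** (1 / 3) if iqr > 0 else spread / 10.0
        n_bins = max(1, int(np.ceil(spread / width)))
        edges = np.linspace(taus.min(), taus.max(), n_bins + 1)
    counts, edges = np.histogram(taus, bins=edges)
    return LifetimeResult(
        lifetimes=taus, mean=float(taus.mean()), hist_counts=counts,
        hist_edges=edges, lut_shares=shares,
    )


def s1_energy_scan(
    basis: ExcitonBasis,
    luts: list[LutSiteConfig],
    eps_values: np.ndarray,
    vera_params: VERAParameterSet | None = None,
    **model_kwargs,
) -> np.ndarray:
    """Mean excitation lifetime (ps) versus the lutein phononless S1 energy.

    Every lutein is shifted to each candidate energy in turn; returns
    one tau per grid point.
    """
    eps_values = np.asarray(eps_values, dtype=float)
    if np.any((eps_values < 12000.0) | (eps_values > 20000.0)):
        raise ValueError("S1 energy scan grid must lie within [12,000, 20,000] cm^-1")
    taus = np.empty(eps_values.shape)
    for k, eps in enumerate(eps_values):
        shifted = [lut.with_eps_s1(eps) for lut in luts]
        model = build_combined_model(basis, shifted, vera_params=vera_params, **model_kwargs)
        taus[k] = mean_excitation_lifetime(model)
    return taus


def two_lutein_experiment(
    basis: ExcitonBasis,
    lut1: LutSiteConfig,
    lut2: LutSiteConfig,
    eps_lut1: float | None = None,
    eps_lut2: float | None = None,
    vera_params: VERAParameterSet | None = None,
    **model_kwargs,
) -> tuple[float, dict[str, float]]:
    """Lifetime and per-lutein quenched-population shares for a two-Lut model.

    Optionally overrides each lutein's phononless S1 energy; the shares
    are cumulative sink fluxes up to t = tau (normalized by the total
    dissipated population), the estimator behind energetic-asymmetry
    abolition of Lut2 quenching.
    """
    if eps_lut1 is not None:
        lut1 = lut1.with_eps_s1(eps_lut1)
    if eps_lut2 is not None:
        lut2 = lut2.with_eps_s1(eps_lut2)
    model = build_combined_model(basis, [lut1, lut2], vera_params=vera_params, **model_kwargs)
    tau = mean_excitation_lifetime(model)
    return tau, lut_population_shares(model, t_upto=tau)
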