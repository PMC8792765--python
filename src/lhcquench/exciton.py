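"""Frenkel exciton model of the chlorophyll manifold.

Pigments are represented by transition atomic charges placed on atom
coordinates; excitonic couplings are pairwise Coulomb sums over those
charges screened by an effective dielectric (eps_r = 2 by default).
Site energies are fixed literature-style inputs, not computed in situ.
The site Hamiltonian is diagonalized into exciton states; population
relaxation between excitons follows secular Redfield rates built from an
overdamped Brownian-oscillator spectral density; disorder-averaged
absorption and fluorescence check the model against the familiar
two-band Chl a/b structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import COULOMB_CM_ANGSTROM, CM_TO_RAD_PER_PS, thermal_energy


class CouplingError(RuntimeError):
    """Numerical problem evaluating a Coulomb coupling (e.g. coincident atoms)."""


# ---------------------------------------------------------------------------
# geometry containers
# ---------------------------------------------------------------------------

@dataclass
class PigmentGeometry:
    """One pigment: atom coordinates plus transition charges.

    ``charges`` maps a transition name ("qy" for the chlorophyll Q_y
    band, "s1" for the carotenoid S1 0-0 transition) to one charge per
    atom (elementary charge units); each set must be neutral to 1e-6 e.
    """

    pigment_id: str
    pigment_type: str                      # "CLA" (Chl a), "CHL" (Chl b), "LUT"
    positions: np.ndarray                  # (n_atoms, 3), Angstrom
    charges: dict[str, np.ndarray] = field(default_factory=dict)
    site_energy: float | None = None       # cm^-1
    atom_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        for name, q in list(self.charges.items()):
            q = np.asarray(q, dtype=float)
            if q.shape != (len(self.positions),):
                raise ValueError(
                    f"pigment {self.pigment_id}: transition {name!r} has {q.size} charges "
                    f"for {len(self.positions)} atoms"
                )
            if abs(q.sum()) > 1e-6:
                raise ValueError(
                    f"pigment {self.pigment_id}: transition charges {name!r} are not neutral "
                    f"(sum = {q.sum():.2e} e)"
                )
            self.charges[name] = q

    def transition_dipole(self, transition: str) -> np.ndarray:
        """Transition dipole sum(q_a * r_a) in e*Angstrom."""
        q = self.charges[transition]
        return q @ self.positions

    def transformed(self, rotation: np.ndarray | None = None, translation: np.ndarray | None = None) -> "PigmentGeometry":
        pos = self.positions
        center = pos.mean(axis=0)
        if rotation is not None:
            pos = (pos - center) @ rotation.T + center
        if translation is not None:
            pos = pos + translation
        return PigmentGeometry(
            pigment_id=self.pigment_id,
            pigment_type=self.pigment_type,
            positions=pos,
            charges={k: v.copy() for k, v in self.charges.items()},
            site_energy=self.site_energy,
            atom_names=list(self.atom_names) if self.atom_names else None,
        )


@dataclass
class SnapshotEnsemble:
    """Uncorrelated structural snapshots sharing one pigment roster."""

    snapshots: list[list[PigmentGeometry]]
    times: np.ndarray | None = None        # ps labels, optional
    metadata: dict = field(default_factory=dict)   # e.g. minimum label, pH class

    def __post_init__(self) -> None:
        rosters = {tuple(p.pigment_id for p in snap) for snap in self.snapshots}
        if len(rosters) > 1:
            raise ValueError("all snapshots must share an identical pigment roster")

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)


# ---------------------------------------------------------------------------
# couplings and the site Hamiltonian
# ---------------------------------------------------------------------------

def coulomb_coupling(
    m: PigmentGeometry,
    n: PigmentGeometry,
    eps_r: float = 2.0,
    transition_m: str = "qy",
    transition_n: str = "qy",
) -> float:
    """Coulomb coupling (cm^-1) between two pigment transition densities.

    Pairwise sum over transition atomic charges screened by ``eps_r``;
    at separations much larger than either pigment this converges to the
    point-dipole interaction.
    """
    if eps_r <= 0:
        raise ValueError(f"eps_r must be positive, got {eps_r}")
    if m is n or m.pigment_id == n.pigment_id:
        raise ValueError("coupling requires two distinct pigments")
    qm = m.charges[transition_m]
    qn = n.charges[transition_n]
    diff = m.positions[:, None, :] - n.positions[None, :, :]
    r = np.sqrt((diff * diff).sum(axis=2))
    if np.any(r < 1e-3):
        raise CouplingError(
            f"coincident atoms between pigments {m.pigment_id} and {n.pigment_id}"
        )
    return float(COULOMB_CM_ANGSTROM / eps_r * (qm[:, None] * qn[None, :] / r).sum())


def build_site_hamiltonian(
    snapshot: list[PigmentGeometry],
    site_energies: dict[str, float] | None = None,
    eps_r: float = 2.0,
) -> np.ndarray:
    """Chl-only site Hamiltonian (cm^-1): diagonal site energies, Coulomb couplings.

    Luteins in the snapshot are excluded (the carotenoid is handled as a
    separate vibronic subsystem).  Site energies come from the pigment
    objects unless an explicit ``site_energies`` table (pigment_id ->
    cm^-1) is given.
    """
    chls = [p for p in snapshot if p.pigment_type != "LUT"]
    n = len(chls)
    H = np.zeros((n, n))
    for i, p in enumerate(chls):
        if site_energies is not None:
            if p.pigment_id not in site_energies:
                raise KeyError(f"no site energy configured for pigment {p.pigment_id}")
            H[i, i] = site_energies[p.pigment_id]
        elif p.site_energy is not None:
            H[i, i] = p.site_energy
        else:
            raise KeyError(f"pigment {p.pigment_id} has no site energy")
    for i in range(n):
        for j in range(i + 1, n):
            J = coulomb_coupling(chls[i], chls[j], eps_r=eps_r)
            H[i, j] = H[j, i] = J
    return H


# ---------------------------------------------------------------------------
# exciton basis
# ---------------------------------------------------------------------------

@dataclass
class ExcitonBasis:
    """Diagonalized chlorophyll manifold.

    ``coefficients[n, i]`` is the participation c_ni of site n in
    exciton i; columns are orthonormal and energies ascend.
    """

    energies: np.ndarray               # (n_exc,), cm^-1, ascending
    coefficients: np.ndarray           # (n_site, n_exc)
    oscillator_strengths: np.ndarray   # (n_exc,), relative
    site_ids: list[str]

    @property
    def n_excitons(self) -> int:
        return len(self.energies)

    @property
    def participations(self) -> np.ndarray:
        """|c_ni|^2 table, rows = excitons, columns = sites (rows sum to 1)."""
        return (self.coefficients**2).T


def diagonalize(H: np.ndarray, snapshot: list[PigmentGeometry] | None = None) -> ExcitonBasis:
    """Eigenstates of the site Hamiltonian with mixed oscillator strengths.

    If a snapshot is supplied, exciton dipoles are the
    coefficient-weighted vector sums of the site Q_y dipoles; otherwise
    all site dipoles are taken as unit vectors along a common axis.
    """
    H = np.asarray(H, dtype=float)
    if not np.allclose(H, H.T, atol=1e-9):
        raise ValueError("site Hamiltonian must be symmetric")
    energies, coeff = np.linalg.eigh(H)
    n = H.shape[0]
    if snapshot is not None:
        chls = [p for p in snapshot if p.pigment_type != "LUT"]
        dipoles = np.array([p.transition_dipole("qy") for p in chls])
        site_ids = [p.pigment_id for p in chls]
    else:
        dipoles = np.tile([1.0, 0.0, 0.0], (n, 1))
        site_ids = [f"site{k}" for k in range(n)]
    exc_dipoles = coeff.T @ dipoles
    strengths = (exc_dipoles**2).sum(axis=1)
    return ExcitonBasis(
        energies=energies,
        coefficients=coeff,
        oscillator_strengths=strengths,
        site_ids=site_ids,
    )


# ---------------------------------------------------------------------------
# Redfield relaxation
# ---------------------------------------------------------------------------

@dataclass
class SpectralDensity:
    """Overdamped Brownian-oscillator site spectral density C''(w).

    The cutoff is set high enough (200 cm^-1) that downhill relaxation
    across typical exciton gaps (100-600 cm^-1) proceeds on the sub-ps
    to ps timescale observed for Chl b -> Chl a transfer; a narrow
    low-frequency-only density would strand population in the Chl b
    band.
    """

    reorganization: float = 37.0   # lam, cm^-1
    cutoff: float = 200.0          # gam, cm^-1

    def __call__(self, omega) -> np.ndarray:
        w = np.asarray(omega, dtype=float)
        return 2.0 * self.reorganization * self.cutoff * w / (w * w + self.cutoff**2)


def redfield_rates(
    basis: ExcitonBasis,
    spectral_density: SpectralDensity | None = None,
    temperature: float = 300.0,
) -> np.ndarray:
    """Secular Redfield population rates k[j, i] (ps^-1) for exciton i -> j.

    k_ij = 2*pi*c * sum_n |c_ni|^2 |c_nj|^2 (1 + coth(w_ij/2kT)) C''(w_ij)
    with w_ij the donor-acceptor gap; the odd extension of C'' makes the
    same expression cover uphill transfer and enforces detailed balance.
    Diagonal entries close the columns (population-conserving within the
    exciton manifold).
    """
    if spectral_density is None:
        spectral_density = SpectralDensity()
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kt = thermal_energy(temperature)
    c2 = basis.coefficients**2     # (n_site, n_exc)
    n_exc = basis.n_excitons
    K = np.zeros((n_exc, n_exc))
    for i in range(n_exc):
        for j in range(n_exc):
            if i == j:
                continue
            w_ij = basis.energies[i] - basis.energies[j]
            shared = float(c2[:, i] @ c2[:, j])
            if shared == 0.0:
                continue
            if abs(w_ij) < 1e-8:
                sd = spectral_density
                factor = 4.0 * sd.reorganization * kt / sd.cutoff
            else:
                factor = float((1.0 + 1.0 / np.tanh(w_ij / (2.0 * kt))) * spectral_density(w_ij))
            K[j, i] = CM_TO_RAD_PER_PS * shared * factor
    np.fill_diagonal(K, -K.sum(axis=0))
    return K


# ---------------------------------------------------------------------------
# disorder-averaged steady-state spectra
# ---------------------------------------------------------------------------

@dataclass
class DisorderModel:
    """Gaussian static disorder on site energies (per pigment class)."""

    sigma: dict[str, float] = field(default_factory=lambda: {"CLA": 60.0, "CHL": 90.0, "LUT": 0.0})
    n_realizations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigma.values()):
            raise ValueError("disorder sigma must be non-negative")


def steady_state_and_spectra(
    ensemble: SnapshotEnsemble | list[list[PigmentGeometry]],
    omega_grid: np.ndarray,
    disorder: DisorderModel | None = None,
    site_energies: dict[str, float] | None = None,
    eps_r: float = 2.0,
    temperature: float = 300.0,
    lineshape_sigma: float = 120.0,
    reorganization: float = 37.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disorder- and snapshot-averaged absorption and fluorescence.

    LA(w) ~ w * sum_i f_i chi_i(w); FL(w) ~ w^3 * sum_i f_i chi~_i(w) P_i
    with P_i the emissive quasi-equilibrium (Boltzmann) populations of
    the exciton states, chi Gaussian zero-phonon lines, and the FL line
    of exciton i shifted down by twice its effective reorganization
    energy lam * sum_n |c_ni|^4.  Returns (LA, FL), each area-normalized.
    """
    if disorder is None:
        disorder = DisorderModel()
    omega_grid = np.asarray(omega_grid, dtype=float)
    rng = np.random.default_rng(disorder.seed)
    kt = thermal_energy(temperature)
    la = np.zeros_like(omega_grid)
    fl = np.zeros_like(omega_grid)
    snapshots = list(ensemble)
    for snap in snapshots:
        chls = [p for p in snap if p.pigment_type != "LUT"]
        H0 = build_site_hamiltonian(snap, site_energies=site_energies, eps_r=eps_r)
        for _ in range(disorder.n_realizations):
            shifts = np.array([rng.normal(0.0, disorder.sigma.get(p.pigment_type, 0.0)) for p in chls])
            basis = diagonalize(H0 + np.diag(shifts), snap)
            pr4 = (basis.coefficients**4).sum(axis=0)
            lam_i = reorganization * pr4
            p_eq = np.exp(-(basis.energies - basis.energies.min()) / kt)
            p_eq /= p_eq.sum()
            for i in range(basis.n_excitons):
                f = basis.oscillator_strengths[i]
                la += f * omega_grid * np.exp(-0.5 * ((omega_grid - basis.energies[i]) / lineshape_sigma) ** 2)
                fl += (
                    f * p_eq[i] * omega_grid**3
                    * np.exp(-0.5 * ((omega_grid - (basis.energies[i] - 2.0 * lam_i[i])) / lineshape_sigma) ** 2)
                )
    dx = np.trapezoid(la, omega_grid)
    if dx > 0:
        la = la / dx
    dx = np.trapezoid(fl, omega_grid)
    if dx > 0:
        fl = fl / dx
    return la, fl
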