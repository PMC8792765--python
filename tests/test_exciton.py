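"""Coulomb couplings, exciton diagonalization, Redfield rates and spectra."""

import numpy as np
import pytest

from lhcquench.exciton import (
    CouplingError,
    DisorderModel,
    PigmentGeometry,
    SnapshotEnsemble,
    SpectralDensity,
    build_site_hamiltonian,
    coulomb_coupling,
    diagonalize,
    redfield_rates,
    steady_state_and_spectra,
)
from lhcquench.synthetic import FixtureSpec, generate_snapshot_ensemble
from lhcquench.units import COULOMB_CM_ANGSTROM, KB_CM


def point_pigment(pid, position, charge=0.1, transition="qy", far_sign=1.0):
    """Two-atom pigment: the named charge at ``position`` plus a distant
    compensating charge (transition charge sets must be neutral)."""
    return PigmentGeometry(
        pigment_id=pid, pigment_type="CLA",
        positions=np.array([position, np.asarray(position) + [0.0, 0.0, far_sign * 5000.0]]),
        charges={transition: np.array([charge, -charge])},
        site_energy=15000.0,
    )


def dipole_pigment(pid, center, direction, mu=0.5, sep=2.0, site_energy=15000.0, ptype="CLA"):
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    q = mu / sep
    c = np.asarray(center, dtype=float)
    return PigmentGeometry(
        pigment_id=pid, pigment_type=ptype,
        positions=np.array([c + d * sep / 2, c - d * sep / 2]),
        charges={"qy": np.array([q, -q])},
        site_energy=site_energy,
    )


class TestCoulombCoupling:
    def test_zero_charges_give_zero(self):
        a = point_pigment("A", [0, 0, 0], charge=0.0)
        b = point_pigment("B", [10, 0, 0], charge=0.0)
        assert coulomb_coupling(a, b) == 0.0

    def test_two_point_charges_reference_value(self):
        # q^2 * 116,140 / (eps_r * R) with q = 0.1 e, R = 10 A, eps_r = 2
        a = point_pigment("A", [0, 0, 0], far_sign=1.0)
        b = point_pigment("B", [10, 0, 0], far_sign=-1.0)
        expected = 0.01 * COULOMB_CM_ANGSTROM / (2.0 * 10.0)
        # compensating charges sit 500 A away; correct for their tiny residual
        assert coulomb_coupling(a, b, eps_r=2.0) == pytest.approx(expected, rel=5e-3)
        assert expected == pytest.approx(58.07, abs=0.01)

    def test_symmetric_and_inverse_eps_scaling(self):
        a = dipole_pigment("A", [0, 0, 0], [0, 1, 0])
        b = dipole_pigment("B", [9, 2, 1], [0.3, 1, 0])
        j_ab = coulomb_coupling(a, b, eps_r=2.0)
        assert coulomb_coupling(b, a, eps_r=2.0) == pytest.approx(j_ab, rel=1e-14)
        assert coulomb_coupling(a, b, eps_r=1.0) == pytest.approx(2.0 * j_ab, rel=1e-14)
        assert coulomb_coupling(a, b, eps_r=4.0) == pytest.approx(0.5 * j_ab, rel=1e-14)

    def test_converges_to_point_dipole_form_at_long_range(self):
        mu = 0.6  # e*A
        for R in (60.0, 120.0):
            a = dipole_pigment("A", [0, 0, 0], [0, 0, 1], mu=mu, sep=1.0)
            b = dipole_pigment("B", [R, 0, 0], [0, 0, 1], mu=mu, sep=1.0)
            # side-by-side parallel dipoles: kappa = +1
            expected = COULOMB_CM_ANGSTROM * mu * mu / (2.0 * R**3)
            assert coulomb_coupling(a, b, eps_r=2.0) == pytest.approx(expected, rel=5e-4 * (R / 60.0) ** -1)

    def test_coincident_atoms_raise_with_pigment_ids(self):
        a = point_pigment("A", [0, 0, 0])
        b = point_pigment("B", [0, 0, 0])
        with pytest.raises(CouplingError, match="A.*B"):
            coulomb_coupling(a, b)

    def test_requires_distinct_pigments_and_positive_eps(self):
        a = point_pigment("A", [0, 0, 0])
        with pytest.raises(ValueError):
            coulomb_coupling(a, a)
        b = point_pigment("B", [5, 0, 0])
        with pytest.raises(ValueError):
            coulomb_coupling(a, b, eps_r=0.0)


class TestSiteHamiltonian:
    def test_diagonal_when_uncoupled(self):
        a = dipole_pigment("A", [0, 0, 0], [0, 1, 0], mu=0.0)
        b = dipole_pigment("B", [12, 0, 0], [0, 1, 0], mu=0.0, site_energy=15200.0)
        H = build_site_hamiltonian([a, b])
        np.testing.assert_allclose(H, np.diag([15000.0, 15200.0]))

    def test_symmetric_and_luteins_excluded(self, crystal):
        snap, _, _ = crystal
        H = build_site_hamiltonian(snap)
        assert H.shape == (14, 14)
        np.testing.assert_allclose(H, H.T, atol=1e-12)

    def test_missing_site_energy_raises(self):
        a = dipole_pigment("A", [0, 0, 0], [0, 1, 0])
        a.site_energy = None
        with pytest.raises(KeyError):
            build_site_hamiltonian([a])


class TestDiagonalize:
    def test_zero_coupling_excitons_are_sites(self):
        H = np.diag([15000.0, 15200.0, 15400.0])
        b = diagonalize(H)
        np.testing.assert_allclose(b.energies, [15000.0, 15200.0, 15400.0])
        np.testing.assert_allclose(np.abs(b.coefficients), np.eye(3), atol=1e-12)

    def test_symmetric_dimer_splitting_and_participation(self):
        E, J = 15000.0, -120.0
        b = diagonalize(np.array([[E, J], [J, E]]))
        np.testing.assert_allclose(b.energies, [E - 120.0, E + 120.0])
        np.testing.assert_allclose(b.participations, 0.5, atol=1e-12)

    def test_orthonormality_and_trace_conservation(self, crystal):
        snap, _, basis = crystal
        H = build_site_hamiltonian(snap)
        np.testing.assert_allclose(basis.coefficients.T @ basis.coefficients, np.eye(14), atol=1e-10)
        assert basis.energies.sum() == pytest.approx(np.trace(H), rel=1e-12)
        assert np.all(np.diff(basis.energies) >= 0)
        np.testing.assert_allclose(basis.participations.sum(axis=1), 1.0, atol=1e-12)

    def test_terminal_emitter_localizes_on_trio(self, crystal):
        snap, _, basis = crystal
        chl_ids = [p.pigment_id for p in snap if p.pigment_type != "LUT"]
        trio = [chl_ids.index(t) for t in ("a610", "a611", "a612")]
        loc = (basis.coefficients[trio, 0] ** 2).sum()
        assert loc > 0.8
        assert basis.energies[0] == pytest.approx(14730.0, abs=50.0)

    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(ValueError):
            diagonalize(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestRedfield:
    def _shared_site_basis(self, gap):
        # two excitons sharing two sites -> nonzero rate with known gap
        c = np.array([[np.sqrt(0.7), np.sqrt(0.3)], [np.sqrt(0.3), -np.sqrt(0.7)]])
        from lhcquench.exciton import ExcitonBasis
        return ExcitonBasis(
            energies=np.array([15000.0, 15000.0 + gap]),
            coefficients=c,
            oscillator_strengths=np.ones(2),
            site_ids=["s0", "s1"],
        )

    def test_downhill_uphill_ratio_is_boltzmann(self):
        basis = self._shared_site_basis(400.0)
        K = redfield_rates(basis, temperature=300.0)
        ratio = K[0, 1] / K[1, 0]
        assert ratio == pytest.approx(np.exp(400.0 / (KB_CM * 300.0)), rel=1e-8)
        assert ratio == pytest.approx(6.81, abs=0.03)

    def test_no_shared_sites_no_rate(self):
        from lhcquench.exciton import ExcitonBasis
        basis = ExcitonBasis(
            energies=np.array([15000.0, 15400.0]),
            coefficients=np.eye(2),
            oscillator_strengths=np.ones(2),
            site_ids=["s0", "s1"],
        )
        K = redfield_rates(basis)
        assert np.abs(K).max() == 0.0

    def test_uphill_rate_increases_with_temperature(self):
        basis = self._shared_site_basis(400.0)
        uphill = [redfield_rates(basis, temperature=T)[1, 0] for T in (250.0, 300.0, 350.0)]
        assert uphill[0] < uphill[1] < uphill[2]

    def test_detailed_balance_on_fixture(self, crystal):
        _, _, basis = crystal
        K = redfield_rates(basis, temperature=300.0)
        kt = KB_CM * 300.0
        n = basis.n_excitons
        offdiag = K - np.diag(np.diag(K))
        assert offdiag.min() >= 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if K[i, j] == 0.0:
                    continue
                gap = basis.energies[j] - basis.energies[i]
                assert K[i, j] / K[j, i] == pytest.approx(np.exp(gap / kt), rel=1e-8)


class TestSpectra:
    def test_single_pigment_band_at_site_energy(self):
        p = dipole_pigment("A", [0, 0, 0], [0, 1, 0], mu=0.8)
        grid = np.arange(14000.0, 16000.0, 5.0)
        disorder = DisorderModel(sigma={"CLA": 0.0}, n_realizations=1, seed=0)
        la, fl = steady_state_and_spectra([[p]], grid, disorder=disorder)
        assert grid[np.argmax(la)] == pytest.approx(15000.0, abs=20.0)

    def test_fluorescence_is_stokes_shifted_per_realization(self, crystal):
        snap, _, _ = crystal
        grid = np.arange(14000.0, 16200.0, 5.0)
        for seed in range(4):
            disorder = DisorderModel(n_realizations=1, seed=seed)
            la, fl = steady_state_and_spectra([snap], grid, disorder=disorder)
            assert grid[np.argmax(fl)] <= grid[np.argmax(la)]

    def test_two_band_structure_and_minima_similarity(self):
        # disorder-averaged LA nearly identical across two jittered "minima"
        grid = np.arange(14200.0, 16000.0, 10.0)
        spectra = []
        for seed in (3, 11):
            ens = generate_snapshot_ensemble(FixtureSpec(seed=seed), 3)
            disorder = DisorderModel(n_realizations=30, seed=seed)
            la, _ = steady_state_and_spectra(ens, grid, disorder=disorder)
            spectra.append(la / la.max())
        rms = np.sqrt(np.mean((spectra[0] - spectra[1]) ** 2))
        assert rms < 0.02
        # Chl a and Chl b bands both present
        la = spectra[0]
        a_band = la[(grid > 14600) & (grid < 15100)].max()
        b_band = la[(grid > 15300) & (grid < 15800)].max()
        assert a_band > 0.5 and b_band > 0.15

    def test_disorder_averaging_converges(self):
        snap = list(generate_snapshot_ensemble(FixtureSpec(seed=5), 1))[0]
        grid = np.arange(14200.0, 16000.0, 20.0)

        def averaged(n, seed):
            d = DisorderModel(n_realizations=n, seed=seed)
            la, _ = steady_state_and_spectra([snap], grid, disorder=d)
            return la / np.trapezoid(la, grid)

        diffs = []
        for n in (5, 20, 80):
            a, b = averaged(n, 21), averaged(n, 22)
            diffs.append(np.sqrt(np.mean((a - b) ** 2)))
        assert diffs[2] < diffs[0]
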