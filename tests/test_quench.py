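"""Combined exciton-vibronic kinetics: golden-rule rates, lifetimes,
energy scans and the two-lutein asymmetry experiment."""

import numpy as np
import pytest

from lhcquench.exciton import ExcitonBasis
from lhcquench.quench import (
    GAMMA_CHL_DEFAULT,
    DivergenceError,
    LutSiteConfig,
    build_combined_model,
    exciton_lut_coupling,
    fgr_transfer_rate,
    gaussian_overlap,
    lut_population_shares,
    mean_excitation_lifetime,
    model_from_snapshot,
    s1_energy_scan,
    snapshot_lifetime_distribution,
    two_lutein_experiment,
)
from lhcquench.synthetic import FixtureSpec, generate_snapshot_ensemble
from lhcquench.units import CM_TO_RAD_PER_PS, KB_CM


def single_exciton_basis(energy=14800.0):
    return ExcitonBasis(
        energies=np.array([energy]),
        coefficients=np.eye(1),
        oscillator_strengths=np.ones(1),
        site_ids=["s0"],
    )


class TestCouplingRotation:
    def test_identity_basis_returns_site_couplings(self):
        basis = ExcitonBasis(
            energies=np.array([15000.0, 15100.0]),
            coefficients=np.eye(2),
            oscillator_strengths=np.ones(2),
            site_ids=["a", "b"],
        )
        j = np.array([10.0, -3.0])
        np.testing.assert_allclose(exciton_lut_coupling(basis, j), j)

    def test_parseval_on_random_orthonormal_bases(self, rng):
        for n in (4, 9, 14):
            q, _ = np.linalg.qr(rng.standard_normal((n, n)))
            basis = ExcitonBasis(
                energies=np.sort(rng.normal(15000.0, 200.0, n)),
                coefficients=q,
                oscillator_strengths=np.ones(n),
                site_ids=[f"s{k}" for k in range(n)],
            )
            j_site = rng.normal(0.0, 10.0, n)
            j_exc = exciton_lut_coupling(basis, j_site)
            assert np.sum(j_exc**2) == pytest.approx(np.sum(j_site**2), rel=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            exciton_lut_coupling(single_exciton_basis(), np.array([1.0, 2.0]))


class TestGoldenRule:
    def test_zero_coupling_zero_rates(self):
        kf, kb = fgr_transfer_rate(0.0, 0.3, 14800.0, 120.0, 14050.0, 450.0)
        assert kf == kb == 0.0

    def test_rate_scales_with_coupling_squared(self):
        k1, _ = fgr_transfer_rate(5.0, 0.3, 14800.0, 120.0, 14050.0, 450.0)
        k2, _ = fgr_transfer_rate(10.0, 0.3, 14800.0, 120.0, 14050.0, 450.0)
        assert k2 == pytest.approx(4.0 * k1, rel=1e-12)

    def test_narrow_lineshape_closed_form(self):
        # two sigma = 5 Gaussians at equal centers: overlap = 1/(2 sigma sqrt(pi))
        sigma, J, fc2 = 5.0, 7.0, 0.25
        overlap = 1.0 / (2.0 * sigma * np.sqrt(np.pi))
        assert gaussian_overlap(15000.0, sigma, 15000.0, sigma) == pytest.approx(overlap, rel=1e-12)
        kf, kb = fgr_transfer_rate(J, fc2, 15000.0, sigma, 15000.0, sigma, level_gap=0.0)
        expected = CM_TO_RAD_PER_PS * 2.0 * np.pi * fc2 * J**2 * overlap
        assert kf == pytest.approx(expected, rel=1e-12)
        assert kb == pytest.approx(expected, rel=1e-12)

    def test_detailed_balance_for_uphill_and_downhill(self):
        for gap in (+300.0, -300.0):
            kf, kb = fgr_transfer_rate(7.0, 0.3, 14800.0, 120.0, 14800.0 - gap, 450.0,
                                       temperature=300.0, level_gap=gap)
            assert kf / kb == pytest.approx(np.exp(gap / (KB_CM * 300.0)), rel=1e-12)

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            fgr_transfer_rate(7.0, 0.3, 14800.0, -1.0, 14050.0, 450.0)


class TestCombinedModel:
    def test_no_luteins_reduces_to_intrinsic_lifetime(self, crystal):
        _, _, basis = crystal
        model = build_combined_model(basis, [])
        assert mean_excitation_lifetime(model) == pytest.approx(4000.0, rel=1e-9)

    def test_single_state_lifetime_is_inverse_rate(self):
        model = build_combined_model(single_exciton_basis(), [], gamma_chl=0.02)
        assert mean_excitation_lifetime(model) == pytest.approx(50.0, rel=1e-12)

    def test_missing_site_couplings_rejected(self, crystal):
        _, _, basis = crystal
        with pytest.raises(ValueError):
            build_combined_model(basis, [LutSiteConfig(lut_id="LUT1")])

    def test_generator_structure(self, crystal):
        _, luts, basis = crystal
        model = build_combined_model(basis, luts)
        A = model.generator
        offdiag = A - np.diag(np.diag(A))
        assert offdiag.min() >= 0.0
        # columns sum to minus the decay out of the tracked manifold
        loss = -A.sum(axis=0)
        assert np.all(loss > 0.0)
        assert model.initial.sum() == pytest.approx(1.0)

    def test_both_terminal_emitter_pathways_active(self, crystal):
        # transfer from excitons near TE+ into |S1,1,0> and from TE- into
        # |S1,0,0> both carry nonzero forward rates
        _, luts, basis = crystal
        model = build_combined_model(basis, [luts[0]])
        n_exc = basis.n_excitons
        amax = 4
        sl = model.lut_slices["LUT1"]
        idx00 = sl.start + 0
        idx10 = sl.start + (amax + 1)  # (b1, b2) = (1, 0)
        assert model.generator[idx00, 0] > 0.0          # TE- -> S1(0,0)
        te_plus = np.argmin(np.abs(basis.energies - 15120.0))
        assert model.generator[idx10, te_plus] > 0.0    # near TE+ -> S1(1,0)

    def test_fgr_detailed_balance_inside_model(self, crystal):
        _, luts, basis = crystal
        model = build_combined_model(basis, [luts[0]])
        A = model.generator
        n_exc = basis.n_excitons
        kt = KB_CM * 300.0
        amax = 4
        w1, w2 = 1100.0, 1520.0
        sl = model.lut_slices["LUT1"]
        k = 0
        for b1 in range(amax + 1):
            for b2 in range(amax + 1):
                level_e = luts[0].eps_s1 + b1 * w1 + b2 * w2
                for i in range(n_exc):
                    kf = A[sl.start + k, i]
                    kb = A[i, sl.start + k]
                    if kf == 0.0 and kb == 0.0:
                        continue
                    gap = basis.energies[i] - level_e
                    assert kf / kb == pytest.approx(np.exp(gap / kt), rel=1e-8)
                k += 1


class TestLifetime:
    def test_matrix_inverse_agrees_with_time_domain(self, crystal):
        snap, luts, basis = crystal
        import lhcquench.vera as vera
        p = vera.lutein_pyridine_params(a_max=2)  # 23-state combined model
        model = build_combined_model(basis, [luts[0]], vera_params=p)
        tau_inv = mean_excitation_lifetime(model, method="inverse")
        tau_ode = mean_excitation_lifetime(model, method="ode")
        assert tau_ode == pytest.approx(tau_inv, rel=1e-3)

    def test_monotone_in_coupling_strength(self, crystal):
        _, luts, basis = crystal
        taus = []
        for scale in (0.5, 1.0, 1.5, 2.0):
            lut = LutSiteConfig(lut_id="LUT1", site_couplings=scale * luts[0].site_couplings)
            taus.append(mean_excitation_lifetime(build_combined_model(basis, [lut])))
        assert all(t2 < t1 for t1, t2 in zip(taus, taus[1:]))

    def test_monotone_in_sink_rates(self, crystal):
        _, luts, basis = crystal
        from lhcquench.quench import s1_sink_rates
        from lhcquench.vera import lutein_pyridine_params
        p = lutein_pyridine_params()
        base = s1_sink_rates(p, 14050.0)
        taus = []
        for scale in (0.5, 1.0, 2.0):
            lut = LutSiteConfig(lut_id="LUT1", site_couplings=luts[0].site_couplings,
                                decay_rates=scale * base)
            taus.append(mean_excitation_lifetime(build_combined_model(basis, [lut])))
        assert taus[0] > taus[1] > taus[2]

    def test_adding_identical_second_lutein_decreases_lifetime(self, crystal):
        _, luts, basis = crystal
        lut1 = luts[0]
        twin = LutSiteConfig(lut_id="LUT2", site_couplings=lut1.site_couplings)
        tau_one = mean_excitation_lifetime(build_combined_model(basis, [lut1]))
        tau_two = mean_excitation_lifetime(build_combined_model(basis, [lut1, twin]))
        assert tau_two < tau_one

    def test_divergence_error_on_non_dissipative_generator(self):
        model = build_combined_model(single_exciton_basis(), [], gamma_chl=0.01)
        model.generator[:] = 0.0
        with pytest.raises(DivergenceError):
            mean_excitation_lifetime(model)


class TestEnergyScan:
    def test_resonance_points_quench_more_than_baseline(self, crystal):
        _, luts, basis = crystal
        taus = s1_energy_scan(basis, [luts[0]], np.array([13600.0, 14050.0, 14750.0]))
        assert taus[0] < taus[1]
        assert taus[2] < taus[1]

    def test_shutoff_above_18000(self, crystal):
        _, luts, basis = crystal
        tau = s1_energy_scan(basis, [luts[0]], np.array([18500.0]))[0]
        assert tau == pytest.approx(1.0 / GAMMA_CHL_DEFAULT, rel=0.01)

    def test_scan_is_continuous(self, crystal):
        _, luts, basis = crystal
        eps = np.array([14400.0, 14401.0, 14410.0, 14500.0])
        taus = s1_energy_scan(basis, [luts[0]], eps)
        d1 = abs(taus[1] - taus[0])
        d10 = abs(taus[2] - taus[0])
        d100 = abs(taus[3] - taus[0])
        # differences shrink proportionally with the step
        assert d1 < 0.2 * d10 + 1e-6
        assert d10 < 0.2 * d100 + 1e-6

    def test_grid_bounds_enforced(self, crystal):
        _, luts, basis = crystal
        with pytest.raises(ValueError):
            s1_energy_scan(basis, [luts[0]], np.array([11000.0]))


class TestTwoLutein:
    def test_symmetric_luteins_nearly_equal_quenchers(self, crystal):
        _, luts, basis = crystal
        tau1 = mean_excitation_lifetime(build_combined_model(basis, [luts[0]]))
        tau, shares = two_lutein_experiment(basis, luts[0], luts[1])
        assert tau < tau1  # second quencher shortens the lifetime
        ratio = shares["LUT2"] / shares["LUT1"]
        assert 0.5 <= ratio <= 1.0

    def test_energetic_asymmetry_abolishes_lut2_quenching(self, crystal):
        _, luts, basis = crystal
        _, shares = two_lutein_experiment(basis, luts[0], luts[1],
                                          eps_lut1=13600.0, eps_lut2=15250.0)
        lut2_frac = shares["LUT2"] / (shares["LUT1"] + shares["LUT2"])
        assert lut2_frac < 0.10

    def test_shares_sum_below_one(self, crystal):
        _, luts, basis = crystal
        model = build_combined_model(basis, luts)
        shares = lut_population_shares(model)
        assert 0.0 < sum(shares.values()) <= 1.0


class TestSnapshotDistribution:
    def test_identical_snapshots_give_zero_width(self):
        spec = FixtureSpec(sigma_trans=0.0, sigma_rot_deg=0.0, seed=3)
        ens = generate_snapshot_ensemble(spec, 4)
        res = snapshot_lifetime_distribution(ens, [LutSiteConfig(lut_id="LUT1")])
        assert np.ptp(res.lifetimes) < 1e-6

    def test_snapshot_order_does_not_change_histogram(self, rng):
        ens = generate_snapshot_ensemble(FixtureSpec(seed=9), 8)
        luts = [LutSiteConfig(lut_id="LUT1")]
        res1 = snapshot_lifetime_distribution(ens, luts)
        shuffled = list(ens)
        rng.shuffle(shuffled)
        res2 = snapshot_lifetime_distribution(shuffled, luts)
        np.testing.assert_allclose(np.sort(res1.lifetimes), np.sort(res2.lifetimes), rtol=1e-12)
        np.testing.assert_allclose(res1.hist_counts, res2.hist_counts)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            snapshot_lifetime_distribution([], [LutSiteConfig(lut_id="LUT1")])
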