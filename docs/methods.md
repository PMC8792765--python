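# Methods

This note records the model equations as implemented, the default
parameter values and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions.

## Units

All energies, frequencies, spectral densities and widths are in cm⁻¹,
time in ps, lengths in Å, charges in elementary charges. An energy
assembled from cm⁻¹ quantities becomes an angular rate through
2πc = 0.188365 rad ps⁻¹ per cm⁻¹; k_B = 0.6950348 cm⁻¹ K⁻¹
(k_BT = 208.5 cm⁻¹ at 300 K); the Coulomb constant e²/4πε₀ =
116,140 cm⁻¹ Å.

## Carotenoid vibronic model

Four singlet electronic states (S0, S1, S2, Sn) are dressed with the
two optically coupled backbone stretches, ω₁ = 1100 cm⁻¹ (C-C) and
ω₂ = 1520 cm⁻¹ (C=C), giving levels |i, a₁, a₂⟩ with energies
ε = ε_i + (a₁+½)ω₁ + (a₂+½)ω₂ and a default truncation of a_max = 4
quanta per mode (100 levels; convergence was checked by doubling a_max,
which changes the reported lifetimes by well under 1%). Mode
frequencies are taken independent of the electronic state (no Duschinsky
rotation), so inter-state vibrational overlaps are Franck-Condon factors
of equal-frequency displaced oscillators, computed from the closed-form
associated-Laguerre expression with the convention that the Huang-Rhys
factor is S = d²/2 (⟨0|0⟩² = e^{-d²/2}).

Relaxation is second-order (golden-rule) in the system-bath coupling
with an overdamped Drude spectral density per channel,
C″(ω) = 2λγω/(ω²+γ²), and rates evaluated at the level gap Δ:

    k(Δ) = 2πc · C″(|Δ|) / (1 − e^{−|Δ|/k_BT})        (downhill)
    k(−Δ) = k(Δ) · e^{−|Δ|/k_BT}                      (uphill)

so detailed balance holds identically. IVR moves one quantum of one
mode within an electronic state with the harmonic ladder scaling
(a for emission from level a, a+1 for absorption); there is no
population transfer between the two modes except through the bath. IC
connects state pairs listed in the parameter set (S2→S1 and S1→S0 by
default; Sn has no IC channel and exists only as the terminus of the
S1 excited-state absorption), each channel weighted by the product of
the squared FC overlaps of both modes. The exact bath-model prefactors
behind these rates are a design choice of this package — the defining
constraints we impose are (i) golden-rule second order, (ii) Drude
form, (iii) detailed balance by construction.

### Reference parameter set

`lutein_pyridine_params()` is a synthetic stand-in parameterization of
lutein in pyridine, calibrated once against the published solution-phase
observables rather than fitted to a measured surface:

| quantity | value | constraint |
|---|---|---|
| ε_S1 | 14,050 cm⁻¹ | near-IR phononless S1 energy |
| ε_S2 | 20,600 cm⁻¹ | visible 0-0 absorption of lutein in pyridine |
| ε_Sn | 31,950 cm⁻¹ | ε_Sn − ε_S1 = 17,900 cm⁻¹ (S1 ESA position) |
| d(S0-S1) | (1.10, 1.20) | strong S1 vibronic progression |
| d(S0-S2) | (0.90, 1.00) | absorption progression |
| IVR λ, γ (all states) | 60, 50 cm⁻¹ | S1 vibrational relaxation ≈ 1 ps |
| IC S2→S1 λ, γ | 490, 300 cm⁻¹ | S2 lifetime ≈ 100 fs |
| IC S1→S0 λ, γ | 82, 28 cm⁻¹ | S1 lifetime ≈ 14 ps |
| band widths (Voigt) | 350-380 / 100-150 cm⁻¹ | solution linewidths |

The three bath (λ, γ) pairs were adjusted during development until the
simulated S2 decay, S1 decay and S1 vibrational relaxation reproduced
the timescales above, then frozen; they are not revisited by any test.

### Spectra

Every vibronic line is dressed with an area-normalized Voigt profile
(Gaussian ⊗ Lorentzian, widths per optical band). Linear absorption
sums thermally weighted S0→S2 transitions; the S0→S1 (two-photon)
lineshape uses FC structure only, since the band is one-photon
forbidden, with an optional rigid +150 cm⁻¹ output shift for comparison
against octanol data. The difference spectrum is
ΔA = ESA − SE − GSB with ESA from S1→Sn, SE from dipole-allowed
populated bands (S2→S0; S1 carries zero strength) and GSB proportional
to the depletion of each S0 level relative to thermal equilibrium; with
full ground-state recovery ΔA → 0 identically. The pump is a Gaussian
pulse (default FWHM 100 fs, transform-limited spectral width) centered
on the S2 0-0 line; pumping moves population S0→S2 with FC- and
spectrally-weighted rates, conserving total population.

## Transient-absorption fitting

The residual stacks (model − data) over the ΔA surface — sub-picosecond
delays down-weighted by 0.3 by default, as they are dominated by the
pump overlap — with an optional weighted linear-absorption block so the
TA fit cannot silently degrade the LA fit. Optimization is bounded
trust-region least squares (energies constrained to ±3000 cm⁻¹ of the
start, displacements to [0, 2]) with jittered restarts (default 8,
fixed seed); the objective is normalized by the dataset's peak |ΔA| and
uses explicit finite-difference steps (≈3 cm⁻¹ for energies, 10⁻²
relative for displacements) because the raw surface amplitudes are
small. ε_S1 is frozen by default: it is degenerate with ε_Sn and the
S0-S1 displacements, which is also why the parameter-recovery harness
frees the displacements the TA surface actually determines — d(S0-S2)
through the bleach and d(S1-Sn) through the ESA lineshape — while the
S0-S1 displacements are constrained in practice by the two-photon
lineshape, which this package treats as an independent check rather
than part of the fit.

## Chlorophyll exciton model

Site energies are fixed literature-style inputs (the package does not
compute them in situ); couplings are screened transition-charge Coulomb
sums with ε_r = 2. Redfield population rates use a shared overdamped
Brownian-oscillator spectral density with λ = 37 cm⁻¹ and γ = 200 cm⁻¹.
The cutoff matters: with a low cutoff (tens of cm⁻¹) the density is
negligible at typical exciton gaps (100-600 cm⁻¹) and population is
stranded in the Chl b band for tens of ps, whereas measured Chl b → a
transfer is sub-picosecond; γ = 200 cm⁻¹ restores sub-ps to ps
relaxation across the manifold. Absorption and fluorescence use
Gaussian-dressed zero-phonon lines (σ = 120 cm⁻¹), fluorescence shifted
by twice the participation-weighted reorganization energy and weighted
by ω³ and the Boltzmann steady state; static disorder is Gaussian on
site energies (σ = 60 cm⁻¹ Chl a, 90 cm⁻¹ Chl b; 100 realizations by
default, seeded).

## Combined quenching model

Chlorophyll excitons and each lutein S1 vibronic ladder exchange
population incoherently. The forward rate from exciton i to S1 level
(b₁, b₂) is

    k = 2πc · 2π |J_i|² FC² ∫ χ̃′_i(ω) σ(ω) dω

with J_i = Σ_n c_ni J_n,Lut (Parseval-conserving rotation of the site
couplings), FC the product of ⟨0|b_α⟩ overlaps with the S0-S1
displacements, χ̃′_i an area-normalized Gaussian donor fluorescence line
centered at E_i − λ_i, and σ an area-normalized acceptor Gaussian of
full width at half maximum Δω₁₀ = 1070 cm⁻¹ centered on the vibronic
transition energy ε_S1 + b₁ω₁ + b₂ω₂. Reading Δω₁₀ as a FWHM rather
than a standard deviation is load-bearing: with σ = 1070 cm⁻¹ the
spectral overlap is nearly flat across the physically interesting range
of S1 energies and the resonance structure of the quenching pathway
disappears; with FWHM = 1070 cm⁻¹ the single-channel terminal-emitter →
S1 rate comes out near (200-300 ps)⁻¹ and shifting ε_S1 onto either
vibronic resonance shortens the lifetime by ~40%, both in line with the
phenomenology the model is built to capture. Uphill rates carry
Boltzmann factors of the level gap, so every cross pair satisfies
detailed balance exactly.

Ground states are not tracked ("instantaneous IVR on the ground
state"): each exciton decays with the intrinsic Γ_Chl = (4 ns)⁻¹ and
each S1 level decays into an untracked sink with its total S1→S0 IC
rate, recomputed for the configured ε_S1 (sink rates fall mildly with
increasing ε_S1 through the Drude tail). Intra-S1 IVR is retained so
the |1,1,0⟩ ↔ |1,0,0⟩ bottleneck is represented. The mean excitation
lifetime is the population-integrated τ_ex = 1ᵀ(−A)⁻¹p₀ with initial
populations proportional to exciton oscillator strengths; this
definition reduces exactly to 1/Γ_Chl without quenchers and agrees with
time-domain integration to better than 0.1%. Per-lutein quenching
shares are cumulative sink fluxes up to t = τ_ex normalized by the
total dissipated population — one of several defensible estimators; it
was chosen because it is basis-free and robust to the integration
horizon.

## Synthetic data

Pigments are small neutral point-charge clusters (four charges per
chlorophyll Q_y, five alternating charges along the lutein backbone for
S1), sufficient for Coulomb couplings at inter-pigment distances and
orders of magnitude cheaper than atomistic geometries. The crystal-like
fixture places a near-collinear a610-a611-a612 trio (lowest exciton
14,737 cm⁻¹, 0.99 trio-localized — the terminal emitter), five further
Chl a, six Chl b on an outer ring, Lut1 beside the trio and Lut2 beside
the a603/a604 pair. Lutein charge amplitudes are rescaled
deterministically so the strongest Lut1-trio site coupling equals
11.15 cm⁻¹ (inside the weak 10-20 cm⁻¹ window; the strongest
exciton-basis coupling is then ≈7 cm⁻¹) and Lut2's target is 0.80 of
Lut1's. These two calibration constants, the site-energy table and the
snapshot jitter (σ_trans = 0.045 Å, σ_rot = 0.3° rigid-body moves per
pigment) were fixed once so that the fixture reproduces, jointly: a
quenched lifetime of ≈500 ps with Lut1 at ε_S1 = 14,050 cm⁻¹, snapshot
lifetimes spread over several hundred ps with ensemble means between
500 and 600 ps, ≥95% of snapshot couplings inside the 10-20 cm⁻¹ band,
resonance-point lifetimes dropping to ≈300 ps, a symmetric-Lut2 share
ratio of ≈0.6, and abolition of Lut2 quenching (<10% share) under the
13,600/15,250 cm⁻¹ asymmetry. They are calibration, not physics: the
generator raises `CalibrationError` rather than silently re-tuning if a
modified spec violates its own bands.

What the generator does *not* emulate: real MD conformational
dynamics (jitter is isotropic rigid-body noise, uncorrelated between
pigments and snapshots), protonation-state differences (the pH label is
metadata only), in-situ site-energy fluctuations, atomistic transition
densities, and any short-range (exchange/overlap) coupling
contributions. Passing tests therefore demonstrate the kinetic
machinery and its calibration bands, not structural realism.

Synthetic TA surfaces are the forward model plus seeded additive
Gaussian noise expressed as a fraction of the peak |ΔA| (noise 0.02 ↔
peak SNR 50), with an optional linear baseline drift.

## Numerical choices and degenerate inputs

- Propagation: stepwise matrix exponentials for constant generators
  (exact), LSODA for pumped dynamics (rtol 1e-8, atol 1e-12, max step a
  quarter of the pulse width); the two agree to 1e-6 on shared cases.
- Zero-gap transfer uses the finite ω → 0 limit of the Drude rate,
  2πc·2λk_BT/γ.
- Degenerate FC tables (zero displacement) are exact identity matrices;
  IC then connects only equal quantum numbers.
- Lifetime histograms use Freedman-Diaconis binning; a zero-spread
  ensemble yields a single two-edge bin.
- PDB coordinates round-trip at 1e-3 Å (format precision); couplings
  move by < 0.05 cm⁻¹.
- Small integer seeds everywhere; two seeds give statistically
  indistinguishable ensembles but byte-identical outputs only for equal
  seeds.

## Known limitations

- Coherent (off-diagonal) dynamics, Duschinsky rotation, anharmonicity
  and carotenoid conformer bands are out of scope.
- Donor lineshapes in the golden-rule overlap are single Gaussians; a
  structured fluorescence lineshape would modulate individual channel
  rates by factors of order unity.
- The exciton spectral density is a single overdamped term for all
  sites; vibronic structure in the Chl manifold is not represented.
- Absolute quenching rates inherit the uncertainty of the S1 transition
  charges; relative lifetime changes between configurations are the
  supported contract.
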