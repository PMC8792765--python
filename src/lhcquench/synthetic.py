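"""Synthetic input generation: snapshot ensembles, a crystal-like LHCII
fixture, and noisy transient-absorption surfaces.

Pigments are represented as small neutral point-charge clusters (four
charges for a chlorophyll Q_y transition, five for the lutein S1
transition) — sufficient for Coulomb couplings and orders of magnitude
cheaper than atomistic geometries.  The crystal fixture places a
strongly coupled chlorophyll-a trio (the terminal-emitter domain) with
lutein 1 alongside it and lutein 2 near a pair of mid-energy Chl a
sites; lutein charge amplitudes are scaled deterministically so that the
strongest site-basis coupling to the trio hits a configurable target in
the 10-20 cm^-1 window.  Snapshot ensembles apply seeded rigid-body
jitter (translation + rotation) to every pigment, emulating the coupling
disorder sampled by molecular-dynamics snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exciton import PigmentGeometry, SnapshotEnsemble, build_site_hamiltonian, coulomb_coupling, diagonalize
from .quench import LutSiteConfig
from .tafit import TADataset, default_pump, simulate_ta
from .vera.params import VERAParameterSet, lutein_pyridine_params


class CalibrationError(RuntimeError):
    """A generated fixture violates its calibration acceptance band."""


# ---------------------------------------------------------------------------
# pigment templates (local frames, Angstrom / elementary charges)
# ---------------------------------------------------------------------------

#: Chlorophyll proxy: 4 charges, Q_y dipole ~4 D along the local +y axis.
CHL_ATOMS = np.array([
    [0.0, 3.0, 0.0],
    [0.0, -3.0, 0.0],
    [1.8, 0.0, 0.0],
    [-1.8, 0.0, 0.0],
])
CHL_ATOM_NAMES = ["NA", "NB", "NC", "ND"]
CHL_QY = np.array([0.14, -0.14, 0.01, -0.01])

#: Lutein proxy: 5 charges along the local +z axis (conjugated backbone);
#: small net S1 dipole plus higher multipoles.  Amplitudes are rescaled
#: by the fixture calibration.
LUT_ATOMS = np.array([
    [0.0, 0.0, -4.8],
    [0.0, 0.0, -2.4],
    [0.0, 0.0, 0.0],
    [0.0, 0.0, 2.4],
    [0.0, 0.0, 4.8],
])
LUT_ATOM_NAMES = ["C1", "C2", "C3", "C4", "C5"]
LUT_S1 = np.array([0.030, -0.042, 0.0, 0.042, -0.030])


def _rotation_to(axis_from: np.ndarray, axis_to: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector ``axis_from`` to ``axis_to``."""
    a = axis_from / np.linalg.norm(axis_from)
    b = axis_to / np.linalg.norm(axis_to)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(a, a)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _make_chl(pid: str, ptype: str, center, dipole_dir, site_energy: float) -> PigmentGeometry:
    R = _rotation_to(np.array([0.0, 1.0, 0.0]), np.asarray(dipole_dir, dtype=float))
    return PigmentGeometry(
        pigment_id=pid, pigment_type=ptype,
        positions=CHL_ATOMS @ R.T + np.asarray(center, dtype=float),
        charges={"qy": CHL_QY.copy()},
        site_energy=site_energy, atom_names=list(CHL_ATOM_NAMES),
    )


def _make_lut(pid: str, center, axis_dir, scale: float = 1.0) -> PigmentGeometry:
    R = _rotation_to(np.array([0.0, 0.0, 1.0]), np.asarray(axis_dir, dtype=float))
    return PigmentGeometry(
        pigment_id=pid, pigment_type="LUT",
        positions=LUT_ATOMS @ R.T + np.asarray(center, dtype=float),
        charges={"s1": scale * LUT_S1},
        site_energy=None, atom_names=list(LUT_ATOM_NAMES),
    )


# ---------------------------------------------------------------------------
# fixture specification
# ---------------------------------------------------------------------------

#: Literature-style chlorophyll site energies (cm^-1) for the 14-site roster.
DEFAULT_SITE_ENERGIES = {
    "a610": 14820.0, "a611": 14850.0, "a612": 14880.0,
    "a602": 14820.0, "a603": 14950.0, "a604": 14980.0,
    "a613": 14835.0, "a614": 14850.0,
    "b601": 15420.0, "b605": 15480.0, "b606": 15530.0,
    "b607": 15580.0, "b608": 15450.0, "b609": 15510.0,
}

TRIO = ("a610", "a611", "a612")


@dataclass
class FixtureSpec:
    """Geometry and calibration targets of the synthetic LHCII fixture."""

    n_chla: int = 8
    n_chlb: int = 6
    trio: tuple[str, str, str] = TRIO
    lut_ids: tuple[str, ...] = ("LUT1", "LUT2")
    coupling_target: float = 11.15       # strongest Lut1-trio site coupling, cm^-1
    coupling_band: tuple[float, float] = (10.0, 20.0)
    lut2_coupling_scale: float = 0.80    # Lut2 target relative to Lut1
    sigma_trans: float = 0.045           # rigid-body jitter, Angstrom
    sigma_rot_deg: float = 0.3           # rigid-body jitter, degrees
    site_energies: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SITE_ENERGIES))
    eps_r: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling_target <= 0:
            raise ValueError("coupling target must be positive")
        if not set(self.trio) <= {k for k in self.site_energies if k.startswith("a")}:
            raise ValueError("terminal-emitter trio must be a subset of the Chl a roster")


def _base_layout(spec: FixtureSpec) -> list[PigmentGeometry]:
    """Deterministic reference geometry of the 14-Chl + 2-Lut fixture."""
    se = spec.site_energies
    pigments = [
        # terminal-emitter trio: near-collinear, head-to-tail -> strong
        # negative couplings, lowest exciton localized and red-shifted
        _make_chl("a610", "CLA", (0.0, 0.0, 0.0), (0.0, 1.0, 0.0), se["a610"]),
        _make_chl("a611", "CLA", (0.0, 11.5, 0.0), (0.0, 1.0, 0.0), se["a611"]),
        _make_chl("a612", "CLA", (0.0, 23.0, 0.0), (0.0, 1.0, 0.0), se["a612"]),
        # remaining Chl a
        _make_chl("a602", "CLA", (16.0, 2.0, 0.0), (1.0, 0.4, 0.0), se["a602"]),
        _make_chl("a603", "CLA", (18.0, 12.0, 0.0), (0.4, 1.0, 0.0), se["a603"]),
        _make_chl("a604", "CLA", (17.0, 24.0, 0.0), (1.0, -0.5, 0.0), se["a604"]),
        _make_chl("a613", "CLA", (-15.0, 5.0, 0.0), (0.8, 0.6, 0.0), se["a613"]),
        _make_chl("a614", "CLA", (-16.0, 18.0, 0.0), (0.2, 1.0, 0.0), se["a614"]),
        # Chl b ring (higher site energies, weaker mixing)
        _make_chl("b601", "CHL", (27.0, -4.0, 0.0), (0.0, 1.0, 0.0), se["b601"]),
        _make_chl("b605", "CHL", (33.0, 4.0, 0.0), (1.0, 0.0, 0.0), se["b605"]),
        _make_chl("b606", "CHL", (27.0, 30.0, 0.0), (0.5, 1.0, 0.0), se["b606"]),
        _make_chl("b607", "CHL", (-26.0, -4.0, 0.0), (1.0, 0.3, 0.0), se["b607"]),
        _make_chl("b608", "CHL", (-28.0, 14.0, 0.0), (0.0, 1.0, 0.0), se["b608"]),
        _make_chl("b609", "CHL", (-26.0, 28.0, 0.0), (0.7, -0.7, 0.0), se["b609"]),
    ]
    luts = []
    if "LUT1" in spec.lut_ids:
        luts.append(_make_lut("LUT1", (-6.0, 15.0, 3.0), (1.0, 0.0, 0.0)))
    if "LUT2" in spec.lut_ids:
        luts.append(_make_lut("LUT2", (23.5, 15.0, 3.0), (1.0, 0.0, 0.0)))
    return pigments + luts


def _scale_lut_charges(snapshot: list[PigmentGeometry], spec: FixtureSpec) -> None:
    """Rescale each lutein's charges so its strongest trio coupling hits the target."""
    chls = {p.pigment_id: p for p in snapshot if p.pigment_type != "LUT"}
    trio = [chls[t] for t in spec.trio]
    others = [p for pid, p in chls.items() if pid not in spec.trio]
    for lut in snapshot:
        if lut.pigment_type != "LUT":
            continue
        ref = trio if lut.pigment_id == "LUT1" else (
            [chls["a603"], chls["a604"]] if "a603" in chls and "a604" in chls else trio
        )
        strongest = max(
            abs(coulomb_coupling(c, lut, eps_r=spec.eps_r, transition_m="qy", transition_n="s1"))
            for c in ref
        )
        if strongest <= 0:
            raise CalibrationError(f"{lut.pigment_id} has zero coupling to its reference Chls")
        target = spec.coupling_target
        if lut.pigment_id != "LUT1":
            target *= spec.lut2_coupling_scale
        lut.charges["s1"] = lut.charges["s1"] * (target / strongest)


def generate_crystal_fixture(
    spec: FixtureSpec | None = None,
) -> tuple[list[PigmentGeometry], list[LutSiteConfig]]:
    """Single calibrated snapshot standing in for the minimized crystal structure.

    Returns the pigment list and the lutein channel configurations
    (couplings recomputed from geometry by the kinetics layer).  Raises
    :class:`CalibrationError` if the construction misses its bands.
    """
    if spec is None:
        spec = FixtureSpec()
    snapshot = _base_layout(spec)
    _scale_lut_charges(snapshot, spec)
    # calibration checks: trio localization of the lowest exciton
    H = build_site_hamiltonian(snapshot, eps_r=spec.eps_r)
    basis = diagonalize(H, snapshot)
    chl_ids = [p.pigment_id for p in snapshot if p.pigment_type != "LUT"]
    trio_idx = [chl_ids.index(t) for t in spec.trio]
    loc = float((basis.coefficients[trio_idx, 0] ** 2).sum())
    if loc < 0.8:
        raise CalibrationError(f"lowest exciton trio localization {loc:.3f} < 0.8")
    luts = [LutSiteConfig(lut_id=pid) for pid in spec.lut_ids]
    return snapshot, luts


def generate_snapshot_ensemble(
    spec: FixtureSpec | None = None,
    n_snapshots: int = 50,
    metadata: dict | None = None,
) -> SnapshotEnsemble:
    """Seeded rigid-body-jittered snapshots around the crystal fixture.

    Every pigment is independently translated (sigma_trans per axis) and
    rotated about a random axis through its center (sigma_rot_deg);
    couplings recomputed from the jittered geometries fluctuate around
    the fixture values.  Deterministic for a given (spec, seed).
    """
    if spec is None:
        spec = FixtureSpec()
    if n_snapshots < 1:
        raise ValueError("need at least one snapshot")
    base, _ = generate_crystal_fixture(spec)
    rng = np.random.default_rng(spec.seed)
    snapshots = []
    for _ in range(n_snapshots):
        snap = []
        for p in base:
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            angle = np.deg2rad(rng.normal(0.0, spec.sigma_rot_deg))
            K = np.array([
                [0, -axis[2], axis[1]],
                [axis[2], 0, -axis[0]],
                [-axis[1], axis[0], 0],
            ])
            R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
            t = rng.normal(0.0, spec.sigma_trans, size=3)
            snap.append(p.transformed(rotation=R, translation=t))
        snapshots.append(snap)
    meta = {"minimum": "crystal-like", "ph_class": "neutral"}
    if metadata:
        meta.update(metadata)
    return SnapshotEnsemble(snapshots=snapshots, metadata=meta)


def lut_trio_couplings(
    snapshot: list[PigmentGeometry], spec: FixtureSpec | None = None, lut_id: str = "LUT1"
) -> np.ndarray:
    """Site-basis couplings (cm^-1) of one lutein to the terminal-emitter trio."""
    if spec is None:
        spec = FixtureSpec()
    chls = {p.pigment_id: p for p in snapshot}
    lut = chls[lut_id]
    return np.array([
        coulomb_coupling(chls[t], lut, eps_r=spec.eps_r, transition_m="qy", transition_n="s1")
        for t in spec.trio
    ])


# ---------------------------------------------------------------------------
# synthetic transient absorption
# ---------------------------------------------------------------------------

@dataclass
class TAGeneratorSpec:
    """Noisy synthetic TA surface from a known generating parameter set."""

    params: VERAParameterSet = field(default_factory=lutein_pyridine_params)
    delays: np.ndarray = field(default_factory=lambda: np.concatenate([
        np.arange(0.3, 1.0, 0.2), np.arange(1.0, 20.0, 1.0), np.arange(20.0, 44.0, 4.0),
    ]))
    wavenumbers: np.ndarray = field(default_factory=lambda: np.arange(13000.0, 24000.0, 150.0))
    noise_sigma: float = 0.0
    baseline_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


def generate_synthetic_ta(spec: TAGeneratorSpec | None = None) -> TADataset:
    """Forward-model dA surface plus seeded additive Gaussian noise.

    ``noise_sigma`` is expressed as a fraction of the surface's peak
    absolute amplitude (so ``1/noise_sigma`` is the peak SNR); an
    optional linear ``baseline_drift`` (same scale, across delay) mimics
    slow instrument drift.  Metadata records the generating parameters.
    """
    if spec is None:
        spec = TAGeneratorSpec()
    da = simulate_ta(spec.params, spec.delays, spec.wavenumbers)
    rng = np.random.default_rng(spec.seed)
    scale = np.abs(da).max()
    if spec.noise_sigma > 0:
        da = da + rng.normal(0.0, spec.noise_sigma * scale, size=da.shape)
    if spec.baseline_drift > 0:
        ramp = np.linspace(0.0, spec.baseline_drift * scale, spec.delays.size)
        da = da + ramp[None, :]
    return TADataset(
        delays=spec.delays.copy(), wavenumbers=spec.wavenumbers.copy(), da=da,
        noise_sigma=(np.full_like(da, spec.noise_sigma * scale) if spec.noise_sigma > 0 else None),
        metadata={
            "generating_params": spec.params.to_dict(),
            "noise_sigma": spec.noise_sigma,
            "seed": spec.seed,
        },
    )
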