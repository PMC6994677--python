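"""Synthetic instrument-data generators for the full analysis chain.

No scattering data were deposited for this protein system, so the
pipeline is exercised end-to-end on synthetic inputs whose generating
parameters are the published structural and dynamical values of the four
folding states of apomyoglobin:

=======  =====================================  =========================
state    structure                              dynamics
=======  =====================================  =========================
pd6      globular, Rg = 14.8 Å (Guinier α = 0)  rigid body + one mode
pd4      molten globule, Rg = 25.4 Å, ν = 0.46  ZIF, D = 1.7, τ = 49.63
pd2      acid unfolded, Rg = 26.7 Å, ν = 0.55   ZIF, D = 3.0, τ = 50.89
gdmcl    GdmCl denatured, Rg = 70.2 Å, ν = 0.64 Zimm, D = 1.2, τ = 0
=======  =====================================  =========================

(D in Å²/ns, τ = internal friction time in ns.)  All stochastic output is
driven by an explicit seed; SANS noise is 2% relative by default and ISF
noise grows linearly with Fourier time, emulating echo-amplitude loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .sans_models import (ScatteringCurve, eval_generalized_guinier,
                          eval_excluded_volume_form_factor)
from .nse_core import ISFSet, QRecord
from .polymer_dynamics import ZimmModelSpec, simulate_spectra
from .rigid_body_modes import (RigidBodySystem, ScatteringCenter,
                               rigid_body_Dq, enm_modes,
                               mode_effective_diffusion)

__all__ = [
    "SampleStateSpec",
    "STATES",
    "FixtureRegistry",
    "generate_sans",
    "generate_nse",
    "generate_scalars",
    "zimm_spec_for_state",
    "write_synthetic_pdb",
]


@dataclass
class SampleStateSpec:
    """Generating parameters of one folding state."""

    name: str
    rg: float                        # Å
    r_h: float                       # Å
    nu: float | None = None          # unfolded states
    guinier_alpha: float | None = None  # pd6
    kuhn_length: float | None = None    # Å (N = 20 beads)
    com_diffusion: float | None = None  # Å²/ns
    tau_intern: float = 0.0          # ns
    eta: float = 1.7                 # mPa·s
    temperature: float = 283.15      # K
    s_q0: float = 1.0
    d_conc: float = np.nan           # Å²/ns, DLS at concentration
    d_dilute: float = np.nan         # Å²/ns, DLS extrapolated
    eta_conc: float = np.nan         # mPa·s
    eta_dilute: float = np.nan       # mPa·s
    sans_rel_sigma: float = 0.02
    isf_sigma0: float = 0.02

    @property
    def unfolded(self):
        return self.nu is not None


STATES = {
    "pd6": SampleStateSpec(
        name="pd6", rg=14.8, r_h=19.6, guinier_alpha=0.0,
        com_diffusion=8.2, eta=1.7,
        s_q0=1.163, d_conc=6.1, d_dilute=8.2,
        eta_conc=2.2, eta_dilute=1.70),
    "pd4": SampleStateSpec(
        name="pd4", rg=25.4, r_h=30.0, nu=0.46, kuhn_length=15.1,
        com_diffusion=1.7, tau_intern=49.63, eta=1.7,
        s_q0=0.436, d_conc=1.4, d_dilute=2.5,
        eta_conc=5.01, eta_dilute=1.72),
    "pd2": SampleStateSpec(
        name="pd2", rg=26.7, r_h=18.0, nu=0.55, kuhn_length=13.6,
        com_diffusion=3.0, tau_intern=50.89, eta=1.7,
        s_q0=0.485, d_conc=6.0, d_dilute=3.8,
        eta_conc=np.nan, eta_dilute=1.74),
    "gdmcl": SampleStateSpec(
        name="gdmcl", rg=70.2, r_h=56.7, nu=0.64, kuhn_length=13.4,
        com_diffusion=1.2, tau_intern=0.0, eta=1.9,
        s_q0=0.615, d_conc=2.3, d_dilute=2.0,
        eta_conc=2.83, eta_dilute=1.97),
}

DEFAULT_CONCENTRATIONS = (3.0, 6.0, 15.0, 30.0)   # mg/mL
DEFAULT_Q_SANS = np.geomspace(0.008, 0.35, 120)   # 1/Å
DEFAULT_Q_NSE = (0.05, 0.07, 0.09, 0.11, 0.13, 0.15)
DEFAULT_T_NSE = np.geomspace(0.5, 90.0, 30)       # ns


def _get_state(state) -> SampleStateSpec:
    if isinstance(state, SampleStateSpec):
        return state
    try:
        return STATES[state]
    except KeyError:
        raise ValueError(f"unknown state {state!r}; expected one of "
                         f"{sorted(STATES)}") from None


def zimm_spec_for_state(state, n_beads: int = 20) -> ZimmModelSpec:
    """ZimmModelSpec with the state's published chain parameters."""
    st = _get_state(state)
    if not st.unfolded:
        raise ValueError(f"state {st.name} is not chain-like")
    return ZimmModelSpec(
        n_beads=n_beads, flory_exponent=st.nu, kuhn_length=st.kuhn_length,
        solvent_viscosity=st.eta, temperature=st.temperature,
        internal_friction=st.tau_intern, com_diffusion=st.com_diffusion)


# ---------------------------------------------------------------------------
# SANS
# ---------------------------------------------------------------------------

def _interaction_sq(st: SampleStateSpec, q, concentration):
    """Phenomenological concentration-scaled structure factor.

    Denatured states: screened repulsion, S < 1 at low q, → 1 at high q.
    pd6: weak low-q attraction (S > 1) with a shallow minimum near
    q = 0.07 1/Å (monomer contact at 2π/q ≈ 90 Å).  Both are linear in
    concentration, so extrapolation to c = 0 recovers the form factor
    exactly.
    """
    x = concentration / 30.0
    if st.unfolded:
        xi = 1.5 * st.rg
        return 1.0 - 0.45 * x * np.exp(-(q * xi) ** 2 / 3.0)
    bump = 0.35 * np.exp(-(q / 0.030) ** 2)
    dip = 0.18 * np.exp(-((q - 0.07) / 0.025) ** 2)
    return 1.0 + x * (bump - dip)


def form_factor_curve(state, q) -> np.ndarray:
    """Noiseless normalized form factor P(q) of the state (P(0) = 1)."""
    st = _get_state(state)
    q = np.asarray(q, dtype=float)
    if st.unfolded:
        return eval_excluded_volume_form_factor(q, st.rg, st.nu)
    return eval_generalized_guinier(q, 1.0, st.rg, st.guinier_alpha)


def generate_sans(state, q=None, concentrations=DEFAULT_CONCENTRATIONS,
                  seed=None, rel_sigma=None) -> list[ScatteringCurve]:
    """Seeded SANS curves I(q,c) = c·P(q)·S(q;c) + Gaussian noise.

    One curve per concentration (mg/mL).  `rel_sigma` overrides the
    state's relative noise level; `seed=None` with `rel_sigma=0` gives
    exact noiseless curves.
    """
    st = _get_state(state)
    q = DEFAULT_Q_SANS if q is None else np.asarray(q, dtype=float)
    sig_rel = st.sans_rel_sigma if rel_sigma is None else rel_sigma
    if sig_rel > 0 and seed is None:
        raise ValueError("a seed is required for noisy output")
    rng = np.random.default_rng(seed)
    p = form_factor_curve(st, q)
    curves = []
    for c in concentrations:
        ideal = c * p * _interaction_sq(st, q, c)
        sigma = sig_rel * np.abs(ideal)
        noisy = ideal + rng.normal(size=len(q)) * sigma
        curves.append(ScatteringCurve(
            q=q, intensity=noisy, sigma=sigma, concentration=c,
            temperature=st.temperature,
            label=f"{st.name} {c:g} mg/mL (synthetic)"))
    return curves


# ---------------------------------------------------------------------------
# NSE
# ---------------------------------------------------------------------------

def generate_nse(state, q_values=DEFAULT_Q_NSE, t_grid=None,
                 seed=None, sigma0=None, n_beads: int = 20) -> ISFSet:
    """Seeded normalized ISF spectra for a folding state.

    Chain-like states are simulated from the ZIF dynamic structure factor
    with the state's published (ν, l, D, τ_intern, η, T); the pd6-like
    globular state decays as exp(-q²·D(q)·t) where D(q) is the rigid-body
    first cumulant of a coordinate fixture plus a single internal-mode
    contribution of ≈20% of D₀.  Noise is Gaussian with
    σ(t) = σ₀·(1 + t/t_max), emulating the echo-amplitude loss of real
    spin-echo data at long Fourier times.
    """
    st = _get_state(state)
    t = DEFAULT_T_NSE if t_grid is None else np.asarray(t_grid, dtype=float)
    s0 = st.isf_sigma0 if sigma0 is None else sigma0
    if s0 > 0 and seed is None:
        raise ValueError("a seed is required for noisy output")
    rng = np.random.default_rng(seed)

    if st.unfolded:
        clean = simulate_spectra(zimm_spec_for_state(st, n_beads=n_beads),
                                 q_values, t)
    else:
        clean = _globular_isf(st, q_values, t)

    records = []
    tmax = t.max() if len(t) else 1.0
    for rec in clean:
        sigma = s0 * (1.0 + rec.t / tmax)
        values = rec.values + rng.normal(size=len(rec.t)) * sigma
        records.append(QRecord(rec.q, rec.t, values,
                               np.maximum(sigma, 1e-9)))
    meta = dict(clean.metadata)
    meta.update(sample=st.name, temperature=st.temperature, seed=seed)
    return ISFSet(records, metadata=meta)


def _globular_isf(st, q_values, t):
    fix = FixtureRegistry()
    system = RigidBodySystem(fix.coordinates("tetrahedron"),
                             fix.diffusion_matrix("globular",
                                                  d_trans=st.com_diffusion))
    q = np.asarray(q_values, dtype=float)
    d0 = rigid_body_Dq(system, q, n_orientations=300,
                       convergence_check=False)
    modes = enm_modes(fix.coordinates("tetrahedron"), cutoff=30.0,
                      temperature=st.temperature)
    dmode = mode_effective_diffusion(
        fix.coordinates("tetrahedron"), modes.vector(7),
        modes.relaxation_rate, modes.amplitude(7), q, n_orientations=300)
    dmode *= 0.2 * d0.mean() / dmode.mean()    # ≈20% internal share
    dtot = d0 + dmode
    records = [QRecord(float(qi), t, np.exp(-qi**2 * di * t),
                       np.zeros_like(t))
               for qi, di in zip(q, dtot)]
    return ISFSet(records, metadata={"model": "rigid-body+mode7"})


# ---------------------------------------------------------------------------
# scalar side measurements
# ---------------------------------------------------------------------------

def generate_scalars(state, seed=None, rel_sigma: float = 0.02):
    """(D_dls, η_conc, η_dilute, S_q0) for the named state.

    Deterministic without a seed (the published values); with a seed the
    values are reproducibly perturbed by `rel_sigma` relative Gaussian
    noise.
    """
    st = _get_state(state)
    vals = np.array([st.d_conc, st.eta_conc, st.eta_dilute, st.s_q0])
    if seed is not None:
        rng = np.random.default_rng(seed)
        vals = vals * (1.0 + rel_sigma * rng.normal(size=4))
    return tuple(vals)


# ---------------------------------------------------------------------------
# coordinate and matrix fixtures
# ---------------------------------------------------------------------------

class FixtureRegistry:
    """Self-contained coordinate sets and diffusion matrices for tests.

    All fixtures are generated in memory; nothing is downloaded.
    """

    def coordinates(self, name: str, b: float = 1.0,
                    spacing: float = 13.6) -> list[ScatteringCenter]:
        if name == "dumbbell":
            pos = np.array([[0.0, 0.0, -10.0], [0.0, 0.0, 10.0]])
        elif name == "tetrahedron":
            a = 15.0 / np.sqrt(2.0)
            pos = np.array([[a, a, a], [a, -a, -a], [-a, a, -a],
                            [-a, -a, a]]) / np.sqrt(3.0) * np.sqrt(2.0)
        elif name == "chain20":
            # gentle 3-D helix so the network is never collinear
            i = np.arange(20)
            turn = 2.0 * np.pi / 7.5
            radius = spacing / (2.0 * np.sin(turn / 2.0) * np.sqrt(2.0))
            rise = np.sqrt(max(spacing**2
                               - (2.0 * radius * np.sin(turn / 2.0)) ** 2,
                               1.0))
            pos = np.stack([radius * np.cos(turn * i),
                            radius * np.sin(turn * i),
                            rise * i], axis=1)
        else:
            raise KeyError(f"unknown coordinate fixture {name!r}")
        pos = pos - pos.mean(axis=0)
        return [ScatteringCenter(p, b, label=f"{name}{j}")
                for j, p in enumerate(pos)]

    def diffusion_matrix(self, name: str, d_trans: float = 6.0,
                         d_rot: float = 0.01) -> np.ndarray:
        """6×6 matrices in Å²/ns (translation) and rad²/ns (rotation)."""
        mat = np.zeros((6, 6))
        if name == "isotropic":
            mat[:3, :3] = d_trans * np.eye(3)
        elif name == "globular":
            mat[:3, :3] = d_trans * np.eye(3)
            mat[3:, 3:] = d_rot * np.eye(3)
        elif name == "axial_dumbbell":
            mat[:3, :3] = np.diag([0.9, 0.9, 1.2]) * d_trans
            mat[3:, 3:] = np.diag([1.0, 1.0, 0.1]) * d_rot
        else:
            raise KeyError(f"unknown matrix fixture {name!r}")
        return mat


_PDB_TEMPLATE = ("ATOM  {serial:5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
                 "{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
                 "{bfac:6.2f}          {element:>2s}\n")


def write_synthetic_pdb(path, kind: str = "water_methane") -> None:
    """Write a small synthetic PDB fixture (hand-built coordinates).

    ``water_methane``: a hydroxyl O–H pair plus an aliphatic C–H pair —
    the minimal case distinguishing labile from non-labile hydrogens.
    ``mini_helix``: a 12-residue glycine Cα/N/C/O trace on an α-helical
    path for coarse-graining and network-mode tests.  Both are synthetic
    constructions, not deposited structures.
    """
    lines = []

    def atom(serial, name, res, resseq, xyz, element):
        lines.append(_PDB_TEMPLATE.format(
            serial=serial, name=name, alt=" ", res=res, chain="A",
            resseq=resseq, x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0,
            bfac=0.0, element=element))

    if kind == "water_methane":
        atom(1, "O", "HOH", 1, (0.0, 0.0, 0.0), "O")
        atom(2, "H1", "HOH", 1, (0.96, 0.0, 0.0), "H")
        atom(3, "C", "CH4", 2, (6.0, 0.0, 0.0), "C")
        atom(4, "H1", "CH4", 2, (7.09, 0.0, 0.0), "H")
    elif kind == "mini_helix":
        serial = 1
        for i in range(12):
            phi = 100.0 * np.pi / 180.0 * i
            ca = np.array([2.3 * np.cos(phi), 2.3 * np.sin(phi), 1.5 * i])
            for name, offset, element in (
                    ("N", (-0.5, 0.4, -0.6), "N"),
                    ("CA", (0.0, 0.0, 0.0), "C"),
                    ("C", (0.7, -0.4, 0.6), "C"),
                    ("O", (1.1, -1.2, 0.9), "O")):
                atom(serial, name, "GLY", i + 1, ca + np.asarray(offset),
                     element)
                serial += 1
    else:
        raise KeyError(f"unknown PDB fixture {kind!r}")
    lines.append("END\n")
    from pathlib import Path
    Path(path).write_text("".join(lines))
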