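"""Rigid-body first-cumulant diffusion and elastic-network modes.

For a compact, native-like protein the spin-echo initial slope is set by
coupled translational–rotational rigid-body diffusion.  Given scattering
centers (positions r_j, coherent scattering lengths b_j) and the 6×6
generalized diffusion matrix D (translational block in Å²/ns, rotational
block in rad²/ns, coupling blocks mixed), the q-dependent first cumulant
is

    D₀(q) = (1/(q²F(q))) Σ_{j,k} ⟨ b_j e^{-i q·r_j} (q, q×r_j) · D ·
                                     (q, q×r_k)ᵀ b_k e^{+i q·r_k} ⟩

with ⟨…⟩ the orientational average (deterministic spherical quadrature
here) and F(q) the orientationally averaged form factor, i.e. the Debye
double sum Σ b_j b_k sinc(q r_jk).  The conjugate-phase convention makes
the average manifestly real and non-negative for a PSD diffusion matrix.

Internal dynamics on top of the rigid body is described by elastic-network
(anisotropic network model) normal modes: modes 1–6 are the rigid-body
null space, mode 7 is the first internal motion.  Its contribution to the
effective diffusion is

    D_eff^α(q) = λ_α k_α/(q²F(q)) ⟨ |Σ_j b_j e^{-i q·r_j} (q·e_j^α)|² ⟩

with eigenvector e^α, amplitude k_α = k_B T/(m̄ ω²_α) and relaxation rate
λ_α (an input here — the mode friction is not modelled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RigidBodySystem",
    "ScatteringCenter",
    "NormalModeSet",
    "FormFactorTable",
    "COHERENT_B",
    "read_coordinates",
    "read_diffusion_matrix",
    "fibonacci_sphere",
    "form_factor",
    "rigid_body_Dq",
    "enm_modes",
    "mode_effective_diffusion",
    "internal_dynamics_residual",
]

#: Bound coherent neutron scattering lengths, fm.
COHERENT_B = {
    "H": -3.739, "D": 6.671, "C": 6.646, "N": 9.36, "O": 5.803,
    "S": 2.847, "P": 5.13, "FE": 9.45, "NA": 3.63, "MG": 5.375,
    "CL": 9.577, "K": 3.67, "CA": 4.70, "ZN": 5.680, "SE": 7.970,
    "CU": 7.718, "MN": -3.73,
}

#: Mean atomic masses (amu) for the mass-weighting of network modes.
ATOMIC_MASS = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "FE": 55.845,
}


@dataclass
class ScatteringCenter:
    position: np.ndarray        # Å, shape (3,)
    b: float                    # fm
    label: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("position must be a finite 3-vector")


@dataclass
class RigidBodySystem:
    """Scattering centers plus a 6×6 generalized diffusion matrix.

    The matrix is laid out [[D_tt, D_tr], [D_rt, D_rr]] about the center
    of diffusion; it must be symmetric positive semidefinite.
    """

    centers: list[ScatteringCenter]
    diffusion_matrix: np.ndarray

    def __post_init__(self):
        if len(self.centers) == 0:
            raise ValueError("need at least one scattering center")
        d = np.asarray(self.diffusion_matrix, dtype=float)
        if d.shape != (6, 6):
            raise ValueError("diffusion matrix must be 6x6")
        if not np.allclose(d, d.T, atol=1e-10 * max(1.0, np.abs(d).max())):
            raise ValueError("diffusion matrix must be symmetric")
        if np.linalg.eigvalsh(d).min() < -1e-10 * max(1.0, np.abs(d).max()):
            raise ValueError("diffusion matrix must be positive semidefinite")
        self.diffusion_matrix = d

    @property
    def positions(self):
        return np.stack([c.position for c in self.centers])

    @property
    def b(self):
        return np.array([c.b for c in self.centers])


@dataclass
class NormalModeSet:
    """Elastic-network modes sorted by eigenvalue.

    Eigenvectors are orthonormal under uniform mass weighting (mean mass
    m̄); the first internal mode is numbered α = 7 following the
    convention that 1–6 are the rigid-body modes.
    """

    eigenvectors: np.ndarray    # (n_modes, n_centers, 3)
    eigenvalues: np.ndarray     # ω²_α, ascending
    mean_mass: float            # amu
    temperature: float = 283.15
    relaxation_rate: float = 1.0   # λ_α, 1/ns (input, not modelled)

    def amplitude(self, alpha):
        """k_α = k_B T/(m̄ ω²_α) for the 1-based mode number α ≥ 7.

        Units are set by the (arbitrary) network spring constant; only
        q-shapes of mode quantities are physically meaningful.
        """
        if alpha < 7:
            raise ValueError("modes 1-6 are rigid-body; amplitudes "
                             "are defined for alpha >= 7")
        from .constants import KB
        w2 = self.eigenvalues[alpha - 1]
        return KB * self.temperature / (self.mean_mass * w2)

    def vector(self, alpha):
        return self.eigenvectors[alpha - 1]


@dataclass
class FormFactorTable:
    q: np.ndarray
    F: np.ndarray               # fm²
    quadrature: str = "debye"

    def __post_init__(self):
        if np.any(self.F <= 0):
            raise ValueError("form factor must be positive")

    def interp(self, q):
        return np.interp(q, self.q, self.F)


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

_LABILE_PARTNERS = ("N", "O", "S")
_LABILE_CUTOFF = 1.25    # Å, covalent X–H bond length upper bound


def read_coordinates(path, deuterate_labile: bool = False,
                     coarse_grain_residues: bool = False,
                     include_hetero: bool = False) -> list[ScatteringCenter]:
    """Read scattering centers from a PDB file.

    Coherent scattering lengths come from the bundled table; with
    `deuterate_labile` set, hydrogens bonded to N, O or S (within 1.25 Å)
    take the deuterium scattering length, emulating H/D exchange of
    surface-exposed labile protons in heavy water.  With
    `coarse_grain_residues`, one center per residue is produced at the
    b-weighted centroid carrying the summed residue b.
    """
    import biotite.structure.io.pdb as pdbio

    pdb = pdbio.PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="first")
    if not include_hetero:
        atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no atoms")

    elements = [e.upper() if e else "" for e in atoms.element]
    unknown = [f"{i}:{atoms.atom_name[i]}" for i, e in enumerate(elements)
               if e not in COHERENT_B]
    if unknown:
        raise ValueError(f"{path}: unknown element(s) for atom record(s) "
                         + ", ".join(unknown[:10]))

    coords = atoms.coord
    b = np.array([COHERENT_B[e] for e in elements])
    if deuterate_labile:
        heavies = np.array([e in _LABILE_PARTNERS for e in elements])
        hpos = coords[heavies] if heavies.any() else np.empty((0, 3))
        for i, e in enumerate(elements):
            if e != "H" or len(hpos) == 0:
                continue
            d = np.linalg.norm(hpos - coords[i], axis=1)
            if d.min() <= _LABILE_CUTOFF:
                b[i] = COHERENT_B["D"]

    if coarse_grain_residues:
        centers = []
        keys = list(zip(atoms.chain_id, atoms.res_id))
        seen = {}
        for i, key in enumerate(keys):
            seen.setdefault(key, []).append(i)
        for key, idx in seen.items():
            bi = b[idx]
            btot = bi.sum()
            if abs(btot) < 1e-9:
                warnings.warn(f"residue {key} has near-zero net b; "
                              "using unweighted centroid")
                centroid = coords[idx].mean(axis=0)
            else:
                centroid = (bi[:, None] * coords[idx]).sum(axis=0) / btot
            centers.append(ScatteringCenter(centroid, float(btot),
                                            label=f"{key[0]}{key[1]}"))
        return centers

    return [ScatteringCenter(coords[i], float(b[i]),
                             label=str(atoms.atom_name[i]))
            for i in range(len(b))]


def read_diffusion_matrix(path) -> np.ndarray:
    """Read a 6×6 whitespace-separated diffusion matrix.

    '#' header lines are ignored; a ``# units = ...`` header documents
    the expected layout (Å²/ns translation, rad²/ns rotation).
    """
    rows = [[float(x) for x in line.split()]
            for line in Path(path).read_text().splitlines()
            if line.strip() and not line.strip().startswith("#")]
    mat = np.asarray(rows, dtype=float)
    if mat.shape != (6, 6):
        raise ValueError(f"{path}: expected a 6x6 matrix, got {mat.shape}")
    return mat


# ---------------------------------------------------------------------------
# orientational averages
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors on the sphere, shape (n, 3)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def form_factor(centers, q_grid, n_orientations: int | None = None
                ) -> FormFactorTable:
    """Orientationally averaged form factor F(q) = ⟨|Σ b e^{iq·r}|²⟩, fm².

    The exact average is the Debye double sum Σ b_j b_k sinc(q r_jk),
    used by default; a spherical quadrature of `n_orientations` points is
    available for cross-checks against the quadrature used in the
    first-cumulant averages.
    """
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    pos = np.stack([c.position for c in centers])
    b = np.array([c.b for c in centers])
    if n_orientations:
        dirs = fibonacci_sphere(n_orientations)
        f = np.empty(len(q))
        for i, qi in enumerate(q):
            phases = np.exp(1j * qi * dirs @ pos.T)     # (O, J)
            amp = phases @ b
            f[i] = np.mean(np.abs(amp) ** 2)
        return FormFactorTable(q, f, quadrature=f"fibonacci({n_orientations})")
    rjk = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    bb = b[:, None] * b[None, :]
    f = np.array([(bb * np.sinc(qi * rjk / np.pi)).sum() for qi in q])
    return FormFactorTable(q, f, quadrature="debye")


def rigid_body_Dq(system: RigidBodySystem, q_grid,
                  n_orientations: int = 500,
                  convergence_check: bool = True):
    """First-cumulant rigid-body diffusion D₀(q) in Å²/ns.

    Orientational averages use a deterministic Fibonacci spherical
    quadrature; when doubling the point count changes any value by more
    than 1%, a warning carrying both values is emitted.
    """
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))

    def evaluate(n_dirs):
        dirs = fibonacci_sphere(n_dirs)
        pos, b, dmat = system.positions, system.b, system.diffusion_matrix
        out = np.empty(len(q))
        for i, qi in enumerate(q):
            qvec = qi * dirs                              # (O, 3)
            phase = np.exp(1j * (qvec @ pos.T))           # (O, J)
            cross = np.cross(qvec[:, None, :], pos[None, :, :])  # (O, J, 3)
            v = np.concatenate([np.broadcast_to(qvec[:, None, :], cross.shape),
                                cross], axis=-1)          # (O, J, 6)
            w = np.einsum("oj,ojk->ok", b * phase, v)     # (O, 6) complex
            num = np.einsum("ok,kl,ol->o", np.conj(w), dmat, w).real
            den = np.mean(np.abs(phase @ b) ** 2)
            out[i] = np.mean(num) / (qi**2 * den)
        return out

    d0 = evaluate(n_orientations)
    if convergence_check:
        d0_fine = evaluate(2 * n_orientations)
        rel = np.abs(d0_fine - d0) / np.where(d0 != 0, np.abs(d0), 1.0)
        if np.any(rel > 0.01):
            warnings.warn(
                "orientational quadrature not converged to 1%: "
                f"n={n_orientations} gives {d0[np.argmax(rel)]:.4g}, "
                f"n={2*n_orientations} gives {d0_fine[np.argmax(rel)]:.4g}",
                stacklevel=2)
        d0 = d0_fine
    return d0


# ---------------------------------------------------------------------------
# elastic-network modes
# ---------------------------------------------------------------------------

def enm_modes(centers, cutoff: float = 13.0, spring_constant: float = 1.0,
              mean_mass: float = 110.0, temperature: float = 283.15,
              relaxation_rate: float = 1.0) -> NormalModeSet:
    """Anisotropic-network normal modes of the scattering centers.

    Builds the standard Hookean pair Hessian (uniform spring constant for
    pairs within `cutoff`), mass-weights by the mean mass and
    diagonalizes.  Exactly six near-zero modes must emerge (a connected
    network); otherwise the network is disconnected and a larger cutoff
    is required.  Default mean mass 110 amu is one residue.
    """
    pos = np.stack([c.position for c in centers])
    n = len(pos)
    if n < 2:
        raise ValueError("need at least two centers")
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    contact = (dist <= cutoff) & (dist > 0)

    # connectivity check on the contact graph
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import csr_matrix
    ncomp, _ = connected_components(csr_matrix(contact), directed=False)
    if ncomp != 1:
        raise ValueError(
            f"elastic network is disconnected ({ncomp} components) at "
            f"cutoff {cutoff} Å; increase the cutoff")

    hessian = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            if not contact[i, j]:
                continue
            d = diff[i, j]
            block = -spring_constant * np.outer(d, d) / (d @ d)
            hessian[3*i:3*i+3, 3*j:3*j+3] = block
            hessian[3*j:3*j+3, 3*i:3*i+3] = block
            hessian[3*i:3*i+3, 3*i:3*i+3] -= block
            hessian[3*j:3*j+3, 3*j:3*j+3] -= block

    evals, evecs = np.linalg.eigh(hessian / mean_mass)
    evals = np.clip(evals, 0.0, None)
    scale = evals[6] if n * 3 > 6 else 1.0
    if n * 3 > 6 and np.any(evals[:6] > 1e-8 * scale):
        raise ValueError("fewer than six rigid-body modes; network "
                         "geometry is degenerate")
    return NormalModeSet(
        eigenvectors=evecs.T.reshape(3 * n, n, 3),
        eigenvalues=evals,
        mean_mass=mean_mass,
        temperature=temperature,
        relaxation_rate=relaxation_rate,
    )


def mode_effective_diffusion(centers, eigenvector, relaxation_rate,
                             amplitude, q_grid,
                             n_orientations: int = 500):
    """Mode-specific effective diffusion D_eff^α(q).

    `eigenvector` has one 3-vector per center; the result is invariant
    under a global sign flip of the eigenvector and non-negative for a
    real mode.  Units follow λ_α·k_α.
    """
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    pos = np.stack([c.position for c in centers])
    b = np.array([c.b for c in centers])
    e = np.asarray(eigenvector, dtype=float)
    if e.shape != pos.shape:
        raise ValueError("eigenvector shape must match the centers")
    dirs = fibonacci_sphere(n_orientations)
    out = np.empty(len(q))
    for i, qi in enumerate(q):
        qvec = qi * dirs
        phase = np.exp(-1j * (qvec @ pos.T))          # (O, J)
        proj = qvec @ e.T                             # (O, J)
        amp_sum = np.einsum("oj,oj->o", b * phase, proj + 0j)
        num = np.mean(np.abs(amp_sum) ** 2)
        den = np.mean(np.abs(np.exp(1j * (qvec @ pos.T)) @ b) ** 2)
        out[i] = relaxation_rate * amplitude * num / (qi**2 * den)
    return out


def internal_dynamics_residual(measured, rigid_q, rigid_d0):
    """ΔD_eff(q) = D_eff(q) - D₀(q) and its mean fractional share.

    `measured` is an EffectiveDiffusionCurve; the rigid-body curve is
    interpolated onto its q support.  Returns (ΔD array, σ array,
    mean fractional contribution ΔD/D_eff).
    """
    d0 = np.interp(measured.q, np.atleast_1d(rigid_q),
                   np.atleast_1d(rigid_d0))
    delta = measured.D_eff - d0
    frac = float(np.mean(delta / measured.D_eff))
    return delta, measured.sigma.copy(), frac
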