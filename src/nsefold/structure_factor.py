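"""Interparticle structure factors and hydrodynamic-function estimators.

The experimental structure factor of a concentrated protein solution is
obtained by dividing its scattering curve by the form factor measured at
high dilution.  For charged globular proteins the result is modelled with
the mean-spherical-approximation (MSA) closure for hard spheres carrying a
screened-Coulomb (Yukawa) repulsion — the classical macro-ion model.

The MSA solution here is computed by spectral iteration of the
Ornstein–Zernike relation under the MSA closure (g = 0 inside the core,
c = -βu outside), anchored to the analytic Percus–Yevick hard-sphere
solution so that the zero-charge limit is exact.  When the bare MSA
produces an unphysical negative contact value g(σ⁺) < 0 (dilute, strongly
coupled systems) the standard rescaling to an equivalent larger-diameter
system with g(σ'⁺) = 0 is applied.

The module also hosts the two scalar estimators of the hydrodynamic
function H(c,q) used to correct spin-echo diffusion coefficients:
H_{c,q0} = D_c·S(q→0)/D_0 at low q, and H_{c,qL} = η_dilute/η_conc at
high q (the direction of the viscosity ratio is fixed by requiring the
two estimators to agree for weakly interacting solutions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dst
import lmfit

from .constants import KB, bjerrum_length
from .sans_models import ScatteringCurve, FitFailure

__all__ = [
    "StructureFactorCurve",
    "MSAParams",
    "HydrodynamicCorrection",
    "experimental_structure_factor",
    "percus_yevick_sq",
    "eval_msa_sq",
    "fit_msa",
    "hydrodynamic_function_low_q",
    "hydrodynamic_function_high_q",
    "stokes_einstein_rh",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StructureFactorCurve:
    q: np.ndarray
    S: np.ndarray
    sigma: np.ndarray
    smoothing: str = "none"

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.q) == len(self.S) == len(self.sigma)):
            raise ValueError("q, S, sigma must have equal length")
        if np.any(self.S <= 0):
            raise ValueError("structure factor must be positive")

    def interp(self, q):
        return np.interp(q, self.q, self.S)


@dataclass
class MSAParams:
    """Screened-Coulomb sphere parameters for the MSA structure factor."""

    sphere_radius: float          # Å
    volume_fraction: float
    effective_charge: float       # elementary charges
    screening_length: float       # Å (Debye length)
    temperature: float = 283.15   # K
    dielectric: float = 78.3

    def __post_init__(self):
        if not (0.0 < self.volume_fraction < 0.74):
            raise ValueError("volume fraction must lie in (0, 0.74)")
        if self.sphere_radius <= 0:
            raise ValueError("radius must be positive")
        if self.screening_length <= 0:
            raise ValueError("screening length must be positive")

    def contact_potential(self) -> float:
        """βu at contact (r = σ) in units of k_B T, DLVO convention."""
        lb = bjerrum_length(self.temperature, self.dielectric)
        kappa_r = self.sphere_radius / self.screening_length
        sigma = 2.0 * self.sphere_radius
        return (self.effective_charge**2 * lb
                / ((1.0 + kappa_r) ** 2 * sigma))


@dataclass
class HydrodynamicCorrection:
    S_q0: float
    D_c: float
    D_0: float
    H_q0: float
    eta_conc: float = np.nan
    eta_dilute: float = np.nan
    H_qL: float = np.nan


# ---------------------------------------------------------------------------
# experimental structure factor
# ---------------------------------------------------------------------------

def experimental_structure_factor(high_c: ScatteringCurve,
                                  form: ScatteringCurve,
                                  smooth_window: int = 5) -> StructureFactorCurve:
    """S(c,q) by pointwise division of a concentrated curve by the form
    factor, followed by centered moving-average smoothing.

    Both curves are brought onto their common q range by linear
    interpolation of the form factor; uncertainties are propagated in
    quadrature and averaged over the smoothing window.
    """
    qlo = max(high_c.q[0], form.q[0])
    qhi = min(high_c.q[-1], form.q[-1])
    if qlo >= qhi:
        raise ValueError("curves have no overlapping q range")
    mask = (high_c.q >= qlo) & (high_c.q <= qhi)
    q = high_c.q[mask]
    p = np.interp(q, form.q, form.intensity)
    sp = np.interp(q, form.q, form.sigma)
    if np.any(p <= 0):
        raise ValueError("form factor is non-positive inside the range")
    i = high_c.intensity[mask]
    si = high_c.sigma[mask]
    s = i / p
    ss = np.abs(s) * np.sqrt((si / np.where(i != 0, i, 1)) ** 2 + (sp / p) ** 2)

    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        sm = np.convolve(np.pad(s, pad, mode="edge"), kernel, mode="valid")
        sse = np.convolve(np.pad(ss**2, pad, mode="edge"), kernel,
                          mode="valid") / smooth_window
        s, ss = sm[:len(q)], np.sqrt(sse[:len(q)])
    return StructureFactorCurve(q, s, ss,
                                smoothing=f"moving-average({smooth_window})")


# ---------------------------------------------------------------------------
# Percus–Yevick hard spheres (closed form; the zero-charge anchor/oracle)
# ---------------------------------------------------------------------------

def percus_yevick_sq(q, radius, volume_fraction):
    """Analytic Percus–Yevick hard-sphere structure factor.

    Wertheim's solution: with x = q·σ (σ = 2R diameter) and volume
    fraction η, the direct correlation function inside the core is
    -(a + b s + η a s³/2) and its Fourier transform is closed-form.
    """
    eta = volume_fraction
    if not (0 < eta < 0.74):
        raise ValueError("volume fraction must lie in (0, 0.74)")
    x = np.asarray(q, dtype=float) * 2.0 * radius
    a = (1 + 2 * eta) ** 2 / (1 - eta) ** 4
    b = -6 * eta * (1 + eta / 2) ** 2 / (1 - eta) ** 4
    c = eta * a / 2
    out = np.empty_like(x)
    small = np.abs(x) < 1e-3
    xs = x[~small]
    sx, cx = np.sin(xs), np.cos(xs)
    # moments ∫0..1 s^n sin(xs) ds for n = 1, 2, 4
    i1 = (sx - xs * cx) / xs**2
    i2 = (2 * xs * sx - (xs**2 - 2) * cx - 2) / xs**3
    i4 = (-(xs**4 - 12 * xs**2 + 24) * cx
          + (4 * xs**3 - 24 * xs) * sx + 24) / xs**5
    term = (a * i1 + b * i2 + c * i4) / xs
    out[~small] = 1.0 / (1.0 + 24.0 * eta * term)
    # q -> 0: ∫ s²(a + bs + cs³) ds = a/3 + b/4 + c/6
    out[small] = 1.0 / (1.0 + 24.0 * eta * (a / 3.0 + b / 4.0 + c / 6.0))
    return out


# ---------------------------------------------------------------------------
# MSA via Ornstein–Zernike iteration
# ---------------------------------------------------------------------------

class _OZGrid:
    """Sine-transform grid for radial OZ iteration (σ = 1 units)."""

    def __init__(self, n=2**13, dr=4.0 / 2**11):
        self.n = n
        self.dr = dr
        self.r = dr * np.arange(1, n + 1)
        self.dk = np.pi / (dr * (n + 1))
        self.k = self.dk * np.arange(1, n + 1)

    def fourier(self, fr):
        """3-D radial FT: f̂(k) = 4π/k ∫ r f(r) sin(kr) dr via DST-I."""
        return (4 * np.pi * self.dr / (2 * self.k)
                * dst(self.r * fr, type=1))

    def inverse(self, fk):
        return (self.dk / (4 * np.pi**2 * self.r)
                * dst(self.k * fk, type=1))


_DEFAULT_GRID: _OZGrid | None = None


def _default_grid() -> _OZGrid:
    global _DEFAULT_GRID
    if _DEFAULT_GRID is None:
        _DEFAULT_GRID = _OZGrid(n=2**12, dr=2.0**-8)
    return _DEFAULT_GRID


def _solve_oz_msa(eta, kappa, gamma0, grid=None, tol=1e-11, x0=None):
    """Solve OZ + MSA closure for a hard core (σ = 1) with a Yukawa tail.

    βu(r) = gamma0·e^(-kappa·r)/r for r > 1 (gamma0·e^(-kappa) is the
    contact potential).  The fixed point in the indirect correlation
    γ = h - c is found by a Newton–Krylov solve of the OZ residual.
    Returns (S(k) on the grid, g(σ⁺) contact value, γ solution, grid).
    """
    from scipy.optimize import newton_krylov
    from scipy.optimize._nonlin import NoConvergence

    g = grid or _default_grid()
    rho = 6.0 * eta / np.pi
    core = g.r < 1.0
    betau = np.where(core, 0.0, gamma0 * np.exp(-kappa * g.r) / g.r)

    def resid(gam):
        c = np.where(core, -1.0 - gam, -betau)
        ck = g.fourier(c)
        gamk = rho * ck**2 / (1.0 - rho * ck)
        return g.inverse(gamk) - gam

    start = np.zeros_like(g.r) if x0 is None else x0
    try:
        gam = newton_krylov(resid, start, f_tol=tol, maxiter=200)
    except (NoConvergence, ValueError):
        try:
            # a stale warm start can strand the Krylov solve; retry cold
            gam = newton_krylov(resid, np.zeros_like(g.r), f_tol=tol,
                                maxiter=300)
        except (NoConvergence, ValueError) as exc:
            raise FitFailure(f"OZ iteration did not converge: {exc}") from exc
    c = np.where(core, -1.0 - gam, -betau)
    h = gam + c
    ck = g.fourier(c)
    sk = 1.0 / (1.0 - rho * ck)
    # contact value g(1+): first few grid points outside the core,
    # extrapolated linearly back to r = 1
    i0 = np.searchsorted(g.r, 1.0)
    r2, h2 = g.r[i0:i0 + 4], h[i0:i0 + 4]
    contact = float(np.polyval(np.polyfit(r2, 1.0 + h2, 1), 1.0))
    return sk, contact, gam, g


def eval_msa_sq(q, params: MSAParams, rescale: bool = True):
    """MSA structure factor for charged spheres on the given q grid (1/Å).

    Zero charge returns the analytic Percus–Yevick solution exactly; with
    charge the OZ/MSA solution is evaluated relative to its own
    zero-charge limit on the same grid so that discretization error
    cancels (PY-anchored spectral solver).  If the contact value g(σ⁺) is
    negative the system is rescaled to an equivalent larger diameter with
    g = 0 at contact (rescaled MSA); if no physical rescaling exists an
    error is raised.
    """
    q = np.asarray(q, dtype=float)
    sigma = 2.0 * params.sphere_radius
    gamma_contact = params.contact_potential()
    if gamma_contact == 0.0:
        return percus_yevick_sq(q, params.sphere_radius,
                                params.volume_fraction)

    kappa = sigma / params.screening_length       # in σ = 1 units
    gamma0 = gamma_contact * np.exp(kappa)        # βu = gamma0 e^{-κr}/r

    warm = {"x0": None}

    def solve(scale):
        """Solve with the hard core inflated by `scale` (physical
        potential unchanged)."""
        eta_s = params.volume_fraction * scale**3
        if eta_s >= 0.74:
            raise FitFailure("rescaled MSA exceeds close packing")
        kappa_s = kappa * scale
        gamma_s = gamma0 / scale                  # βu(r') = γ0 e^{-κ σ s x}/(σ s x)
        sk, contact, gam, grid = _solve_oz_msa(eta_s, kappa_s, gamma_s,
                                               x0=warm["x0"])
        warm["x0"] = gam
        return sk, contact, grid

    scale = 1.0
    sk, contact, grid = solve(scale)
    if rescale and contact < -1e-3:
        lo, hi = 1.0, 1.0
        for _ in range(40):       # bracket: contact grows with scale
            hi *= 1.15
            if params.volume_fraction * hi**3 >= 0.74:
                raise FitFailure("no physical rescaling: contact value "
                                 "negative up to close packing")
            try:
                sk, contact, grid = solve(hi)
            except FitFailure:
                warm["x0"] = None     # marginal solve; move the bracket on
                continue
            if contact >= 0:
                break
            lo = hi
        else:
            raise FitFailure("no physical rescaling found")
        mid = hi
        for _ in range(25):       # bisect g(σ'⁺) = 0
            mid = 0.5 * (lo + hi)
            try:
                sk, contact, grid = solve(mid)
            except FitFailure:
                warm["x0"] = None
                lo = mid          # treat as still-unphysical side
                continue
            if abs(contact) < 1e-3 or hi - lo < 1e-4:
                break
            if contact < 0:
                lo = mid
            else:
                hi = mid
        scale = mid

    # PY anchor on the same grid and effective packing
    eta_eff = params.volume_fraction * scale**3
    rho_eff = 6.0 * eta_eff / np.pi
    c_hs = np.where(grid.r < 1.0, _py_cr(grid.r, eta_eff), 0.0)
    sk_hs_num = 1.0 / (1.0 - rho_eff * grid.fourier(c_hs))

    k_dimless = q * sigma * scale
    ratio = np.interp(k_dimless, grid.k, sk / sk_hs_num)
    return percus_yevick_sq(k_dimless / (2.0 * params.sphere_radius),
                            params.sphere_radius, eta_eff) * ratio


def _py_cr(r, eta):
    """Wertheim PY direct correlation function inside the unit core."""
    a = (1 + 2 * eta) ** 2 / (1 - eta) ** 4
    b = -6 * eta * (1 + eta / 2) ** 2 / (1 - eta) ** 4
    return -(a + b * r + eta * a * r**3 / 2.0)


# ---------------------------------------------------------------------------
# MSA fitting
# ---------------------------------------------------------------------------

_MSA_BOUNDS = {
    "sphere_radius": (2.0, 500.0),
    "volume_fraction": (1e-4, 0.5),
    "effective_charge": (0.0, 200.0),
    "screening_length": (2.0, 1000.0),
}


def fit_msa(s_exp: StructureFactorCurve, init: MSAParams,
            frozen: tuple[str, ...] = ("sphere_radius", "volume_fraction")):
    """Bounded weighted least squares of the MSA model to an experimental
    structure-factor curve over the non-frozen parameters.

    Returns (MSAParams, reduced χ²).  A fit whose charge collapses to the
    lower bound signals an effectively uncharged (degenerate) system.
    """
    if len(s_exp.q) < 10:
        raise FitFailure("need at least 10 points to fit the MSA model")
    params = lmfit.Parameters()
    for name in _MSA_BOUNDS:
        val = getattr(init, name)
        lo, hi = _MSA_BOUNDS[name]
        if not (lo <= val <= hi):
            raise ValueError(f"initial {name}={val} outside bounds [{lo},{hi}]")
        params.add(name, value=val, min=lo, max=hi, vary=name not in frozen)

    sig = np.where(s_exp.sigma > 0, s_exp.sigma, 1.0)

    def resid(p):
        trial = MSAParams(
            sphere_radius=p["sphere_radius"].value,
            volume_fraction=p["volume_fraction"].value,
            effective_charge=p["effective_charge"].value,
            screening_length=p["screening_length"].value,
            temperature=init.temperature, dielectric=init.dielectric)
        try:
            model = eval_msa_sq(s_exp.q, trial)
        except FitFailure:
            return np.full_like(s_exp.S, 1e3)
        return (model - s_exp.S) / sig

    out = lmfit.minimize(resid, params, method="least_squares")
    if not out.success:
        raise FitFailure(f"MSA fit did not converge: {out.message}")
    fitted = MSAParams(
        sphere_radius=out.params["sphere_radius"].value,
        volume_fraction=out.params["volume_fraction"].value,
        effective_charge=out.params["effective_charge"].value,
        screening_length=out.params["screening_length"].value,
        temperature=init.temperature, dielectric=init.dielectric)
    return fitted, out.redchi


# ---------------------------------------------------------------------------
# hydrodynamic functions and Stokes–Einstein
# ---------------------------------------------------------------------------

def hydrodynamic_function_low_q(d_c, s_q0, d_0):
    """Low-q hydrodynamic function H_{c,q0} = D_c·S(q→0)/D_0."""
    if d_c <= 0 or s_q0 <= 0 or d_0 <= 0:
        raise ValueError("all inputs must be positive")
    return d_c * s_q0 / d_0


def hydrodynamic_function_high_q(eta_conc, eta_dilute):
    """High-q hydrodynamic function H_{c,qL} = η_dilute/η_conc."""
    if eta_conc <= 0 or eta_dilute <= 0:
        raise ValueError("viscosities must be positive")
    return eta_dilute / eta_conc


def stokes_einstein_rh(d, eta, temperature):
    """Hydrodynamic radius R_H = k_B T/(6πηD) in Å (D in Å²/ns, η mPa·s)."""
    if d <= 0 or eta <= 0 or temperature <= 0:
        raise ValueError("all inputs must be positive")
    return KB * temperature / (6.0 * np.pi * eta * d)
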