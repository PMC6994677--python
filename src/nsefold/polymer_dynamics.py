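"""Zimm and Zimm-with-internal-friction (ZIF) chain dynamics.

A flexible protein chain is modelled as N beads of Kuhn length l with
excluded-volume exponent ν.  With hydrodynamic interactions the normal
modes p = 1..p_max relax with times

    τ_p = η R_E³ / (√(3π) k_B T) · p^(-3ν)

(η solvent viscosity, R_E end-to-end distance).  Internal friction —
dihedral barriers, transient hydrogen bonds, intrachain collisions — adds
a mode-independent time: τ_p(ZIF) = τ_p + τ_intern, damping the fast,
high-p modes.  The coherent dynamic structure factor of the chain is

    I(q,t) = exp(-q² D (H/S) t)/N · Σ_{n,m} exp(-q² B(n,m,t)/6)
    B(n,m,t) = |n-m|^{2ν} l² + (4R_E²/π²) Σ_p A(p)/p^{2ν+1}
               · cos(πpn/N) cos(πpm/N) [1 - e^{-t/τ_p}]

with D the center-of-mass diffusion coefficient and H/S the
hydrodynamic-function/structure-factor correction.  Spin-echo data are
normalized, so the model is always evaluated as I(q,t)/I(q,0).

The global ZIF fit adjusts only (D, τ_intern) simultaneously over all
measured q, with the structural parameters (ν, l, N) fixed from SANS and
(η, T) from side measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import lmfit

from .constants import KB
from .sans_models import FitFailure
from .nse_core import ISFSet, QRecord

__all__ = [
    "ZimmModelSpec",
    "ZIFFitResult",
    "zimm_relaxation_times",
    "zif_relaxation_times",
    "first_zimm_time",
    "zimm_com_diffusion",
    "mode_correlator_B",
    "zimm_isf",
    "simulate_spectra",
    "fit_zif_global",
]

#: Prefactor convention for the first Zimm time, τ_1 = η R_E³/(PREF · k_B T).
#: √(3π) is the standard Zimm-with-excluded-volume choice; exposed so the
#: sensitivity to the (convention-dependent) prefactor can be probed.
ZIMM_TIME_PREFACTOR = float(np.sqrt(3.0 * np.pi))

#: Asymptotic Zimm center-of-mass diffusion prefactor,
#: D = 8/(3·(6π³)^(1/2)) · k_B T/(η R_E) ≈ 0.196·k_B T/(η R_E).
ZIMM_DIFFUSION_PREFACTOR = 8.0 / (3.0 * np.sqrt(6.0 * np.pi**3))


@dataclass
class ZimmModelSpec:
    """Full parameterization of the bead-spring chain ISF.

    R_E defaults to l·N^ν when not given.  A(p) ≡ 1 for the plain Zimm
    and ZIF models; the array hook exists for damped-amplitude variants.
    """

    n_beads: int
    flory_exponent: float
    kuhn_length: float                  # Å
    solvent_viscosity: float            # mPa·s
    temperature: float                  # K
    end_to_end: float | None = None     # Å
    p_max: int | None = None
    mode_amplitudes: np.ndarray | None = None
    internal_friction: float = 0.0      # ns
    com_diffusion: float | None = None  # Å²/ns; default: Zimm value
    h_over_s: float = 1.0
    time_prefactor: float = ZIMM_TIME_PREFACTOR

    def __post_init__(self):
        if self.n_beads < 2:
            raise ValueError("need at least 2 beads")
        if not (0.3 <= self.flory_exponent <= 1.0):
            raise ValueError("flory exponent out of [0.3, 1]")
        if self.kuhn_length <= 0 or self.solvent_viscosity <= 0 \
                or self.temperature <= 0:
            raise ValueError("l, η, T must be positive")
        if self.internal_friction < 0:
            raise ValueError("internal friction time must be >= 0")
        if self.end_to_end is None:
            self.end_to_end = self.kuhn_length * self.n_beads**self.flory_exponent
        else:
            expect = self.kuhn_length * self.n_beads**self.flory_exponent
            if abs(self.end_to_end - expect) > 0.01 * expect:
                raise ValueError(
                    f"end-to-end {self.end_to_end:.3g} inconsistent with "
                    f"l·N^ν = {expect:.3g} (beyond 1%)")
        if self.p_max is None:
            self.p_max = self.n_beads
        if self.p_max > self.n_beads:
            raise ValueError("p_max cannot exceed the bead count")
        if self.mode_amplitudes is None:
            self.mode_amplitudes = np.ones(self.p_max)
        else:
            self.mode_amplitudes = np.asarray(self.mode_amplitudes,
                                              dtype=float)
            if len(self.mode_amplitudes) != self.p_max:
                raise ValueError("need one amplitude per mode")
        if self.com_diffusion is None:
            self.com_diffusion = zimm_com_diffusion(
                self.solvent_viscosity, self.temperature, self.end_to_end)

    @classmethod
    def from_chain(cls, nu, l, n_beads=20, eta=1.7, temperature=283.15,
                   **kw):
        return cls(n_beads=n_beads, flory_exponent=nu, kuhn_length=l,
                   solvent_viscosity=eta, temperature=temperature, **kw)


@dataclass
class ZIFFitResult:
    com_diffusion: float        # Å²/ns
    internal_friction: float    # ns
    first_zimm_time: float      # ns, from the spec, not fitted
    chi2: float                 # reduced χ² over all jointly fitted points
    covariance: np.ndarray
    per_q_rms: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.internal_friction < -1e-12 or self.chi2 < 0:
            raise ValueError("invalid fit result")


# ---------------------------------------------------------------------------
# relaxation times
# ---------------------------------------------------------------------------

def zimm_com_diffusion(eta, temperature, r_end):
    """Zimm center-of-mass diffusion D = 0.196·k_B T/(η R_E) in Å²/ns."""
    return ZIMM_DIFFUSION_PREFACTOR * KB * temperature / (eta * r_end)


def zimm_relaxation_times(spec: ZimmModelSpec) -> np.ndarray:
    """Mode relaxation times τ_p = η R_E³/(√(3π) k_B T)·p^(-3ν), ns."""
    p = np.arange(1, spec.p_max + 1)
    tau1 = (spec.solvent_viscosity * spec.end_to_end**3
            / (spec.time_prefactor * KB * spec.temperature))
    return tau1 * p ** (-3.0 * spec.flory_exponent)


def zif_relaxation_times(tau_p, tau_intern):
    """ZIF times τ_p + τ_intern (elementwise; Zimm limit at τ_intern = 0)."""
    if tau_intern < 0:
        raise ValueError("internal friction time must be >= 0")
    return np.asarray(tau_p, dtype=float) + tau_intern


def first_zimm_time(spec: ZimmModelSpec) -> float:
    """First (slowest) Zimm mode time τ_1 in ns; scales as R_E³."""
    return float(zimm_relaxation_times(spec)[0])


# ---------------------------------------------------------------------------
# dynamic structure factor
# ---------------------------------------------------------------------------

def _mode_tables(spec):
    p = np.arange(1, spec.p_max + 1)
    n = np.arange(spec.n_beads)
    taus = zif_relaxation_times(zimm_relaxation_times(spec),
                                spec.internal_friction)
    cos = np.cos(np.pi * p[None, :] * n[:, None] / spec.n_beads)  # (N, P)
    amp = spec.mode_amplitudes / p ** (2.0 * spec.flory_exponent + 1.0)
    return taus, cos, amp


def mode_correlator_B(n, m, t, spec: ZimmModelSpec):
    """Pair correlator B(n,m,t) in Å² (static part + mode relaxation).

    Symmetric in (n, m); bead indices run 0..N-1.  B(n,m,0) is the static
    mean-squared distance |n-m|^{2ν} l² of the excluded-volume chain.
    """
    if not (0 <= n < spec.n_beads and 0 <= m < spec.n_beads):
        raise ValueError("bead indices out of range")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    taus, cos, amp = _mode_tables(spec)
    static = abs(n - m) ** (2.0 * spec.flory_exponent) * spec.kuhn_length**2
    relax = 1.0 - np.exp(-t[..., None] / taus)              # (..., P)
    mode = (4.0 * spec.end_to_end**2 / np.pi**2) * np.sum(
        amp * cos[n] * cos[m] * relax, axis=-1)
    return static + mode


def _isf_unnormalized(q, t, spec):
    """Σ_{n,m} exp(-q²B/6)/N over the time grid (no COM factor)."""
    taus, cos, amp = _mode_tables(spec)
    n = np.arange(spec.n_beads)
    static = (np.abs(n[:, None] - n[None, :]) ** (2.0 * spec.flory_exponent)
              * spec.kuhn_length**2)
    pref = 4.0 * spec.end_to_end**2 / np.pi**2
    out = np.empty(len(t))
    for i, ti in enumerate(t):
        w = amp * (1.0 - np.exp(-ti / taus))
        b = static + pref * (cos * w) @ cos.T
        out[i] = np.exp(np.clip(-q**2 * b / 6.0, -700, 0)).sum()
    return out / spec.n_beads


def zimm_isf(q, t, spec: ZimmModelSpec):
    """Normalized coherent ISF I(q,t)/I(q,0) of the (Z)IF chain.

    Exactly 1 at t = 0; reduces to exp(-q²·D·(H/S)·t) when all internal
    modes are frozen (τ_intern → ∞).
    """
    if q <= 0:
        raise ValueError("q must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    inner = _isf_unnormalized(q, t, spec)
    inner0 = _isf_unnormalized(q, np.array([0.0]), spec)[0]
    com = np.exp(-q**2 * spec.com_diffusion * spec.h_over_s * t)
    return com * inner / inner0


def simulate_spectra(spec: ZimmModelSpec, q_values, t_grid) -> ISFSet:
    """Noiseless ISFSet over the requested (q, t) grid (deterministic)."""
    t = np.asarray(t_grid, dtype=float)
    records = [QRecord(float(q), t, zimm_isf(float(q), t, spec),
                       np.zeros_like(t))
               for q in q_values]
    return ISFSet(records, metadata={
        "model": "ZIF" if spec.internal_friction > 0 else "Zimm",
        "nu": spec.flory_exponent, "N": spec.n_beads,
        "l": spec.kuhn_length, "eta": spec.solvent_viscosity,
        "T": spec.temperature, "D": spec.com_diffusion,
        "tau_intern": spec.internal_friction,
    })


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------

def fit_zif_global(data: ISFSet, spec: ZimmModelSpec,
                   fit_internal_friction: bool = True) -> ZIFFitResult:
    """Simultaneous multi-q weighted fit with (D, τ_intern) free.

    All structural/thermodynamic fields of `spec` are held fixed; only
    the center-of-mass diffusion and the internal-friction time vary.
    χ² is the reduced chi-square over all jointly fitted (q, t) points.
    """
    if len(data) < 2:
        raise FitFailure("global ZIF fit needs at least 2 q values")
    for rec in data:
        if np.all(rec.sigma <= 0):
            raise FitFailure(f"q={rec.q}: uncertainties are required")

    params = lmfit.Parameters()
    params.add("D", value=max(spec.com_diffusion, 1e-3), min=1e-4, max=100.0)
    params.add("tau_intern", value=max(spec.internal_friction, 1.0),
               min=0.0, max=1e4, vary=fit_internal_friction)

    def resid(p):
        trial = replace(spec, internal_friction=p["tau_intern"].value,
                        com_diffusion=p["D"].value)
        chunks = []
        for rec in data:
            model = zimm_isf(rec.q, rec.t, trial)
            chunks.append((model - rec.values) * rec.weights())
        return np.concatenate(chunks)

    out = lmfit.minimize(resid, params, method="least_squares")
    if not out.success:
        trace = {name: par.value for name, par in out.params.items()}
        raise FitFailure(f"global ZIF fit did not converge: {out.message}; "
                         f"last parameters {trace}")

    n_points = sum(len(rec.t) for rec in data)
    n_free = 2 if fit_internal_friction else 1
    chi2 = float(np.sum(out.residual**2) / (n_points - n_free))
    cov = out.covar if out.covar is not None else np.full((2, 2), np.nan)
    per_q = {}
    best = replace(spec, internal_friction=out.params["tau_intern"].value,
                   com_diffusion=out.params["D"].value)
    for rec in data:
        model = zimm_isf(rec.q, rec.t, best)
        per_q[rec.q] = float(np.sqrt(np.mean((model - rec.values) ** 2)))
    return ZIFFitResult(
        com_diffusion=float(out.params["D"].value),
        internal_friction=float(out.params["tau_intern"].value),
        first_zimm_time=first_zimm_time(spec),
        chi2=chi2,
        covariance=cov,
        per_q_rms=per_q,
    )
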