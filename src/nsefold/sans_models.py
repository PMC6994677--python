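"""SANS form-factor models for folded and unfolded protein states.

Two form factors cover the folding series of a small globular protein:

* a *generalized Guinier* law ``I(q) = A exp(-Rg² q² / (3 - α))`` for the
  compact, native-like state (α = 0 recovers the standard Guinier law for
  a spheroid);
* the *polymer-with-excluded-volume* form factor for partially and fully
  unfolded states, parameterized by the radius of gyration Rg and the
  Flory (excluded-volume) exponent ν.  Its high-q power law ``P ~ q^(-1/ν)``
  connects ν to the Porod exponent m through ν = 1/m, and ν = 1/2 recovers
  the closed-form Debye function of a Gaussian chain.

Derived chain quantities follow from the standard excluded-volume
relations ``Rg² = l² N^(2ν) / [(2ν+1)(2ν+2)]`` (Kuhn length l, N beads)
and ``R_E = sqrt((2ν+1)(2ν+2)) · Rg`` (end-to-end distance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.special import gammainc, gamma as gamma_fn
import lmfit

from .constants import N_AVOGADRO, ANGSTROM3_IN_LITRE, NM_TO_A

__all__ = [
    "ScatteringCurve",
    "GuinierFit",
    "PolymerChainParams",
    "CompactnessReport",
    "eval_generalized_guinier",
    "eval_excluded_volume_form_factor",
    "debye_function",
    "fit_form_factor",
    "nu_from_porod",
    "kuhn_length",
    "radius_of_gyration_from_kuhn",
    "end_to_end",
    "compactness",
    "overlap_concentration",
    "extrapolate_infinite_dilution",
    "kratky_transform",
    "read_sans",
    "write_sans",
]

#: Upper bound of the Guinier validity window, q_max · Rg.
GUINIER_QRG_MAX = 1.3

SPHERE_LIMIT = np.sqrt(5.0 / 3.0)  # R_H/Rg of a solid sphere, 1.29
RANDOM_COIL = 0.65                 # R_H/Rg of a random coil


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ScatteringCurve:
    """One 1-D SANS intensity profile I(q) with 1-σ uncertainties.

    q is in 1/Å, strictly increasing and positive; intensity and sigma are
    in the same (arbitrary) units; concentration in mg/mL, temperature in K.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    concentration: float = np.nan
    temperature: float = np.nan
    label: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or len(self.q) == 0:
            raise ValueError("q must be a non-empty 1-D array")
        if not (len(self.q) == len(self.intensity) == len(self.sigma)):
            raise ValueError("q, intensity and sigma must have equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be positive and strictly increasing")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")

    def __len__(self):
        return len(self.q)

    def fit_weights(self) -> np.ndarray:
        """1/σ² weights; zero σ entries get the median σ of the curve."""
        s = self.sigma.copy()
        bad = s <= 0
        if bad.all():
            s[:] = 1.0
        elif bad.any():
            s[bad] = np.median(s[~bad])
        return 1.0 / s**2


@dataclass
class GuinierFit:
    amplitude: float
    radius_of_gyration: float
    shape_parameter: float
    valid_qmax: float
    covariance: np.ndarray
    chi2: float = np.nan

    def __post_init__(self):
        if self.radius_of_gyration <= 0:
            raise ValueError("Rg must be positive")
        if not (0.0 <= self.shape_parameter <= 2.0):
            raise ValueError("shape parameter must lie in [0, 2]")


@dataclass
class PolymerChainParams:
    n_beads: int
    flory_exponent: float
    kuhn_length: float
    radius_of_gyration: float
    end_to_end: float
    porod_exponent: float
    amplitude: float = 1.0
    covariance: np.ndarray | None = None
    chi2: float = np.nan

    def __post_init__(self):
        nu = self.flory_exponent
        if not (0.3 <= nu <= 1.0):
            raise ValueError("flory exponent out of [0.3, 1]")
        if abs(nu * self.porod_exponent - 1.0) > 5e-2:
            raise ValueError("porod exponent inconsistent with nu = 1/m")
        expect = end_to_end(self.radius_of_gyration, nu)
        if abs(self.end_to_end - expect) > 1e-6 * max(1.0, expect):
            raise ValueError("end-to-end inconsistent with (Rg, nu)")


@dataclass
class CompactnessReport:
    hydrodynamic_radius: float
    radius_of_gyration: float
    ratio: float
    reference_sphere_limit: float = SPHERE_LIMIT
    reference_random_coil: float = RANDOM_COIL

    def to_dict(self):
        return asdict(self)


class FitFailure(RuntimeError):
    """A least-squares fit failed to converge or was degenerate."""


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def eval_generalized_guinier(q, amplitude, rg, alpha=0.0):
    """Generalized Guinier intensity A·exp(-Rg² q² / (3-α)).

    α = 0 is the standard Guinier law for a globular particle; α = 1 and 2
    describe rod- and plate-like scatterers.
    """
    if alpha >= 3:
        raise ValueError("shape parameter alpha must be < 3")
    if rg <= 0:
        raise ValueError("Rg must be positive")
    q = np.asarray(q, dtype=float)
    return amplitude * np.exp(-(rg**2) * q**2 / (3.0 - alpha))


def debye_function(x):
    """Debye form factor of a Gaussian chain, x = q²Rg².  P = 2(e⁻ˣ+x-1)/x²."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x > 1e-12
    out[nz] = 2.0 * (np.expm1(-x[nz]) + x[nz]) / x[nz] ** 2
    return out


def eval_excluded_volume_form_factor(q, rg, nu):
    """Form factor of a polymer with excluded-volume statistics, P(0) = 1.

    Uses the two-term lower-incomplete-gamma expression with
    U = q²Rg²(2ν+1)(2ν+2)/6:

        P = γ(1/(2ν), U) / (ν U^(1/(2ν))) - γ(1/ν, U) / (ν U^(1/ν))

    which reduces to the Debye function at ν = 1/2 and decays as
    q^(-1/ν) at large qRg.
    """
    if rg <= 0:
        raise ValueError("Rg must be positive")
    if not (0.3 <= nu <= 1.0):
        raise ValueError("flory exponent must lie in [0.3, 1]")
    q = np.asarray(q, dtype=float)
    u = q**2 * rg**2 * (2 * nu + 1) * (2 * nu + 2) / 6.0
    a1, a2 = 1.0 / (2 * nu), 1.0 / nu
    out = np.ones_like(u)
    nz = u > 1e-10
    un = u[nz]
    # gammainc is the regularized lower incomplete gamma P(a, x)
    g1 = gammainc(a1, un) * gamma_fn(a1)
    g2 = gammainc(a2, un) * gamma_fn(a2)
    out[nz] = g1 / (nu * un**a1) - g2 / (nu * un**a2)
    return out


# ---------------------------------------------------------------------------
# derived chain quantities
# ---------------------------------------------------------------------------

def nu_from_porod(m):
    """Flory exponent from the Porod (high-q power-law) exponent, ν = 1/m."""
    if np.any(np.asarray(m) <= 0):
        raise ValueError("Porod exponent must be positive")
    return 1.0 / np.asarray(m)


def kuhn_length(rg, nu, n_beads):
    """Kuhn length l = Rg·sqrt((2ν+1)(2ν+2)) / N^ν for an N-bead chain."""
    if rg <= 0:
        raise ValueError("Rg must be positive")
    if n_beads < 1:
        raise ValueError("need at least one bead")
    return rg * np.sqrt((2 * nu + 1) * (2 * nu + 2)) / n_beads**nu


def radius_of_gyration_from_kuhn(l, nu, n_beads):
    """Inverse of :func:`kuhn_length`: Rg from (l, ν, N)."""
    return l * n_beads**nu / np.sqrt((2 * nu + 1) * (2 * nu + 2))


def end_to_end(rg, nu):
    """End-to-end distance R_E = sqrt((2ν+1)(2ν+2))·Rg."""
    if rg <= 0:
        raise ValueError("Rg must be positive")
    return np.sqrt((2 * nu + 1) * (2 * nu + 2)) * rg


def compactness(r_h, rg):
    """Compactness ratio R_H/Rg with the solid-sphere (1.29) and
    random-coil (0.65) reference values attached."""
    if r_h <= 0 or rg <= 0:
        raise ValueError("radii must be positive")
    return CompactnessReport(r_h, rg, r_h / rg)


def overlap_concentration(molar_mass, rg):
    """Overlap concentration c* = M / (N_A · 4πRg³/3) in g/L, Rg in Å.

    Below c* chain coils do not interpenetrate and the solution is dilute.
    """
    if molar_mass <= 0 or rg <= 0:
        raise ValueError("molar mass and Rg must be positive")
    volume_litre = (4.0 * np.pi / 3.0) * rg**3 * ANGSTROM3_IN_LITRE
    return molar_mass / (N_AVOGADRO * volume_litre)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _weighted_residual(model, curve, mask):
    w = np.sqrt(curve.fit_weights()[mask])

    def resid(params):
        return (model(curve.q[mask], params) - curve.intensity[mask]) * w

    return resid


def fit_form_factor(curve: ScatteringCurve, model: str = "excluded_volume",
                    q_window: tuple[float, float] | None = None,
                    n_beads: int = 20, alpha: float | None = None):
    """Weighted least-squares form-factor fit.

    model "guinier": fits (A, Rg) at fixed α (default 0); the fit window is
    iteratively shrunk until q_max·Rg ≤ 1.3 (at most 10 iterations).
    model "excluded_volume": fits (A, Rg, ν); returns a
    :class:`PolymerChainParams` with the Kuhn length computed for `n_beads`.
    """
    if q_window is not None:
        mask = (curve.q >= q_window[0]) & (curve.q <= q_window[1])
    else:
        mask = np.ones_like(curve.q, dtype=bool)
    if mask.sum() < 5:
        raise FitFailure("need at least 5 points in the fit window")

    if model == "guinier":
        return _fit_guinier(curve, mask, 0.0 if alpha is None else alpha)
    if model == "excluded_volume":
        return _fit_excluded_volume(curve, mask, n_beads)
    raise ValueError(f"unknown model {model!r}")


def _guess_rg(curve, mask):
    """Crude Guinier-slope starting value from the lowest-q points."""
    q, i = curve.q[mask], np.clip(curve.intensity[mask], 1e-300, None)
    k = max(5, len(q) // 4)
    slope = np.polyfit(q[:k] ** 2, np.log(i[:k]), 1)[0]
    if not np.isfinite(slope) or slope >= 0:
        return np.nan
    return float(np.sqrt(-3.0 * slope))


def _fit_guinier(curve, mask, alpha):
    rg0 = _guess_rg(curve, mask)
    if not np.isfinite(rg0) or rg0 < 1e-3:
        raise FitFailure("curve has no Guinier decay (flat or rising)")

    params = lmfit.Parameters()
    params.add("amplitude", value=float(curve.intensity[mask][0]), min=0)
    params.add("rg", value=rg0, min=1e-3)

    def model(q, p):
        return eval_generalized_guinier(q, p["amplitude"], p["rg"], alpha)

    out = None
    for _ in range(10):
        if mask.sum() < 5:
            raise FitFailure("Guinier window shrank below 5 points")
        out = lmfit.minimize(_weighted_residual(model, curve, mask), params)
        if not out.success:
            raise FitFailure(f"Guinier fit failed: {out.message}")
        rg = out.params["rg"].value
        qmax = curve.q[mask][-1]
        if qmax * rg <= GUINIER_QRG_MAX:
            break
        mask = mask & (curve.q <= GUINIER_QRG_MAX / rg)
        params = out.params
    rg = out.params["rg"].value
    if rg < 1e-2:
        raise FitFailure("fitted Rg is degenerate (flat curve)")
    cov = out.covar if out.covar is not None else np.full((2, 2), np.nan)
    return GuinierFit(
        amplitude=out.params["amplitude"].value,
        radius_of_gyration=rg,
        shape_parameter=alpha,
        valid_qmax=float(curve.q[mask][-1]),
        covariance=cov,
        chi2=out.redchi,
    )


def _fit_excluded_volume(curve, mask, n_beads):
    rg0 = _guess_rg(curve, mask)
    if not np.isfinite(rg0):
        rg0 = 2.0 / curve.q[mask][len(curve.q[mask]) // 2]

    params = lmfit.Parameters()
    params.add("amplitude", value=float(curve.intensity[mask][0]), min=0)
    params.add("rg", value=rg0, min=1.0)
    params.add("nu", value=0.55, min=0.3, max=1.0)

    def model(q, p):
        return p["amplitude"] * eval_excluded_volume_form_factor(
            q, p["rg"], p["nu"])

    out = lmfit.minimize(_weighted_residual(model, curve, mask), params)
    if not out.success:
        raise FitFailure(f"excluded-volume fit failed: {out.message}")
    rg, nu = out.params["rg"].value, out.params["nu"].value
    cov = out.covar if out.covar is not None else np.full((3, 3), np.nan)
    return PolymerChainParams(
        n_beads=n_beads,
        flory_exponent=nu,
        kuhn_length=kuhn_length(rg, nu, n_beads),
        radius_of_gyration=rg,
        end_to_end=end_to_end(rg, nu),
        porod_exponent=1.0 / nu,
        amplitude=out.params["amplitude"].value,
        covariance=cov,
        chi2=out.redchi,
    )


# ---------------------------------------------------------------------------
# curve manipulation
# ---------------------------------------------------------------------------

def interpolate_curve(curve: ScatteringCurve, q: np.ndarray) -> ScatteringCurve:
    """Linear interpolation of (I, σ) onto a new q grid (within support)."""
    q = np.asarray(q, dtype=float)
    if q[0] < curve.q[0] - 1e-12 or q[-1] > curve.q[-1] + 1e-12:
        raise ValueError("requested q grid extends beyond the curve support")
    return ScatteringCurve(
        q=q,
        intensity=np.interp(q, curve.q, curve.intensity),
        sigma=np.interp(q, curve.q, curve.sigma),
        concentration=curve.concentration,
        temperature=curve.temperature,
        label=curve.label,
    )


def extrapolate_infinite_dilution(curves: list[ScatteringCurve],
                                  q: np.ndarray | None = None) -> ScatteringCurve:
    """Zero-concentration form factor from a dilution series.

    For every q, I/c is fitted linearly in c (weighted by the propagated
    uncertainties of I/c) and the intercept is the form factor per unit
    mass.  With a single input curve the scaled curve is passed through
    with a warning attached to its label.
    """
    if len(curves) == 0:
        raise ValueError("no curves given")
    if any(not np.isfinite(c.concentration) or c.concentration <= 0
           for c in curves):
        raise ValueError("every curve needs a positive concentration")
    if len(curves) == 1:
        c = curves[0]
        import warnings
        warnings.warn("single concentration: returning I/c without "
                      "extrapolation", stacklevel=2)
        return ScatteringCurve(c.q, c.intensity / c.concentration,
                               c.sigma / c.concentration,
                               concentration=0.0, temperature=c.temperature,
                               label=c.label + " (single-c passthrough)")

    if q is None:
        qlo = max(c.q[0] for c in curves)
        qhi = min(c.q[-1] for c in curves)
        base = min(curves, key=len)
        q = base.q[(base.q >= qlo) & (base.q <= qhi)]
    interp = [interpolate_curve(c, q) for c in curves]

    conc = np.array([c.concentration for c in interp])
    y = np.stack([c.intensity / c.concentration for c in interp])   # (C, Q)
    sy = np.stack([np.where(c.sigma > 0, c.sigma, np.median(c.sigma[c.sigma > 0])
                            if (c.sigma > 0).any() else 1.0) / c.concentration
                   for c in interp])

    if np.ptp(conc) < 1e-8 * conc.mean():
        # degenerate design (repeated concentration): weighted mean of I/c
        w = 1.0 / sy**2
        mean = (w * y).sum(axis=0) / w.sum(axis=0)
        return ScatteringCurve(q, mean, 1.0 / np.sqrt(w.sum(axis=0)),
                               concentration=0.0,
                               temperature=curves[0].temperature,
                               label="averaged (single concentration level)")

    # weighted linear fit per q: y = intercept + slope*c
    w = 1.0 / sy**2
    sw = w.sum(axis=0)
    swc = (w * conc[:, None]).sum(axis=0)
    swc2 = (w * conc[:, None] ** 2).sum(axis=0)
    swy = (w * y).sum(axis=0)
    swcy = (w * conc[:, None] * y).sum(axis=0)
    delta = sw * swc2 - swc**2
    intercept = (swc2 * swy - swc * swcy) / delta
    var_intercept = swc2 / delta

    return ScatteringCurve(q, intercept, np.sqrt(var_intercept),
                           concentration=0.0,
                           temperature=curves[0].temperature,
                           label="extrapolated to infinite dilution")


def kratky_transform(curve: ScatteringCurve, rg: float, i0: float):
    """Dimensionless Kratky coordinates (x = qRg, y = x² I/I0).

    A Gaussian chain plateaus at y → 2; a globular particle shows a single
    interior maximum.
    """
    if rg <= 0 or i0 <= 0:
        raise ValueError("Rg and I0 must be positive")
    x = curve.q * rg
    return x, x**2 * curve.intensity / i0


# ---------------------------------------------------------------------------
# text-file interface
# ---------------------------------------------------------------------------

def read_sans(path) -> ScatteringCurve:
    """Read a 3-column (q, I, σ) text file.

    '#' comment headers may carry ``key = value`` metadata: concentration
    (mg/mL), temperature (K), label, and ``q_unit`` (``1/A`` default, or
    ``1/nm`` which is converted at parse time).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip().lower()] = val.strip()
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected at least 2 columns")
        rows.append([float(x) for x in parts[:3]] if len(parts) >= 3
                    else [float(parts[0]), float(parts[1]), 0.0])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows)
    q, intensity, sigma = arr[:, 0], arr[:, 1], arr[:, 2]
    unit = meta.get("q_unit", "1/A").lower()
    if unit in ("1/nm", "nm^-1", "nm-1"):
        q = q / NM_TO_A
    elif unit not in ("1/a", "a^-1", "a-1", "1/angstrom"):
        raise ValueError(f"{path}: unknown q unit {unit!r}")
    return ScatteringCurve(
        q=q, intensity=intensity, sigma=sigma,
        concentration=float(meta.get("concentration", "nan")),
        temperature=float(meta.get("temperature", "nan")),
        label=meta.get("label", path.stem),
    )


def write_sans(curve: ScatteringCurve, path) -> None:
    path = Path(path)
    lines = ["# q_unit = 1/A"]
    if np.isfinite(curve.concentration):
        lines.append(f"# concentration = {curve.concentration:g}")
    if np.isfinite(curve.temperature):
        lines.append(f"# temperature = {curve.temperature:g}")
    if curve.label:
        lines.append(f"# label = {curve.label}")
    lines.append("# q  intensity  sigma")
    for qi, ii, si in zip(curve.q, curve.intensity, curve.sigma):
        lines.append(f"{qi:.8g} {ii:.8g} {si:.8g}")
    path.write_text("\n".join(lines) + "\n")


def fit_report_json(fit, path=None) -> str:
    """Serialize a fit result dataclass to a JSON record."""
    d = {}
    for key, val in asdict(fit).items():
        if isinstance(val, np.ndarray):
            d[key] = val.tolist()
        elif isinstance(val, (np.floating, np.integer)):
            d[key] = val.item()
        else:
            d[key] = val
    text = json.dumps(d, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
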