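"""Neutron spin-echo data model and per-q fits.

A spin-echo measurement delivers the normalized intermediate scattering
function S(q,t)/S(q,0) on a grid of Fourier times t (ns) for a handful of
momentum transfers q (1/Å).  Three per-q analyses are provided:

* *initial slope* (cumulant) fit ``A·exp(-D₁t - D₂t²)`` restricted to the
  early decay; D₁/q² is the effective diffusion coefficient in Å²/ns;
* *stretched exponential* (Kohlrausch–Williams–Watts) fit
  ``A·exp(-D'q²t^β)``; the mean stretching exponent β across q
  distinguishes simple diffusion (β ≈ 1) from the broad internal-mode
  spectrum of a flexible chain (Zimm prediction β ≈ 0.85);
* the corrected *effective diffusion* D_eff(q) = (D₁/q²)·S(c,q)/H_{c,q0},
  which removes the interparticle structure factor and the solvent-
  mediated hydrodynamic function from the measured collective decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit

from .sans_models import FitFailure
from .structure_factor import StructureFactorCurve
from .constants import US_TO_NS

__all__ = [
    "ISFSet",
    "QRecord",
    "CumulantFit",
    "StretchedExpFit",
    "EffectiveDiffusionCurve",
    "read_isf",
    "write_isf",
    "fit_initial_slope",
    "fit_stretched_exponential",
    "effective_diffusion",
    "linearity_diagnostic",
]


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class QRecord:
    """Normalized ISF at one momentum transfer."""

    q: float
    t: np.ndarray           # ns, ascending, >= 0
    values: np.ndarray      # S(q,t)/S(q,0)
    sigma: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.t) == len(self.values) == len(self.sigma)):
            raise ValueError("t, values, sigma must have equal length")
        if np.any(self.t < 0) or np.any(np.diff(self.t) <= 0):
            raise ValueError("Fourier times must be non-negative ascending")
        s0 = self.sigma[0] if self.sigma[0] > 0 else 0.0
        if self.values[0] > 1.05 + 3 * s0:
            raise ValueError("ISF at the smallest time exceeds 1.05 beyond 3σ")

    def weights(self):
        s = self.sigma.copy()
        bad = s <= 0
        if bad.all():
            s[:] = 1.0
        elif bad.any():
            s[bad] = np.median(s[~bad])
        return 1.0 / s


@dataclass
class ISFSet:
    """Collection of per-q normalized ISF records with sample metadata."""

    records: list[QRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        qs = [r.q for r in self.records]
        if len(set(qs)) != len(qs):
            raise ValueError("q values must be unique")
        self.records = sorted(self.records, key=lambda r: r.q)

    @property
    def q(self):
        return np.array([r.q for r in self.records])

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class CumulantFit:
    """Per-q initial-slope parameters of A·exp(-D₁t - D₂t²).

    D1 is in 1/ns as fitted; D1/q² (Å²/ns) is the diffusion-coefficient
    reading used downstream.
    """

    q: np.ndarray
    amplitude: np.ndarray
    D1: np.ndarray              # 1/ns
    D1_err: np.ndarray
    D2: np.ndarray              # 1/ns²
    window_fraction: float
    unphysical: np.ndarray      # flags D1 < 0

    def diffusion(self):
        """D₁/q² in Å²/ns, with propagated uncertainty."""
        return self.D1 / self.q**2, self.D1_err / self.q**2


@dataclass
class StretchedExpFit:
    """Per-q Kohlrausch fit A·exp(-D'q²t^β); D' units depend on β."""

    q: np.ndarray
    amplitude: np.ndarray
    rate_coefficient: np.ndarray
    stretching_exponent: np.ndarray
    beta_err: np.ndarray
    at_bounds: np.ndarray

    @property
    def mean_beta(self):
        """Unweighted arithmetic mean of β across q."""
        return float(np.mean(self.stretching_exponent))


@dataclass
class EffectiveDiffusionCurve:
    q: np.ndarray
    D_eff: np.ndarray           # Å²/ns
    sigma: np.ndarray

    def __post_init__(self):
        if np.any(self.D_eff <= 0):
            raise ValueError("effective diffusion must be positive")


# ---------------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------------

def read_isf(path) -> ISFSet:
    """Read a normalized-ISF text file.

    Dialect A (blocks): '#' headers with ``key = value`` metadata, then
    per-q blocks introduced by a line ``q = <value>`` followed by rows
    ``t  S/S0  sigma``.  Dialect B (flat): 4 columns ``q t S/S0 sigma``.
    Header ``t_unit`` may be ``ns`` (default) or ``us``.  A missing σ
    column is filled with a 2% constant relative error (with a warning).
    """
    import warnings
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    blocks: dict[float, list[list[float]]] = {}
    current_q = None
    flat = None
    missing_sigma = False
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip().lower()] = val.strip()
            continue
        if line.lower().startswith("q") and "=" in line:
            current_q = float(line.partition("=")[2])
            blocks.setdefault(current_q, [])
            flat = False
            continue
        parts = line.split()
        try:
            nums = [float(x) for x in parts]
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: malformed row {line!r}") from exc
        if flat is None:
            flat = current_q is None
        if flat:
            if len(nums) == 3:
                nums.append(np.nan)
                missing_sigma = True
            if len(nums) != 4:
                raise ValueError(f"{path}:{ln}: flat dialect needs 4 columns")
            blocks.setdefault(nums[0], []).append(nums[1:])
        else:
            if current_q is None:
                raise ValueError(f"{path}:{ln}: data before any 'q =' line")
            if len(nums) == 2:
                nums.append(np.nan)
                missing_sigma = True
            blocks[current_q].append(nums[:3])
    if not blocks or all(len(v) == 0 for v in blocks.values()):
        raise ValueError(f"{path}: no ISF data found")
    if missing_sigma:
        warnings.warn("missing sigma column: filled with 2% relative error",
                      stacklevel=2)

    tscale = 1.0
    unit = meta.get("t_unit", "ns").lower()
    if unit in ("us", "µs", "mus"):
        tscale = US_TO_NS
    elif unit != "ns":
        raise ValueError(f"unknown time unit {unit!r}")

    records = []
    for qval, rows in sorted(blocks.items()):
        arr = np.asarray(rows, dtype=float)
        t, v, s = arr[:, 0] * tscale, arr[:, 1], arr[:, 2]
        s = np.where(np.isnan(s), 0.02 * np.abs(v), s)
        order = np.argsort(t)
        if np.any(np.diff(t[order]) <= 0):
            raise ValueError(f"{path}: duplicate Fourier times at q={qval}")
        records.append(QRecord(qval, t[order], v[order], s[order]))
    return ISFSet(records, metadata=dict(meta))


def write_isf(isf: ISFSet, path) -> None:
    from pathlib import Path

    lines = [f"# {k} = {v}" for k, v in isf.metadata.items()]
    if "t_unit" not in isf.metadata:
        lines.append("# t_unit = ns")
    for rec in isf:
        lines.append(f"q = {rec.q:.6g}")
        for t, v, s in zip(rec.t, rec.values, rec.sigma):
            lines.append(f"{t:.8g} {v:.8g} {s:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def _per_q_fit(rec, model, params):
    w = rec.weights()

    def resid(p):
        return (model(rec.t, p) - rec.values) * w

    out = lmfit.minimize(resid, params)
    if not out.success:
        raise FitFailure(f"fit failed at q={rec.q}: {out.message}")
    return out


def fit_initial_slope(isf: ISFSet, decay_window_fraction: float = 0.4
                      ) -> CumulantFit:
    """Weighted per-q fit of A·exp(-D₁t - D₂t²) over the initial decay.

    The fit window keeps times where the signal is above
    `decay_window_fraction` of its t→0 amplitude, so that the quadratic
    term remains a small correction.  A negative fitted D₁ is flagged as
    unphysical rather than raised.
    """
    qs, amps, d1s, d1e, d2s, flags = [], [], [], [], [], []
    for rec in isf:
        mask = rec.values >= decay_window_fraction * rec.values[0]
        if mask.sum() < 5:
            mask = np.zeros_like(mask)
            mask[:5] = True       # fall back to the 5 earliest times
        sub = QRecord(rec.q, rec.t[mask], rec.values[mask], rec.sigma[mask])

        span = max(sub.t[-1], 1e-9)
        params = lmfit.Parameters()
        params.add("A", value=1.0, min=0.8, max=1.2)
        params.add("D1", value=1.0 / span, min=-10.0 / span)
        params.add("D2", value=0.0)

        def model(t, p):
            return p["A"] * np.exp(-p["D1"] * t - p["D2"] * t**2)

        out = _per_q_fit(sub, model, params)
        qs.append(rec.q)
        amps.append(out.params["A"].value)
        d1s.append(out.params["D1"].value)
        err = out.params["D1"].stderr
        d1e.append(err if err is not None else np.nan)
        d2s.append(out.params["D2"].value)
        flags.append(out.params["D1"].value < 0)
    return CumulantFit(np.array(qs), np.array(amps), np.array(d1s),
                       np.array(d1e), np.array(d2s),
                       decay_window_fraction, np.array(flags))


def fit_stretched_exponential(isf: ISFSet,
                              beta_bounds=(0.3, 1.2),
                              beta_init: float = 0.85) -> StretchedExpFit:
    """Weighted per-q Kohlrausch fit A·exp(-D'q²t^β).

    β is bounded to `beta_bounds`; a β pinned at either bound is flagged.
    The across-q mean β is exposed as ``result.mean_beta``.
    """
    qs, amps, rates, betas, berr, pinned = [], [], [], [], [], []
    for rec in isf:
        if len(rec.t) < 6:
            raise FitFailure(f"q={rec.q}: need at least 6 points")
        tpos = rec.t[rec.t > 0]
        t_ref = tpos[len(tpos) // 2] if len(tpos) else 1.0
        v_ref = np.interp(t_ref, rec.t, rec.values)
        rate0 = max(-np.log(max(v_ref, 1e-6)) / (rec.q**2 * t_ref**beta_init),
                    1e-6)
        params = lmfit.Parameters()
        params.add("A", value=1.0, min=0.8, max=1.2)
        params.add("Dp", value=rate0, min=0.0)
        params.add("beta", value=beta_init, min=beta_bounds[0],
                   max=beta_bounds[1])

        def model(t, p):
            arg = p["Dp"] * rec.q**2 * np.power(np.clip(t, 0, None),
                                                p["beta"])
            return p["A"] * np.exp(-np.clip(arg, 0.0, 500.0))

        out = _per_q_fit(rec, model, params)
        b = out.params["beta"].value
        qs.append(rec.q)
        amps.append(out.params["A"].value)
        rates.append(out.params["Dp"].value)
        betas.append(b)
        err = out.params["beta"].stderr
        berr.append(err if err is not None else np.nan)
        pinned.append(min(b - beta_bounds[0], beta_bounds[1] - b) < 1e-4)
    return StretchedExpFit(np.array(qs), np.array(amps), np.array(rates),
                           np.array(betas), np.array(berr),
                           np.array(pinned))


def effective_diffusion(cumulants: CumulantFit,
                        s_cq: StructureFactorCurve | None = None,
                        h_q0: float = 1.0) -> EffectiveDiffusionCurve:
    """Corrected effective diffusion D_eff(q) = (D₁/q²)·S(c,q)/H_{c,q0}.

    With no structure factor given, S ≡ 1 (dilute limit).  Uncertainties
    propagate from the D₁ standard errors (S and H enter as exact
    factors).
    """
    if h_q0 <= 0:
        raise ValueError("hydrodynamic function must be positive")
    d, derr = cumulants.diffusion()
    s = s_cq.interp(cumulants.q) if s_cq is not None else np.ones_like(d)
    deff = d * s / h_q0
    sigma = np.abs(derr) * s / h_q0
    return EffectiveDiffusionCurve(cumulants.q, deff, sigma)


def linearity_diagnostic(curve: EffectiveDiffusionCurve):
    """OLS of D_eff on q: returns (slope, intercept, R²).

    A positive slope with R² close to 1 is the signature of the Zimm
    regime of local chain relaxations; a flat curve indicates simple
    center-of-mass diffusion.
    """
    if len(curve.q) < 4:
        raise ValueError("need at least 4 points")
    slope, intercept = np.polyfit(curve.q, curve.D_eff, 1)
    pred = slope * curve.q + intercept
    ss_res = np.sum((curve.D_eff - pred) ** 2)
    ss_tot = np.sum((curve.D_eff - curve.D_eff.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)
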