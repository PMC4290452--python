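"""Analytic scaling models for spindle mechanics.

- Maximal-midzone-overlap (MMO) microtubule number N = 2 L_T / (L_s + L_m).
- Power-law fits F_c = A·L^p (free or fixed exponent), log-log least squares.
- Conserved-volume cylinder scaling EI ∝ r_c⁴ ∝ L^−2.
- Reinforced-rod buckling closed forms f_c = 8π²EI/λ², λ = 2π(EI/α)^{1/4}
  (equivalently f_c = 2√(EI·α)).
- Null-model exceedance probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PowerLawFit:
    """F = A·L^p fitted in log-log space."""

    prefactor: float
    exponent: float
    mode: str  # "free-exponent" | "fixed-exponent"
    residual: float

    def predict(self, L):
        return self.prefactor * np.asarray(L, dtype=float) ** self.exponent


def n_mmo(L_T: float, L_s, L_m: float = 2.5):
    """Continuous MMO microtubule number 2 L_T / (L_s + L_m)."""
    L_s = np.asarray(L_s, dtype=float)
    if np.any(L_s + L_m <= 0):
        raise ValueError("require L_s + L_m > 0")
    out = 2.0 * L_T / (L_s + L_m)
    return float(out) if out.ndim == 0 else out


def n_mmo_rounded(L_T: float, L_s, L_m: float = 2.5):
    """Rounded companion of :func:`n_mmo`, for discrete architectures."""
    return np.round(n_mmo(L_T, L_s, L_m)).astype(int)


def fit_power_law(L, F, fixed_exponent: float | None = None) -> PowerLawFit:
    """Least-squares power-law fit in log-log space.

    With *fixed_exponent* only the prefactor A is fitted (as in fits where
    the exponent is imposed by theory).
    """
    L = np.asarray(L, dtype=float)
    F = np.asarray(F, dtype=float)
    if len(L) < 2 or len(L) != len(F):
        raise ValueError("need >= 2 matched (L, F) points")
    if np.any(L <= 0) or np.any(F <= 0):
        raise ValueError("power-law fit requires positive data")
    logl, logf = np.log(L), np.log(F)
    if fixed_exponent is None:
        p, a = np.polyfit(logl, logf, 1)
        mode = "free-exponent"
    else:
        p = float(fixed_exponent)
        a = np.mean(logf - p * logl)
        mode = "fixed-exponent"
    resid = float(np.sum((logf - (a + p * logl)) ** 2))
    return PowerLawFit(prefactor=float(np.exp(a)), exponent=float(p), mode=mode, residual=resid)


def cylinder_radius(V: float, L: float) -> float:
    """Radius of the solid cylinder of volume V and length L: √(V/(πL))."""
    if V <= 0 or L <= 0:
        raise ValueError("require positive volume and length")
    return float(np.sqrt(V / (np.pi * L)))


def cylinder_scaling(V: float, L) -> np.ndarray:
    """Relative transverse stiffness of a conserved-volume cylinder.

    EI ∝ r_c⁴ with r_c = √(V/(πL)), hence EI ∝ L^−2.  Returned in units
    where a cylinder of unit radius has stiffness 1.
    """
    L = np.asarray(L, dtype=float)
    if V <= 0 or np.any(L <= 0):
        raise ValueError("require positive volume and length")
    r_c = np.sqrt(V / (np.pi * L))
    out = r_c**4
    return float(out) if out.ndim == 0 else out


def reinforced_critical_force(EI: float, alpha: float) -> tuple[float, float]:
    """Critical force and buckling wavelength of an elastically confined rod.

    λ = 2π(EI/α)^{1/4} and f_c = 8π²EI/λ² = 2√(EI·α).  EI in pN·μm²,
    α in Pa (pN·μm⁻²); returns (f_c pN, λ μm).
    """
    if EI <= 0:
        raise ValueError("require EI > 0")
    if alpha <= 0:
        raise ValueError("α must be positive (α = 0 falls back to the Euler "
                         "formula, which needs an explicit length)")
    lam = 2.0 * np.pi * (EI / alpha) ** 0.25
    f_c = 8.0 * np.pi**2 * EI / lam**2
    return float(f_c), float(lam)


def euler_force(EI: float, L: float) -> float:
    """Euler critical force π²EI/L² of a hinged prismatic beam."""
    if EI <= 0 or L <= 0:
        raise ValueError("require positive EI and L")
    return float(np.pi**2 * EI / L**2)


def null_comparison(wt_median: float, null_samples) -> float:
    """Fraction of null-model samples strictly exceeding the wild-type median."""
    null_samples = np.asarray(null_samples, dtype=float)
    if len(null_samples) == 0:
        raise ValueError("need at least one null sample")
    return float(np.mean(null_samples > wt_median))
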