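"""Cellular bookkeeping: tubulin budget and forces resisting spindle elongation.

The fission yeast cell is a sphero-cylinder of radius R_c ≈ 1.6 μm and length
L_c ≈ 14.3 μm.  Tubulin accounting converts polymerised microtubule length to
dimer counts (13 protofilaments, one 8-nm dimer layer per protofilament) and
to concentrations, using the relative spindle fluorescence intensity to scale
the polymerized pool up to the total cellular pool.

Drag on a daughter nucleus squeezed inside the cell wall greatly exceeds the
Stokes estimate; it is modelled as γ = (9π²/(2√2))·η·r_nucleus/ε^(5/2) with
clearance ε = (r_cell − r_nucleus)/r_nucleus.  (The source expression is
typographically corrupted; this reconstruction reproduces the published
25–110 pN·s·μm⁻¹ range and is a named, swappable strategy.)  Spindle-ablation
relaxation x(t) = x0·e^(−t/τ) yields the elastic (F_e = x0·γ/τ) and drag
(F_v = γ·v_s/2) forces opposing elongation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

#: Dimers per μM per μm³ (Avogadro's number scaled: 602.214 dimers·μm⁻³·μM⁻¹).
DIMERS_PER_UM3_PER_UM = 602.214

#: Tubulin dimer axial spacing (nm) and protofilament count of one microtubule.
DIMER_LENGTH_NM = 8.0
N_PROTOFILAMENTS = 13

#: Drag-formula prefactor 9π²/(2√2); see module docstring.
DRAG_PREFACTOR = 9.0 * np.pi**2 / (2.0 * np.sqrt(2.0))


@dataclass
class CellGeometry:
    """Fission yeast cell geometry and transport parameters."""

    R_c: float = 1.6          # cell radius, μm
    L_c: float = 14.3         # cell length at mitotic entry, μm
    r_cell: float = 1.6       # radius used in the drag estimate, μm
    r_nucleus: float = 0.9    # daughter nucleus radius, μm (range 0.8-1.0)
    eta_cell: float = 1.0     # cytoplasmic viscosity, pN·s·μm⁻²

    @property
    def volume(self) -> float:
        return cell_volume(self.R_c, self.L_c)

    @property
    def clearance(self) -> float:
        """ε = (r_cell − r_nucleus)/r_nucleus."""
        return (self.r_cell - self.r_nucleus) / self.r_nucleus


@dataclass
class RelaxationFit:
    """Exponential relaxation x(t) = x0·e^(−t/τ) with transport parameters."""

    x_0: float                # initial displacement, μm
    tau: float                # relaxation time τ = γ/k, s
    gamma: float | None = None  # drag, pN·s·μm⁻¹
    v_s: float | None = None    # spindle elongation speed, μm·min⁻¹

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("relaxation time must be positive")

    @property
    def spring_constant(self) -> float | None:
        """k = γ/τ, pN·μm⁻¹."""
        return None if self.gamma is None else self.gamma / self.tau

    def predict(self, t):
        return self.x_0 * np.exp(-np.asarray(t, dtype=float) / self.tau)


def cell_volume(R_c: float, L_c: float) -> float:
    """Sphero-cylinder volume V_c = 2πR_c³(L_c/(2R_c) − 1/3), μm³.

    Reduces to the sphere volume at L_c = 2R_c.
    """
    if R_c <= 0 or L_c <= 2.0 * R_c / 3.0:
        raise ValueError("nonphysical cell dimensions")
    return float(2.0 * np.pi * R_c**3 * (L_c / (2.0 * R_c) - 1.0 / 3.0))


def polymer_to_dimers(L_um: float) -> float:
    """Tubulin dimer count in L μm of microtubule polymer (13 pf × 8 nm)."""
    if L_um < 0:
        raise ValueError("polymer length must be >= 0")
    return L_um * 1000.0 / DIMER_LENGTH_NM * N_PROTOFILAMENTS


def concentrations(
    dimers_polymerized: float,
    V_c: float,
    relative_intensity: float | None = 0.16,
) -> dict:
    """Polymerized, free and total tubulin concentrations (μM).

    The relative spindle intensity is interpreted as the fraction of cellular
    tubulin polymerised in the spindle, so total = polymerized / intensity
    and free = total − polymerized.  The returned dict logs the chain,
    including the (not internally consistent) total-abundance candidates.
    """
    if V_c <= 0:
        raise ValueError("cell volume must be positive")
    polymerized = dimers_polymerized / (V_c * DIMERS_PER_UM3_PER_UM)
    out = {
        "polymerized_uM": float(polymerized),
        "chain": [
            f"polymerized = {dimers_polymerized:.1f} dimers / "
            f"({V_c:.1f} um3 x {DIMERS_PER_UM3_PER_UM} dimers/um3/uM)"
        ],
    }
    if relative_intensity is not None:
        if not 0 < relative_intensity <= 1:
            raise ValueError("relative intensity must lie in (0, 1]")
        total = polymerized / relative_intensity
        out["total_uM"] = float(total)
        out["free_uM"] = float(total - polymerized)
        out["chain"].append(f"total = polymerized / {relative_intensity}")
        out["chain"].append("free = total - polymerized")
        # two candidate whole-cell abundance chains (they disagree; both logged)
        out["abundance_from_total"] = float(total * V_c * DIMERS_PER_UM3_PER_UM)
        out["abundance_from_polymer"] = float(dimers_polymerized / relative_intensity)
    return out


def nucleus_drag(eta: float, r_cell: float, r_nucleus: float) -> float:
    """Translational drag γ (pN·s·μm⁻¹) of a nucleus in a narrow cell.

    γ = (9π²/(2√2))·η·r_nucleus/ε^(5/2), ε = (r_cell − r_nucleus)/r_nucleus.
    """
    if not 0 < r_nucleus < r_cell:
        raise ValueError("require 0 < r_nucleus < r_cell")
    eps = (r_cell - r_nucleus) / r_nucleus
    return float(DRAG_PREFACTOR * eta * r_nucleus / eps**2.5)


def relaxation_fit(t, x, gamma: float | None = None, v_s: float | None = None) -> RelaxationFit:
    """Fit x(t) = x0·e^(−t/τ) to displacement data.

    Log-linear least squares when all displacements are positive (exact on
    noiseless exponentials); otherwise nonlinear least squares.  Non-decaying
    data draws a warning but still returns the best fit.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(t) < 3 or len(t) != len(x):
        raise ValueError("need >= 3 matched (t, x) points")
    if x[-1] > x[0]:
        import warnings

        warnings.warn("displacement data do not decay; fit may be unreliable", stacklevel=2)
    if np.all(x > 0):
        slope, intercept = np.polyfit(t, np.log(x), 1)
        x0 = float(np.exp(intercept))
        tau = float(-1.0 / slope) if slope < 0 else np.inf
        if np.isfinite(tau):
            return RelaxationFit(x_0=x0, tau=tau, gamma=gamma, v_s=v_s)
    popt, _ = curve_fit(lambda tt, a, b: a * np.exp(-tt / b), t, x,
                        p0=(x[0] if x[0] != 0 else 1.0, max(t[-1] / 2, 1e-6)))
    return RelaxationFit(x_0=float(popt[0]), tau=float(abs(popt[1])), gamma=gamma, v_s=v_s)


def force_estimates(fit: RelaxationFit) -> dict:
    """Drag, elastic and total forces resisting elongation (pN).

    F_v = γ·v_s/2 (v_s converted from μm·min⁻¹ to μm·s⁻¹ here),
    F_e = x0·γ/τ, total = F_v + F_e.
    """
    if fit.gamma is None or fit.v_s is None:
        raise ValueError("fit must carry gamma and v_s")
    v_s_um_per_s = fit.v_s / 60.0
    f_v = fit.gamma * v_s_um_per_s / 2.0
    f_e = fit.x_0 * fit.gamma / fit.tau
    return {
        "F_v_pN": float(f_v),
        "F_e_pN": float(f_e),
        "total_pN": float(f_v + f_e),
        "chain": [f"v_s = {fit.v_s} um/min = {v_s_um_per_s:.5f} um/s",
                  "F_v = gamma*v_s/2", "F_e = x0*gamma/tau"],
    }


def tubulin_budget_report(
    L_T: float = 27.1,
    R_c: float = 1.6,
    L_c: float = 14.3,
    relative_intensity: float = 0.16,
) -> dict:
    """Full tubulin-budget recomputation (volume, dimers, concentrations)."""
    v_c = cell_volume(R_c, L_c)
    dimers = polymer_to_dimers(L_T)
    conc = concentrations(dimers, v_c, relative_intensity)
    return {"V_c_um3": v_c, "dimers_polymerized": dimers, **conc}


def force_report(
    r_nucleus_range=(0.8, 1.0),
    r_cell: float = 1.6,
    eta: float = 1.0,
    v_s: float = 0.9,
    x_0: float = 1.4,
    tau: float = 9.7,
) -> dict:
    """Drag/elastic/total force estimates over the nucleus-radius range."""
    out = {"r_nucleus_um": list(r_nucleus_range)}
    for key, r_n in zip(("lo", "hi"), r_nucleus_range):
        gamma = nucleus_drag(eta, r_cell, r_n)
        fit = RelaxationFit(x_0=x_0, tau=tau, gamma=gamma, v_s=v_s)
        est = force_estimates(fit)
        out[key] = {"gamma_pN_s_per_um": gamma, **{k: v for k, v in est.items() if k != "chain"}}
    return out
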