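"""Area moment of inertia tensors for cross-linked microtubule bundles.

Each microtubule is a uniform hollow cylinder (inner radius r1 = 7.5 nm,
outer radius r2 = 12.5 nm).  Its contribution to the bundle moment about the
neutral axis (the centroid of the microtubule centres) is y²·A_MT + I_MT,
where A_MT = π(r2² − r1²) is the annulus area and I_MT = (π/4)(r2⁴ − r1⁴)
the single-microtubule moment.  Summing over microtubules gives

    I_xx = N·I_MT + A_MT Σ (y_i − ȳ)²
    I_yy = N·I_MT + A_MT Σ (x_i − x̄)²
    I_xy = −A_MT Σ (x_i − x̄)(y_i − ȳ)

The 2×2 tensor's eigenvalues I_min ≤ I_max set the most compliant and
stiffest bending directions; their ratio is the bundle anisotropy.  Stiffness
is reported in MT units (multiples of I_MT) and converted to physical
flexural rigidity via EI_MT = 20 pN·μm².

Cross-linkers are modelled as rectangular support elements (width w, span h)
with the same material as microtubules: each contributes its own-axis
rectangle tensor (orientation θ with respect to the y-axis) plus a
parallel-axis area term w·h·d² for its offset d from the neutral axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ifta import CrossSection, SpindleAxis, cross_sections, classify_midzone, nn_distances
from .synthetic import lattice_positions
from .traces import SpindleReconstruction

#: Flexural rigidity of one microtubule, pN·μm² (converts MT units to EI).
EI_MT_PN_UM2 = 20.0


@dataclass
class MicrotubuleSection:
    """Hollow-cylinder cross-section of a single microtubule (nm)."""

    r1: float = 7.5
    r2: float = 12.5

    def __post_init__(self):
        if not 0 < self.r1 < self.r2:
            raise ValueError("require 0 < r1 < r2")

    @property
    def area(self) -> float:
        """A_MT = π(r2² − r1²), nm²."""
        return np.pi * (self.r2**2 - self.r1**2)

    @property
    def moment(self) -> float:
        """I_MT = (π/4)(r2⁴ − r1⁴), nm⁴."""
        return np.pi / 4.0 * (self.r2**4 - self.r1**4)


@dataclass
class LinkerElement:
    """Rectangular cross-linker: width w, span h (gap between the linked
    microtubule surfaces), orientation θ w.r.t. the y-axis, midpoint (nm)."""

    w: float
    h: float
    theta: float
    midpoint: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        if self.w < 0:
            raise ValueError("linker width must be >= 0")
        if self.h <= 0:
            raise ValueError("linker span must be > 0")
        self.midpoint = np.asarray(self.midpoint, dtype=float)


@dataclass
class Link:
    """A linker element attached between centres i and j of a section."""

    i: int
    j: int
    element: LinkerElement


@dataclass
class InertiaTensor:
    """Symmetric 2×2 area-moment tensor with its eigen-decomposition."""

    I_xx: float
    I_yy: float
    I_xy: float
    degeneracy_tol: float = 1e-9

    def __post_init__(self):
        evals, evecs = np.linalg.eigh(self.matrix)
        self.I_min = float(evals[0])
        self.I_max = float(evals[1])
        self.principal_axes = evecs.T  # rows: axis of I_min, axis of I_max

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.I_xx, self.I_xy], [self.I_xy, self.I_yy]])

    @property
    def anisotropy(self) -> float:
        """I_max / I_min (1 for mechanically isotropic sections)."""
        return self.I_max / self.I_min

    @property
    def is_isotropic(self) -> bool:
        return abs(self.I_max - self.I_min) <= self.degeneracy_tol * max(abs(self.I_max), 1.0)

    @property
    def mean(self) -> float:
        return 0.5 * (self.I_min + self.I_max)

    def in_mt_units(self, section: "MicrotubuleSection") -> "InertiaTensor":
        m = section.moment
        return InertiaTensor(self.I_xx / m, self.I_yy / m, self.I_xy / m)


def bundle_tensor(centres: np.ndarray, section: MicrotubuleSection | None = None) -> InertiaTensor:
    """Area-moment tensor of N microtubules at 2D *centres* (nm), nm⁴.

    The neutral axis sits at the centroid of the centres.
    """
    centres = np.asarray(centres, dtype=float).reshape(-1, 2)
    if len(centres) == 0:
        raise ValueError("bundle must contain at least one microtubule")
    if section is None:
        section = MicrotubuleSection()
    n = len(centres)
    dev = centres - centres.mean(axis=0)
    i_xx = n * section.moment + section.area * np.sum(dev[:, 1] ** 2)
    i_yy = n * section.moment + section.area * np.sum(dev[:, 0] ** 2)
    i_xy = -section.area * np.sum(dev[:, 0] * dev[:, 1])
    return InertiaTensor(i_xx, i_yy, i_xy)


def bundle_tensor_matrix_form(centres: np.ndarray, section: MicrotubuleSection | None = None) -> np.ndarray:
    """Equivalent matrix form N[I_MT·I₂ + A_MT(tr(Σ)I₂ − Σ)] with Σ the
    (population) covariance of the centres; agrees with the explicit sums."""
    centres = np.asarray(centres, dtype=float).reshape(-1, 2)
    if section is None:
        section = MicrotubuleSection()
    n = len(centres)
    cov = np.cov(centres.T, bias=True).reshape(2, 2) if n > 1 else np.zeros((2, 2))
    return n * (section.moment * np.eye(2) + section.area * (np.trace(cov) * np.eye(2) - cov))


def linker_tensor(link: LinkerElement, neutral_point: np.ndarray | None = None) -> np.ndarray:
    """Tensor contribution (nm⁴) of one rectangular cross-linker.

    Own-axis term (wh/12)·[[h²cos²θ + w²sin²θ, (w²−h²)sinθcosθ],
                           [(w²−h²)sinθcosθ, h²sin²θ + w²cos²θ]]
    plus the parallel-axis area term w·h·d² for the offset d of the linker
    midpoint from the neutral axis (diagonal y²/x² terms and the −xy product
    term, mirroring the single-microtubule decomposition).
    """
    w, h, th = link.w, link.h, link.theta
    if w == 0.0:
        return np.zeros((2, 2))
    s, c = np.sin(th), np.cos(th)
    own = (w * h / 12.0) * np.array(
        [
            [h * h * c * c + w * w * s * s, (w * w - h * h) * s * c],
            [(w * w - h * h) * s * c, h * h * s * s + w * w * c * c],
        ]
    )
    if neutral_point is None:
        return own
    dx, dy = link.midpoint - np.asarray(neutral_point, dtype=float)
    area = w * h
    parallel = area * np.array([[dy * dy, -dx * dy], [-dx * dy, dx * dx]])
    return own + parallel


def composite_tensor(
    centres: np.ndarray,
    links: list[Link],
    section: MicrotubuleSection | None = None,
) -> InertiaTensor:
    """Bundle tensor plus all linker contributions (reduces to the bundle
    tensor exactly at w = 0).  The neutral axis is the microtubule centroid."""
    centres = np.asarray(centres, dtype=float).reshape(-1, 2)
    base = bundle_tensor(centres, section)
    neutral = centres.mean(axis=0)
    mat = base.matrix
    for lk in links:
        if lk.i >= len(centres) or lk.j >= len(centres) or lk.i < 0 or lk.j < 0:
            raise ValueError(f"link ({lk.i}, {lk.j}) references a missing centre")
        mat = mat + linker_tensor(lk.element, neutral)
    return InertiaTensor(mat[0, 0], mat[1, 1], mat[0, 1])


def make_link(
    centres: np.ndarray,
    i: int,
    j: int,
    w: float,
    section: MicrotubuleSection | None = None,
) -> Link:
    """Build the rectangular linker bridging centres i and j.

    The span h is the surface-to-surface gap (separation − 2 r2), the long
    axis lies along the centre connection line, and θ is that line's angle
    from the y-axis.
    """
    if section is None:
        section = MicrotubuleSection()
    centres = np.asarray(centres, dtype=float)
    d = centres[j] - centres[i]
    sep = float(np.linalg.norm(d))
    h = sep - 2.0 * section.r2
    if h <= 0:
        raise ValueError(f"centres {i},{j} overlap: no gap to bridge")
    theta = float(np.arctan2(d[0], d[1]))  # angle from the y-axis
    mid = 0.5 * (centres[i] + centres[j])
    return Link(i, j, LinkerElement(w=w, h=h, theta=theta, midpoint=mid))


def infer_links(
    section: CrossSection,
    cutoff: float | None = None,
    w: float = 0.0,
    midzone: bool = False,
    lattice_spacing: float = 40.0,
    mt_section: MicrotubuleSection | None = None,
) -> list[Link]:
    """Links between neighbouring centres of a cross-section.

    Pairs within *cutoff* (default 1.25x the lattice spacing) are linked:
    antiparallel pairs only inside the midzone, parallel-only outside.
    """
    if cutoff is None:
        cutoff = 1.25 * lattice_spacing
    c = section.centres
    links = []
    for i in range(len(c)):
        for j in range(i + 1, len(c)):
            if np.linalg.norm(c[j] - c[i]) > cutoff:
                continue
            anti = section.pole_labels[i] != section.pole_labels[j]
            if midzone != anti:
                continue
            links.append(make_link(c, i, j, w, mt_section))
    return links


def idealized_series(
    packing: str,
    spacing: float,
    N_max: int,
    w: float = 0.0,
    mt_section: MicrotubuleSection | None = None,
) -> pd.DataFrame:
    """Stiffness eigenvalues of idealized arrays as fibres are added.

    Returns a frame with per-N I_min, I_max, mean (MT units) and an isotropy
    flag (degenerate eigenvalues within 1e-9).
    """
    if mt_section is None:
        mt_section = MicrotubuleSection()
    rows = []
    for n in range(1, N_max + 1):
        pos = lattice_positions(n, packing, spacing)
        if w > 0 and n > 1:
            links = _all_neighbour_links(pos, 1.25 * spacing, w, mt_section)
            tensor = composite_tensor(pos, links, mt_section)
        else:
            tensor = bundle_tensor(pos, mt_section)
        t = tensor.in_mt_units(mt_section)
        rows.append(
            {
                "N": n,
                "I_min": t.I_min,
                "I_max": t.I_max,
                "mean": t.mean,
                "isotropic": t.is_isotropic,
            }
        )
    return pd.DataFrame(rows)


def _all_neighbour_links(pos, cutoff, w, mt_section):
    links = []
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if np.linalg.norm(pos[j] - pos[i]) <= cutoff:
                links.append(make_link(pos, i, j, w, mt_section))
    return links


def stiffness_profile(
    spindle: SpindleReconstruction,
    axis: SpindleAxis,
    step: float = 100.0,
    w: float = 0.0,
    mt_section: MicrotubuleSection | None = None,
    ei_mt: float = EI_MT_PN_UM2,
) -> pd.DataFrame:
    """Per-section minimal transverse stiffness and anisotropy along the axis.

    Columns: axial_position_nm, n_mt, I_min_mt, I_max_mt, anisotropy,
    EI_min_pN_um2 (= I_min in MT units × EI_MT).  Empty sections are skipped.
    """
    if mt_section is None:
        mt_section = MicrotubuleSection()
    sections = cross_sections(spindle, axis, step=step)
    lo, hi = classify_midzone(sections)
    rows = []
    for s in sections:
        if len(s.centres) == 0:
            continue
        in_mid = (not np.isnan(lo)) and lo <= s.axial_position <= hi
        if w > 0 and len(s.centres) > 1:
            d = nn_distances(s)
            spacing = float(np.median(d)) if len(d) else 40.0
            links = infer_links(s, w=w, midzone=in_mid, lattice_spacing=spacing,
                                mt_section=mt_section)
            tensor = composite_tensor(s.centres, links, mt_section)
        else:
            tensor = bundle_tensor(s.centres, mt_section)
        t = tensor.in_mt_units(mt_section)
        rows.append(
            {
                "axial_position_nm": s.axial_position,
                "n_mt": len(s.centres),
                "I_min_mt": t.I_min,
                "I_max_mt": t.I_max,
                "anisotropy": t.anisotropy,
                "EI_min_pN_um2": t.I_min * ei_mt,
                "in_midzone": in_mid,
            }
        )
    return pd.DataFrame(rows)
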