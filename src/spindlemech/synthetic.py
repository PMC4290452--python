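"""Synthetic spindle architectures and 3D trace sets.

Emulates the geometry of electron-tomography reconstructions of fission-yeast
anaphase B spindles: two half-spindles of pole-anchored microtubules, a
square-packed antiparallel lattice (~40 nm) in the midzone, hexagonally packed
(~30 nm) parallel regions near the poles, total polymer ~27.1 μm, with
optional global curvature and per-point positional noise.

Architectures follow either the maximal-midzone-overlap (MMO) rule — every
microtubule monodisperse with length (L_s + L_m)/2 so all plus ends meet the
far edge of the midzone — or a null statistical model in which per-pole counts
are Poisson and the fixed polymer budget is partitioned uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import (
    NM_PER_UM,
    MicrotubuleTrace,
    SpindleArchitecture,
    SpindleReconstruction,
)

#: Microtubule outer radius (nm) used for lattice feasibility checks.
MT_OUTER_RADIUS_NM = 12.5

#: Wild-type fission yeast constants: total polymer (μm), midzone width (μm).
WILD_TYPE_L_T = 27.1
WILD_TYPE_L_M = 2.5


@dataclass
class PackingSpec:
    """Lattice geometry for synthetic trace generation.

    midzone_lattice / polar_lattice are centre-to-centre spacings in nm
    (defaults 40 / 30, the square midzone and hexagonal polar spacings).
    curvature is the reciprocal radius of a global circular arc in μm^-1.
    """

    midzone_lattice: float = 40.0
    polar_lattice: float = 30.0
    midzone_width: float = WILD_TYPE_L_M
    positional_noise_sd: float = 0.0
    curvature: float = 0.0
    seed: int | None = None
    transition_nm: float = 100.0
    point_spacing_nm: float = 50.0

    def __post_init__(self):
        if self.midzone_lattice <= 2 * MT_OUTER_RADIUS_NM:
            raise ValueError("midzone lattice constant must exceed the microtubule diameter")
        if self.polar_lattice <= 2 * MT_OUTER_RADIUS_NM:
            raise ValueError("polar lattice constant must exceed the microtubule diameter")
        if self.midzone_width < 0:
            raise ValueError("midzone width must be non-negative")


@dataclass
class NullModelSpec:
    """Null statistical model: Poisson per-pole counts, random polymer partition."""

    mean_per_pole: float
    L_T: float
    L_s: float
    seed: int | None = None

    def __post_init__(self):
        if self.mean_per_pole <= 0:
            raise ValueError("mean_per_pole must be positive")
        if self.L_T <= 0:
            raise ValueError("L_T must be positive")
        if self.L_s <= 0:
            raise ValueError("L_s must be positive")


def mmo_architecture(L_T: float, L_s: float, L_m: float = WILD_TYPE_L_M) -> SpindleArchitecture:
    """Maximal-midzone-overlap architecture.

    N = round(2 L_T / (L_s + L_m)) monodisperse microtubules of length
    (L_s + L_m)/2, split as evenly as possible between the poles (an odd
    remainder goes to pole A).  The realized total polymer is N × L_MT, which
    differs from L_T only through the rounding of N.
    """
    if not (L_s >= L_m >= 0 and L_s > 0):
        raise ValueError("require L_s >= L_m >= 0 with L_s > 0")
    n = int(round(2.0 * L_T / (L_s + L_m)))
    if n < 2:
        raise ValueError(f"MMO count N={n} < 2: no bipolar structure possible")
    l_mt = (L_s + L_m) / 2.0
    n_a = (n + 1) // 2
    n_b = n // 2
    return SpindleArchitecture(
        spindle_length=L_s,
        lengths_pole_A=np.full(n_a, l_mt),
        lengths_pole_B=np.full(n_b, l_mt),
    )


def sample_null_architecture(spec: NullModelSpec) -> SpindleArchitecture:
    """Draw one random architecture from the null model.

    Per-pole counts ~ Poisson(mean_per_pole), re-drawn while either pole is
    empty (the spindle must be bipolar).  L_T is partitioned uniformly at
    random via sorted-uniform spacings.  Lengths exceeding L_s are truncated,
    the surplus spawning additional microtubules on a uniformly random pole,
    so the realized total polymer equals L_T exactly.
    """
    rng = np.random.default_rng(spec.seed)
    while True:
        n_a = rng.poisson(spec.mean_per_pole)
        n_b = rng.poisson(spec.mean_per_pole)
        if n_a > 0 and n_b > 0:
            break
    n = n_a + n_b
    cuts = np.sort(rng.uniform(0.0, 1.0, n - 1)) if n > 1 else np.empty(0)
    lengths = np.diff(np.concatenate(([0.0], cuts, [1.0]))) * spec.L_T
    pole = np.array([0] * n_a + [1] * n_b)

    out_len: list[float] = []
    out_pole: list[int] = []
    surplus = 0.0
    for li, pi in zip(lengths, pole):
        if li > spec.L_s:
            surplus += li - spec.L_s
            li = spec.L_s
        out_len.append(li)
        out_pole.append(pi)
    while surplus > 1e-12:
        piece = min(surplus, spec.L_s)
        out_len.append(piece)
        out_pole.append(int(rng.integers(0, 2)))
        surplus -= piece
    out_len = np.asarray(out_len)
    out_pole = np.asarray(out_pole)
    return SpindleArchitecture(
        spindle_length=spec.L_s,
        lengths_pole_A=out_len[out_pole == 0],
        lengths_pole_B=out_len[out_pole == 1],
    )


# ---------------------------------------------------------------------------
# Idealized lattice growth sequences
# ---------------------------------------------------------------------------

# Square growth in lattice units: configurations chosen so that each N is the
# compact square-packed motif observed as fibres are added (row of 3 at N=3,
# the 2x2 motif at N=4, ...).  Configurations need not be nested.
_SQUARE_BASE = {
    1: [(0, 0)],
    2: [(0, 0), (1, 0)],
    3: [(0, 0), (1, 0), (2, 0)],
    4: [(0, 0), (1, 0), (0, 1), (1, 1)],
    5: [(0, 0), (1, 0), (0, 1), (1, 1), (2, 0)],
    6: [(0, 0), (1, 0), (2, 0), (0, 1), (1, 1), (2, 1)],
    7: [(0, 0), (1, 0), (2, 0), (0, 1), (1, 1), (2, 1), (0, 2)],
    8: [(0, 0), (1, 0), (2, 0), (0, 1), (1, 1), (2, 1), (0, 2), (1, 2)],
    9: [(0, 0), (1, 0), (2, 0), (0, 1), (1, 1), (2, 1), (0, 2), (1, 2), (2, 2)],
}


def _square_sites(n: int) -> np.ndarray:
    if n <= 9:
        sites = _SQUARE_BASE[n]
    else:
        # continue row-major fill of the 3-wide block beyond the 3x3
        sites = list(_SQUARE_BASE[9])
        k = 9
        while k < n:
            row, col = divmod(k, 3)
            sites.append((col, row))
            k += 1
    return np.asarray(sites, dtype=float)


def _hex_sites(n: int) -> np.ndarray:
    # hexagonal lattice points sorted by (distance from origin, angle):
    # origin, pair, equilateral triangle, edge-sharing rhombus, ... shells.
    m = 6
    a1 = np.array([1.0, 0.0])
    a2 = np.array([0.5, np.sqrt(3.0) / 2.0])
    pts = []
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            pts.append(i * a1 + j * a2)
    pts = np.asarray(pts)
    r = np.linalg.norm(pts, axis=1)
    ang = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2 * np.pi)
    order = np.lexsort((ang, np.round(r, 9)))
    return pts[order[:n]]


def lattice_positions(n: int, packing: str, spacing: float) -> np.ndarray:
    """Deterministic idealized-array growth sequence, centred on its centroid.

    square: 1, pair, row of 3, 2x2, 2x2+1, 3x2, ... (row-major 3-wide block).
    hexagonal: 1, pair, equilateral triangle, rhombus, ... compact shells.
    Returns (n, 2) positions in the units of *spacing* (nm).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if packing == "square":
        sites = _square_sites(n)
    elif packing == "hexagonal":
        sites = _hex_sites(n)
    else:
        raise ValueError(f"unknown packing {packing!r}")
    pos = sites * spacing
    return pos - pos.mean(axis=0)


def checkerboard_sites(n_a: int, n_b: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Interleaved antiparallel midzone sites on a square lattice.

    Sites of one checkerboard colour go to pole A, the other to pole B, each
    pole's sites chosen nearest the block centre.  Raises if the architecture
    needs more sites than a 5x5 block provides.
    """
    n = n_a + n_b
    for k in range(2, 6):
        cols = {0: [], 1: []}
        for i in range(k):
            for j in range(k):
                cols[(i + j) % 2].append((i, j))
        if len(cols[0]) >= n_a and len(cols[1]) >= n_b:
            break
    else:
        raise ValueError(f"architecture with {n} microtubules exceeds the 5x5 midzone block")
    centre = (k - 1) / 2.0
    out = []
    for colour, count in ((0, n_a), (1, n_b)):
        sites = np.asarray(cols[colour], dtype=float)
        d = np.linalg.norm(sites - centre, axis=1)
        order = np.lexsort((sites[:, 1], sites[:, 0], np.round(d, 9)))
        out.append(sites[order[:count]] * spacing)
    all_sites = np.vstack(out)
    centroid = all_sites.mean(axis=0)
    return out[0] - centroid, out[1] - centroid


# ---------------------------------------------------------------------------
# Trace synthesis
# ---------------------------------------------------------------------------

def synthesize_traces(arch: SpindleArchitecture, pack: PackingSpec) -> SpindleReconstruction:
    """Generate a 3D trace set realizing *arch* with the packing of *pack*.

    Microtubules run parallel to a common axis (straight, or a circular arc of
    the given curvature).  Within the central midzone interval antiparallel
    microtubules occupy interleaved square-lattice sites; outside it same-pole
    microtubules relax to hexagonal packing, with a linear blend over a
    transition zone.  Gaussian positional noise is added per point and minus
    ends sit at the poles.  Coordinates are nm; ``scale_applied`` is True
    (synthetic data needs no shrinkage correction).
    """
    rng = np.random.default_rng(pack.seed)
    ls_nm = arch.spindle_length * NM_PER_UM
    lm_nm = pack.midzone_width * NM_PER_UM
    m0 = (ls_nm - lm_nm) / 2.0
    m1 = (ls_nm + lm_nm) / 2.0
    n_a = len(arch.lengths_pole_A)
    n_b = len(arch.lengths_pole_B)

    sq_a, sq_b = checkerboard_sites(n_a, n_b, pack.midzone_lattice)
    hex_a = lattice_positions(n_a, "hexagonal", pack.polar_lattice)
    hex_b = lattice_positions(n_b, "hexagonal", pack.polar_lattice)

    traces = []
    for pole, lengths, sq, hx in (
        ("A", arch.lengths_pole_A, sq_a, hex_a),
        ("B", arch.lengths_pole_B, sq_b, hex_b),
    ):
        for i, l_um in enumerate(lengths):
            l_nm = min(l_um * NM_PER_UM, ls_nm)
            n_pts = max(2, int(np.ceil(l_nm / pack.point_spacing_nm)) + 1)
            s_local = np.linspace(0.0, l_nm, n_pts)
            # axial coordinate measured from pole A
            s_axis = s_local if pole == "A" else ls_nm - s_local
            w = _midzone_weight(s_axis, m0, m1, pack.transition_nm)
            off = (1.0 - w)[:, None] * hx[i] + w[:, None] * sq[i]
            pts = _embed(s_axis, off, ls_nm, pack.curvature)
            if pack.positional_noise_sd > 0:
                pts = pts + rng.normal(0.0, pack.positional_noise_sd, pts.shape)
            traces.append(MicrotubuleTrace(f"{pole}{i}", pole, pts, minus_end="first"))
    meta = {
        "synthetic": True,
        "L_s_um": arch.spindle_length,
        "L_T_um": arch.total_polymer,
        "packing": vars(pack).copy(),
    }
    return SpindleReconstruction(traces=traces, scale_applied=True, metadata=meta)


def _midzone_weight(s_axis, m0, m1, trans):
    """Blend weight: 0 in the polar phase, 1 in the midzone, linear ramps."""
    w = np.zeros_like(s_axis)
    if trans <= 0:
        return np.where((s_axis >= m0) & (s_axis <= m1), 1.0, 0.0)
    w = np.clip((s_axis - (m0 - trans)) / trans, 0.0, 1.0)
    w = np.minimum(w, np.clip(((m1 + trans) - s_axis) / trans, 0.0, 1.0))
    return w


def _embed(s_axis, offsets, ls_nm, curvature_per_um):
    """Map (axial position, 2D lateral offset) to 3D nm coordinates.

    Straight axis along +x, or a circular arc in the x-y plane whose
    arc length parameterises the axial coordinate.
    """
    if curvature_per_um == 0.0:
        return np.column_stack([s_axis, offsets[:, 0], offsets[:, 1]])
    r_nm = NM_PER_UM / curvature_per_um
    phi = s_axis / r_nm
    axis = np.column_stack([r_nm * np.sin(phi), r_nm * (1.0 - np.cos(phi)), np.zeros_like(phi)])
    normal = np.column_stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)])
    binormal = np.array([0.0, 0.0, 1.0])
    return axis + offsets[:, [0]] * normal + offsets[:, [1]] * binormal


def wild_type_preset(L_s: float = 2.5, **pack_kwargs) -> tuple[SpindleArchitecture, PackingSpec]:
    """Wild-type fission yeast preset: L_T=27.1 μm, L_m=2.5 μm, 40/30 nm lattices.

    At the default L_s = 2.5 μm the MMO rule gives the 11-microtubule early
    anaphase B spindle; longer L_s gives later anaphase stages with distinct
    polar regions.
    """
    arch = mmo_architecture(WILD_TYPE_L_T, L_s, WILD_TYPE_L_M)
    pack = PackingSpec(midzone_width=WILD_TYPE_L_M, **pack_kwargs)
    return arch, pack
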