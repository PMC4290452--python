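"""Coarse-grained buckling simulations of bipolar spindles.

A spindle architecture (per-pole microtubule lengths + spindle length) is
realized as bead-spring filaments with flexural rigidity EI_MT = 20 pN·μm²,
segmented at 0.1 μm, minus ends tethered by stiff Hookean springs to points
Monte-Carlo-sampled on the faces of two spindle pole bodies (SPBs) confined
to the x-axis.  Cross-linkers with a 50 nm bridging length bind pairs of
antiparallel filaments inside the central midzone cylinder during an
initialisation phase; detachment is then frozen and the poles are compressed
by a spring whose rest length drops by Δ = 1 μm and whose constant ramps
linearly to k_max.  Buckling shows up as a transient force peak followed by
a decay to the equilibrium plateau; the critical force F_c is the mean force
borne by the pole spring over the final hold window, summarised as the
median over stochastic replicates.

Optional lateral elastic confinement of strength α (Pa = pN·μm⁻²) anchors
every model point to the spindle axis with stiffness α per unit length,
reproducing reinforced buckling with wavelength λ = 2π(EI/α)^{1/4}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _engine
from .traces import SpindleArchitecture


@dataclass
class SimConfig:
    """Physical and numerical constants of the simulation (μm, pN, s)."""

    kT: float = 0.0042            # thermal energy, pN·μm (27 °C)
    viscosity: float = 1.0        # cytoplasmic viscosity, pN·s·μm⁻²
    dt: float = 0.001             # time step, s
    segment: float = 0.1          # filament segmentation, μm
    EI_MT: float = 20.0           # microtubule flexural rigidity, pN·μm²
    steric_radius: float = 0.030  # μm; repulsion engages below 2x this
    steric_k: float = 200.0       # pN·μm⁻¹ per segment
    midzone_width: float = 2.5    # cross-linker confinement cylinder, μm
    spb_radius: float = 0.060     # SPB face radius, μm
    spb_depth: float = 0.100      # SPB depth, μm (geometry bookkeeping)
    spb_link_k: float = 1000.0    # tether / initialisation spring, pN·μm⁻¹
    n_linkers: int = 300
    linker_rest: float = 0.050    # bridging length, μm
    linker_k: float = 1000.0      # pN·μm⁻¹
    centring: float = 20.0        # weak lateral centring during init, Pa
    k_stretch: float = 2.0e5      # axial inextensibility spring, pN·μm⁻¹
    mt_diameter: float = 0.025    # μm, for the slender-body drag estimate
    max_links_per_bead: int = 2
    capture_distance: float = 0.075  # linker capture radius, μm

    def __post_init__(self):
        for name in ("kT", "viscosity", "dt", "segment", "EI_MT", "steric_radius",
                     "steric_k", "midzone_width", "spb_radius", "spb_link_k",
                     "linker_rest", "linker_k", "k_stretch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def drag_per_bead(self, fil_length: float) -> float:
        """Slender-body transverse drag per bead: 4πη/ln(L/d) × segment."""
        log_term = max(np.log(max(fil_length, 2 * self.segment) / self.mt_diameter), 1.0)
        return 4.0 * np.pi * self.viscosity / log_term * self.segment

    @property
    def spb_drag(self) -> float:
        """Stokes drag of one SPB, pN·s·μm⁻¹."""
        return 6.0 * np.pi * self.viscosity * self.spb_radius


@dataclass
class RampProtocol:
    """Force-ramp protocol: binding, ramp, hold.

    Durations in s; *time_scale* compresses all durations uniformly for
    desk-scale runs (the ramp rate speeds up correspondingly).
    """

    t_init: float = 50.0
    delta: float = 1.0            # rest-length reduction, μm
    t_ramp: float = 150.0
    k_max: float = 240.0          # pN·μm⁻¹ (1500 for reinforced runs)
    t_hold: float = 50.0
    time_scale: float = 1.0
    sample_dt: float = 0.1

    def __post_init__(self):
        for name in ("t_init", "delta", "t_ramp", "k_max", "t_hold", "time_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def scaled(self, name: str) -> float:
        return getattr(self, name) * self.time_scale


@dataclass
class ForceTrace:
    """Compressive force borne by the pole-to-pole spring during a ramp."""

    times: np.ndarray
    force: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.force = np.asarray(self.force, dtype=float)


@dataclass
class SimState:
    """Mutable simulation state (positions in μm)."""

    pos: np.ndarray
    fil_ptr: np.ndarray
    fil_dir: np.ndarray
    fil_of_bead: np.ndarray
    ds: np.ndarray
    gamma_bead: np.ndarray
    teth_bead: np.ndarray
    teth_spb: np.ndarray
    teth_dx: np.ndarray
    teth_dy: np.ndarray
    teth_dz: np.ndarray
    spb_x: np.ndarray
    lk_a: np.ndarray
    lk_b: np.ndarray
    bead_link_count: np.ndarray
    n_lk: int = 0
    alpha: float = 0.0
    bound: bool = False
    seed: int | None = None
    time: float = 0.0
    metadata: dict = field(default_factory=dict)

    @property
    def n_filaments(self) -> int:
        return len(self.fil_ptr) - 1

    def copy(self) -> "SimState":
        return SimState(
            pos=self.pos.copy(), fil_ptr=self.fil_ptr.copy(), fil_dir=self.fil_dir.copy(),
            fil_of_bead=self.fil_of_bead.copy(), ds=self.ds.copy(),
            gamma_bead=self.gamma_bead.copy(), teth_bead=self.teth_bead.copy(),
            teth_spb=self.teth_spb.copy(), teth_dx=self.teth_dx.copy(),
            teth_dy=self.teth_dy.copy(),
            teth_dz=self.teth_dz.copy(), spb_x=self.spb_x.copy(),
            lk_a=self.lk_a.copy(), lk_b=self.lk_b.copy(),
            bead_link_count=self.bead_link_count.copy(), n_lk=self.n_lk,
            alpha=self.alpha, bound=self.bound, seed=self.seed, time=self.time,
            metadata=dict(self.metadata),
        )


class SimulationDiverged(RuntimeError):
    pass


def _sample_face_points(n: int, cfg: SimConfig, rng) -> np.ndarray:
    """Monte-Carlo positions on the SPB face, pairwise >= 2x steric radius.

    The face radius grows with √(N/6) beyond 6 microtubules (constant areal
    density); if rejection stalls the disc is widened by 10% and sampling
    restarts, so dense poles remain feasible.
    """
    min_sep = 2.0 * cfg.steric_radius
    radius = cfg.spb_radius * np.sqrt(max(n, 6) / 6.0)
    for _ in range(60):
        pts: list[np.ndarray] = []
        failures = 0
        while len(pts) < n and failures < 2000:
            while True:
                cand = rng.uniform(-radius, radius, 2)
                if cand @ cand <= radius * radius:
                    break
            if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
                pts.append(cand)
            else:
                failures += 1
        if len(pts) == n:
            return np.asarray(pts)
        radius *= 1.1
    raise RuntimeError(f"could not place {n} minus ends on the SPB face")


def init_state(arch: SpindleArchitecture, cfg: SimConfig | None = None,
               seed: int | None = 0) -> SimState:
    """Initial straight bipolar configuration for *arch*.

    SPBs sit on the x-axis at separation L_s; each microtubule is discretized
    at ~0.1 μm and extends from its sampled SPB-face point toward the
    opposite pole.  Each microtubule is connected to its SPB by a pair of
    stiff Hookean springs: one on the minus end, one clamping the adjacent
    model point one segment along the axis, so the minus-end orientation is
    held against the pole.
    """
    if cfg is None:
        cfg = SimConfig()
    rng = np.random.default_rng(seed)
    ls = arch.spindle_length
    lengths = [(+1, l) for l in arch.lengths_pole_A] + [(-1, l) for l in arch.lengths_pole_B]
    n_a = len(arch.lengths_pole_A)
    n_b = len(arch.lengths_pole_B)
    face_a = _sample_face_points(n_a, cfg, rng)
    face_b = _sample_face_points(n_b, cfg, rng)

    fil_ptr = [0]
    pos_chunks, dirs, ds_list, gb_list = [], [], [], []
    teth_bead, teth_spb, teth_dx, teth_dy, teth_dz = [], [], [], [], []
    faces = np.vstack([face_a, face_b])
    for k, (direction, length) in enumerate(lengths):
        n_seg = max(1, int(round(length / cfg.segment)))
        dsf = length / n_seg
        nb = n_seg + 1
        s = np.arange(nb) * dsf
        x0 = 0.0 if direction == 1 else ls
        x = x0 + direction * s
        dy, dz = faces[k]
        chunk = np.column_stack([x, np.full(nb, dy), np.full(nb, dz)])
        pos_chunks.append(chunk)
        dirs.append(direction)
        ds_list.append(dsf)
        gb_list.append(cfg.drag_per_bead(length))
        # pair of Hookean springs: minus-end anchor plus an orientation
        # clamp on the adjacent model point, one segment along the axis
        spb_index = 0 if direction == 1 else 1
        teth_bead.append(fil_ptr[-1])
        teth_spb.append(spb_index)
        teth_dx.append(0.0)
        teth_dy.append(dy)
        teth_dz.append(dz)
        teth_bead.append(fil_ptr[-1] + 1)
        teth_spb.append(spb_index)
        teth_dx.append(direction * dsf)
        teth_dy.append(dy)
        teth_dz.append(dz)
        fil_ptr.append(fil_ptr[-1] + nb)

    pos = np.vstack(pos_chunks)
    fil_ptr = np.asarray(fil_ptr, dtype=np.int64)
    fil_of_bead = np.empty(len(pos), dtype=np.int64)
    for f in range(len(fil_ptr) - 1):
        fil_of_bead[fil_ptr[f]:fil_ptr[f + 1]] = f
    return SimState(
        pos=pos,
        fil_ptr=fil_ptr,
        fil_dir=np.asarray(dirs, dtype=np.int64),
        fil_of_bead=fil_of_bead,
        ds=np.asarray(ds_list),
        gamma_bead=np.asarray(gb_list),
        teth_bead=np.asarray(teth_bead, dtype=np.int64),
        teth_spb=np.asarray(teth_spb, dtype=np.int64),
        teth_dx=np.asarray(teth_dx),
        teth_dy=np.asarray(teth_dy),
        teth_dz=np.asarray(teth_dz),
        spb_x=np.array([0.0, ls]),
        lk_a=np.zeros(cfg.n_linkers, dtype=np.int64),
        lk_b=np.zeros(cfg.n_linkers, dtype=np.int64),
        bead_link_count=np.zeros(len(pos), dtype=np.int64),
        seed=seed,
        metadata={"L_s": ls, "n_A": n_a, "n_B": n_b},
    )


def single_filament_state(L: float, span: float | None = None,
                          cfg: SimConfig | None = None, seed: int | None = 0,
                          perturbation: float = 0.005) -> SimState:
    """A single filament hinged between the two SPBs (Euler-buckling stand-in).

    Both ends are tethered (single-point springs, so the ends pivot freely);
    a small random transverse perturbation seeds symmetry breaking.
    """
    if cfg is None:
        cfg = SimConfig()
    if span is None:
        span = L
    rng = np.random.default_rng(seed)
    n_seg = max(2, int(round(L / cfg.segment)))
    nb = n_seg + 1
    dsf = L / n_seg
    x = np.linspace(0.0, span, nb)
    pos = np.column_stack([x, np.zeros(nb), np.zeros(nb)])
    if perturbation > 0:
        pos[1:-1, 1:] += rng.normal(0.0, perturbation, (nb - 2, 2))
    _engine.seed_rng(_derive_seed(seed, 77))
    return SimState(
        pos=pos,
        fil_ptr=np.array([0, nb], dtype=np.int64),
        fil_dir=np.array([1], dtype=np.int64),
        fil_of_bead=np.zeros(nb, dtype=np.int64),
        ds=np.array([dsf]),
        gamma_bead=np.array([cfg.drag_per_bead(L)]),
        teth_bead=np.array([0, nb - 1], dtype=np.int64),
        teth_spb=np.array([0, 1], dtype=np.int64),
        teth_dx=np.zeros(2),
        teth_dy=np.zeros(2),
        teth_dz=np.zeros(2),
        spb_x=np.array([0.0, span]),
        lk_a=np.zeros(1, dtype=np.int64),
        lk_b=np.zeros(1, dtype=np.int64),
        bead_link_count=np.zeros(nb, dtype=np.int64),
        bound=True,
        seed=seed,
        metadata={"L_s": span, "single_filament": True},
    )


def _advance(state: SimState, cfg: SimConfig, n_steps: int, *,
             pole_k0=0.0, pole_k_rate=0.0, pole_k_max=0.0, pole_rest=None,
             centring=0.0, bind=False, bind_every=50, bind_batch=8,
             record_every=0):
    """Low-level wrapper around the compiled kernel (mutates *state*)."""
    if pole_rest is None:
        pole_rest = float(state.spb_x[1] - state.spb_x[0])
    n_rec_max = (n_steps // record_every + 1) if record_every > 0 else 1
    forces_out = np.zeros(n_rec_max)
    status, n_lk, n_rec = _engine.advance(
        state.pos, state.fil_ptr, state.fil_dir, state.fil_of_bead,
        state.ds, state.gamma_bead,
        state.teth_bead, state.teth_spb, state.teth_dx, state.teth_dy, state.teth_dz,
        cfg.spb_link_k,
        state.spb_x, cfg.spb_drag,
        state.lk_a, state.lk_b, state.bead_link_count, state.n_lk,
        cfg.linker_rest, cfg.linker_k,
        n_steps, cfg.dt, cfg.kT,
        cfg.EI_MT, cfg.k_stretch,
        2.0 * cfg.steric_radius, cfg.steric_k,
        state.alpha, centring,
        pole_k0, pole_k_rate, pole_k_max, pole_rest,
        bind, bind_every, bind_batch,
        cfg.capture_distance, cfg.midzone_width / 2.0, cfg.max_links_per_bead,
        record_every, forces_out,
    )
    state.n_lk = int(n_lk)
    state.time += n_steps * cfg.dt
    if status != _engine.STATUS_OK:
        raise SimulationDiverged(
            f"simulation diverged (NaN) at t≈{state.time:.3f} s; "
            f"n_filaments={state.n_filaments}, n_linkers={state.n_lk}"
        )
    return forces_out[:n_rec]


def step(state: SimState, cfg: SimConfig | None = None, n_steps: int = 1, **kwargs) -> SimState:
    """Advance *state* by n_steps of free dynamics (no pole load by default)."""
    if cfg is None:
        cfg = SimConfig()
    _advance(state, cfg, n_steps, **kwargs)
    return state


def _has_possible_attachment(state: SimState, cfg: SimConfig) -> bool:
    centre = 0.5 * (state.spb_x[0] + state.spb_x[1])
    lo, hi = centre - cfg.midzone_width / 2, centre + cfg.midzone_width / 2
    spans = []
    for f in range(state.n_filaments):
        xs = state.pos[state.fil_ptr[f]:state.fil_ptr[f + 1], 0]
        spans.append((state.fil_dir[f], xs.min(), xs.max()))
    for d1, a1, b1 in spans:
        if d1 != 1:
            continue
        for d2, a2, b2 in spans:
            if d2 != -1:
                continue
            lo12 = max(a1, a2, lo)
            hi12 = min(b1, b2, hi)
            if hi12 > lo12:
                return True
    return False


def bind_linkers(state: SimState, cfg: SimConfig | None = None,
                 protocol: RampProtocol | None = None, rng_seed: int | None = None) -> SimState:
    """Initialisation phase: SPBs pinned by a stiff spring at the spindle
    rest length, weak centring on, cross-linkers binding antiparallel
    filament pairs inside the midzone cylinder.  After this phase detachment
    is frozen (linkers persist unchanged through the ramp).

    Raises if no antiparallel attachment is geometrically possible.
    """
    if cfg is None:
        cfg = SimConfig()
    if protocol is None:
        protocol = RampProtocol()
    if not _has_possible_attachment(state, cfg):
        raise ValueError("no antiparallel microtubule pairs overlap the midzone: "
                         "spindle halves cannot be connected")
    _engine.seed_rng(_derive_seed(state.seed, rng_seed))
    n_steps = max(1, int(round(protocol.scaled("t_init") / cfg.dt)))
    _advance(
        state, cfg, n_steps,
        pole_k0=cfg.spb_link_k, pole_k_max=cfg.spb_link_k,
        pole_rest=float(state.metadata.get("L_s", state.spb_x[1] - state.spb_x[0])),
        centring=cfg.centring, bind=True,
    )
    if state.n_lk == 0:
        raise ValueError("no cross-linkers bound during initialisation")
    state.bound = True
    return state


def _derive_seed(*parts) -> int:
    h = 0
    for p in parts:
        if p is not None:
            h = (h * 1000003 + int(p) + 1) % (2**31 - 1)
    return h


def linker_graph_connected(state: SimState) -> bool:
    """True if the linker attachment graph connects the two poles."""
    import networkx as nx  # local: only needed for this diagnostic

    g = nx.Graph()
    g.add_nodes_from(range(state.n_filaments))
    for l in range(state.n_lk):
        g.add_edge(int(state.fil_of_bead[state.lk_a[l]]),
                   int(state.fil_of_bead[state.lk_b[l]]))
    pole_a = [f for f in range(state.n_filaments) if state.fil_dir[f] == 1]
    pole_b = [f for f in range(state.n_filaments) if state.fil_dir[f] == -1]
    if not pole_a or not pole_b:
        return False
    comp = nx.node_connected_component(g, pole_a[0])
    return all(f in comp for f in pole_a + pole_b)


def run_ramp(state: SimState, protocol: RampProtocol | None = None,
             cfg: SimConfig | None = None) -> ForceTrace:
    """Execute the ramp + hold phases on a bound state, recording the force.

    The pole-spring rest length drops by Δ, its constant ramps linearly from
    0 to k_max over t_ramp and is held for t_hold; the returned trace holds
    the compressive force at each sample.
    """
    if cfg is None:
        cfg = SimConfig()
    if protocol is None:
        protocol = RampProtocol()
    if not state.bound:
        raise ValueError("state must be bound (bind_linkers) before the ramp")
    ls = float(state.metadata.get("L_s", state.spb_x[1] - state.spb_x[0]))
    rest = ls - protocol.delta
    record_every = max(1, int(round(protocol.sample_dt / cfg.dt)))
    n_ramp = max(1, int(round(protocol.scaled("t_ramp") / cfg.dt)))
    n_hold = max(1, int(round(protocol.scaled("t_hold") / cfg.dt)))
    rate = protocol.k_max / protocol.scaled("t_ramp")
    f_ramp = _advance(state, cfg, n_ramp, pole_k0=0.0, pole_k_rate=rate,
                      pole_k_max=protocol.k_max, pole_rest=rest,
                      record_every=record_every)
    f_hold = _advance(state, cfg, n_hold, pole_k0=protocol.k_max,
                      pole_k_max=protocol.k_max, pole_rest=rest,
                      record_every=record_every)
    force = np.concatenate([f_ramp, f_hold])
    times = np.arange(len(force)) * record_every * cfg.dt
    return ForceTrace(times=times, force=force, seed=state.seed)


def simulate_architecture(arch: SpindleArchitecture, cfg: SimConfig | None = None,
                          protocol: RampProtocol | None = None, seed: int = 0,
                          alpha: float = 0.0) -> tuple[ForceTrace, SimState]:
    """Full pipeline: init → bind → ramp; returns (force trace, final state)."""
    if cfg is None:
        cfg = SimConfig()
    if protocol is None:
        protocol = RampProtocol()
    state = init_state(arch, cfg, seed)
    if alpha:
        apply_confinement(state, alpha)
    bind_linkers(state, cfg, protocol)
    trace = run_ramp(state, protocol, cfg)
    return trace, state


def critical_force(traces: list[ForceTrace], protocol: RampProtocol | None = None) -> float:
    """Median (over replicates) of the mean force in the final hold window."""
    if protocol is None:
        protocol = RampProtocol()
    if not traces:
        raise ValueError("need at least one force trace")
    hold = protocol.scaled("t_hold")
    per_rep = []
    for tr in traces:
        t_end = tr.times[-1]
        mask = tr.times >= t_end - hold + 1e-9
        if tr.times[-1] - tr.times[0] < hold - 1e-9 or mask.sum() == 0:
            raise ValueError("force trace shorter than the hold window")
        per_rep.append(float(tr.force[mask].mean()))
    return float(np.median(per_rep))


def effective_stiffness(F_c: float, L_s: float) -> float:
    """EI_eff = F_c (L_s/π)², pN·μm²."""
    if F_c <= 0 or L_s <= 0:
        raise ValueError("require positive F_c and L_s")
    return float(F_c * (L_s / np.pi) ** 2)


def apply_confinement(state: SimState, alpha: float) -> SimState:
    """Confine every model point laterally to the spindle axis.

    Each bead acquires a Hookean restoring force toward the x-axis with
    stiffness α × segment length (α in Pa = pN·μm⁻²); axial motion is
    unconstrained.  α = 0 leaves the dynamics unchanged.
    """
    if alpha < 0:
        raise ValueError("confinement strength must be >= 0")
    state.alpha = float(alpha)
    return state


def backbone_deflection(state: SimState, bin_width: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Spindle backbone |lateral deflection| vs axial position.

    Beads are binned along x between the SPBs; the backbone is the mean
    lateral position per bin, smoothed at the segment scale.
    """
    lo, hi = np.sort(state.spb_x)
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 3:
        return np.empty(0), np.empty(0)
    x = state.pos[:, 0]
    idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    centres, defl = [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if not sel.any():
            continue
        centres.append(0.5 * (edges[b] + edges[b + 1]))
        defl.append(np.hypot(state.pos[sel, 1].mean(), state.pos[sel, 2].mean()))
    defl = np.asarray(defl)
    if len(defl) >= 3:
        defl = np.convolve(defl, np.ones(3) / 3.0, mode="same")
    return np.asarray(centres), defl


def count_buckle_modes(state: SimState, cfg: SimConfig | None = None) -> int:
    """Number of strict local maxima of the backbone lateral deflection.

    Returns 0 when the peak deflection is below 2x the steric radius
    (pre-buckling).
    """
    if cfg is None:
        cfg = SimConfig()
    _, defl = backbone_deflection(state, bin_width=cfg.segment)
    if len(defl) < 3 or defl.max() < 2.0 * cfg.steric_radius:
        return 0
    count = 0
    for i in range(1, len(defl) - 1):
        if defl[i] > defl[i - 1] and defl[i] > defl[i + 1]:
            count += 1
    return max(count, 1)


def desk_scale_protocol(time_scale: float = 0.25, **kwargs) -> RampProtocol:
    """Desk-scale protocol: uniformly compressed durations (default 0.25x)."""
    return replace(RampProtocol(**kwargs), time_scale=time_scale)
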