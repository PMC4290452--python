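"""Domain types and I/O for 3D microtubule trace data.

A reconstructed spindle is a set of microtubule polylines in nanometres,
each labelled with its pole of origin and with an explicit minus-end marker
(the pole-proximal end).  Freeze-substitution shrinks microtubules in the
tomograms (apparent diameter ~18 nm instead of 25 nm), so raw coordinates
are corrected by a uniform scale factor of 25/18 before any physical
quantity is computed.

Coordinates are stored in nanometres throughout; conversion to micrometres
happens only through :func:`nm_to_um`, the single documented unit boundary
used by the simulation and architecture layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Uniform correction for freeze-substitution shrinkage of microtubules.
SHRINKAGE_FACTOR = 25.0 / 18.0

NM_PER_UM = 1000.0

TSV_COLUMNS = ["mt_id", "pole", "point_index", "x_nm", "y_nm", "z_nm", "minus_end_flag"]


def nm_to_um(x):
    """Convert nanometres to micrometres.

    The only sanctioned unit-conversion site in the package: reconstruction
    space is nm, simulation/architecture space is μm.
    """
    return np.asarray(x, dtype=float) / NM_PER_UM


def um_to_nm(x):
    """Inverse of :func:`nm_to_um`."""
    return np.asarray(x, dtype=float) * NM_PER_UM


class TraceFormatError(ValueError):
    """Raised when a trace file violates the documented dialect."""


@dataclass
class MicrotubuleTrace:
    """One microtubule as an ordered 3D polyline.

    Parameters
    ----------
    id : str
        Unique microtubule identifier.
    pole : str
        Pole-of-origin label (one of the two pole identifiers of the spindle).
    points : (n, 3) ndarray
        Ordered coordinates in nm.
    minus_end : {"first", "last"}
        Which end of the polyline is pole-proximal.
    """

    id: str
    pole: str
    points: np.ndarray
    minus_end: str = "first"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise TraceFormatError(f"trace {self.id!r}: points must be (n, 3)")
        if len(self.points) < 2:
            raise TraceFormatError(f"trace {self.id!r}: needs at least 2 points")
        seg = np.diff(self.points, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) == 0.0):
            raise TraceFormatError(f"trace {self.id!r}: consecutive points must be distinct")
        if self.minus_end not in ("first", "last"):
            raise TraceFormatError(f"trace {self.id!r}: minus_end must be 'first' or 'last'")

    @property
    def minus_end_point(self) -> np.ndarray:
        """Coordinates (nm) of the pole-proximal end."""
        return self.points[0] if self.minus_end == "first" else self.points[-1]

    @property
    def plus_end_point(self) -> np.ndarray:
        return self.points[-1] if self.minus_end == "first" else self.points[0]

    def length_nm(self) -> float:
        """Polyline (contour) length in nm."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class SpindleReconstruction:
    """A set of traced microtubules with shrinkage-correction state."""

    traces: list[MicrotubuleTrace]
    scale_applied: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        poles = self.pole_labels()
        if len(poles) > 2:
            raise TraceFormatError(f"more than two pole labels present: {sorted(poles)}")

    def pole_labels(self) -> set[str]:
        return {t.pole for t in self.traces}

    def traces_for_pole(self, pole: str) -> list[MicrotubuleTrace]:
        return [t for t in self.traces if t.pole == pole]


@dataclass
class SpindleArchitecture:
    """Abstract spindle: per-pole microtubule length lists plus spindle length.

    All lengths in μm.  This is the input shared by the buckling simulation
    and the maximal-midzone-overlap / null statistical models.
    """

    spindle_length: float
    lengths_pole_A: np.ndarray
    lengths_pole_B: np.ndarray

    def __post_init__(self):
        self.lengths_pole_A = np.atleast_1d(np.asarray(self.lengths_pole_A, dtype=float))
        self.lengths_pole_B = np.atleast_1d(np.asarray(self.lengths_pole_B, dtype=float))
        if np.any(self.lengths_pole_A <= 0) or np.any(self.lengths_pole_B <= 0):
            raise ValueError("all microtubule lengths must be positive")
        if self.spindle_length <= 0:
            raise ValueError("spindle length must be positive")

    @property
    def total_polymer(self) -> float:
        """L_T: total polymerised tubulin length, μm."""
        return float(self.lengths_pole_A.sum() + self.lengths_pole_B.sum())

    @property
    def n_microtubules(self) -> int:
        return len(self.lengths_pole_A) + len(self.lengths_pole_B)


# ---------------------------------------------------------------------------
# I/O: TSV is the canonical interchange dialect, JSON the structured mirror.
# ---------------------------------------------------------------------------

def read_traces(path, dialect: str = "tsv") -> SpindleReconstruction:
    """Read a trace file in the documented TSV or JSON dialect.

    TSV columns: mt_id, pole, point_index, x_nm, y_nm, z_nm, minus_end_flag
    (UTF-8, tab-separated, '.' decimal).  No unit conversion is performed.

    Raises
    ------
    TraceFormatError
        On malformed rows, duplicate (mt_id, point_index), more than two pole
        labels, or traces with fewer than 2 points — with row-level context.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "json":
        return _read_json(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path) -> SpindleReconstruction:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"mt_id": str, "pole": str})
    except Exception as exc:  # noqa: BLE001 - re-raise with dialect context
        raise TraceFormatError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing columns {missing}")
    if df[["mt_id", "point_index"]].duplicated().any():
        dup = df[df[["mt_id", "point_index"]].duplicated()].iloc[0]
        raise TraceFormatError(
            f"{path}: duplicate (mt_id, point_index) = ({dup['mt_id']}, {dup['point_index']})"
        )
    for col in ("x_nm", "y_nm", "z_nm"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise TraceFormatError(f"{path}: non-numeric {col} at row {bad + 2}")

    traces = []
    for mt_id, grp in df.groupby("mt_id", sort=False):
        grp = grp.sort_values("point_index")
        if len(grp) < 2:
            raise TraceFormatError(f"{path}: microtubule {mt_id!r} has fewer than 2 points")
        poles = grp["pole"].unique()
        if len(poles) != 1:
            raise TraceFormatError(f"{path}: microtubule {mt_id!r} has conflicting pole labels")
        flags = grp["minus_end_flag"].to_numpy()
        marked = np.flatnonzero(flags != 0)
        if len(marked) != 1 or marked[0] not in (0, len(grp) - 1):
            raise TraceFormatError(
                f"{path}: microtubule {mt_id!r}: exactly one terminal point must carry minus_end_flag"
            )
        minus_end = "first" if marked[0] == 0 else "last"
        pts = grp[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        traces.append(MicrotubuleTrace(str(mt_id), str(poles[0]), pts, minus_end))
    return SpindleReconstruction(traces=traces, metadata={"source": str(path)})


def _read_json(path: Path) -> SpindleReconstruction:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    traces = [
        MicrotubuleTrace(
            id=str(t["id"]),
            pole=str(t["pole"]),
            points=np.asarray(t["points"], dtype=float),
            minus_end=t.get("minus_end", "first"),
        )
        for t in doc["traces"]
    ]
    return SpindleReconstruction(
        traces=traces,
        scale_applied=bool(doc.get("scale_applied", False)),
        metadata=dict(doc.get("metadata", {})),
    )


def write_traces(spindle: SpindleReconstruction, path, dialect: str = "tsv") -> None:
    """Write a reconstruction in the TSV or JSON dialect (round-trip exact)."""
    path = Path(path)
    if dialect == "tsv":
        rows = []
        for t in spindle.traces:
            n = len(t.points)
            minus_idx = 0 if t.minus_end == "first" else n - 1
            for i, (x, y, z) in enumerate(t.points):
                rows.append((t.id, t.pole, i, repr(float(x)), repr(float(y)),
                             repr(float(z)), int(i == minus_idx)))
        df = pd.DataFrame(rows, columns=TSV_COLUMNS)
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "json":
        doc = {
            "traces": [
                {"id": t.id, "pole": t.pole, "minus_end": t.minus_end,
                 "points": t.points.tolist()}
                for t in spindle.traces
            ],
            "scale_applied": spindle.scale_applied,
            "metadata": spindle.metadata,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_imod_points(path, pole_assignment: dict | None = None) -> SpindleReconstruction:
    """Best-effort import of IMOD ASCII point listings (``model obj cont x y z``).

    Convenience only; contours become traces named ``obj.cont`` and pole labels
    must be supplied via *pole_assignment* (trace id -> pole) or default to the
    object number.  Not bit-specified.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 5:
                continue
            try:
                vals = [float(p) for p in parts[-5:]]
            except ValueError:
                continue
            obj, cont = int(vals[0]), int(vals[1])
            rows.append((obj, cont, vals[2], vals[3], vals[4]))
    traces = []
    by_contour: dict[tuple, list] = {}
    for obj, cont, x, y, z in rows:
        by_contour.setdefault((obj, cont), []).append((x, y, z))
    for (obj, cont), pts in by_contour.items():
        tid = f"{obj}.{cont}"
        pole = (pole_assignment or {}).get(tid, str(obj))
        if len(pts) >= 2:
            traces.append(MicrotubuleTrace(tid, pole, np.asarray(pts), "first"))
    return SpindleReconstruction(traces=traces, metadata={"source": str(path), "format": "imod-ascii"})


# ---------------------------------------------------------------------------
# Shrinkage correction and derived quantities
# ---------------------------------------------------------------------------

def apply_shrinkage_correction(
    spindle: SpindleReconstruction, factor: float = SHRINKAGE_FACTOR
) -> SpindleReconstruction:
    """Scale all coordinates uniformly by *factor* (default 25/18), once.

    Isotropic by assumption: the same factor applies to x, y and z.
    A second application raises, so the correction cannot be stacked.
    """
    if spindle.scale_applied:
        raise ValueError("shrinkage correction already applied to this reconstruction")
    traces = [
        MicrotubuleTrace(t.id, t.pole, t.points * factor, t.minus_end)
        for t in spindle.traces
    ]
    meta = dict(spindle.metadata)
    meta["shrinkage_factor"] = factor
    return SpindleReconstruction(traces=traces, scale_applied=True, metadata=meta)


def total_polymer(spindle: SpindleReconstruction) -> float:
    """Total polymerised microtubule length L_T in μm (corrected coordinates)."""
    if not spindle.traces:
        raise ValueError("empty spindle: no traces")
    return float(nm_to_um(sum(t.length_nm() for t in spindle.traces)))


def architecture_from_reconstruction(
    spindle: SpindleReconstruction,
    spindle_length_um: float | None = None,
    step_nm: float = 200.0,
) -> SpindleArchitecture:
    """Collapse a reconstruction to per-pole length lists plus spindle length.

    The spindle length is the fibre-tracking (IFTA) contour length between the
    poles; pass *spindle_length_um* to skip re-tracing.
    """
    poles = sorted(spindle.pole_labels())
    if len(poles) != 2:
        raise ValueError(f"need exactly two pole labels, got {poles}")
    if spindle_length_um is None:
        from .ifta import trace_axis  # deferred: ifta depends on these types

        axis = trace_axis(spindle, step_nm)
        spindle_length_um = float(nm_to_um(axis.contour_length))
    lengths = {
        p: np.array([t.length_nm() for t in spindle.traces_for_pole(p)]) / NM_PER_UM
        for p in poles
    }
    return SpindleArchitecture(
        spindle_length=spindle_length_um,
        lengths_pole_A=lengths[poles[0]],
        lengths_pole_B=lengths[poles[1]],
    )


def per_microtubule_lengths(spindle: SpindleReconstruction) -> pd.DataFrame:
    """Per-microtubule contour lengths as a tidy frame (id, pole, length_um)."""
    return pd.DataFrame(
        {
            "mt_id": [t.id for t in spindle.traces],
            "pole": [t.pole for t in spindle.traces],
            "length_um": [nm_to_um(t.length_nm()) for t in spindle.traces],
        }
    )
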