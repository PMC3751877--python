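"""Lengths, multi-slice cross-sectional areas (CSA) and traced volumes.

Acquisition geometry: sagittal series of parallel slices of thickness ``t``
with an interslice gap ``g``; each slice's measurement is taken to represent a
slab of one centre-to-centre spacing ``s = t + g`` (default 4 mm + 0.8 mm =
4.8 mm).  A structure measured as a length ``l_i`` on each slice ``i`` of the
window yields a cross-sectional area ``sum_i l_i * s`` (mm^2); a structure
traced as a polygon of area ``a_i`` per slice yields a volume
``sum_i a_i * s`` (mm^3).  No inter-slice interpolation is applied: the
estimate is a pure slab sum.

Length parameters: AIVH, PIVH (anterior/posterior intervertebral height),
IVDL (disc length), ADML, PDML (anterior/posterior disc material length) and
ADSL (antero-posterior dural sac length).  Their CSAs are CAIH, CPIH, CIVD,
CADM, CPDM and CDS; CAIH/CPIH live in the frontal plane, the remainder in the
axial plane — the plane is bookkeeping only, the formula is identical.
Volumes VADM/VPDM come from per-slice traced areas of the anterior/posterior
disc material.

The dural sac is the one structure with a missingness channel: slices listed
as missing-dural in the session filename carry no ADSL measurement and are
excluded from the CDS sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon

from .roi_io import (
    CSA_FOR_LENGTH,
    LENGTH_STRUCTURES,
    VOLUME_STRUCTURES,
    FileNameMeta,
    RoiPoint,
    RoiRecord,
)

#: Axial-plane CSA parameters; CAIH/CPIH are frontal-plane (metadata only).
CSA_PLANES: dict[str, str] = {
    "CAIH": "frontal",
    "CPIH": "frontal",
    "CIVD": "axial",
    "CADM": "axial",
    "CPDM": "axial",
    "CDS": "axial",
}

MEASUREMENT_COLUMNS = ["participant", "level", "slice", "structure", "value", "unit"]


@dataclass(frozen=True)
class SliceGeometry:
    """Slice thickness and interslice gap, in millimetres."""

    thickness: float = 4.0
    gap: float = 0.8

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("slice thickness must be > 0")
        if self.gap < 0:
            raise ValueError("interslice gap must be >= 0")

    @property
    def spacing(self) -> float:
        """Centre-to-centre slice spacing, thickness + gap."""
        return self.thickness + self.gap


@dataclass(frozen=True)
class StructureSeries:
    """Per-slice values of one structure for one participant-level.

    ``samples`` is an ordered tuple of (slice_index, value) pairs with strictly
    increasing slice indices and non-negative values (mm for lengths, mm^2 for
    traced areas).
    """

    participant_id: str
    level: str
    structure: str
    samples: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        samples = tuple((int(i), float(v)) for i, v in self.samples)
        object.__setattr__(self, "samples", samples)
        idx = [i for i, _ in samples]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("slice indices must be strictly increasing")
        if any(v < 0 for _, v in samples):
            raise ValueError("structure values must be >= 0")

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(v for _, v in self.samples)

    @property
    def slices(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.samples)


def segment_length(p1: RoiPoint | Sequence[float], p2: RoiPoint | Sequence[float]) -> float:
    """Euclidean distance between two image-plane points, in mm."""
    x1, y1 = p1
    x2, y2 = p2
    return math.hypot(x2 - x1, y2 - y1)


def polygon_area(vertices: Sequence[RoiPoint] | Sequence[Sequence[float]]) -> float:
    """Absolute shoelace area of a simple polygon, in mm^2.

    Invariant to vertex-order reversal and cyclic rotation.  Raises
    ``ValueError`` for fewer than 3 vertices or a self-intersecting outline.
    """
    pts = [(float(x), float(y)) for x, y in vertices]
    if len(pts) < 3:
        raise ValueError("a traced polygon needs at least 3 vertices")
    if not _ShapelyPolygon(pts).is_valid:
        raise ValueError("traced polygon is self-intersecting or degenerate")
    s = 0.0
    for (x1, y1), (x2, y2) in zip(pts, pts[1:] + pts[:1]):
        s += x1 * y2 - x2 * y1
    return abs(s) / 2.0


def _slab_sum(values: Sequence[float], spacing: float) -> float:
    return float(sum(values)) * spacing


def csa(series: StructureSeries, geom: SliceGeometry) -> float:
    """Cross-sectional area from per-slice lengths: sum_i l_i * (t + g)."""
    if not series.samples:
        raise ValueError(
            f"empty series for {series.structure}: no measured slices "
            "(distinct from a measurement of zero)"
        )
    return _slab_sum(series.values, geom.spacing)


def volume(areas: StructureSeries, geom: SliceGeometry) -> float:
    """Volume from per-slice traced areas: sum_i a_i * (t + g)."""
    if not areas.samples:
        raise ValueError(f"empty series for {areas.structure}: no traced slices")
    return _slab_sum(areas.values, geom.spacing)


def build_measurement_table(
    records: Iterable[RoiRecord],
    geom: SliceGeometry,
    metas: Iterable[FileNameMeta] | Mapping[tuple[str, str], FileNameMeta],
) -> pd.DataFrame:
    """Turn one rater session's records into a tidy measurement table.

    Emits one row per (participant, level, slice, length structure) with the
    length recomputed from coordinates, one CSA row per (participant, level,
    CSA parameter), and one volume row per (participant, level, VADM/VPDM).
    Aggregate rows have an empty ``slice``.  The CDS sum runs only over slices
    not listed as missing-dural in the session metadata; ADSL records on a
    declared-missing slice are an error, as is any record outside the
    [first_slice, last_slice] window or a window slice with no record.
    """
    if isinstance(metas, Mapping):
        meta_by_key = dict(metas)
    else:
        meta_by_key = {(m.participant_id, m.level): m for m in metas}

    grouped: dict[tuple[str, str], list[RoiRecord]] = {}
    for r in records:
        grouped.setdefault((r.participant_id, r.level), []).append(r)

    rows: list[dict] = []
    for key in sorted(grouped):
        pid, level = key
        if key not in meta_by_key:
            raise ValueError(f"no session metadata for participant {pid} level {level}")
        meta = meta_by_key[key]
        missing = set(meta.missing_dural_slices)
        window = list(meta.slices)

        by_struct: dict[str, dict[int, RoiRecord]] = {}
        for r in grouped[key]:
            if not (meta.first_slice <= r.slice_index <= meta.last_slice):
                raise ValueError(
                    f"{pid}/{level}: {r.structure} on slice {r.slice_index} lies "
                    f"outside the window [{meta.first_slice}, {meta.last_slice}]"
                )
            if r.structure == "ADSL" and r.slice_index in missing:
                raise ValueError(
                    f"{pid}/{level}: ADSL measured on slice {r.slice_index} "
                    "declared missing-dural in the filename"
                )
            slot = by_struct.setdefault(r.structure, {})
            if r.slice_index in slot:
                raise ValueError(
                    f"{pid}/{level}: duplicate {r.structure} record on slice {r.slice_index}"
                )
            slot[r.slice_index] = r

        for structure in LENGTH_STRUCTURES:
            expect = [s for s in window if not (structure == "ADSL" and s in missing)]
            have = by_struct.get(structure, {})
            absent = [s for s in expect if s not in have]
            if absent:
                raise ValueError(
                    f"{pid}/{level}: missing {structure} records on slices {absent}"
                )
            samples = []
            for s in expect:
                rec = have[s]
                val = segment_length(rec.points[0], rec.points[1])
                samples.append((s, val))
                rows.append(
                    dict(participant=pid, level=level, slice=s,
                         structure=structure, value=val, unit="mm")
                )
            series = StructureSeries(pid, level, structure, tuple(samples))
            rows.append(
                dict(participant=pid, level=level, slice=None,
                     structure=CSA_FOR_LENGTH[structure],
                     value=csa(series, geom), unit="mm2")
            )

        for structure in VOLUME_STRUCTURES:
            have = by_struct.get(structure, {})
            absent = [s for s in window if s not in have]
            if absent:
                raise ValueError(
                    f"{pid}/{level}: missing {structure} records on slices {absent}"
                )
            samples = tuple(
                (s, polygon_area(have[s].points)) for s in window
            )
            series = StructureSeries(pid, level, structure, samples)
            rows.append(
                dict(participant=pid, level=level, slice=None,
                     structure=structure, value=volume(series, geom), unit="mm3")
            )

    table = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    table["slice"] = table["slice"].astype("Int64")
    return table


def write_measurement_table(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize a measurement table as tidy CSV (empty slice for aggregates)."""
    out = table.copy()
    out.to_csv(path, index=False, lineterminator="\n")


def read_measurement_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"participant": str, "level": str})
    table["slice"] = table["slice"].astype("Int64")
    return table[MEASUREMENT_COLUMNS]
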