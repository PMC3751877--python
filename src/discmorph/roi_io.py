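"""Reading, writing and validation of ROI measurement exports.

Each rater session is stored as one CSV file per participant-level, holding the
region-of-interest (ROI) measurements drawn on every sagittal slice of the
measured window: a two-point line per length structure and a traced polygon per
volume structure.  Filenames carry the participant id, segment number and the
first/last measured slice, with a bracket group listing slices on which the
dural sac could not be measured.

CSV dialect (canonical stand-in for a DICOM viewer's ROI export)::

    participant,level,slice,structure,point_index,x_mm,y_mm,declared_value

one row per point, ``point_index`` ascending from 1 within a record, UTF-8,
dot decimal separator, LF line endings.  ``declared_value`` is the value the
measurement tool reported (mm for lengths, mm^2 for traced areas) and is
carried through unmodified; it is only ever compared against the value
recomputed from the coordinates, never used for analysis.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

# --- structure vocabulary -------------------------------------------------

#: Length structures, in canonical measurement order: anterior/posterior
#: intervertebral height, disc length, anterior/posterior disc material
#: length, antero-posterior dural sac length.
LENGTH_STRUCTURES: tuple[str, ...] = ("AIVH", "PIVH", "IVDL", "ADML", "PDML", "ADSL")

#: Traced-polygon structures: volumes of anterior/posterior disc material.
VOLUME_STRUCTURES: tuple[str, ...] = ("VADM", "VPDM")

STRUCTURES: tuple[str, ...] = LENGTH_STRUCTURES + VOLUME_STRUCTURES

#: Cross-sectional-area parameter derived from each length structure.
CSA_FOR_LENGTH: dict[str, str] = {
    "AIVH": "CAIH",
    "PIVH": "CPIH",
    "IVDL": "CIVD",
    "ADML": "CADM",
    "PDML": "CPDM",
    "ADSL": "CDS",
}
CSA_STRUCTURES: tuple[str, ...] = tuple(CSA_FOR_LENGTH[s] for s in LENGTH_STRUCTURES)

LEVELS: tuple[str, ...] = ("L3-L4", "L4-L5", "L5-S1")

#: Segment number (as encoded in filenames) to disc level.
SEGMENT_LEVELS: dict[int, str] = {1: "L3-L4", 2: "L4-L5", 3: "L5-S1"}
LEVEL_SEGMENTS: dict[str, int] = {v: k for k, v in SEGMENT_LEVELS.items()}

_STRUCTURE_ORDER = {s: i for i, s in enumerate(STRUCTURES)}

CSV_HEADER = [
    "participant",
    "level",
    "slice",
    "structure",
    "point_index",
    "x_mm",
    "y_mm",
    "declared_value",
]


class RoiParseError(ValueError):
    """Raised for malformed filenames or ROI CSV content."""


class RoiPoint(NamedTuple):
    """A point in the sagittal image plane, in millimetres."""

    x: float
    y: float


@dataclass(frozen=True)
class RoiRecord:
    """One stored measurement: a structure on one slice of one rater session.

    Length structures carry exactly two points (the endpoints of the measured
    line); volume structures carry the vertices of a simple traced polygon.
    """

    participant_id: str
    level: str
    slice_index: int
    structure: str
    points: tuple[RoiPoint, ...]
    declared_value: float | None = None

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise RoiParseError(f"unknown structure label {self.structure!r}")
        if self.level not in LEVELS:
            raise RoiParseError(f"unknown disc level {self.level!r}")
        if self.slice_index < 1:
            raise RoiParseError(f"slice index must be >= 1, got {self.slice_index}")
        pts = tuple(RoiPoint(float(p[0]), float(p[1])) for p in self.points)
        object.__setattr__(self, "points", pts)
        for p in pts:
            if not (math.isfinite(p.x) and math.isfinite(p.y)):
                raise RoiParseError(f"non-finite coordinate in {self.structure} record")
        if self.is_length and len(pts) != 2:
            raise RoiParseError(
                f"length structure {self.structure} needs exactly 2 points, got {len(pts)}"
            )
        if not self.is_length:
            if len(pts) < 3:
                raise RoiParseError(
                    f"volume structure {self.structure} needs a polygon of >=3 "
                    f"vertices, got {len(pts)}"
                )

    @property
    def is_length(self) -> bool:
        return self.structure in LENGTH_STRUCTURES

    def sort_key(self) -> tuple:
        return (
            self.participant_id,
            self.level,
            self.slice_index,
            _STRUCTURE_ORDER[self.structure],
        )


@dataclass(frozen=True)
class FileNameMeta:
    """Metadata encoded in a session file name.

    ``missing_dural_slices`` lists slices inside the measured window on which
    the dural sac length could not be measured (the bracket group of the
    naming convention).
    """

    participant_id: str
    segment_number: int
    first_slice: int
    last_slice: int
    missing_dural_slices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "missing_dural_slices", tuple(int(i) for i in self.missing_dural_slices)
        )
        if self.first_slice > self.last_slice:
            raise RoiParseError(
                f"first slice {self.first_slice} > last slice {self.last_slice}"
            )
        for i in self.missing_dural_slices:
            if not (self.first_slice <= i <= self.last_slice):
                raise RoiParseError(
                    f"missing dural slice {i} outside window "
                    f"[{self.first_slice}, {self.last_slice}]"
                )

    @property
    def level(self) -> str:
        try:
            return SEGMENT_LEVELS[self.segment_number]
        except KeyError:
            raise RoiParseError(f"segment number {self.segment_number} has no disc level")

    @property
    def slices(self) -> tuple[int, ...]:
        return tuple(range(self.first_slice, self.last_slice + 1))


_FILENAME_RE = re.compile(
    r"^(?P<id>[^_\[\]]+)_(?P<segment>\d+)_(?P<first>\d+)-(?P<last>\d+)"
    r"(?:\[(?P<missing>\d+(?:,\d+)*)\])?"
    r"(?P<ext>\.[A-Za-z0-9]+)?$"
)


def parse_filename(name: str) -> FileNameMeta:
    """Parse ``<id>_<segment>_<first>-<last>[i,j,...].csv`` into metadata.

    Raises :class:`RoiParseError` naming the offending component on malformed
    input, including a first slice beyond the last.
    """
    base = Path(name).name
    m = _FILENAME_RE.match(base)
    if m is None:
        raise RoiParseError(
            f"filename {base!r} does not match "
            "'<id>_<segment>_<first>-<last>[<i>,<j>,...]' (bad id, segment or "
            "slice-range component)"
        )
    missing = m.group("missing")
    return FileNameMeta(
        participant_id=m.group("id"),
        segment_number=int(m.group("segment")),
        first_slice=int(m.group("first")),
        last_slice=int(m.group("last")),
        missing_dural_slices=tuple(int(i) for i in missing.split(",")) if missing else (),
    )


def render_filename(meta: FileNameMeta, extension: str = ".csv") -> str:
    """Inverse of :func:`parse_filename`."""
    bracket = (
        "[" + ",".join(str(i) for i in meta.missing_dural_slices) + "]"
        if meta.missing_dural_slices
        else ""
    )
    return (
        f"{meta.participant_id}_{meta.segment_number}_"
        f"{meta.first_slice}-{meta.last_slice}{bracket}{extension}"
    )


# --- CSV reading / writing ------------------------------------------------


def _fmt(x: float) -> str:
    # repr round-trips exactly; integral floats still get a decimal point
    return repr(float(x))


def write_roi_csv(records: Iterable[RoiRecord], path: str | Path) -> None:
    """Write records in the canonical dialect, one row per point."""
    recs = sorted(records, key=RoiRecord.sort_key)
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(CSV_HEADER)
        for r in recs:
            declared = "" if r.declared_value is None else _fmt(r.declared_value)
            for i, p in enumerate(r.points, start=1):
                w.writerow(
                    [
                        r.participant_id,
                        r.level,
                        r.slice_index,
                        r.structure,
                        i,
                        _fmt(p.x),
                        _fmt(p.y),
                        declared,
                    ]
                )


def read_roi_csv(path: str | Path) -> list[RoiRecord]:
    """Read a ROI CSV into records ordered by (slice, canonical structure order).

    Raises :class:`RoiParseError` on unknown structure labels or a point count
    inconsistent with the structure class.
    """
    groups: dict[tuple, list[tuple[int, RoiPoint, float | None]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != CSV_HEADER:
            raise RoiParseError(f"{path}: bad or missing header, expected {CSV_HEADER}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(CSV_HEADER):
                raise RoiParseError(f"{path}:{lineno}: expected {len(CSV_HEADER)} fields")
            pid, level, slc, structure, pidx, x, y, declared = [c.strip() for c in row]
            if structure not in STRUCTURES:
                raise RoiParseError(f"{path}:{lineno}: unknown structure {structure!r}")
            key = (pid, level, int(slc), structure)
            groups.setdefault(key, []).append(
                (int(pidx), RoiPoint(float(x), float(y)), float(declared) if declared else None)
            )
    records = []
    for (pid, level, slc, structure), rows in groups.items():
        rows.sort(key=lambda t: t[0])
        if [i for i, _, _ in rows] != list(range(1, len(rows) + 1)):
            raise RoiParseError(
                f"{path}: non-contiguous point_index for {structure} on slice {slc}"
            )
        declared_vals = {d for _, _, d in rows if d is not None}
        if len(declared_vals) > 1:
            raise RoiParseError(
                f"{path}: conflicting declared values for {structure} on slice {slc}"
            )
        records.append(
            RoiRecord(
                participant_id=pid,
                level=level,
                slice_index=slc,
                structure=structure,
                points=tuple(p for _, p, _ in rows),
                declared_value=declared_vals.pop() if declared_vals else None,
            )
        )
    records.sort(key=RoiRecord.sort_key)
    return records


# --- validation against coordinates ---------------------------------------


@dataclass(frozen=True)
class RecordCheck:
    """Outcome of comparing one record's declared value to its coordinates."""

    participant_id: str
    level: str
    slice_index: int
    structure: str
    declared: float | None
    recomputed: float
    flagged: bool

    @property
    def unverifiable(self) -> bool:
        return self.declared is None


@dataclass(frozen=True)
class SwapSuggestion:
    """A structure-label permutation that would resolve flags on one slice.

    ``relabel`` maps the structure label a record currently carries to the
    label whose declared value its coordinates actually support — the
    "altered order of measurements" failure mode.  Suggestions are advisory
    only and never applied automatically.
    """

    participant_id: str
    level: str
    slice_index: int
    relabel: dict[str, str]


@dataclass
class ValidationReport:
    checks: list[RecordCheck] = field(default_factory=list)
    suggestions: list[SwapSuggestion] = field(default_factory=list)
    tolerance: float = 0.05

    @property
    def flagged(self) -> list[RecordCheck]:
        return [c for c in self.checks if c.flagged]

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)

    @property
    def n_unverifiable(self) -> int:
        return sum(1 for c in self.checks if c.unverifiable)

    @property
    def ok(self) -> bool:
        return self.n_flagged == 0


def recompute_value(record: RoiRecord) -> float:
    """Value implied by a record's coordinates: length (mm) or area (mm^2)."""
    from . import morphometry  # local import: morphometry depends on this module

    if record.is_length:
        return morphometry.segment_length(record.points[0], record.points[1])
    return morphometry.polygon_area(record.points)


def validate_records(
    records: Sequence[RoiRecord], tolerance: float = 0.05
) -> ValidationReport:
    """Check declared values against values recomputed from coordinates.

    Records whose declared value differs from the recomputed one by more than
    ``tolerance`` are flagged.  When all flags within one slice can be resolved
    by permuting structure labels (values entered under the wrong structure),
    the resolving permutation is reported as a suggestion.  Report-only: no
    record is modified.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    report = ValidationReport(tolerance=tolerance)
    by_slice: dict[tuple, list[tuple[RoiRecord, RecordCheck]]] = {}
    for r in sorted(records, key=RoiRecord.sort_key):
        recomputed = recompute_value(r)
        flagged = r.declared_value is not None and abs(r.declared_value - recomputed) > tolerance
        check = RecordCheck(
            r.participant_id, r.level, r.slice_index, r.structure,
            r.declared_value, recomputed, flagged,
        )
        report.checks.append(check)
        if flagged:
            key = (r.participant_id, r.level, r.slice_index, r.is_length)
            by_slice.setdefault(key, []).append((r, check))

    for (pid, level, slc, _is_len), flagged_pairs in by_slice.items():
        if len(flagged_pairs) < 2:
            continue
        recs = [r for r, _ in flagged_pairs]
        declared = [r.declared_value for r in recs]
        recomputed = [c.recomputed for _, c in flagged_pairs]
        for perm in permutations(range(len(recs))):
            if all(
                abs(declared[perm[i]] - recomputed[i]) <= tolerance
                for i in range(len(recs))
            ):
                relabel = {
                    recs[i].structure: recs[perm[i]].structure for i in range(len(recs))
                }
                if any(k != v for k, v in relabel.items()):
                    report.suggestions.append(SwapSuggestion(pid, level, slc, relabel))
                break
    return report
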