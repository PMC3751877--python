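import numpy as np
import pytest

from discmorph import FileNameMeta, RoiPoint, RoiRecord, SliceGeometry


@pytest.fixture
def geom() -> SliceGeometry:
    return SliceGeometry(thickness=4.0, gap=0.8)


def length_record(pid, level, slc, structure, value, declared=None):
    return RoiRecord(
        participant_id=pid, level=level, slice_index=slc, structure=structure,
        points=(RoiPoint(0.0, 0.0), RoiPoint(value, 0.0)),
        declared_value=declared,
    )


def rect_record(pid, level, slc, structure, area, declared=None, height=2.0):
    w = area / height
    return RoiRecord(
        participant_id=pid, level=level, slice_index=slc, structure=structure,
        points=(RoiPoint(0, 0), RoiPoint(w, 0), RoiPoint(w, height), RoiPoint(0, height)),
        declared_value=declared,
    )


def full_session(pid="P01", level="L4-L5", first=2, last=8, missing=(),
                 value=10.0, area=40.0):
    """A complete single-participant session: every structure on every slice."""
    from discmorph import LENGTH_STRUCTURES, VOLUME_STRUCTURES, LEVEL_SEGMENTS

    records = []
    for s in range(first, last + 1):
        for structure in LENGTH_STRUCTURES:
            if structure == "ADSL" and s in missing:
                continue
            records.append(length_record(pid, level, s, structure, value))
        for structure in VOLUME_STRUCTURES:
            records.append(rect_record(pid, level, s, structure, area))
    meta = FileNameMeta(pid, LEVEL_SEGMENTS[level], first, last, tuple(missing))
    return records, meta


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
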