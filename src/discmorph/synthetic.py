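"""Two-rater measurement-study simulator with known ground truth.

The simulator emulates the study design the analysis modules expect: a cohort
of participants, one lumbar disc level each, measured on a sagittal series by
two sessions ("raters" A and B).  Each participant has a true slice window
(start slice in {1..4}, end slice in {6..9}); each rater may mis-select the
start/end slice by one with probability ``epsilon`` per end.  True structure
sizes vary between participants and between slices within a participant;
each rater's stored value is truth + rater bias + Gaussian error, floored at
zero.  Some slices lack a measurable dural sac and are recorded through the
filename bracket mechanism, identically for both raters (missingness is a
property of the scan, not of the rater).

Everything is derived from a single mandatory seed, so identical
configurations reproduce bit-identical studies, and the generator can emit
the per-session ROI CSV files so the full file-based pipeline
(roi_io -> morphometry -> agreement/reliability) is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import agreement, reliability
from .morphometry import SliceGeometry, build_measurement_table
from .roi_io import (
    LENGTH_STRUCTURES,
    LEVEL_SEGMENTS,
    VOLUME_STRUCTURES,
    FileNameMeta,
    RoiPoint,
    RoiRecord,
    render_filename,
    write_roi_csv,
)

START_CATEGORIES: tuple[int, ...] = (1, 2, 3, 4)
END_CATEGORIES: tuple[int, ...] = (6, 7, 8, 9)

#: Default true mean length per structure (mm), matching the magnitudes of the
#: structures the method measures: intervertebral heights around 9-15 mm, disc
#: length around 31 mm, disc-material extents of a few mm, dural sac ~8.5 mm.
DEFAULT_LENGTH_MEANS: dict[str, float] = {
    "AIVH": 14.7,
    "PIVH": 9.5,
    "IVDL": 31.1,
    "ADML": 3.5,
    "PDML": 3.6,
    "ADSL": 8.5,
}

#: Between-participant SD of the true structure size (mm).  Chosen as a
#: realistic anatomical spread (roughly 10-15% of the mean for the large
#: structures, relatively wider for the small disc-material extents).
DEFAULT_LENGTH_BETWEEN_SD: dict[str, float] = {
    "AIVH": 2.0,
    "PIVH": 1.5,
    "IVDL": 3.0,
    "ADML": 1.2,
    "PDML": 1.2,
    "ADSL": 1.5,
}

#: Per-slice traced-area truth (mm^2) for the volume structures; magnitudes
#: consistent with disc-material volumes of ~1-2 * 10^3 mm^3 over a 7-slice
#: window at 4.8 mm spacing.
DEFAULT_AREA_MEANS: dict[str, float] = {"VADM": 63.0, "VPDM": 39.0}
DEFAULT_AREA_BETWEEN_SD: dict[str, float] = {"VADM": 15.0, "VPDM": 10.0}


@dataclass(frozen=True)
class RaterParams:
    """Systematic bias and random error of one measurement session."""

    length_bias: float = 0.0       # mm, added to every length
    length_error_sd: float = 0.5   # mm, per-measurement Gaussian error
    area_bias: float = 0.0         # mm^2, added to every traced area
    area_error_sd: float = 4.0     # mm^2


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the two-rater simulator.

    The seed is mandatory; all randomness flows from it.  ``epsilon`` is the
    probability, per window end and per rater, of shifting the selected
    start/end slice by +/-1 (clamped to the ordinal category sets).
    """

    seed: int
    n_participants: int = 32
    level_probs: Mapping[str, float] = field(
        default_factory=lambda: {"L3-L4": 10 / 32, "L4-L5": 12 / 32, "L5-S1": 10 / 32}
    )
    start_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.10, 2: 0.70, 3: 0.15, 4: 0.05}
    )
    end_probs: Mapping[int, float] = field(
        default_factory=lambda: {6: 0.05, 7: 0.15, 8: 0.70, 9: 0.10}
    )
    length_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_MEANS)
    )
    length_between_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_BETWEEN_SD)
    )
    length_slice_sd: float = 0.8   # mm, truth variation across slices
    area_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AREA_MEANS)
    )
    area_between_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AREA_BETWEEN_SD)
    )
    area_slice_sd: float = 5.0     # mm^2
    rater_a: RaterParams = field(default_factory=RaterParams)
    rater_b: RaterParams = field(
        default_factory=lambda: RaterParams(length_bias=0.2, area_bias=2.0)
    )
    epsilon: float = 0.1
    p_missing_dural: float = 0.05
    geometry: SliceGeometry = field(default_factory=SliceGeometry)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in [0, 1]")
        if not (0.0 <= self.p_missing_dural <= 1.0):
            raise ValueError("p_missing_dural must lie in [0, 1]")
        for sd_map in (self.length_between_sd, self.area_between_sd):
            if any(v < 0 for v in sd_map.values()):
                raise ValueError("SDs must be >= 0")

    def noiseless(self) -> "SimConfig":
        """The same study with zero bias, error, slice confusion and missingness."""
        return replace(
            self,
            rater_a=RaterParams(0.0, 0.0, 0.0, 0.0),
            rater_b=RaterParams(0.0, 0.0, 0.0, 0.0),
            epsilon=0.0,
            p_missing_dural=0.0,
        )


@dataclass
class TruthBundle:
    """A simulated study: ground truth plus both raters' stored measurements."""

    config: SimConfig
    truth: pd.DataFrame                       # participant, level, slice, structure, value
    windows: pd.DataFrame                     # participant, level, rater, start, end + truth
    missing_dural: dict[str, tuple[int, ...]]
    records: dict[str, list[RoiRecord]]       # rater -> ROI records
    metas: dict[str, list[FileNameMeta]]      # rater -> filename metadata

    def measurement_table(self, rater: str) -> pd.DataFrame:
        return build_measurement_table(
            self.records[rater], self.config.geometry, self.metas[rater]
        )

    @property
    def n_window_mismatches(self) -> int:
        w = self.windows.pivot_table(
            index=["participant", "level"], columns="rater",
            values=["start", "end"], aggfunc="first",
        )
        return int(
            ((w[("start", "A")] != w[("start", "B")])
             | (w[("end", "A")] != w[("end", "B")])).sum()
        )

    def slice_choice_pairs(self, which: str) -> list[tuple[int, int]]:
        """Per-participant (rater A, rater B) start- or end-slice choices."""
        if which not in ("start", "end"):
            raise ValueError("which must be 'start' or 'end'")
        w = self.windows.pivot_table(
            index=["participant", "level"], columns="rater",
            values=which, aggfunc="first",
        )
        return [(int(a), int(b)) for a, b in zip(w["A"], w["B"])]


def _categorical(rng: np.random.Generator, probs: Mapping) -> int | str:
    keys = list(probs.keys())
    p = np.asarray([probs[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def _shift_choice(rng: np.random.Generator, value: int, categories: tuple[int, ...],
                  epsilon: float) -> int:
    if rng.random() < epsilon:
        shifted = value + (1 if rng.random() < 0.5 else -1)
        if shifted in categories:
            return shifted
    return value


def _length_record(pid: str, level: str, slc: int, structure: str, value: float,
                   declared_decimals: int = 3) -> RoiRecord:
    # points along the x-axis: only the separation matters downstream
    return RoiRecord(
        participant_id=pid, level=level, slice_index=slc, structure=structure,
        points=(RoiPoint(0.0, 0.0), RoiPoint(round(value, 6), 0.0)),
        declared_value=round(round(value, 6), declared_decimals),
    )


def _area_record(pid: str, level: str, slc: int, structure: str, area: float,
                 declared_decimals: int = 3) -> RoiRecord:
    # rectangle of fixed 4 mm height and width area/4
    w = round(area, 6) / 4.0
    return RoiRecord(
        participant_id=pid, level=level, slice_index=slc, structure=structure,
        points=(RoiPoint(0.0, 0.0), RoiPoint(w, 0.0), RoiPoint(w, 4.0), RoiPoint(0.0, 4.0)),
        declared_value=round(w * 4.0, declared_decimals),
    )


def simulate_study(config: SimConfig, out_dir: str | Path | None = None) -> TruthBundle:
    """Simulate a two-rater study; optionally write it as ROI CSV file sets.

    With ``out_dir`` given, writes ``<out>/truth.csv`` and one ROI CSV per
    participant under ``<out>/rater_A/`` and ``<out>/rater_B/``, named with
    the filename convention (including missing-dural brackets).
    """
    rng = np.random.default_rng(config.seed)
    all_slices = range(min(START_CATEGORIES), max(END_CATEGORIES) + 1)

    truth_rows: list[dict] = []
    window_rows: list[dict] = []
    missing_dural: dict[str, tuple[int, ...]] = {}
    records: dict[str, list[RoiRecord]] = {"A": [], "B": []}
    metas: dict[str, list[FileNameMeta]] = {"A": [], "B": []}

    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        level = str(_categorical(rng, config.level_probs))
        start_true = int(_categorical(rng, config.start_probs))
        end_true = int(_categorical(rng, config.end_probs))
        if start_true >= end_true:  # cannot occur with the default category sets
            raise RuntimeError("infeasible true window drawn")
        missing = tuple(
            s for s in all_slices if rng.random() < config.p_missing_dural
        )
        missing_dural[pid] = missing

        # ground truth per slice
        truth: dict[tuple[int, str], float] = {}
        for structure in LENGTH_STRUCTURES:
            b = rng.normal(0.0, config.length_between_sd[structure])
            for s in all_slices:
                v = max(
                    0.0,
                    config.length_means[structure] + b
                    + rng.normal(0.0, config.length_slice_sd),
                )
                truth[(s, structure)] = v
                truth_rows.append(
                    dict(participant=pid, level=level, slice=s,
                         structure=structure, value=v)
                )
        for structure in VOLUME_STRUCTURES:
            b = rng.normal(0.0, config.area_between_sd[structure])
            for s in all_slices:
                v = max(
                    0.0,
                    config.area_means[structure] + b
                    + rng.normal(0.0, config.area_slice_sd),
                )
                truth[(s, structure)] = v
                truth_rows.append(
                    dict(participant=pid, level=level, slice=s,
                         structure=structure, value=v)
                )

        for rater, params in (("A", config.rater_a), ("B", config.rater_b)):
            start = _shift_choice(rng, start_true, START_CATEGORIES, config.epsilon)
            end = _shift_choice(rng, end_true, END_CATEGORIES, config.epsilon)
            if start >= end:
                raise RuntimeError("infeasible realized window")
            window_rows.append(
                dict(participant=pid, level=level, rater=rater,
                     start=start, end=end, start_true=start_true, end_true=end_true)
            )
            window = range(start, end + 1)
            miss_in_window = tuple(s for s in missing if start <= s <= end)
            metas[rater].append(
                FileNameMeta(pid, LEVEL_SEGMENTS[level], start, end, miss_in_window)
            )
            for s in window:
                for structure in LENGTH_STRUCTURES:
                    if structure == "ADSL" and s in miss_in_window:
                        continue
                    v = max(
                        0.0,
                        truth[(s, structure)] + params.length_bias
                        + (rng.normal(0.0, params.length_error_sd)
                           if params.length_error_sd > 0 else 0.0),
                    )
                    records[rater].append(_length_record(pid, level, s, structure, v))
                for structure in VOLUME_STRUCTURES:
                    # floored at the smallest traceable outline (0.01 mm^2): a
                    # stored ROI polygon cannot have zero area
                    v = max(
                        0.01,
                        truth[(s, structure)] + params.area_bias
                        + (rng.normal(0.0, params.area_error_sd)
                           if params.area_error_sd > 0 else 0.0),
                    )
                    records[rater].append(_area_record(pid, level, s, structure, v))

    bundle = TruthBundle(
        config=config,
        truth=pd.DataFrame(truth_rows),
        windows=pd.DataFrame(window_rows),
        missing_dural=missing_dural,
        records=records,
        metas=metas,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.truth.to_csv(out / "truth.csv", index=False, lineterminator="\n")
        for rater in ("A", "B"):
            rdir = out / f"rater_{rater}"
            rdir.mkdir(exist_ok=True)
            by_meta: dict[str, list[RoiRecord]] = {}
            for r in records[rater]:
                by_meta.setdefault(r.participant_id, []).append(r)
            for meta in metas[rater]:
                write_roi_csv(
                    by_meta[meta.participant_id], rdir / render_filename(meta)
                )
    return bundle


def expected_difference_stats(config: SimConfig) -> dict[str, float]:
    """Closed-form targets for the between-rater difference distribution.

    For length parameters the difference A - B has mean
    ``bias_A - bias_B`` and SD ``sqrt(sd_A^2 + sd_B^2)`` (ignoring the
    zero-floor, negligible for the default structure sizes), hence an expected
    LOA half-width of ``1.96 * sqrt(sd_A^2 + sd_B^2)``.
    """
    bias = config.rater_a.length_bias - config.rater_b.length_bias
    sd = float(np.hypot(config.rater_a.length_error_sd, config.rater_b.length_error_sd))
    return {
        "length_bias": bias,
        "length_sd_diff": sd,
        "length_loa_half_width": 1.96 * sd,
    }


def expected_icc(config: SimConfig) -> float:
    """Closed-form ICC(2,1) target for slice-level length measurements.

    Between-unit truth variance pools the participant and slice components
    (averaged over structures); the rater component is the variance of the two
    fixed biases and the error component the mean error variance.
    """
    sigma_s2 = float(
        np.mean([v**2 for v in config.length_between_sd.values()])
    ) + config.length_slice_sd**2
    db = config.rater_a.length_bias - config.rater_b.length_bias
    sigma_r2 = db**2 / 2.0
    sigma_e2 = (
        config.rater_a.length_error_sd**2 + config.rater_b.length_error_sd**2
    ) / 2.0
    return sigma_s2 / (sigma_s2 + sigma_r2 + sigma_e2)


def recover_parameters(bundle: TruthBundle) -> pd.DataFrame:
    """Side-by-side of simulated truth and pipeline estimates.

    Runs the full agreement + reliability battery on the bundle's measurement
    tables and reports, per parameter, the estimated bias, SD of differences,
    LOA half-width and ICC(2,1) next to the closed-form expectations implied
    by the configuration (length parameters only; CSA/volume expectations
    scale with the realized windows and are left blank).
    """
    table_a = bundle.measurement_table("A")
    table_b = bundle.measurement_table("B")
    series, _ = agreement.pair_measurements(table_a, table_b)
    exp = expected_difference_stats(bundle.config)
    exp_icc = expected_icc(bundle.config)
    rows = []
    for parameter, s in series.items():
        ba = agreement.bland_altman(s)
        try:
            icc = reliability.icc_2_1(np.column_stack([s.a, s.b])).estimate
        except ValueError:
            icc = float("nan")
        is_len = parameter in LENGTH_STRUCTURES
        rows.append(
            dict(
                parameter=parameter,
                n=ba.n,
                bias=ba.bias,
                expected_bias=exp["length_bias"] if is_len else float("nan"),
                sd_diff=ba.sd_diff,
                expected_sd_diff=exp["length_sd_diff"] if is_len else float("nan"),
                loa_half_width=(ba.loa_upper - ba.loa_lower) / 2.0,
                expected_loa_half_width=(
                    exp["length_loa_half_width"] if is_len else float("nan")
                ),
                icc=icc,
                expected_icc=exp_icc if is_len else float("nan"),
            )
        )
    return pd.DataFrame(rows)
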