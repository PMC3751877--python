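"""Bland-Altman agreement analysis between two measurement sessions.

Pairing rules: per-slice length measurements are compared only on slices both
sessions measured; per-participant CSA and volume parameters are compared only
for participants whose measured slice window (start and end slice) agrees
between sessions — all other participants are excluded and logged.  The
dural-sac CSA (CDS) uses its own criterion, identity of the two sessions' ADSL
slice sets, since dural-sac slices have their own missingness channel.

For paired differences ``d_i = a_i - b_i``::

    bias        d_bar = mean(d)
    sd_diff     s_d   = sample SD of d (n-1 denominator)
    95% LOA     d_bar +/- 1.96 * s_d
    CI of bias  d_bar +/- 1.96 * s_d / sqrt(n)

Bias is considered present when the CI of the bias excludes zero.  The LOA
span as a proportion of the mean measured value, ``(upper - lower)/mean * 100``
(reported to one decimal), summarizes relative precision; values below 50% are
conventionally treated as acceptable.  Differences falling outside the LOA are
flagged as outliers for human review against the original ROI files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .roi_io import CSA_FOR_LENGTH, CSA_STRUCTURES, LENGTH_STRUCTURES, VOLUME_STRUCTURES

#: Parameters analysed at slice level vs participant level.
SLICE_PARAMETERS: tuple[str, ...] = LENGTH_STRUCTURES
PARTICIPANT_PARAMETERS: tuple[str, ...] = CSA_STRUCTURES + VOLUME_STRUCTURES
ALL_PARAMETERS: tuple[str, ...] = SLICE_PARAMETERS + PARTICIPANT_PARAMETERS

DEFAULT_LOA_MULTIPLIER = 1.96


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP) if x >= 0 else \
        -((-Decimal(repr(float(x)))).quantize(q, rounding=ROUND_HALF_UP))
    return float(d)


@dataclass(frozen=True)
class PairedSeries:
    """Same-unit measurement pairs for one parameter across two sessions."""

    parameter: str
    unit_ids: tuple
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if a.shape != b.shape or a.ndim != 1 or len(self.unit_ids) != a.size:
            raise ValueError("unit_ids, a and b must be 1-d and of equal length")
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("paired series must be complete (no missing values)")

    @property
    def n(self) -> int:
        return int(self.a.size)

    @property
    def diffs(self) -> np.ndarray:
        return self.a - self.b

    @property
    def means(self) -> np.ndarray:
        return (self.a + self.b) / 2.0


@dataclass(frozen=True)
class Exclusion:
    participant: str
    level: str
    parameter: str
    reason: str


@dataclass(frozen=True)
class BlandAltmanResult:
    parameter: str
    n: int
    mean_of_measurements: float
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple[float, float]
    loa_proportion: float
    bias_present: bool
    degenerate: bool
    outlier_ids: tuple = ()


def _session_windows(table: pd.DataFrame) -> dict[tuple[str, str], dict]:
    """Per (participant, level): slice window from non-ADSL length rows and
    the set of ADSL slices (its missingness channel is separate)."""
    lengths = table[table["structure"].isin(LENGTH_STRUCTURES) & table["slice"].notna()]
    out: dict[tuple[str, str], dict] = {}
    for (pid, level), grp in lengths.groupby(["participant", "level"], sort=True):
        core = grp[grp["structure"] != "ADSL"]["slice"].astype(int)
        adsl = frozenset(grp[grp["structure"] == "ADSL"]["slice"].astype(int))
        out[(pid, level)] = {
            "window": (int(core.min()), int(core.max())) if len(core) else None,
            "adsl_slices": adsl,
        }
    return out


def pair_measurements(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[dict[str, PairedSeries], list[Exclusion]]:
    """Pair two measurement tables per parameter, applying the exclusion rules.

    Returns a parameter -> :class:`PairedSeries` mapping (parameters with no
    pairs are omitted) and the exclusion log.  Raises ``ValueError`` when the
    tables share no participants.
    """
    common = set(zip(table_a["participant"], table_a["level"])) & set(
        zip(table_b["participant"], table_b["level"])
    )
    if not common:
        raise ValueError("measurement tables share no participant-levels")
    exclusions: list[Exclusion] = []
    for pid, level in sorted(
        set(zip(table_a["participant"], table_a["level"])) ^ set(
            zip(table_b["participant"], table_b["level"])
        )
    ):
        exclusions.append(Exclusion(pid, level, "all", "present in only one session"))

    series: dict[str, PairedSeries] = {}

    # slice-level length parameters: common slices only
    la = table_a[table_a["slice"].notna()]
    lb = table_b[table_b["slice"].notna()]
    merged = la.merge(
        lb,
        on=["participant", "level", "slice", "structure"],
        suffixes=("_a", "_b"),
    ).sort_values(["structure", "participant", "level", "slice"])
    for structure in SLICE_PARAMETERS:
        sub = merged[merged["structure"] == structure]
        if len(sub) == 0:
            continue
        series[structure] = PairedSeries(
            parameter=structure,
            unit_ids=tuple(
                (p, l, int(s))
                for p, l, s in zip(sub["participant"], sub["level"], sub["slice"])
            ),
            a=sub["value_a"].to_numpy(),
            b=sub["value_b"].to_numpy(),
        )

    # participant-level parameters: windows must agree
    win_a = _session_windows(table_a)
    win_b = _session_windows(table_b)
    included: dict[str, list] = {p: [] for p in PARTICIPANT_PARAMETERS}
    agg_a = table_a[table_a["slice"].isna()].set_index(["participant", "level", "structure"])
    agg_b = table_b[table_b["slice"].isna()].set_index(["participant", "level", "structure"])
    window_params = tuple(p for p in PARTICIPANT_PARAMETERS if p != "CDS")
    for key in sorted(common):
        pid, level = key
        wa, wb = win_a.get(key), win_b.get(key)
        if wa is None or wb is None:
            continue
        if wa["window"] == wb["window"]:
            for p in window_params:
                included[p].append(key)
        else:
            exclusions.append(
                Exclusion(
                    pid, level, "CSA/volume",
                    f"slice window mismatch: {wa['window'][0]}-{wa['window'][1]} vs "
                    f"{wb['window'][0]}-{wb['window'][1]}",
                )
            )
        if wa["adsl_slices"] == wb["adsl_slices"]:
            included["CDS"].append(key)
        else:
            exclusions.append(
                Exclusion(
                    pid, level, "CDS",
                    "dural-sac slice sets differ: "
                    f"{sorted(wa['adsl_slices'])} vs {sorted(wb['adsl_slices'])}",
                )
            )
    for p in PARTICIPANT_PARAMETERS:
        keys = included[p]
        if not keys:
            continue
        a_vals = [float(agg_a.loc[(pid, level, p), "value"]) for pid, level in keys]
        b_vals = [float(agg_b.loc[(pid, level, p), "value"]) for pid, level in keys]
        series[p] = PairedSeries(
            parameter=p, unit_ids=tuple(keys),
            a=np.array(a_vals), b=np.array(b_vals),
        )
    return series, exclusions


def loa_proportion(loa_lower: float, loa_upper: float, mean: float) -> float:
    """LOA span as a percentage of the mean value, to one decimal.

    ``((upper + (-1)*lower) / mean) * 100``; values below 50% indicate
    acceptable relative precision.  Requires ``mean > 0``.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0 for a LOA proportion")
    return round_half_away((loa_upper - loa_lower) / mean * 100.0, 1)


def bland_altman(
    series: PairedSeries, multiplier: float = DEFAULT_LOA_MULTIPLIER
) -> BlandAltmanResult:
    """Bland-Altman bias, LOA, CI of bias and LOA-proportion for one parameter."""
    n = series.n
    if n < 2:
        raise ValueError(f"{series.parameter}: need at least 2 pairs, got {n}")
    d = series.diffs
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if not math.isfinite(sd):
        raise ValueError(f"{series.parameter}: SD of differences is not finite")
    degenerate = sd == 0.0
    loa_lo = bias - multiplier * sd
    loa_hi = bias + multiplier * sd
    half = multiplier * sd / math.sqrt(n)
    ci = (bias - half, bias + half)
    mean_all = float(np.mean(series.means))
    prop = loa_proportion(loa_lo, loa_hi, mean_all) if mean_all > 0 else float("nan")
    result = BlandAltmanResult(
        parameter=series.parameter,
        n=n,
        mean_of_measurements=mean_all,
        bias=bias,
        sd_diff=sd,
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        ci_bias=ci,
        loa_proportion=prop,
        bias_present=not (ci[0] <= 0.0 <= ci[1]),
        degenerate=degenerate,
    )
    outliers = flag_outliers(series, result)
    return BlandAltmanResult(**{**result.__dict__, "outlier_ids": tuple(outliers)})


def flag_outliers(series: PairedSeries, result: BlandAltmanResult) -> list:
    """Unit ids whose difference falls outside the LOA, most extreme first.

    Flagged ids are meant to be cross-referenced back to their ROI records for
    human review; assigning a cause stays a human task.
    """
    d = series.diffs
    mask = (d < result.loa_lower) | (d > result.loa_upper)
    idx = np.nonzero(mask)[0]
    order = idx[np.argsort(-np.abs(d[idx] - result.bias), kind="stable")]
    return [series.unit_ids[i] for i in order]


def loa_precision_factor(n: int) -> float:
    """Half-width of the 95% CI of each LOA limit, as a multiple of s_d.

    Large-sample approximation ``1.96 * sqrt(3/n)``; monotonically decreasing
    in the number of pairs n.
    """
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    return 1.96 * math.sqrt(3.0 / n)


def plot_data(series: PairedSeries, result: BlandAltmanResult) -> pd.DataFrame:
    """Bland-Altman plot data: per-pair mean and difference plus bias/LOA lines."""
    return pd.DataFrame(
        {
            "parameter": result.parameter,
            "unit_id": ["/".join(str(p) for p in u) if isinstance(u, tuple) else str(u)
                        for u in series.unit_ids],
            "mean": series.means,
            "difference": series.diffs,
            "bias": result.bias,
            "loa_lower": result.loa_lower,
            "loa_upper": result.loa_upper,
        }
    )


def printed_loa_attainable(
    bias: float,
    sd: float,
    loa_lower: float,
    loa_upper: float,
    *,
    bias_decimals: int = 1,
    sd_decimals: int = 1,
    loa_decimals: int = 1,
    multiplier: float = DEFAULT_LOA_MULTIPLIER,
) -> bool:
    """Whether printed LOA are consistent with printed bias and SD under rounding.

    Checks, by exact interval arithmetic, whether some unrounded bias ``m`` and
    SD ``s`` within the half-ulp neighbourhoods of the printed values produce
    ``m - multiplier*s`` and ``m + multiplier*s`` that round to the printed LOA
    bounds.  Used as a consistency audit of reported agreement tables.
    """
    hb = 0.5 * 10.0 ** (-bias_decimals)
    hs = 0.5 * 10.0 ** (-sd_decimals)
    hl = 0.5 * 10.0 ** (-loa_decimals)
    c = multiplier
    # feasibility region for s from pairwise constraints on m
    s_lo = max(
        sd - hs,
        (loa_upper - loa_lower - 2 * hl) / (2 * c),
        (loa_upper - hl - bias - hb) / c,
        (bias - hb - loa_lower - hl) / c,
        0.0,
    )
    s_hi = min(
        sd + hs,
        (loa_upper - loa_lower + 2 * hl) / (2 * c),
        (loa_upper + hl - bias + hb) / c,
        (bias + hb - loa_lower + hl) / c,
    )
    return s_lo <= s_hi + 1e-12
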