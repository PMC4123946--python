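"""Per-pixel land-use trajectory metrics: ASF, PALU and FC.

For every observation date and every pixel:

* **ASF** (age of secondary forest) — years the pixel has been continuously
  SF since the start of the current SF run. A run that starts at the first
  stack date is a *minimum* age: the true abandonment date precedes the
  series, so the value carries a censored flag.
* **PALU** (period of active land use) — duration in years of the
  uninterrupted NF run immediately preceding the current SF run. Pixels SF
  from the first date (no observed prior clearance) get PALU = 0 with a
  ``palu_zero`` flag.
* **FC** (frequency of clearance) — cumulative count of observed MF→NF or
  SF→NF transitions. Pixels that were NF at the first date and have never
  shown a clearance carry ``fc_nf_start``; their single unobserved clearance
  places them in the low FC class when binning.

Events happen between acquisitions, so a state change is dated at the first
date the new state is observed; durations accumulate in decimal years and
are floored to whole years when binned. A NODATA date is transparent: the
run continues across it if the same label resumes, and a label change across
the gap is dated at the first post-gap observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .codes import MF, NF, NODATA, SF, THEMATIC, THEMATIC_LABELS, WATER
from .core import ClassifiedStack, decimal_year, format_date


@dataclass(frozen=True)
class BinSpec:
    """Ordered, exhaustive classes for a trajectory metric.

    ``upper_bounds`` are inclusive upper edges in whole years (the last one
    may be ``inf``); values are floored to integer years before binning.
    """

    metric: str
    labels: tuple[str, ...]
    upper_bounds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.upper_bounds):
            raise ValueError("labels and upper_bounds must have equal length")
        if list(self.upper_bounds) != sorted(self.upper_bounds):
            raise ValueError("upper_bounds must be non-decreasing")

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Class index per cell (-1 where the value is undefined/NaN)."""
        vals = np.asarray(values, dtype=float)
        out = np.full(vals.shape, -1, dtype=np.int8)
        defined = ~np.isnan(vals)
        floored = np.floor(vals[defined])
        if floored.size and floored.max() > self.upper_bounds[-1]:
            raise ValueError(f"value {floored.max()} outside {self.metric} bin support")
        idx = np.searchsorted(np.asarray(self.upper_bounds), floored, side="left")
        out[defined] = idx.astype(np.int8)
        return out


#: regrowth age: initial <=5 yr, intermediate 6-15 yr, advanced >=16 yr
ASF_BINS = BinSpec("asf", ("initial", "intermediate", "advanced"), (5, 15, float("inf")))
#: active-use period: short <=2 yr, medium 3-4 yr, long >=5 yr
PALU_BINS = BinSpec("palu", ("short", "medium", "long"), (2, 4, float("inf")))
#: clearance count: low 1x, medium 2x, high >=3x (flagged zeros count as low)
FC_BINS = BinSpec("fc", ("low", "medium", "high"), (1, 2, float("inf")))


@dataclass(frozen=True)
class MetricMaps:
    """Per-date metric grids, each of shape ``(n_dates, rows, cols)``.

    ``asf`` and ``palu`` are decimal years, NaN wherever the pixel is not SF
    at that date (or unobserved); ``fc`` is a cumulative integer count,
    -1 on WATER cells.
    """

    dates: tuple
    asf: np.ndarray = field(repr=False)
    asf_censored: np.ndarray = field(repr=False)
    palu: np.ndarray = field(repr=False)
    palu_zero: np.ndarray = field(repr=False)
    fc: np.ndarray = field(repr=False)
    fc_nf_start: np.ndarray = field(repr=False)


def compute_metrics(stack: ClassifiedStack) -> MetricMaps:
    """Single chronological traversal computing ASF, PALU and FC together."""
    grids = stack.grids()
    times = stack.times
    n, shape = stack.n_dates, stack.shape

    prev = np.full(shape, NODATA, dtype=np.uint8)  # last non-NODATA label
    sf_onset = np.full(shape, np.nan)
    nf_start = np.full(shape, np.nan)
    palu_cur = np.full(shape, np.nan)
    censored = np.zeros(shape, dtype=bool)
    pzero = np.zeros(shape, dtype=bool)
    fc = np.zeros(shape, dtype=np.int32)
    first_label = grids[0]

    asf = np.full((n, *shape), np.nan)
    asf_c = np.zeros((n, *shape), dtype=bool)
    palu = np.full((n, *shape), np.nan)
    palu_z = np.zeros((n, *shape), dtype=bool)
    fc_out = np.zeros((n, *shape), dtype=np.int32)
    fc_nfs = np.zeros((n, *shape), dtype=bool)

    for k in range(n):
        g = grids[k]
        t = times[k]
        obs = (g != NODATA) & (g != WATER)
        first_obs = obs & (prev == NODATA)

        # --- first observation of a pixel ---
        f_sf = first_obs & (g == SF)
        sf_onset[f_sf] = t
        palu_cur[f_sf] = 0.0
        if k == 0:
            # SF standing at the very first date: minimum age, no prior NF
            censored[f_sf] = True
            pzero[f_sf] = True
        f_nf = first_obs & (g == NF)
        nf_start[f_nf] = t

        # --- transitions between observed states ---
        seen = obs & (prev != NODATA) & (g != prev)
        clear = seen & (g == NF) & ((prev == MF) | (prev == SF))
        fc[clear] += 1
        nf_start[clear] = t
        ended_sf = clear & (prev == SF)
        sf_onset[ended_sf] = np.nan
        censored[ended_sf] = False
        pzero[ended_sf] = False

        regrow = seen & (g == SF) & (prev == NF)
        sf_onset[regrow] = t
        palu_cur[regrow] = t - nf_start[regrow]
        censored[regrow] = False
        pzero[regrow] = False

        # MF -> SF with the intervening clearance unobserved (long gap):
        # the run starts now but no NF period was seen, so PALU = 0.
        skip = seen & (g == SF) & (prev == MF)
        sf_onset[skip] = t
        palu_cur[skip] = 0.0
        censored[skip] = False
        pzero[skip] = False

        # return to MF (only possible on an uncorrected stack): runs end
        back = seen & (g == MF)
        sf_onset[back] = np.nan
        nf_start[back] = np.nan
        censored[back] = False
        pzero[back] = False

        prev[obs] = g[obs]

        is_sf = obs & (g == SF)
        asf[k][is_sf] = t - sf_onset[is_sf]
        asf_c[k] = censored & is_sf
        palu[k][is_sf] = palu_cur[is_sf]
        palu_z[k] = pzero & is_sf
        fc_out[k] = fc
        fc_out[k][stack.water_mask] = -1
        fc_nfs[k] = (first_label == NF) & (fc == 0)

    return MetricMaps(
        dates=stack.dates, asf=asf, asf_censored=asf_c,
        palu=palu, palu_zero=palu_z, fc=fc_out, fc_nf_start=fc_nfs,
    )


def compute_asf(stack: ClassifiedStack) -> MetricMaps:
    """ASF per pixel and date (full MetricMaps; see :func:`compute_metrics`)."""
    return compute_metrics(stack)


def compute_palu(stack: ClassifiedStack) -> MetricMaps:
    """PALU per pixel and date (full MetricMaps; see :func:`compute_metrics`)."""
    return compute_metrics(stack)


def compute_fc(stack: ClassifiedStack) -> MetricMaps:
    """FC per pixel and date (full MetricMaps; see :func:`compute_metrics`)."""
    return compute_metrics(stack)


def bin_metric(values: np.ndarray, spec: BinSpec) -> np.ndarray:
    """Map a metric grid to class indices (-1 = undefined/NODATA)."""
    return spec.assign(values)


def effective_fc(metrics: MetricMaps, k: int) -> np.ndarray:
    """FC grid at date ``k`` with flagged zero counts promoted to 1.

    Pixels currently SF whose clearance was never observed — SF standing at
    the first date, or NF at the first date that later regrew — underwent at
    least one (pre-series) clearance, so for class binning they are counted
    in the low class (1 time).
    """
    fc = metrics.fc[k].astype(float)
    fc[metrics.fc[k] < 0] = np.nan
    is_sf = ~np.isnan(metrics.asf[k])
    promote = is_sf & (metrics.fc[k] == 0)
    fc[promote] = 1
    fc[~is_sf & (metrics.fc[k] == 0)] = np.nan  # FC class undefined off-SF zeros
    return fc


def crosstab_palu_fc(metrics: MetricMaps, k: int = -1) -> pd.DataFrame:
    """PALU-class x FC-class percentage of SF area at date index ``k``.

    Cells sum to 100 over the pixels that are SF at the date.
    """
    if k < 0:
        k = len(metrics.dates) + k
    is_sf = ~np.isnan(metrics.asf[k])
    n_sf = int(is_sf.sum())
    if n_sf == 0:
        raise ValueError(f"no SF pixels at date {format_date(metrics.dates[k])}")
    p_cls = PALU_BINS.assign(metrics.palu[k])
    f_cls = FC_BINS.assign(effective_fc(metrics, k))
    tab = np.zeros((3, 3))
    sel = is_sf & (p_cls >= 0) & (f_cls >= 0)
    np.add.at(tab, (p_cls[sel], f_cls[sel]), 1)
    tab = 100.0 * tab / n_sf
    return pd.DataFrame(tab, index=list(PALU_BINS.labels), columns=list(FC_BINS.labels))


def landcover_proportion_table(stack: ClassifiedStack) -> pd.DataFrame:
    """Per-date percentage of MF/NF/SF over the thematic area.

    WATER and NODATA cells are excluded from the denominator.
    """
    rows = []
    for m in stack.maps:
        counts = {lab: np.count_nonzero(m.grid == code) for lab, code in zip(THEMATIC_LABELS, THEMATIC)}
        total = sum(counts.values())
        row = {"date": format_date(m.date), "year": m.date.year}
        for lab in THEMATIC_LABELS:
            row[lab] = 100.0 * counts[lab] / total if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def ols_trend(years: np.ndarray, percents: np.ndarray) -> tuple[float, float, float]:
    """OLS of class percentage on calendar year: (slope %/yr, intercept, R^2)."""
    years = np.asarray(years, dtype=float)
    percents = np.asarray(percents, dtype=float)
    if years.size < 3:
        raise ValueError("trend needs at least three points")
    if np.ptp(years) == 0:
        raise ValueError("years are constant; trend undefined")
    res = _stats.linregress(years, percents)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def landcover_trends(stack: ClassifiedStack) -> pd.DataFrame:
    """Linear trend of each thematic class proportion against year."""
    table = landcover_proportion_table(stack)
    rows = []
    for lab in THEMATIC_LABELS:
        slope, intercept, r2 = ols_trend(table["year"].to_numpy(), table[lab].to_numpy())
        rows.append({"class": lab, "slope_pct_per_yr": slope, "intercept": intercept, "r_squared": r2})
    return pd.DataFrame(rows)


def sf_class_proportion_curves(
    stack: ClassifiedStack, metrics: MetricMaps, spec: BinSpec
) -> pd.DataFrame:
    """Share of current SF area per metric class, by years since SF onset.

    The site-level onset is the first date at which any *non-censored* SF
    exists (first-date SF has unknown onset and does not define it, though
    it is included in the shares). One row per date from the onset on;
    columns are the class labels plus ``years_since_onset``; shares sum
    to 100 where any binnable SF exists.
    """
    times = stack.times
    onset_k = None
    for k in range(stack.n_dates):
        has_new_sf = np.any(~np.isnan(metrics.asf[k]) & ~metrics.asf_censored[k])
        if has_new_sf:
            onset_k = k
            break
    if onset_k is None:
        return pd.DataFrame(columns=["date", "years_since_onset", *spec.labels])
    rows = []
    for k in range(onset_k, stack.n_dates):
        is_sf = ~np.isnan(metrics.asf[k])
        if spec.metric == "asf":
            cls = spec.assign(metrics.asf[k])
        elif spec.metric == "palu":
            cls = spec.assign(metrics.palu[k])
        elif spec.metric == "fc":
            cls = spec.assign(effective_fc(metrics, k))
        else:
            raise ValueError(f"unknown metric {spec.metric!r}")
        sel = is_sf & (cls >= 0)
        n = int(sel.sum())
        row = {
            "date": format_date(stack.dates[k]),
            "years_since_onset": times[k] - times[onset_k],
        }
        for i, lab in enumerate(spec.labels):
            row[lab] = 100.0 * int(((cls == i) & sel).sum()) / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
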