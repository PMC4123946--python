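"""Transition areas, annual deforestation/regrowth rates and period typology.

Two relative-rate conventions are exposed. The first is the standard
annualized logarithmic rate of change between two area measurements,

    r = (100 / dt) * ln(A2 / A1)        [% per year]

which is exact for compound change of a class area. The second normalizes
the transition area by the source-class area,

    r = 100 * T / (A_source(t1) * dt)   [% per year]

which is the convention needed to express reclearance and regrowth
intensities relative to the (small) source class; it can legitimately
exceed 100 % per year when the gap is longer than one year or the flux
exceeds the standing area of the reference class. The absolute rate is
always R = T / dt in hectares per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import MF, NF, NODATA, SF, THEMATIC, THEMATIC_LABELS, WATER
from .core import ClassifiedStack, LandCoverMap, decimal_years, format_date

PROCESSES = ("mf_deforestation", "sf_deforestation", "total_deforestation", "regrowth")


@dataclass(frozen=True)
class TransitionSummary:
    """Cross-tabulated thematic transition areas between two dates."""

    t1: object
    t2: object
    dt_years: float
    #: 3x3 matrix in hectares, rows = class at t1, cols = class at t2,
    #: both indexed in THEMATIC order (MF, NF, SF); only cells that are
    #: thematic (non-WATER, non-NODATA) at BOTH dates contribute.
    matrix_ha: np.ndarray = field(repr=False)
    #: standing class areas (ha) at t1 and t2 over the full thematic area
    areas_t1: dict = field(default_factory=dict)
    areas_t2: dict = field(default_factory=dict)

    def _cell(self, a: int, b: int) -> float:
        return float(self.matrix_ha[THEMATIC.index(a), THEMATIC.index(b)])

    @property
    def t_mf_to_nf(self) -> float:
        return self._cell(MF, NF)

    @property
    def t_sf_to_nf(self) -> float:
        return self._cell(SF, NF)

    @property
    def t_nf_to_sf(self) -> float:
        return self._cell(NF, SF)


class RateError(ValueError):
    pass


def transition_areas(map1: LandCoverMap, map2: LandCoverMap, dt: float) -> TransitionSummary:
    """Exact 3x3 thematic cross-tabulation times pixel area.

    Cells that are WATER on either date are excluded by construction of the
    common mask; cells NODATA on either date are excluded from the matrix
    (their label at one end is unknown).
    """
    if map1.shape != map2.shape:
        raise RateError(f"shape mismatch {map1.shape} vs {map2.shape}")
    if not dt > 0:
        raise RateError("dt must be positive")
    g1, g2 = map1.grid, map2.grid
    valid = (g1 != WATER) & (g2 != WATER) & (g1 != NODATA) & (g2 != NODATA)
    # codes 1..3 -> 0..2; joint index into a 3x3 tally
    idx = (g1[valid].astype(np.int64) - 1) * 3 + (g2[valid].astype(np.int64) - 1)
    counts = np.bincount(idx, minlength=9).reshape(3, 3)
    matrix = counts.astype(float) * map1.pixel_area_ha
    areas1 = {lab: map1.class_area_ha(code) for lab, code in zip(THEMATIC_LABELS, THEMATIC)}
    areas2 = {lab: map2.class_area_ha(code) for lab, code in zip(THEMATIC_LABELS, THEMATIC)}
    return TransitionSummary(
        t1=map1.date, t2=map2.date, dt_years=dt, matrix_ha=matrix,
        areas_t1=areas1, areas_t2=areas2,
    )


def relative_rate_ln(a1: float, a2: float, dt: float) -> float:
    """Annualized logarithmic rate of change, % per year."""
    if not dt > 0:
        raise RateError("dt must be positive")
    if a1 <= 0 or a2 <= 0:
        raise RateError(f"areas must be positive for the log rate (got {a1}, {a2})")
    return (100.0 / dt) * math.log(a2 / a1)


def absolute_rate(a1: float, a2: float, dt: float) -> float:
    """Net area change per year, ha / yr."""
    if not dt > 0:
        raise RateError("dt must be positive")
    return (a2 - a1) / dt


@dataclass(frozen=True)
class RateRecord:
    """Relative (% / yr) and absolute (ha / yr) rates for one date pair."""

    t1: object
    t2: object
    dt_years: float
    #: process -> (r, R); r is NaN where the denominator area is zero
    rates: dict


def _rel(convention: str, a_source: float, t: float, dt: float, sign: int) -> float:
    """Relative rate for a transition of area ``t`` out of ``a_source``."""
    if a_source <= 0:
        return float("nan")
    if convention == "ln_area":
        a2 = a_source - t if sign < 0 else a_source + t
        if a2 <= 0:
            return float("nan")
        return relative_rate_ln(a_source, a2, dt)
    if convention == "transition_fraction":
        return 100.0 * t / (a_source * dt)
    raise RateError(f"unknown rate convention {convention!r}")


def period_rate_table(
    stack: ClassifiedStack,
    convention: str = "mixed",
    regrowth_denominator: str = "NF",
) -> list[RateRecord]:
    """Rates for every consecutive date pair of a (corrected) stack.

    ``convention`` is ``"ln_area"``, ``"transition_fraction"`` or ``"mixed"``
    (default): logarithmic for MF and total deforestation, where the source
    class is large and the log rate is the standard report, and
    transition-fraction for SF deforestation and regrowth, whose fluxes are
    normalized by small reference areas. ``regrowth_denominator`` selects the
    reference area for the relative regrowth rate (``"NF"`` or ``"SF"`` at
    t1). Absolute rates are convention-independent: R = T / dt.

    Under ``ln_area`` the deforestation r values are signed (negative for
    loss); under ``transition_fraction`` they are positive intensities.
    """
    if regrowth_denominator not in ("NF", "SF"):
        raise RateError("regrowth_denominator must be 'NF' or 'SF'")

    def conv(process: str) -> str:
        if convention != "mixed":
            return convention
        return "ln_area" if process in ("mf_deforestation", "total_deforestation") else "transition_fraction"

    records = []
    for k in range(stack.n_dates - 1):
        m1, m2 = stack.maps[k], stack.maps[k + 1]
        dt = decimal_years(m1.date, m2.date)
        ts = transition_areas(m1, m2, dt)
        a_mf, a_sf, a_nf = ts.areas_t1["MF"], ts.areas_t1["SF"], ts.areas_t1["NF"]
        a_reg = a_nf if regrowth_denominator == "NF" else a_sf
        defo_total = ts.t_mf_to_nf + ts.t_sf_to_nf
        rates = {
            "mf_deforestation": (
                _rel(conv("mf_deforestation"), a_mf, ts.t_mf_to_nf, dt, -1),
                ts.t_mf_to_nf / dt,
            ),
            "sf_deforestation": (
                _rel(conv("sf_deforestation"), a_sf, ts.t_sf_to_nf, dt, -1),
                ts.t_sf_to_nf / dt,
            ),
            "total_deforestation": (
                _rel(conv("total_deforestation"), a_mf + a_sf, defo_total, dt, -1),
                defo_total / dt,
            ),
            "regrowth": (
                _rel(conv("regrowth"), a_reg, ts.t_nf_to_sf, dt, +1),
                ts.t_nf_to_sf / dt,
            ),
        }
        records.append(RateRecord(t1=m1.date, t2=m2.date, dt_years=dt, rates=rates))
    return records


def rate_records_frame(records: list[RateRecord]) -> pd.DataFrame:
    """Flatten rate records to one row per period."""
    rows = []
    for rec in records:
        row = {
            "t1": format_date(rec.t1),
            "t2": format_date(rec.t2),
            "dt_years": rec.dt_years,
        }
        for proc, (r, big_r) in rec.rates.items():
            row[f"{proc}_r_pct_yr"] = r
            row[f"{proc}_R_ha_yr"] = big_r
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_rates(records: list[RateRecord]) -> pd.DataFrame:
    """Distribution summary per process and unit.

    Rows: minimum, maximum, mean, median, inter-quartile range (Q3 - Q1,
    linear-interpolation quantiles), sample standard deviation (ddof=1;
    reported as 0 for a single record, with ``n_undefined`` tracking rates
    excluded for zero denominators).
    """
    if not records:
        raise RateError("no rate records to summarize")
    stats = ["minimum", "maximum", "mean", "median", "iqr", "sd"]
    out = {}
    qc = {}
    for proc in PROCESSES:
        for unit, pick in (("r_pct_yr", 0), ("R_ha_yr", 1)):
            vals = np.array([rec.rates[proc][pick] for rec in records], dtype=float)
            defined = vals[~np.isnan(vals)]
            qc[(proc, unit)] = int(np.isnan(vals).sum())
            if defined.size == 0:
                out[(proc, unit)] = [float("nan")] * 6
                continue
            q1, q3 = np.percentile(defined, [25, 75])
            sd = float(np.std(defined, ddof=1)) if defined.size > 1 else 0.0
            out[(proc, unit)] = [
                float(defined.min()), float(defined.max()), float(defined.mean()),
                float(np.median(defined)), float(q3 - q1), sd,
            ]
    frame = pd.DataFrame(out, index=stats)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["process", "unit"])
    frame.attrs["n_undefined"] = qc
    return frame


@dataclass(frozen=True)
class IndicatorPair:
    """Period typology: a clearance-composition label and a net-balance label.

    clearance in {a, b, c, e}:
      a) clearance of MF only (SF clearance negligible)
      b) MF clearance > SF clearance (both present)
      c) MF clearance < SF clearance
      e) reclearance of SF only (MF clearance negligible)
    balance in {d, f}:
      d) total clearance > regrowth
      f) regrowth > total clearance
    The two groupings are orthogonal and reported as a pair.
    """

    clearance: str
    balance: str
    tie: bool = False
    degenerate: bool = False


def classify_period_indicator(summary: TransitionSummary, eps_frac: float = 0.01) -> IndicatorPair:
    """Label a period by its clearance composition and net balance.

    A clearance term is treated as "little or no" when it does not exceed
    ``eps_frac`` of the larger of the two clearance terms (default 1 %).
    Equal clearances are labelled ``b`` with ``tie=True``; a period with no
    clearance at all is labelled ``a`` with ``degenerate=True``. Equality of
    clearance and regrowth is labelled ``d`` with ``tie=True``.
    """
    t_mf, t_sf, t_reg = summary.t_mf_to_nf, summary.t_sf_to_nf, summary.t_nf_to_sf
    eps = eps_frac * max(t_mf, t_sf)
    tie = False
    degenerate = False
    if t_mf <= eps and t_sf <= eps:
        clearance = "a"
        degenerate = True
    elif t_sf <= eps:
        clearance = "a"
    elif t_mf <= eps:
        clearance = "e"
    elif t_mf > t_sf:
        clearance = "b"
    elif t_mf < t_sf:
        clearance = "c"
    else:
        clearance = "b"
        tie = True
    total_clear = t_mf + t_sf
    if total_clear > t_reg:
        balance = "d"
    elif t_reg > total_clear:
        balance = "f"
    else:
        balance = "d"
        tie = True
    return IndicatorPair(clearance=clearance, balance=balance, tie=tie, degenerate=degenerate)
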