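"""Synthetic landscape simulator with known per-pixel trajectory truth.

Each pixel evolves independently as a continuous-time semi-Markov chain over
the deforestation cycle

    MF --(clearance hazard)--> NF --(use period)--> SF --(reclearance)--> NF ...

Mature forest faces a constant per-year clearance hazard; cleared land is
actively used for a duration drawn from the configured distribution (default
geometric, mean 2 years, matching the predominance of short use periods);
regrowth faces a constant per-year reclearance hazard. Per-year hazards p
are converted to exponential event rates ``lambda = -ln(1 - p)`` so they
scale consistently across irregular observation gaps.

The continuous trajectory is sampled at the configured acquisition dates
(default: a real 21-date 1984-2011 Landsat acquisition calendar with 1-3
year gaps), which reproduces the censoring structure of real series: events
are dated at the first observation of the new state, first-date SF has only
a minimum age, and state flips inside a long gap go unobserved.

Ground truth (ASF / PALU / FC and flags at every pixel and date) is derived
from the *observed* label sequence by an independent, deliberately naive
per-pixel scan (:func:`reference_pixel_metrics`), which doubles as the
oracle for the vectorized implementation in :mod:`lulctraj.metrics`.

Classification noise is injected separately by :func:`corrupt_with_confusion`
from a row-stochastic confusion matrix (probability of each observed label
given the true class), emulating published error-matrix structure.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .codes import GRID_DTYPE, MF, NF, NODATA, SF, THEMATIC, WATER
from .core import ClassifiedStack, LandCoverMap, build_stack, parse_date

#: Landsat acquisition calendar of a 1984-2011 Rondonia time-series
#: (annual with occasional 2-3 year gaps) — the default observation dates.
DEFAULT_DATES: tuple[int, ...] = (
    19840617, 19860810, 19870712, 19890717, 19900618, 19910925, 19940816,
    19950803, 19960704, 19970723, 19980624, 19990729, 20010803, 20030724,
    20050713, 20060716, 20070703, 20080806, 20090809, 20100625, 20110612,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic landscape.

    Hazards are per-year probabilities in [0, 1]; ``palu_distribution`` is
    ``("geometric", mean_years)`` or ``("constant", years)`` over whole-year
    active-use durations (support >= 1). ``p_initial_sf`` / ``p_initial_nf``
    seed censored starts (pixels already SF or NF at the first date);
    ``water_border`` pixels of permanent water frame the grid to exercise
    the common-mask path.
    """

    shape: tuple[int, int] = (100, 100)
    dates: tuple[int, ...] = DEFAULT_DATES
    pixel_area_ha: float = 0.09  # one 30 m Landsat pixel
    p_clear_mf: float = 0.02
    palu_distribution: tuple = ("geometric", 2.0)
    p_reclear_sf: float = 0.10
    p_initial_sf: float = 0.05
    p_initial_nf: float = 0.03
    water_border: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dates) < 2:
            raise ValueError("need at least two observation dates")
        if min(self.shape) < 1:
            raise ValueError("degenerate grid shape")
        for name in ("p_clear_mf", "p_reclear_sf", "p_initial_sf", "p_initial_nf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_initial_sf + self.p_initial_nf > 1.0:
            raise ValueError("p_initial_sf + p_initial_nf must not exceed 1")
        parsed = [parse_date(d) for d in self.dates]
        if parsed != sorted(set(parsed)):
            raise ValueError("dates must be strictly increasing")


@dataclass(frozen=True)
class TrajectoryTruth:
    """True labels and metrics at every pixel and observation date.

    Arrays have shape ``(n_dates, rows, cols)`` and follow the same
    conventions as :class:`lulctraj.metrics.MetricMaps` (NaN off-SF, decimal
    years, cumulative FC).
    """

    dates: tuple
    label: np.ndarray = field(repr=False)
    asf: np.ndarray = field(repr=False)
    asf_censored: np.ndarray = field(repr=False)
    palu: np.ndarray = field(repr=False)
    palu_zero: np.ndarray = field(repr=False)
    fc: np.ndarray = field(repr=False)
    fc_nf_start: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class ConfusionSpec:
    """Row-stochastic map P(labelled j | true class i) over (MF, NF, SF)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3 over (MF, NF, SF)")
        if (m < 0).any():
            raise ValueError("confusion entries must be nonnegative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("confusion rows must sum to 1 within 1e-12")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_error_matrix_counts(cls, counts: np.ndarray) -> "ConfusionSpec":
        """Normalize reference-by-classified counts to row probabilities."""
        counts = np.asarray(counts, dtype=float)
        return cls(counts / counts.sum(axis=1, keepdims=True))


def _draw_palu(dist: tuple, rng: np.random.Generator) -> float:
    kind, param = dist
    if kind == "geometric":
        # geometric on {1, 2, ...} with the given mean: success prob 1/mean
        return float(rng.geometric(1.0 / float(param)))
    if kind == "constant":
        return float(param)
    raise ValueError(f"unknown palu_distribution kind {kind!r}")


def _wait(lam: float, rng: np.random.Generator) -> float:
    """Exponential waiting time; a unit per-year hazard (lam = inf)
    degenerates to a uniform event time within the year."""
    if math.isinf(lam):
        return float(rng.random())
    return float(rng.exponential(1.0 / lam))


def _simulate_events(
    state0: int,
    horizon: float,
    lam_clear: float,
    lam_reclear: float,
    palu_dist: tuple,
    rng: np.random.Generator,
) -> list[tuple[float, int]]:
    """Event list [(time, new_state), ...] for one pixel on [0, horizon]."""
    events = []
    t = 0.0
    state = state0
    while True:
        if state == MF:
            if lam_clear <= 0.0:
                break
            t += _wait(lam_clear, rng)
            state = NF
        elif state == NF:
            t += _draw_palu(palu_dist, rng)
            state = SF
        else:  # SF
            if lam_reclear <= 0.0:
                break
            t += _wait(lam_reclear, rng)
            state = NF
        if t > horizon:
            break
        events.append((t, state))
    return events


def reference_pixel_metrics(labels: list[int], times: np.ndarray) -> dict:
    """Trajectory metrics for one pixel by a plain chronological scan.

    Independent reference implementation of the ASF / PALU / FC definitions
    (used to build simulator truth and as the test oracle for the vectorized
    version). ``labels`` may contain NODATA, which is transparent.
    Returns per-date lists: asf, censored, palu, palu_zero, fc, fc_nf_start.
    """
    n = len(labels)
    asf = [float("nan")] * n
    censored = [False] * n
    palu = [float("nan")] * n
    palu_zero = [False] * n
    fc_out = [0] * n
    fc_nfs = [False] * n

    prev = None
    sf_onset = None
    nf_start = None
    cur_palu = None
    cur_censored = False
    cur_pzero = False
    fc = 0
    for k in range(n):
        lab = labels[k]
        t = times[k]
        if lab not in (NODATA, WATER):
            if prev is None:
                if lab == SF:
                    sf_onset = t
                    cur_palu = 0.0
                    cur_censored = k == 0
                    cur_pzero = k == 0
                elif lab == NF:
                    nf_start = t
            elif lab != prev:
                if lab == NF and prev in (MF, SF):
                    fc += 1
                    nf_start = t
                    sf_onset = None
                    cur_censored = False
                    cur_pzero = False
                elif lab == SF and prev == NF:
                    sf_onset = t
                    cur_palu = t - nf_start
                    cur_censored = False
                    cur_pzero = False
                elif lab == SF and prev == MF:
                    sf_onset = t
                    cur_palu = 0.0
                    cur_censored = False
                    cur_pzero = False
                elif lab == MF:
                    sf_onset = None
                    nf_start = None
                    cur_censored = False
                    cur_pzero = False
            prev = lab
            if lab == SF:
                asf[k] = t - sf_onset
                censored[k] = cur_censored
                palu[k] = cur_palu
                palu_zero[k] = cur_pzero
        fc_out[k] = fc if labels[0] != WATER else -1
        fc_nfs[k] = labels[0] == NF and fc == 0
    return {
        "asf": asf, "censored": censored, "palu": palu,
        "palu_zero": palu_zero, "fc": fc_out, "fc_nf_start": fc_nfs,
    }


def simulate_stack(config: SimulationConfig) -> tuple[ClassifiedStack, TrajectoryTruth]:
    """Simulate a classified stack and its exact trajectory truth.

    Reproducible: identical config (including seed) gives bit-identical
    output. The emitted stack carries the *true* labels; apply
    :func:`corrupt_with_confusion` to add classification noise.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape
    dates = [parse_date(d) for d in config.dates]
    d0 = dates[0]
    times = np.array([(d - d0).days / 365.25 for d in dates])
    horizon = float(times[-1])
    n = len(dates)

    lam_clear = -math.log(1.0 - config.p_clear_mf) if config.p_clear_mf < 1 else math.inf
    lam_reclear = -math.log(1.0 - config.p_reclear_sf) if config.p_reclear_sf < 1 else math.inf

    water = np.zeros((rows, cols), dtype=bool)
    b = config.water_border
    if b > 0:
        water[:b, :] = True
        water[-b:, :] = True
        water[:, :b] = True
        water[:, -b:] = True

    u = rng.random((rows, cols))
    state0 = np.full((rows, cols), MF, dtype=np.uint8)
    state0[u < config.p_initial_sf] = SF
    state0[(u >= config.p_initial_sf) & (u < config.p_initial_sf + config.p_initial_nf)] = NF

    label = np.full((n, rows, cols), WATER, dtype=GRID_DTYPE)
    asf = np.full((n, rows, cols), np.nan)
    asf_c = np.zeros((n, rows, cols), dtype=bool)
    palu = np.full((n, rows, cols), np.nan)
    palu_z = np.zeros((n, rows, cols), dtype=bool)
    fc = np.zeros((n, rows, cols), dtype=np.int32)
    fc_nfs = np.zeros((n, rows, cols), dtype=bool)

    for i in range(rows):
        for j in range(cols):
            if water[i, j]:
                fc[:, i, j] = -1
                continue
            s0 = int(state0[i, j])
            events = _simulate_events(
                s0, horizon, lam_clear, lam_reclear, config.palu_distribution, rng
            )
            # state at each observation date
            labs = []
            ev_idx = 0
            cur = s0
            for k in range(n):
                while ev_idx < len(events) and events[ev_idx][0] <= times[k]:
                    cur = events[ev_idx][1]
                    ev_idx += 1
                labs.append(cur)
            label[:, i, j] = labs
            ref = reference_pixel_metrics(labs, times)
            asf[:, i, j] = ref["asf"]
            asf_c[:, i, j] = ref["censored"]
            palu[:, i, j] = ref["palu"]
            palu_z[:, i, j] = ref["palu_zero"]
            fc[:, i, j] = ref["fc"]
            fc_nfs[:, i, j] = ref["fc_nf_start"]

    maps = [
        LandCoverMap(grid=label[k], date=dates[k], pixel_area_ha=config.pixel_area_ha)
        for k in range(n)
    ]
    stack = build_stack(maps)
    truth = TrajectoryTruth(
        dates=tuple(dates), label=stack.grids(), asf=asf, asf_censored=asf_c,
        palu=palu, palu_zero=palu_z, fc=fc, fc_nf_start=fc_nfs,
    )
    return stack, truth


def truth_to_frame(truth: TrajectoryTruth) -> pd.DataFrame:
    """Flatten a :class:`TrajectoryTruth` to one row per pixel-date."""
    n, rows, cols = truth.label.shape
    pix = np.arange(rows * cols)
    frames = []
    from .core import format_date

    for k in range(n):
        frames.append(
            pd.DataFrame(
                {
                    "pixel_id": pix,
                    "date": format_date(truth.dates[k]),
                    "class": truth.label[k].ravel(),
                    "asf": truth.asf[k].ravel(),
                    "palu": truth.palu[k].ravel(),
                    "fc": truth.fc[k].ravel(),
                    "asf_censored": truth.asf_censored[k].ravel(),
                    "palu_zero": truth.palu_zero[k].ravel(),
                    "fc_nf_start": truth.fc_nf_start[k].ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def corrupt_with_confusion(
    stack: ClassifiedStack, spec: ConfusionSpec, seed: int
) -> ClassifiedStack:
    """Relabel every thematic cell independently per its true-class row.

    WATER and NODATA cells are never corrupted. Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    cum = np.cumsum(spec.matrix, axis=1)
    grids = stack.grids()
    out = grids.copy()
    for k in range(stack.n_dates):
        g = grids[k]
        them = np.isin(g, THEMATIC)
        u = rng.random(g.shape)
        for ci, code in enumerate(THEMATIC):
            cells = them & (g == code)
            # number of cumulative bounds at or below u = chosen column
            idx = np.clip(
                np.sum(u[cells][:, None] >= cum[ci][None, :], axis=1), 0, 2
            )
            out[k][cells] = np.array(THEMATIC, dtype=GRID_DTYPE)[idx]
    return stack.with_grids(out)


def make_reference_sample(
    lc_map: LandCoverMap, n_per_class: int, min_patch_ha: float, seed: int
) -> pd.DataFrame:
    """Random validation points at interior centroids of large patches.

    For each thematic class, the connected components (4-connectivity) with
    area >= ``min_patch_ha`` are enumerated; ``n_per_class`` distinct patches
    are sampled without replacement and each contributes the patch cell
    nearest its centroid. Returns columns ``row``, ``col``, ``label``.

    Raises a ``ValueError`` naming the class when a class lacks enough
    eligible patches.
    """
    rng = np.random.default_rng(seed)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    min_cells = math.ceil(min_patch_ha / lc_map.pixel_area_ha)
    records = []
    for lab, code in zip(("MF", "NF", "SF"), THEMATIC):
        labelled, n_patches = ndimage.label(lc_map.grid == code, structure=structure)
        if n_patches == 0:
            raise ValueError(f"class {lab}: no patches at all")
        sizes = np.bincount(labelled.ravel())[1:]
        eligible = np.nonzero(sizes >= min_cells)[0] + 1
        if eligible.size < n_per_class:
            raise ValueError(
                f"class {lab}: only {eligible.size} patches of >= {min_patch_ha} ha, "
                f"need {n_per_class}"
            )
        chosen = rng.choice(eligible, size=n_per_class, replace=False)
        centroids = ndimage.center_of_mass(np.ones_like(labelled), labelled, chosen)
        for patch_id, (cy, cx) in zip(chosen, centroids):
            ys, xs = np.nonzero(labelled == patch_id)
            d2 = (ys - cy) ** 2 + (xs - cx) ** 2
            best = int(np.argmin(d2))
            records.append({"row": int(ys[best]), "col": int(xs[best]), "label": int(code)})
    return pd.DataFrame(records)
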