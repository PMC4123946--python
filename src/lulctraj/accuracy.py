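"""Error matrices, accuracy statistics, inverse area calibration, overlays.

The error matrix is oriented rows = reference class, columns = classified
class, so omission errors are row-wise and commission errors column-wise.

Pixel counting gives biased class areas whenever classes are confused
asymmetrically. The inverse calibration estimator revises the pixel-count
proportions using the conditional probability of the reference class given
the classified class, estimated from the validation sample:

    p_j  = (n_.j + f_j) / N                 combined classified proportion
    pi_i = sum_j (n_ij / n_.j) * p_j        calibrated proportion of class i

where n_ij are validation counts, n_.j the validation column totals, f_j the
pixels classified as j outside the validation sample and N the combined
total. With an error-free matrix the calibration is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import NODATA, THEMATIC, THEMATIC_LABELS, WATER
from .core import LandCoverMap


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class ErrorMatrix:
    """Reference-by-classified count matrix with fixed orientation."""

    counts: np.ndarray
    labels: tuple[str, ...] = THEMATIC_LABELS

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("error matrix must be square")
        if counts.shape[0] != len(self.labels):
            raise ValueError("labels do not match matrix dimension")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class AccuracyStats:
    overall: float
    omission: np.ndarray  # per reference class, NaN if the row total is 0
    commission: np.ndarray  # per classified class, NaN if the column total is 0
    labels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"omission_error": self.omission, "commission_error": self.commission},
            index=list(self.labels),
        )


def build_error_matrix(points: pd.DataFrame, classified: LandCoverMap) -> ErrorMatrix:
    """Cross-tabulate reference points against a classified map.

    ``points`` must have integer columns ``row``, ``col`` and a reference
    label column ``label`` holding thematic codes. Points landing on WATER
    or NODATA cells are excluded from the tally; the number excluded is
    exposed on the returned matrix as ``n_excluded``.
    """
    k = len(THEMATIC)
    counts = np.zeros((k, k), dtype=np.int64)
    excluded = 0
    rows = points["row"].to_numpy(dtype=int)
    cols = points["col"].to_numpy(dtype=int)
    refs = points["label"].to_numpy(dtype=int)
    mapped = classified.grid[rows, cols]
    for ref, cls in zip(refs, mapped):
        if cls in (WATER, NODATA):
            excluded += 1
            continue
        counts[THEMATIC.index(int(ref)), THEMATIC.index(int(cls))] += 1
    matrix = ErrorMatrix(counts=counts)
    object.__setattr__(matrix, "n_excluded", excluded)
    return matrix


def accuracy_stats(m: ErrorMatrix) -> AccuracyStats:
    """Overall accuracy plus per-class omission and commission errors."""
    if m.n == 0:
        raise ValueError("empty error matrix")
    diag = np.diag(m.counts).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        omission = 1.0 - diag / m.row_totals
        commission = 1.0 - diag / m.col_totals
    omission = np.where(m.row_totals > 0, omission, np.nan)
    commission = np.where(m.col_totals > 0, commission, np.nan)
    overall = float(diag.sum() / m.n)
    return AccuracyStats(overall=overall, omission=omission, commission=commission, labels=m.labels)


@dataclass(frozen=True)
class CalibratedAreas:
    labels: tuple[str, ...]
    p_naive: np.ndarray  # combined classified-class proportions
    pi: np.ndarray  # calibrated reference-class proportions
    total_area_ha: float

    @property
    def areas_naive_ha(self) -> np.ndarray:
        return self.p_naive * self.total_area_ha

    @property
    def areas_calibrated_ha(self) -> np.ndarray:
        return self.pi * self.total_area_ha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p_naive": self.p_naive,
                "pi_calibrated": self.pi,
                "area_naive_ha": self.areas_naive_ha,
                "area_calibrated_ha": self.areas_calibrated_ha,
            },
            index=list(self.labels),
        )


def inverse_calibrate(
    matrix: ErrorMatrix, f_j: np.ndarray, total_area_ha: float = 1.0
) -> CalibratedAreas:
    """Inverse-calibrated class proportions and areas.

    ``f_j`` are the per-class pixel counts of the full map *excluding* the
    validation pixels; the combined total is N = n + sum(f_j).
    """
    f_j = np.asarray(f_j, dtype=float)
    if f_j.shape != (matrix.counts.shape[0],):
        raise CalibrationError("f_j length does not match the matrix dimension")
    if (f_j < 0).any():
        raise CalibrationError("f_j must be nonnegative")
    col = matrix.col_totals.astype(float)
    empty = np.nonzero(col == 0)[0]
    if empty.size:
        names = [matrix.labels[i] for i in empty]
        raise CalibrationError(f"no validation pixels classified as {names}; cannot calibrate")
    n_total = matrix.n + f_j.sum()
    p = (col + f_j) / n_total
    cond = matrix.counts / col[None, :]  # P(reference = i | classified = j)
    pi = cond @ p
    return CalibratedAreas(labels=matrix.labels, p_naive=p, pi=pi, total_area_ha=total_area_ha)


def overlay_incidence(mask: np.ndarray, lc_map: LandCoverMap, mask_label: str = "overlay") -> pd.DataFrame:
    """Overlap area and relative incidence of a mask with each map class.

    For each thematic class: the area (ha) of mask cells carrying that
    class, the share (%) of the mask falling in the class, and the relative
    incidence RI = 100 * overlap / total class area.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != lc_map.shape:
        raise ValueError(f"mask shape {mask.shape} does not match map {lc_map.shape}")
    rows = []
    mask_cells = int(mask.sum())
    for lab, code in zip(THEMATIC_LABELS, THEMATIC):
        overlap = int(np.count_nonzero(mask & (lc_map.grid == code)))
        class_cells = int(np.count_nonzero(lc_map.grid == code))
        rows.append(
            {
                "class": lab,
                "overlap_area_ha": overlap * lc_map.pixel_area_ha,
                "share_of_mask_pct": 100.0 * overlap / mask_cells if mask_cells else 0.0,
                "ri_pct": 100.0 * overlap / class_cells if class_cells else 0.0,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["mask_label"] = mask_label
    out.attrs["mask_area_ha"] = mask_cells * lc_map.pixel_area_ha
    return out


def protection_incidence_ratio(protected: np.ndarray, lc_map: LandCoverMap) -> float:
    """Deforestation incidence outside vs inside a protected mask.

    Deforested means NF or SF (land that left mature forest). The ratio is
    [deforested/thematic outside] / [deforested/thematic inside]; a value of
    2 means land outside protection is deforested at twice the rate inside.
    Returns ``inf`` when the inside shows no deforestation at all.
    """
    protected = np.asarray(protected, dtype=bool)
    if protected.shape != lc_map.shape:
        raise ValueError("protected mask shape does not match map")
    thematic = np.isin(lc_map.grid, THEMATIC)
    deforested = np.isin(lc_map.grid, (THEMATIC[1], THEMATIC[2]))  # NF, SF
    inside_t = np.count_nonzero(thematic & protected)
    outside_t = np.count_nonzero(thematic & ~protected)
    if inside_t == 0 or outside_t == 0:
        raise ValueError("mask must leave thematic area both inside and outside")
    frac_out = np.count_nonzero(deforested & ~protected) / outside_t
    frac_in = np.count_nonzero(deforested & protected) / inside_t
    if frac_in == 0:
        return float("inf")
    return frac_out / frac_in
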