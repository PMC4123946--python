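"""End-to-end pipeline driver: build -> correct -> metrics -> rates -> accuracy.

Given a stack manifest (or a simulation request) the driver runs every stage
and writes CSV products with stable column order into an output directory,
so reruns with the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .accuracy import accuracy_stats, build_error_matrix, inverse_calibrate
from .codes import THEMATIC
from .core import format_date
from .correction import correct_disallowed_transitions
from .io import read_stack, write_stack
from .metrics import (
    ASF_BINS, FC_BINS, PALU_BINS, compute_metrics, crosstab_palu_fc,
    landcover_proportion_table, landcover_trends, sf_class_proportion_curves,
)
from .rates import period_rate_table, rate_records_frame, summarize_rates
from .simulate import SimulationConfig, make_reference_sample, simulate_stack, truth_to_frame

logger = logging.getLogger("lulctraj")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    manifest: str | None = None  # read an existing stack ...
    simulate: SimulationConfig | None = None  # ... or simulate one
    out_dir: str = "lulctraj_out"
    correction: bool = True
    rate_convention: str = "mixed"
    reference_n_per_class: int = 0  # 0 disables the accuracy stage
    reference_min_patch_ha: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.simulate is None):
            raise ValueError("exactly one of manifest / simulate must be given")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a dict of the in-memory products."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("lulctraj %s, seed %d", __version__, config.seed)

    if config.simulate is not None:
        logger.info("stage simulate: %s", config.simulate)
        stack, truth = simulate_stack(config.simulate)
        write_stack(out / "stack_true", stack)
        truth_to_frame(truth).to_csv(out / "trajectory_truth.csv", index=False)
    else:
        logger.info("stage read: %s", config.manifest)
        stack = read_stack(config.manifest)
        truth = None

    if config.correction:
        logger.info("stage correct")
        stack, corrections = correct_disallowed_transitions(stack)
        corrections.to_csv(out / "corrections.csv", index=False)
    else:
        corrections = None

    logger.info("stage metrics")
    metrics = compute_metrics(stack)
    proportions = landcover_proportion_table(stack)
    proportions.to_csv(out / "landcover_proportions.csv", index=False)
    trends = landcover_trends(stack)
    trends.to_csv(out / "landcover_trends.csv", index=False)
    crosstab = crosstab_palu_fc(metrics, -1)
    crosstab.to_csv(out / "palu_fc_crosstab.csv")
    curves = {
        spec.metric: sf_class_proportion_curves(stack, metrics, spec)
        for spec in (ASF_BINS, PALU_BINS, FC_BINS)
    }
    for name, frame in curves.items():
        frame.to_csv(out / f"sf_{name}_class_curves.csv", index=False)

    logger.info("stage rates (%s)", config.rate_convention)
    records = period_rate_table(stack, convention=config.rate_convention)
    rate_records_frame(records).to_csv(out / "period_rates.csv", index=False)
    summary = summarize_rates(records)
    summary.to_csv(out / "rate_summary.csv")

    accuracy = None
    if config.reference_n_per_class > 0:
        logger.info("stage accuracy/calibration")
        last = stack.maps[-1]
        points = make_reference_sample(
            last, config.reference_n_per_class, config.reference_min_patch_ha, config.seed
        )
        points.to_csv(out / "reference_points.csv", index=False)
        matrix = build_error_matrix(points, last)
        matrix.to_frame().to_csv(out / "error_matrix.csv")
        stats = accuracy_stats(matrix)
        stats.to_frame().assign(overall=stats.overall).to_csv(out / "accuracy_stats.csv")
        counts = np.array([np.count_nonzero(last.grid == c) for c in THEMATIC], dtype=float)
        f_j = np.maximum(counts - matrix.col_totals, 0)
        total_area = counts.sum() * last.pixel_area_ha
        calibrated = inverse_calibrate(matrix, f_j, total_area_ha=total_area)
        calibrated.to_frame().to_csv(out / "calibrated_areas.csv")
        accuracy = {"matrix": matrix, "stats": stats, "calibrated": calibrated}

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"lulctraj {__version__}\nseed {config.seed}\n")
        fh.write(f"dates {[format_date(d) for d in stack.dates]}\n")
        fh.write(f"correction {config.correction}\n")

    return {
        "stack": stack,
        "truth": truth,
        "corrections": corrections,
        "metrics": metrics,
        "proportions": proportions,
        "trends": trends,
        "crosstab": crosstab,
        "curves": curves,
        "rate_records": records,
        "rate_summary": summary,
        "accuracy": accuracy,
    }
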