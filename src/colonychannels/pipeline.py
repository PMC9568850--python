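"""End-to-end orchestration: image in, channel-width tables and fits out.

``run_measure`` chains the full measurement: segment the colony, locate its
centre, unwrap to polar coordinates, enhance (CLAHE, despeckle, invert),
measure channel widths on the radial grid, prune outliers by modified
z-score, and fit the radial trend. Every parameter that affects the result
is recorded in the run log, and nothing in the chain is stochastic, so a
rerun on the same input reproduces the same outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import GroupSummary, pairwise_compare, summarise_group
from .core_io import Calibration, Image2D, median_prefilter
from .enhancement import clahe, despeckle, invert
from .polar import DEFAULT_N_ANGULAR, to_polar
from .radial import (
    RadialFitResult,
    RadialSeries,
    fit_radial_trends,
    measure_radial_series,
    normalised_position_summary,
)
from .segmentation import (
    base_area,
    estimate_centre,
    max_full_circumference_radius,
    segment_colony,
)
from .widths import detections_to_table, modified_z_scores

__all__ = ["PipelineConfig", "MeasureResult", "run_measure", "run_compare"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of a measurement run."""

    pixel_size_um: float = 1.0
    prefilter_radius_px: int = 2
    n_angular: int = DEFAULT_N_ANGULAR
    clahe_block_size: int = 60
    clahe_max_slope: float = 3.0
    clahe_bins: int = 256
    prominence_fraction: float = 0.20
    min_distance_px: int = 9
    radial_start_um: float = 200.0
    radial_step_um: float = 50.0
    max_radius_um: float | None = None
    zscore_threshold: float = 3.0
    biofilm_id: str = "biofilm"
    condition: str = ""


@dataclass
class MeasureResult:
    """Everything one measurement run produces."""

    table: pd.DataFrame
    series: RadialSeries
    fits: RadialFitResult | None
    base_area_um2: float
    centre_xy_px: tuple[float, float]
    max_full_radius_um: float
    position_summary: dict
    config: PipelineConfig

    def run_log(self) -> dict:
        return {
            "package": "colonychannels",
            "version": __version__,
            "parameters": asdict(self.config),
            "base_area_um2": self.base_area_um2,
            "centre_xy_px": list(self.centre_xy_px),
            "max_full_radius_um": self.max_full_radius_um,
            "n_detections": int(len(self.table)),
            "n_retained": int(self.table["retained"].sum()),
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "channel_widths.csv", index=False)
        if self.fits is not None:
            pd.DataFrame(
                [
                    {
                        "biofilm_id": self.config.biofilm_id,
                        "model": "linear",
                        "param_1": self.fits.linear.slope,
                        "param_2": self.fits.linear.intercept,
                        "r_squared": self.fits.linear.r_squared,
                    },
                    {
                        "biofilm_id": self.config.biofilm_id,
                        "model": "exponential",
                        "param_1": self.fits.exponential.a,
                        "param_2": self.fits.exponential.b,
                        "r_squared": self.fits.exponential.r_squared,
                    },
                ]
            ).to_csv(out / "radial_fits.csv", index=False)
        pd.DataFrame(
            [
                {
                    "biofilm_id": self.config.biofilm_id,
                    "fraction": f,
                    "radius_um": r,
                    "n": len(widths),
                    "mean_width_um": float(np.mean(widths)) if widths else np.nan,
                }
                for f, (r, widths) in self.position_summary.items()
            ]
        ).to_csv(out / "position_summary.csv", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump(self.run_log(), fh, indent=2)


def run_measure(img: Image2D, config: PipelineConfig | None = None) -> MeasureResult:
    """Run the full channel-width measurement on one colony image."""
    cfg = config or PipelineConfig(pixel_size_um=img.calibration.pixel_size_um)
    px = img.calibration.pixel_size_um

    if cfg.prefilter_radius_px > 0:
        img = median_prefilter(img, cfg.prefilter_radius_px)
    mask = segment_colony(img)
    area = base_area(mask)
    centre = estimate_centre(mask)
    max_full_um = max_full_circumference_radius(mask, centre, cfg.n_angular)
    logger.info(
        "segmented colony: area %.0f um^2, centre (%.1f, %.1f), "
        "max full-circumference radius %.0f um",
        area, centre.x_px, centre.y_px, max_full_um,
    )
    limit_um = max_full_um
    if cfg.max_radius_um is not None:
        limit_um = min(limit_um, cfg.max_radius_um)
    if limit_um < cfg.radial_start_um:
        raise ValueError("colony below measurable size")

    # unwrap the whole measurable annulus (not just the requested range) so
    # the CLAHE tile grid sees the full colony context out to the rim
    polar = to_polar(
        img, centre, cfg.n_angular, max_radius_px=int(np.ceil(max_full_um / px)) + 2
    )
    polar = clahe(polar, cfg.clahe_block_size, cfg.clahe_max_slope, cfg.clahe_bins)
    polar = despeckle(polar)
    polar = invert(polar)

    series = measure_radial_series(
        polar,
        limit_um,
        prominence_fraction=cfg.prominence_fraction,
        min_distance_px=cfg.min_distance_px,
        start_um=cfg.radial_start_um,
        step_um=cfg.radial_step_um,
    )

    # single-pass modified z-score pruning across the biofilm's widths
    widths = np.array([d.width_um for d in series.detections])
    if widths.size:
        retained = np.abs(modified_z_scores(widths)) <= cfg.zscore_threshold
    else:
        retained = np.zeros(0, dtype=bool)
    n_dropped = int((~retained).sum())
    if n_dropped:
        logger.info("outlier filter removed %d of %d detections", n_dropped, len(widths))
    table = detections_to_table(
        series.detections, cfg.biofilm_id, cfg.condition, retained
    )

    kept_dets = [d for d, keep in zip(series.detections, retained) if keep]
    by_radius: dict[float, list[float]] = {r: [] for r in series.widths_by_radius}
    for d in kept_dets:
        by_radius[d.radius_um].append(d.width_um)
    filtered = RadialSeries(widths_by_radius=by_radius, detections=kept_dets)
    radii, _ = filtered.mean_widths()
    fits = fit_radial_trends(filtered) if len(radii) >= 3 else None
    summary = normalised_position_summary(filtered)

    return MeasureResult(
        table=table,
        series=filtered,
        fits=fits,
        base_area_um2=area,
        centre_xy_px=(centre.x_px, centre.y_px),
        max_full_radius_um=max_full_um,
        position_summary=summary,
        config=cfg,
    )


def run_compare(
    tables: pd.DataFrame | list[pd.DataFrame],
    group_col: str = "condition",
    value_col: str = "width_um",
) -> tuple[pd.DataFrame, dict[str, GroupSummary]]:
    """Pairwise Mann-Whitney comparison of retained widths across conditions.

    Accepts one concatenated channel-width table (or a list of per-biofilm
    tables) and returns the pairwise comparison report plus a boxplot-style
    summary per group.
    """
    if isinstance(tables, list):
        table = pd.concat(tables, ignore_index=True)
    else:
        table = tables
    if "retained" in table.columns:
        table = table[table["retained"]]
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    report = pairwise_compare(table, value_col, group_col)
    summaries = {
        g: summarise_group(table.loc[table[group_col] == g, value_col].to_numpy())
        for g in groups
    }
    return report, summaries
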