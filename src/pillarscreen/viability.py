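"""Replicate aggregation and DMSO-normalized relative viability.

Relative cell viability of a drug region is the mean live fluorescent
area of its technical replicates expressed as a percentage of the DMSO
vehicle-control region's mean area:

    relative viability [%] = mean_area(drug) / mean_area(DMSO) x 100

Normalization uses a single designated control region (region 1 by
default); any second control region is carried through like a drug and
serves as a QC readout of plate consistency.  Values are not clipped at
100 — growth above the control is real signal under resistant conditions.
"""

from __future__ import annotations

import pandas as pd

from .chip_model import RegionMap


class AggregationError(ValueError):
    """A region cannot be summarized (e.g. no valid replicates)."""


def aggregate_regions(spots: pd.DataFrame, region_map: RegionMap) -> pd.DataFrame:
    """Mean live area over valid replicates per region.

    Returns a DataFrame ``region_id, mean_area, n_valid`` covering every
    region of the map; raises :class:`AggregationError` naming any region
    left without a single valid replicate.
    """
    required = {"spot_index", "region_id", "replicate", "live_area_px", "valid"}
    missing = required - set(spots.columns)
    if missing:
        raise AggregationError(f"spot table missing columns {sorted(missing)}")
    if (spots.live_area_px < 0).any():
        raise AggregationError("live_area_px must be >= 0")
    valid = spots[spots.valid.astype(bool)]
    grouped = valid.groupby("region_id").live_area_px.agg(["mean", "size"])
    empty = [rid for rid in region_map.region_ids if rid not in grouped.index]
    if empty:
        raise AggregationError(
            f"regions with zero valid replicates: {empty}"
        )
    out = grouped.reindex(list(region_map.region_ids)).reset_index()
    out.columns = ["region_id", "mean_area", "n_valid"]
    out["n_valid"] = out["n_valid"].astype(int)
    return out


def relative_viability(
    summaries: pd.DataFrame,
    control_region: int = 1,
    condition: str = "3D",
) -> pd.DataFrame:
    """Normalize region means to the control region, in percent.

    The control's own entry is set to exactly 100 (not recomputed through
    the division, avoiding representation noise).  Raises on a missing or
    zero-area control.
    """
    if control_region not in set(summaries.region_id):
        raise AggregationError(f"control region {control_region} not in summaries")
    control_mean = float(
        summaries.loc[summaries.region_id == control_region, "mean_area"].iloc[0]
    )
    if control_mean == 0:
        raise ZeroDivisionError(
            f"control region {control_region} has zero mean area; cannot normalize"
        )
    out = summaries.copy()
    out["relative_viability_pct"] = out.mean_area / control_mean * 100.0
    out.loc[out.region_id == control_region, "relative_viability_pct"] = 100.0
    out["condition"] = condition
    out["control_region"] = control_region
    return out[["region_id", "relative_viability_pct", "n_valid", "condition", "control_region"]]
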