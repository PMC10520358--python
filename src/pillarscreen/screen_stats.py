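"""Panel Z-scores, linear distance, and 3D-sensitivity hit calling.

A compound's Z-score standardizes its relative viability by the mean and
SD of the whole panel under one culture condition:

    z = (viability - panel mean) / panel SD

The *linear distance* is the signed perpendicular distance of a compound
from the identity line in the (z_2D, z_3D) plane:

    ld = (-z_3D + z_2D) / sqrt(2)

Large positive values mean the compound kills relatively more under 3D
culture than 2D once each panel is standardized.  A compound is called a
3D-sensitive hit when z_3D <= -1 and ld > 1 (vehicle controls excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class DegeneratePanelError(ValueError):
    """Panel SD is zero; Z-scores are undefined."""


@dataclass(frozen=True)
class PanelStats:
    """Mean/SD used to standardize one panel."""

    mean: float
    sd: float
    sd_mode: str  # "population" or "sample"
    include_controls: bool
    n_used: int


@dataclass(frozen=True)
class HitRule:
    """Thresholds of the 3D-sensitivity selection rule.

    ``z3d_max`` is inclusive (z_3D <= -1 qualifies); ``ld_min`` is strict
    (ld must exceed 1).
    """

    z3d_max: float = -1.0
    ld_min: float = 1.0
    exclude_controls: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.z3d_max) and math.isfinite(self.ld_min)):
            raise ValueError("hit-rule thresholds must be finite")


def _panel_stats(
    values: np.ndarray, used: np.ndarray, sd_mode: str, include_controls: bool
) -> PanelStats:
    if sd_mode not in ("population", "sample"):
        raise ValueError(f"sd_mode must be 'population' or 'sample', got {sd_mode!r}")
    sel = values[used]
    if len(sel) < 2:
        raise DegeneratePanelError("panel needs >= 2 entries to standardize")
    ddof = 0 if sd_mode == "population" else 1
    mean = float(sel.mean())
    sd = float(sel.std(ddof=ddof))
    if sd == 0:
        raise DegeneratePanelError("degenerate panel: all included values are equal")
    return PanelStats(mean, sd, sd_mode, include_controls, int(len(sel)))


def panel_zscores(
    viability: pd.DataFrame,
    control_ids: Sequence[int] = (1, 37),
    include_controls: bool = True,
    sd_mode: str = "population",
    value_col: str = "relative_viability_pct",
    id_col: str = "region_id",
) -> tuple[pd.DataFrame, PanelStats]:
    """Standardize one panel of relative viabilities.

    The mean/SD are computed over the included set (optionally without
    vehicle controls); every compound — controls included — still
    receives a Z-score relative to those statistics.  Returns the input
    with a ``z`` column added, plus the :class:`PanelStats` used.
    """
    values = viability[value_col].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("viability values must be finite")
    ids = viability[id_col].to_numpy()
    used = np.ones(len(values), dtype=bool)
    if not include_controls:
        used &= ~np.isin(ids, list(control_ids))
    stats = _panel_stats(values, used, sd_mode, include_controls)
    out = viability.copy()
    out["z"] = (values - stats.mean) / stats.sd
    return out, stats


@dataclass(frozen=True)
class ZScoreCalibration:
    """Result of fitting the Z-score convention to a published panel."""

    include_controls: bool
    sd_mode: str
    max_abs_dev: dict[str, float]  # per panel label
    all_variants: pd.DataFrame  # one row per variant with per-panel deviations


def calibrate_zscore_convention(
    panel: pd.DataFrame, control_ids: Sequence[int] = (1, 37)
) -> ZScoreCalibration:
    """Identify which mean/SD convention reproduces printed Z columns.

    Standardization leaves two free choices a methods section rarely
    states: whether vehicle controls enter the panel statistics, and
    population vs sample SD.  All four variants are evaluated against the
    printed ``z2d``/``z3d`` columns; the variant minimizing the maximum
    absolute deviation (worst panel) is returned, with the full deviation
    table for the record.
    """
    rows = []
    for include in (True, False):
        for sd_mode in ("population", "sample"):
            devs = {}
            for rv_col, z_col in (("rv2d", "z2d"), ("rv3d", "z3d")):
                zdf, _ = panel_zscores(
                    panel,
                    control_ids=control_ids,
                    include_controls=include,
                    sd_mode=sd_mode,
                    value_col=rv_col,
                    id_col="compound_no",
                )
                devs[z_col] = float(np.abs(zdf.z - panel[z_col]).max())
            rows.append(
                {
                    "include_controls": include,
                    "sd_mode": sd_mode,
                    "max_abs_dev_z2d": devs["z2d"],
                    "max_abs_dev_z3d": devs["z3d"],
                    "max_abs_dev": max(devs.values()),
                }
            )
    table = pd.DataFrame(rows).sort_values("max_abs_dev").reset_index(drop=True)
    best = table.iloc[0]
    return ZScoreCalibration(
        include_controls=bool(best.include_controls),
        sd_mode=str(best.sd_mode),
        max_abs_dev={
            "z2d": float(best.max_abs_dev_z2d),
            "z3d": float(best.max_abs_dev_z3d),
        },
        all_variants=table,
    )


def linear_distance(z3d, z2d):
    """Signed perpendicular distance from the identity line: (-z3d + z2d)/sqrt(2).

    Accepts scalars or arrays; positive values indicate relatively
    stronger kill under 3D culture.  Antisymmetric in its arguments.
    """
    z3d = np.asarray(z3d, dtype=float)
    z2d = np.asarray(z2d, dtype=float)
    if not (np.isfinite(z3d).all() and np.isfinite(z2d).all()):
        raise ValueError("Z-scores must be finite")
    out = (-z3d + z2d) / math.sqrt(2.0)
    return float(out) if out.ndim == 0 else out


def build_comparison(
    z2d_table: pd.DataFrame,
    z3d_table: pd.DataFrame,
    id_col: str = "region_id",
) -> pd.DataFrame:
    """Join the two standardized panels and add the linear distance.

    Both inputs are outputs of :func:`panel_zscores` (must share the same
    compound ids).  Returns ``id, z2d, z3d, ld``.
    """
    a = set(z2d_table[id_col])
    b = set(z3d_table[id_col])
    if a != b:
        raise ValueError(
            f"panels disagree on compounds: only-2D={sorted(a - b)}, only-3D={sorted(b - a)}"
        )
    merged = pd.merge(
        z2d_table[[id_col, "z"]].rename(columns={"z": "z2d"}),
        z3d_table[[id_col, "z"]].rename(columns={"z": "z3d"}),
        on=id_col,
    )
    merged["ld"] = linear_distance(merged.z3d, merged.z2d)
    return merged


def call_hits(
    comparison: pd.DataFrame,
    rule: HitRule | None = None,
    control_ids: Sequence[int] = (1, 37),
    id_col: str = "region_id",
) -> pd.DataFrame:
    """Apply the 3D-sensitivity rule; return flagged table sorted by ld.

    Adds an ``is_hit`` column (z3d <= z3d_max, ld > ld_min, and not a
    vehicle control when ``exclude_controls``) and returns the table
    sorted by descending linear distance, hits first in rank order.
    """
    rule = rule or HitRule()
    out = comparison.copy()
    is_hit = (out.z3d <= rule.z3d_max) & (out.ld > rule.ld_min)
    if rule.exclude_controls:
        is_hit &= ~out[id_col].isin(list(control_ids))
    out["is_hit"] = is_hit
    return out.sort_values(
        ["is_hit", "ld"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)


@dataclass(frozen=True)
class ResistanceShift:
    """2D-vs-3D panel shift summary over non-control compounds."""

    n_compounds: int
    n_higher_3d: int  # compounds with rv3d > rv2d
    slope_through_origin: float  # least-squares slope of rv3d on rv2d


def resistance_shift(
    panel2d: pd.DataFrame,
    panel3d: pd.DataFrame,
    control_ids: Sequence[int] = (1, 37),
    id_col: str = "region_id",
    value_col: str = "relative_viability_pct",
) -> ResistanceShift:
    """Quantify the across-the-board viability shift from 2D to 3D.

    Counts non-control compounds whose 3D viability exceeds their 2D
    viability, and fits the through-origin least-squares slope of 3D
    against 2D (slope > 1 indicates dominance of the resistant regime).
    """
    a, b = set(panel2d[id_col]), set(panel3d[id_col])
    if a != b:
        raise ValueError(
            f"panels disagree on compounds: only-2D={sorted(a - b)}, only-3D={sorted(b - a)}"
        )
    merged = pd.merge(
        panel2d[[id_col, value_col]].rename(columns={value_col: "rv2d"}),
        panel3d[[id_col, value_col]].rename(columns={value_col: "rv3d"}),
        on=id_col,
    )
    merged = merged[~merged[id_col].isin(list(control_ids))]
    x = merged.rv2d.to_numpy(dtype=float)
    y = merged.rv3d.to_numpy(dtype=float)
    sxx = float(np.dot(x, x))
    slope = float(np.dot(x, y) / sxx) if sxx > 0 else float("nan")
    return ResistanceShift(
        n_compounds=len(merged),
        n_higher_3d=int((y > x).sum()),
        slope_through_origin=slope,
    )
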