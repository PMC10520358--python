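"""End-to-end orchestration: synthetic screens, panel comparison, and
reproduction of the published tables from the packaged fixtures."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import round_half_up
from .chip_model import ChipLayout, RegionMap, build_region_map, pillar_chip_layout
from .fixtures import (
    CONTROL_COMPOUNDS,
    NORMALIZATION_CONTROL,
    PRINTED_LINEAR_DISTANCES,
    PUBLISHED_HITS,
    load_drug_panel,
)
from .image_quant import quantify_spots, register_grid
from .screen_stats import (
    HitRule,
    build_comparison,
    calibrate_zscore_convention,
    call_hits,
    linear_distance,
    panel_zscores,
    resistance_shift,
)
from .subculture_qc import compare_to_published
from .synthetic import (
    EffectSpec,
    SyntheticConfig,
    generate_spot_areas,
    render_chip_image,
    sample_true_effects,
)
from .viability import aggregate_regions, relative_viability


class PipelineError(RuntimeError):
    """A pipeline stage is missing its input."""


@dataclass
class PipelineConfig:
    """Configuration of one synthetic 2D/3D screen run."""

    layout: ChipLayout = field(default_factory=pillar_chip_layout)
    region_map: RegionMap | None = None
    n_drugs: int = 70
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    hit_rule: HitRule = field(default_factory=HitRule)
    control_region: int = NORMALIZATION_CONTROL
    seed: int = 0
    through_images: bool = False  # render/register/quantify instead of direct areas
    conditions: tuple[str, ...] = ("2D", "3D")

    def resolved_region_map(self) -> RegionMap:
        if self.region_map is not None:
            return self.region_map
        # controls at region 1 and the panel midpoint; for the 72-region
        # default this lands on (1, 37), the published control positions
        n_regions = self.n_drugs + 2
        return build_region_map(
            self.layout,
            n_regions=n_regions,
            replicates_per_region=6,
            control_region_ids=(1, n_regions // 2 + 1),
        )


@dataclass
class ScreenResult:
    """Outputs of one synthetic screen run."""

    effects: pd.DataFrame
    spots: dict[str, pd.DataFrame]  # per condition
    viability: dict[str, pd.DataFrame]
    comparison: pd.DataFrame  # with is_hit, sorted by ld
    shift: object
    run_log: dict


def _condition_spot_table(
    effects: pd.DataFrame, region_map, config: PipelineConfig, model: str, seed: int
) -> pd.DataFrame:
    synth = SyntheticConfig(
        base_area_px=config.synth.base_area_px,
        noise_cv=config.synth.noise_cv,
        dropout_p=config.synth.dropout_p,
        seed=seed,
        image=config.synth.image,
    )
    spots = generate_spot_areas(effects, region_map, synth, model=model)
    if not config.through_images:
        return spots
    image, _ = render_chip_image(spots, config.layout, synth.image)
    calib = register_grid(image, config.layout)
    quantified = quantify_spots(image, calib, config.layout, region_map)
    # carry the generator's dropout flags through to aggregation
    quantified["valid"] = spots["valid"].to_numpy()
    return quantified


def run_screen_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> ScreenResult:
    """Simulate a paired 2D/3D screen and call 3D-sensitive hits.

    Deterministic for a given config: condition seeds are derived from
    ``config.seed``.  When ``outdir`` is given, spot/viability/comparison
    CSVs, a Z-scatter PNG and a machine-readable run log are written.
    """
    region_map = config.resolved_region_map()
    effects = sample_true_effects(config.n_drugs, config.seed, config.effect_spec)
    spots, viab, ztabs = {}, {}, {}
    for offset, model in ((1, "2D"), (2, "3D")):
        if model not in config.conditions:
            continue
        table = _condition_spot_table(
            effects, region_map, config, model, seed=config.seed * 7919 + offset
        )
        spots[model] = table
        summaries = aggregate_regions(table, region_map)
        viab[model] = relative_viability(summaries, config.control_region, condition=model)
        ztabs[model], _ = panel_zscores(
            viab[model], control_ids=tuple(region_map.control_region_ids),
            include_controls=True,
            sd_mode="population",
        )
    if set(ztabs) != {"2D", "3D"}:
        if outdir is not None:  # preserve the per-condition outputs computed so far
            out = Path(outdir)
            out.mkdir(parents=True, exist_ok=True)
            for model, table in spots.items():
                table.to_csv(out / f"spots_{model.lower()}.csv", index=False)
                viab[model].to_csv(out / f"viability_{model.lower()}.csv", index=False)
        raise PipelineError(
            "comparison stage needs both '2D' and '3D' panels; "
            f"configured conditions: {sorted(ztabs)}"
        )
    comparison = build_comparison(ztabs["2D"], ztabs["3D"])
    controls = tuple(region_map.control_region_ids)
    comparison = call_hits(comparison, config.hit_rule, control_ids=controls)
    shift = resistance_shift(viab["2D"], viab["3D"], control_ids=controls)
    run_log = {
        "package_version": __version__,
        "seed": config.seed,
        "n_drugs": config.n_drugs,
        "through_images": config.through_images,
        "conventions": {
            "sd_mode": "population",
            "include_controls": True,
            "control_region": config.control_region,
            "z3d_max": config.hit_rule.z3d_max,
            "ld_min": config.hit_rule.ld_min,
            "report_rounding": "half-up, 2 dp",
        },
        "n_hits": int(comparison.is_hit.sum()),
    }
    result = ScreenResult(effects, spots, viab, comparison, shift, run_log)
    if outdir is not None:
        _write_screen_outputs(result, Path(outdir))
    return result


def _write_screen_outputs(result: ScreenResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for model in ("2D", "3D"):
        result.spots[model].to_csv(outdir / f"spots_{model.lower()}.csv", index=False)
        result.viability[model].to_csv(outdir / f"viability_{model.lower()}.csv", index=False)
    result.comparison.to_csv(outdir / "comparison.csv", index=False)
    result.comparison[result.comparison.is_hit].to_csv(outdir / "hits.csv", index=False)
    (outdir / "run_log.json").write_text(json.dumps(result.run_log, indent=1))
    try:
        plot_z_scatter(result.comparison, outdir / "z_scatter.png")
    except Exception:  # plotting is best-effort; data outputs matter
        pass


def plot_z_scatter(comparison: pd.DataFrame, path: str | Path) -> None:
    """Scatter of z2d vs z3d with the identity line; hits highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    hit = comparison.get("is_hit", pd.Series(False, index=comparison.index))
    ax.scatter(comparison.z2d[~hit], comparison.z3d[~hit], s=18, c="0.6", label="other")
    ax.scatter(comparison.z2d[hit], comparison.z3d[hit], s=28, c="tab:blue", label="3D-sensitive hit")
    lim = np.array(ax.get_xlim() + ax.get_ylim())
    lo, hi = lim.min(), lim.max()
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.8, label="identity")
    ax.set_xlabel("Z-score (2D screen)")
    ax.set_ylabel("Z-score (3D screen)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# published-table reproduction


def reproduce_published_tables(outdir: str | Path | None = None) -> dict:
    """Recompute the published screen statistics from the packaged panel.

    From the fixture's raw viability columns alone, recomputes both
    Z-score columns (under the calibrated convention), the linear
    distances of the four 3D-sensitive drugs, the hit set, the
    2D-vs-3D resistance-shift summary, and the subculture QC table, and
    reports deviations from the printed values.
    """
    panel = load_drug_panel()
    calib = calibrate_zscore_convention(panel, control_ids=CONTROL_COMPOUNDS)

    ztabs = {}
    for rv_col, label in (("rv2d", "2D"), ("rv3d", "3D")):
        zdf, _ = panel_zscores(
            panel,
            control_ids=CONTROL_COMPOUNDS,
            include_controls=calib.include_controls,
            sd_mode=calib.sd_mode,
            value_col=rv_col,
            id_col="compound_no",
        )
        ztabs[label] = zdf
    comparison = build_comparison(ztabs["2D"], ztabs["3D"], id_col="compound_no")
    comparison = comparison.merge(panel[["compound_no", "drug", "target", "rv2d", "rv3d"]],
                                  on="compound_no")
    flagged = call_hits(comparison, HitRule(), control_ids=CONTROL_COMPOUNDS,
                        id_col="compound_no")
    hits = flagged[flagged.is_hit]

    # linear distances of the four published 3D-sensitive drugs, both from
    # the printed Z columns and recomputed end-to-end from viabilities
    ld_rows = []
    for no, printed in PRINTED_LINEAR_DISTANCES.items():
        prow = panel[panel.compound_no == no].iloc[0]
        crow = comparison[comparison.compound_no == no].iloc[0]
        from_printed_z = linear_distance(prow.z3d, prow.z2d)
        ld_rows.append(
            {
                "compound_no": no,
                "drug": prow.drug,
                "published_ld": printed,
                "ld_from_printed_z": round_half_up(from_printed_z, 2),
                "ld_from_viability": round_half_up(float(crow.ld), 2),
                "abs_dev_printed_z": abs(from_printed_z - printed),
                "abs_dev_viability": abs(float(crow.ld) - printed),
            }
        )
    ld_table = pd.DataFrame(ld_rows)

    shift = resistance_shift(
        panel.rename(columns={"rv2d": "relative_viability_pct"}),
        panel.rename(columns={"rv3d": "relative_viability_pct"}),
        control_ids=CONTROL_COMPOUNDS,
        id_col="compound_no",
    )
    qc = compare_to_published()

    z_dev = {
        "z2d": float(np.abs(ztabs["2D"].z - panel.z2d).max()),
        "z3d": float(np.abs(ztabs["3D"].z - panel.z3d).max()),
    }
    report = {
        "zscore_convention": {
            "include_controls": calib.include_controls,
            "sd_mode": calib.sd_mode,
        },
        "z_max_abs_dev": z_dev,
        "comparison": flagged,
        "hits": hits,
        "hit_names": sorted(hits.drug),
        "hits_match_published": set(hits.drug) == set(PUBLISHED_HITS),
        "linear_distances": ld_table,
        "resistance_shift": shift,
        "subculture_qc": qc,
        "zscore_calibration_table": calib.all_variants,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        flagged.to_csv(outdir / "comparison_recomputed.csv", index=False)
        ld_table.to_csv(outdir / "linear_distances.csv", index=False)
        qc.to_csv(outdir / "subculture_qc.csv", index=False)
        calib.all_variants.to_csv(outdir / "zscore_calibration.csv", index=False)
        summary = {
            "zscore_convention": report["zscore_convention"],
            "z_max_abs_dev": z_dev,
            "hit_names": report["hit_names"],
            "hits_match_published": report["hits_match_published"],
            "n_higher_3d": shift.n_higher_3d,
            "n_compounds": shift.n_compounds,
            "slope_through_origin": shift.slope_through_origin,
        }
        (outdir / "reproduction_summary.json").write_text(json.dumps(summary, indent=1))
        plot_z_scatter(flagged, outdir / "z_scatter.png")
    return report
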