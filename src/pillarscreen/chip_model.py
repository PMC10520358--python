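"""Geometric and logical model of the micropillar/microwell screening chip.

A screening chip is a slide-format array of 532 positions ("spots") on a
regular grid.  Drugs are dispensed region-wise: the chip is divided into
regions of consecutive spots, one drug per region, with a fixed number of
technical replicates per region.  Two regions hold the DMSO vehicle
control.  The subculture pillar dish (73 pillars) is modelled only as
metadata for QC reports.

Spot indices are 0-based and row-major; region ids are 1-based so that
they coincide with compound numbers in screen tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence


class LayoutError(ValueError):
    """A chip layout or region map violates a geometric constraint."""


@dataclass(frozen=True)
class ChipLayout:
    """Regular grid of spots on a slide-format chip.

    Parameters
    ----------
    rows, cols
        Grid dimensions; ``n_spots = rows * cols``.
    pitch_mm
        Center-to-center spacing of adjacent spots, in mm.
    spot_diameter_mm
        Nominal diameter of the circular spot footprint (pillar tip or
        well mouth), in mm.  Must be smaller than the pitch.
    """

    rows: int
    cols: int
    pitch_mm: float = 1.5
    spot_diameter_mm: float = 0.75

    def __post_init__(self) -> None:
        if self.rows < 1:
            raise LayoutError(f"rows must be >= 1, got {self.rows}")
        if self.cols < 1:
            raise LayoutError(f"cols must be >= 1, got {self.cols}")
        if self.pitch_mm <= 0:
            raise LayoutError(f"pitch_mm must be > 0, got {self.pitch_mm}")
        if not 0 < self.spot_diameter_mm < self.pitch_mm:
            raise LayoutError(
                "spot_diameter_mm must satisfy 0 < diameter < pitch; got "
                f"spot_diameter_mm={self.spot_diameter_mm}, pitch_mm={self.pitch_mm}"
            )

    @property
    def n_spots(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class DishLayout:
    """Subculture pillar dish; metadata only (no screening happens on it)."""

    n_pillars: int = 73
    pillar_diameter_mm: float = 5.0
    pitch_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.n_pillars < 1:
            raise LayoutError(f"n_pillars must be >= 1, got {self.n_pillars}")
        if self.pillar_diameter_mm <= 0 or self.pitch_mm <= 0:
            raise LayoutError("pillar_diameter_mm and pitch_mm must be > 0")


def build_chip_layout(
    rows: int, cols: int, pitch_mm: float, spot_diameter_mm: float
) -> ChipLayout:
    """Validate and construct a :class:`ChipLayout`."""
    return ChipLayout(rows, cols, pitch_mm, spot_diameter_mm)


def pillar_chip_layout() -> ChipLayout:
    """The 532-spot micropillar chip: 14 x 38 grid, 1.5 mm pitch, 0.75 mm pillars.

    The grid shape 14 x 38 is the factorisation of 532 consistent with the
    75 x 25 mm slide footprint at 1.5 mm pitch.
    """
    return ChipLayout(rows=14, cols=38, pitch_mm=1.5, spot_diameter_mm=0.75)


def well_chip_layout() -> ChipLayout:
    """The matching 532-well chip: same grid, 1.2 mm well diameter."""
    return ChipLayout(rows=14, cols=38, pitch_mm=1.5, spot_diameter_mm=1.2)


@dataclass(frozen=True)
class RegionMap:
    """Assignment of chip spots to drug regions.

    ``assignment`` maps each 1-based region id to the ordered tuple of
    spot indices holding that region's technical replicates.  Spots not
    assigned to any region are listed in ``unused_spots``.
    """

    n_regions: int
    replicates_per_region: int
    control_region_ids: frozenset[int]
    assignment: Mapping[int, tuple[int, ...]]
    unused_spots: tuple[int, ...]

    def __post_init__(self) -> None:
        ids = set(self.assignment)
        if ids != set(range(1, self.n_regions + 1)):
            raise LayoutError("assignment must cover region ids 1..n_regions")
        if not set(self.control_region_ids) <= ids:
            raise LayoutError(
                f"control_region_ids {sorted(self.control_region_ids)} not all "
                f"within region ids 1..{self.n_regions}"
            )
        seen: set[int] = set()
        for rid, spots in self.assignment.items():
            if len(spots) != self.replicates_per_region:
                raise LayoutError(
                    f"region {rid} has {len(spots)} spots, expected "
                    f"{self.replicates_per_region}"
                )
            overlap = seen.intersection(spots)
            if overlap:
                raise LayoutError(f"spots assigned to multiple regions: {sorted(overlap)}")
            seen.update(spots)
        if seen.intersection(self.unused_spots):
            raise LayoutError("unused_spots overlap assigned spots")

    @property
    def region_ids(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_regions + 1))

    @property
    def drug_region_ids(self) -> tuple[int, ...]:
        """Region ids that hold drugs (i.e. not vehicle controls)."""
        return tuple(r for r in self.region_ids if r not in self.control_region_ids)

    @property
    def n_assigned(self) -> int:
        return self.n_regions * self.replicates_per_region

    def iter_assigned(self):
        """Yield ``(spot_index, region_id, replicate)`` for every assigned spot.

        Replicates are numbered 1..replicates_per_region in assignment order.
        """
        for rid in self.region_ids:
            for k, spot in enumerate(self.assignment[rid], start=1):
                yield spot, rid, k

    def spot_to_region(self) -> dict[int, int]:
        return {s: r for s, r, _ in self.iter_assigned()}


def build_region_map(
    layout: ChipLayout,
    n_regions: int = 72,
    replicates_per_region: int = 6,
    control_region_ids: Sequence[int] = (1, 37),
) -> RegionMap:
    """Assign spots to regions in consecutive row-major blocks.

    Region r (1-based) receives spot indices
    ``[(r-1)*k, r*k)`` with ``k = replicates_per_region``; leftover spots at
    the end of the grid are unused.  The default 72 x 6 layout on the
    532-spot chip leaves 100 unused spots.  The block convention is a
    deterministic stand-in for the (unpublished) physical plate map.
    """
    if n_regions < 1 or replicates_per_region < 1:
        raise LayoutError("n_regions and replicates_per_region must be >= 1")
    needed = n_regions * replicates_per_region
    if needed > layout.n_spots:
        raise LayoutError(
            f"region map needs {needed} spots but layout has only {layout.n_spots}"
        )
    bad = [c for c in control_region_ids if not 1 <= c <= n_regions]
    if bad:
        raise LayoutError(f"control region ids {bad} outside 1..{n_regions}")
    assignment = {
        rid: tuple(range((rid - 1) * replicates_per_region, rid * replicates_per_region))
        for rid in range(1, n_regions + 1)
    }
    unused = tuple(range(needed, layout.n_spots))
    return RegionMap(
        n_regions=n_regions,
        replicates_per_region=replicates_per_region,
        control_region_ids=frozenset(control_region_ids),
        assignment=assignment,
        unused_spots=unused,
    )


def spot_position(layout: ChipLayout, spot_index: int) -> tuple[float, float]:
    """Center of a spot in mm, origin at spot 0, x along columns, y along rows."""
    if not 0 <= spot_index < layout.n_spots:
        raise LayoutError(
            f"spot_index {spot_index} out of range 0..{layout.n_spots - 1}"
        )
    row, col = divmod(spot_index, layout.cols)
    return col * layout.pitch_mm, row * layout.pitch_mm


def spot_index_at(layout: ChipLayout, x_mm: float, y_mm: float) -> int:
    """Index of the grid node nearest to a position (inverse of spot_position)."""
    col = round(x_mm / layout.pitch_mm)
    row = round(y_mm / layout.pitch_mm)
    if not (0 <= col < layout.cols and 0 <= row < layout.rows):
        raise LayoutError(f"position ({x_mm}, {y_mm}) mm falls outside the grid")
    return row * layout.cols + col


# ---------------------------------------------------------------------------
# JSON config round-trip

def chip_config_to_dict(layout: ChipLayout, region_map: RegionMap) -> dict:
    return {
        "rows": layout.rows,
        "cols": layout.cols,
        "pitch_mm": layout.pitch_mm,
        "spot_diameter_mm": layout.spot_diameter_mm,
        "n_regions": region_map.n_regions,
        "replicates_per_region": region_map.replicates_per_region,
        "control_region_ids": sorted(region_map.control_region_ids),
        "assignment": {str(r): list(s) for r, s in region_map.assignment.items()},
    }


def chip_config_from_dict(cfg: Mapping) -> tuple[ChipLayout, RegionMap]:
    layout = ChipLayout(
        rows=int(cfg["rows"]),
        cols=int(cfg["cols"]),
        pitch_mm=float(cfg["pitch_mm"]),
        spot_diameter_mm=float(cfg["spot_diameter_mm"]),
    )
    assignment = {int(r): tuple(s) for r, s in cfg["assignment"].items()}
    assigned = {s for spots in assignment.values() for s in spots}
    unused = tuple(s for s in range(layout.n_spots) if s not in assigned)
    region_map = RegionMap(
        n_regions=int(cfg["n_regions"]),
        replicates_per_region=int(cfg["replicates_per_region"]),
        control_region_ids=frozenset(int(c) for c in cfg["control_region_ids"]),
        assignment=assignment,
        unused_spots=unused,
    )
    return layout, region_map


def save_chip_config(path: str | Path, layout: ChipLayout, region_map: RegionMap) -> None:
    Path(path).write_text(json.dumps(chip_config_to_dict(layout, region_map), indent=1))


def load_chip_config(path: str | Path) -> tuple[ChipLayout, RegionMap]:
    return chip_config_from_dict(json.loads(Path(path).read_text()))
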