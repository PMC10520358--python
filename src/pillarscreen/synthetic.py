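"""Synthetic screens: true drug effects -> spot areas -> rendered chip images.

The generator emulates the statistical structure of the fluorescent
readout the analysis assumes:

* each drug has a *true* relative viability (% of vehicle control) under
  each culture model, with 3D culture shifted toward resistance;
* every assigned chip spot carries a live-cell area proportional to the
  true viability of its region's drug, perturbed by multiplicative
  lognormal replicate noise and subject to random dropout;
* a scanned chip image is a grid of filled fluorescent disks whose pixel
  areas equal the spot areas, on a uniform background, optionally
  blurred.

Everything is seeded and bit-reproducible; the renderer also returns a
ground-truth label mask so that quantification can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import tifffile

from .chip_model import ChipLayout, RegionMap, spot_position

SPOT_TABLE_COLUMNS = ["spot_index", "region_id", "replicate", "live_area_px", "valid"]


class SyntheticError(ValueError):
    """Invalid synthetic-generation parameters."""


@dataclass(frozen=True)
class EffectSpec:
    """Distribution of true per-drug viabilities in the two culture models.

    2D viability is uniform on ``[low2d, high2d]``; the matched 3D
    viability is the 2D value plus ``shift3d`` (the resistance shift) plus
    Gaussian scatter ``sd3d``, truncated at zero.  The default shift of
    75 percentage points mirrors the observed panel-mean gap between
    monolayer and hydrogel-dome screens (~27% vs ~103%).
    """

    low2d: float = 0.0
    high2d: float = 100.0
    shift3d: float = 75.0
    sd3d: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.low2d <= self.high2d:
            raise SyntheticError(
                f"need 0 <= low2d <= high2d, got [{self.low2d}, {self.high2d}]"
            )
        if self.sd3d < 0:
            raise SyntheticError(f"sd3d must be >= 0, got {self.sd3d}")

    @classmethod
    def null(cls) -> "EffectSpec":
        """No drug effect: every drug at 100% viability in both models."""
        return cls(low2d=100.0, high2d=100.0, shift3d=0.0, sd3d=0.0)


@dataclass(frozen=True)
class ImageSpec:
    """Rendering parameters for synthetic scanner images."""

    pixels_per_mm: float = 20.0
    bit_depth: int = 16
    background_level: int = 500
    foreground_level: int = 20000
    blur_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        top = 2**self.bit_depth - 1
        if not 0 <= self.background_level < self.foreground_level <= top:
            raise SyntheticError(
                "need 0 <= background < foreground <= bit-depth maximum; got "
                f"background={self.background_level}, foreground={self.foreground_level}, "
                f"max={top}"
            )
        if self.pixels_per_mm <= 0:
            raise SyntheticError("pixels_per_mm must be > 0")
        if self.blur_sigma_px < 0:
            raise SyntheticError("blur_sigma_px must be >= 0")

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint16 if self.bit_depth == 16 else np.uint8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic chip.

    ``base_area_px`` is the live area of a fully viable (100%) spot; the
    default of 80 px leaves headroom inside a 0.75 mm pillar disk at the
    default 20 px/mm rendering resolution (capacity ~177 px) even for
    resistant spots approaching twice the control area.  ``noise_cv`` is
    the coefficient of variation of the multiplicative replicate noise;
    ``dropout_p`` the probability a spot is lost (spotting failure,
    debris).
    """

    base_area_px: float = 80.0
    noise_cv: float = 0.05
    dropout_p: float = 0.0
    seed: int = 0
    image: ImageSpec = field(default_factory=ImageSpec)

    def __post_init__(self) -> None:
        if self.base_area_px <= 0:
            raise SyntheticError(f"base_area_px must be > 0, got {self.base_area_px}")
        if self.noise_cv < 0:
            raise SyntheticError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if not 0 <= self.dropout_p <= 1:
            raise SyntheticError(f"dropout_p must be in [0, 1], got {self.dropout_p}")


def sample_true_effects(
    n_drugs: int, seed: int, spec: EffectSpec | None = None
) -> pd.DataFrame:
    """Draw true per-drug viabilities for both culture models.

    Returns a DataFrame with columns ``drug_id`` (1..n_drugs),
    ``rv2d_true`` and ``rv3d_true`` (% of control, >= 0).  Vehicle
    controls are not part of this table; they are pinned at 100% when
    areas are generated.
    """
    if n_drugs < 1:
        raise SyntheticError(f"n_drugs must be >= 1, got {n_drugs}")
    spec = spec or EffectSpec()
    rng = np.random.default_rng(seed)
    rv2d = rng.uniform(spec.low2d, spec.high2d, size=n_drugs)
    rv3d = rv2d + spec.shift3d + rng.normal(0.0, spec.sd3d, size=n_drugs) if spec.sd3d > 0 \
        else rv2d + spec.shift3d
    rv3d = np.maximum(rv3d, 0.0)
    return pd.DataFrame(
        {"drug_id": np.arange(1, n_drugs + 1), "rv2d_true": rv2d, "rv3d_true": rv3d}
    )


def effects_by_region(effects: pd.DataFrame, region_map: RegionMap, model: str) -> dict[int, float]:
    """Map each region id to its true viability under one culture model.

    Drug regions (ascending id) are paired with effect rows in order;
    control regions are fixed at 100%.
    """
    col = {"2D": "rv2d_true", "3D": "rv3d_true"}.get(model)
    if col is None:
        raise SyntheticError(f"model must be '2D' or '3D', got {model!r}")
    drug_regions = region_map.drug_region_ids
    if len(effects) != len(drug_regions):
        raise SyntheticError(
            f"effect table has {len(effects)} drugs but the region map has "
            f"{len(drug_regions)} drug regions"
        )
    out = {rid: 100.0 for rid in region_map.control_region_ids}
    out.update(dict(zip(drug_regions, effects[col].to_numpy(dtype=float))))
    return out


def generate_spot_areas(
    effects: pd.DataFrame,
    region_map: RegionMap,
    config: SyntheticConfig,
    model: str = "3D",
) -> pd.DataFrame:
    """Simulate per-spot live areas for one chip (one culture model).

    Each assigned spot receives
    ``area = base_area_px * viability/100 * lognormal(mean 1, cv)`` and is
    then marked invalid with probability ``dropout_p``.  The lognormal is
    parameterised to have unit mean and coefficient of variation
    ``noise_cv`` (sigma^2 = ln(1 + cv^2)), so areas stay positive and
    scale with cell number.  Returns a spot table with columns
    ``spot_index, region_id, replicate, live_area_px, valid``.
    """
    viab = effects_by_region(effects, region_map, model)
    rng = np.random.default_rng(config.seed)
    rows = list(region_map.iter_assigned())
    n = len(rows)
    base = np.array([viab[rid] / 100.0 * config.base_area_px for _, rid, _ in rows])
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
    else:
        noise = np.ones(n)
    valid = rng.random(n) >= config.dropout_p
    return pd.DataFrame(
        {
            "spot_index": [s for s, _, _ in rows],
            "region_id": [r for _, r, _ in rows],
            "replicate": [k for _, _, k in rows],
            "live_area_px": base * noise,
            "valid": valid,
        }
    )


def _disk_pixels(cx: float, cy: float, r_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Candidate pixel centers within ``r_max`` of (cx, cy), sorted by
    (squared distance, row, column) — a deterministic fill order."""
    x0, x1 = int(np.floor(cx - r_max)), int(np.ceil(cx + r_max)) + 1
    y0, y1 = int(np.floor(cy - r_max)), int(np.ceil(cy + r_max)) + 1
    ys, xs = np.mgrid[y0:y1, x0:x1]
    d2 = (xs + 0.5 - cx) ** 2 + (ys + 0.5 - cy) ** 2
    inside = d2 <= r_max**2
    ys, xs, d2 = ys[inside], xs[inside], d2[inside]
    order = np.lexsort((xs, ys, d2))
    return ys[order], xs[order]


def render_chip_image(
    spots: pd.DataFrame, layout: ChipLayout, spec: ImageSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Render a synthetic scanned chip and its ground-truth label mask.

    Each *valid* spot is drawn as a filled disk of exactly
    ``round(live_area_px)`` pixels at ``foreground_level`` on a uniform
    ``background_level``, centered on its grid node; pixels are added in
    order of distance from the center (ties broken row-major), so the
    rendered area is area-exact by construction.  The mask holds the spot
    index of every foreground pixel and -1 elsewhere.  Gaussian blur, if
    requested, is applied to the image only (the mask stays crisp).

    Raises if a requested area exceeds the capacity of the layout's spot
    disk at the given resolution.
    """
    spec = spec or ImageSpec()
    ppm = spec.pixels_per_mm
    pitch_px = layout.pitch_mm * ppm
    margin = pitch_px / 2.0
    height = int(np.ceil((layout.rows - 1) * pitch_px + 2 * margin))
    width = int(np.ceil((layout.cols - 1) * pitch_px + 2 * margin))
    img = np.full((height, width), float(spec.background_level))
    mask = np.full((height, width), -1, dtype=np.int32)

    r_max = layout.spot_diameter_mm / 2.0 * ppm
    for row in spots.itertuples(index=False):
        if not row.valid:
            continue
        k = int(round(float(row.live_area_px)))
        if k == 0:
            continue
        x_mm, y_mm = spot_position(layout, int(row.spot_index))
        cx, cy = margin + x_mm * ppm, margin + y_mm * ppm
        ys, xs = _disk_pixels(cx, cy, r_max)
        if k > len(ys):
            raise SyntheticError(
                f"spot {row.spot_index}: requested area {k} px exceeds the "
                f"{len(ys)} px capacity of a {layout.spot_diameter_mm} mm disk "
                f"at {ppm} px/mm"
            )
        img[ys[:k], xs[:k]] = spec.foreground_level
        mask[ys[:k], xs[:k]] = int(row.spot_index)

    if spec.blur_sigma_px > 0:
        img = scipy.ndimage.gaussian_filter(img, sigma=spec.blur_sigma_px)
    top = float(2**spec.bit_depth - 1)
    img = np.clip(np.rint(img), 0, top).astype(spec.dtype)
    return img, mask


def write_chip_image(path, image: np.ndarray) -> None:
    """Write a rendered chip as a single-channel TIFF."""
    tifffile.imwrite(path, image)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a ground-truth mask as a 16-bit label TIFF (labels are
    spot_index + 1; 0 is background)."""
    tifffile.imwrite(path, (mask + 1).astype(np.uint16))
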