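"""Packaged transcriptions of the published screen and subculture tables.

Two fixture tables ship with the package:

``panel_72_compounds.csv``
    The 72-compound screen panel (70 drugs + 2 DMSO vehicle controls at
    positions 1 and 37) of an A549 lung-cancer line screened at 20 uM
    under 2D monolayer and 3D Matrigel-dome culture.  Columns: compound
    number, drug name, annotated target, relative viability (% of DMSO
    control) under 2D and 3D, and the published panel Z-scores.

    The published table's header row is typographically scrambled; the
    column orientation stored here (first viability column = 2D, second =
    3D; first Z column = 2D, second = 3D) is fixed by internal
    consistency: it reproduces the published linear distances of the four
    3D-sensitive drugs with the printed sign, places all four published
    hits at Z(3D) <= -1, and matches the reported across-the-board higher
    viability (drug resistance) under 3D culture.

``subculture_proliferation.csv``
    Per-passage proliferation rates (%) over six 4-day passages of the
    same line grown as hydrogel domes on a 73-pillar subculture dish, for
    Matrigel and alginate scaffolds.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Compound numbers of the DMSO vehicle-control regions.
CONTROL_COMPOUNDS: tuple[int, int] = (1, 37)

#: Compound number used for viability normalization (position-1 DMSO).
NORMALIZATION_CONTROL: int = 1

#: Published per-scaffold summary rows (mean, STDEV, CV as printed, 1 dp).
PRINTED_SUBCULTURE_SUMMARY: dict[str, tuple[float, float, float]] = {
    "Matrigel": (645.9, 5.4, 0.8),
    "Alginate": (463.7, 10.9, 2.4),
}

#: Published linear distances of the four 3D-sensitive drugs (2 dp).
PRINTED_LINEAR_DISTANCES: dict[int, float] = {14: 1.44, 15: 1.72, 27: 1.57, 59: 1.76}

#: Drug names of the published 3D-sensitive hit set.
PUBLISHED_HITS: frozenset[str] = frozenset(
    {"XL147", "Everolimus (RAD001)", "LGK-974", "Regorafenib"}
)


def _read_packaged_csv(name: str) -> pd.DataFrame:
    ref = resources.files("pillarscreen.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_drug_panel() -> pd.DataFrame:
    """Load the 72-compound 2D/3D screen panel.

    Returns
    -------
    DataFrame with columns ``compound_no, drug, target, rv2d, rv3d, z2d,
    z3d``; exactly 72 rows.  Compounds 1 and 37 are vehicle controls;
    compound 1 (the normalization reference) reads exactly 100.00 in both
    viability columns while the position-37 control floats (90.87 2D,
    110.86 3D), which is why normalization treats region 1 alone as the
    reference.
    """
    df = _read_packaged_csv("panel_72_compounds.csv")
    if len(df) != 72:  # guards the packaged data, not pandas
        raise ValueError(f"panel fixture must have 72 rows, found {len(df)}")
    controls = df[df.compound_no.isin(CONTROL_COMPOUNDS)]
    if len(controls) != 2 or not (controls.drug == "DMSO").all():
        raise ValueError("panel fixture controls at positions 1 and 37 must be DMSO")
    ref = df.loc[df.compound_no == NORMALIZATION_CONTROL]
    if not ((ref.rv2d == 100.0).all() and (ref.rv3d == 100.0).all()):
        raise ValueError("normalization control must read exactly 100.00")
    if (df[["rv2d", "rv3d"]] < 0).any().any():
        raise ValueError("relative viabilities must be >= 0")
    return df


def load_subculture_rates() -> pd.DataFrame:
    """Load the six-passage proliferation-rate table.

    Returns a DataFrame with columns ``ecm, passage_index, rate_pct``;
    six passages per scaffold, all rates positive.
    """
    df = _read_packaged_csv("subculture_proliferation.csv")
    counts = df.groupby("ecm").size()
    if not (counts == 6).all():
        raise ValueError(f"expected 6 passages per scaffold, found {dict(counts)}")
    if not (df.rate_pct > 0).all():
        raise ValueError("proliferation rates must be > 0")
    return df


def subculture_rates(ecm: str) -> list[float]:
    """Convenience: the six per-passage rates for one scaffold, in passage order."""
    df = load_subculture_rates()
    sub = df[df.ecm == ecm].sort_values("passage_index")
    if sub.empty:
        raise KeyError(f"unknown scaffold {ecm!r}; have {sorted(df.ecm.unique())}")
    return sub.rate_pct.tolist()
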