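import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pillarscreen.fixtures import CONTROL_COMPOUNDS
from pillarscreen.screen_stats import (
    DegeneratePanelError,
    HitRule,
    build_comparison,
    calibrate_zscore_convention,
    call_hits,
    linear_distance,
    panel_zscores,
    resistance_shift,
)


def _viab(values, ids=None):
    ids = ids if ids is not None else range(1, len(values) + 1)
    return pd.DataFrame({"region_id": list(ids), "relative_viability_pct": values})


class TestPanelZScores:
    def test_three_point_panel_population_mode(self):
        # hand computation: mean 50, population sd 40.8248
        out, stats = panel_zscores(_viab([0.0, 50.0, 100.0]), control_ids=())
        np.testing.assert_allclose(out.z, [-1.2247, 0.0, 1.2247], atol=1e-4)
        assert stats.sd == pytest.approx(40.8248, abs=1e-4)

    def test_fixture_regorafenib_z3d(self, panel):
        out, _ = panel_zscores(panel, control_ids=CONTROL_COMPOUNDS,
                               value_col="rv3d", id_col="compound_no")
        z = out.loc[out.compound_no == 59, "z"].iloc[0]
        assert z == pytest.approx(-3.38, abs=0.03)

    def test_controls_scored_even_when_excluded_from_stats(self):
        out, stats = panel_zscores(_viab([100.0, 10.0, 20.0, 30.0]),
                                   control_ids=(1,), include_controls=False)
        assert stats.n_used == 3
        assert len(out) == 4 and np.isfinite(out.z).all()

    def test_degenerate_panel_raises(self):
        with pytest.raises(DegeneratePanelError):
            panel_zscores(_viab([50.0, 50.0, 50.0]))

    def test_normalization_invariant(self, panel):
        # population mode over the included set: mean(z)=0, sd(z)=1 to 1e-9
        for col in ("rv2d", "rv3d"):
            out, _ = panel_zscores(panel, control_ids=CONTROL_COMPOUNDS,
                                   value_col=col, id_col="compound_no")
            assert abs(out.z.mean()) < 1e-9
            assert abs(out.z.std(ddof=0) - 1.0) < 1e-9


class TestCalibrateConvention:
    def test_fixture_selects_population_with_controls(self, panel):
        calib = calibrate_zscore_convention(panel)
        assert calib.include_controls is True
        assert calib.sd_mode == "population"
        assert max(calib.max_abs_dev.values()) <= 0.02

    def test_round_trip_on_synthetic_fixture(self):
        # printed z generated under sample SD / controls excluded is identified
        rng = np.random.default_rng(0)
        rv2d = rng.uniform(0, 100, 30)
        rv3d = rng.uniform(50, 150, 30)
        ids = np.arange(1, 31)
        controls = [1, 15]
        mask = ~np.isin(ids, controls)
        fake = pd.DataFrame({
            "compound_no": ids,
            "rv2d": rv2d,
            "rv3d": rv3d,
            "z2d": (rv2d - rv2d[mask].mean()) / rv2d[mask].std(ddof=1),
            "z3d": (rv3d - rv3d[mask].mean()) / rv3d[mask].std(ddof=1),
        })
        calib = calibrate_zscore_convention(fake, control_ids=controls)
        assert calib.include_controls is False
        assert calib.sd_mode == "sample"

    def test_two_point_panel_distinguishes_sd_modes(self):
        # symmetric two-point panel: |z| = 1 (population) vs 1/sqrt(2) (sample)
        out_pop, _ = panel_zscores(_viab([0.0, 100.0]), sd_mode="population")
        out_samp, _ = panel_zscores(_viab([0.0, 100.0]), sd_mode="sample")
        np.testing.assert_allclose(np.abs(out_pop.z), 1.0)
        np.testing.assert_allclose(np.abs(out_samp.z), math.sqrt(0.5))


class TestLinearDistance:
    @pytest.mark.parametrize(
        "z3d,z2d,expected",
        [(-2.64, -0.61, 1.44), (-3.38, -0.89, 1.76), (-1.74, 0.69, 1.72)],
    )
    def test_published_distances(self, z3d, z2d, expected):
        assert linear_distance(z3d, z2d) == pytest.approx(expected, abs=0.005)

    def test_identity_line_gives_zero(self):
        assert linear_distance(1.7, 1.7) == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            linear_distance(float("nan"), 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_antisymmetry(self, a, b):
        assert linear_distance(a, b) == pytest.approx(-linear_distance(b, a), abs=1e-12)


def _fixture_comparison(panel):
    tabs = {}
    for col, label in (("rv2d", "2D"), ("rv3d", "3D")):
        tabs[label], _ = panel_zscores(panel, control_ids=CONTROL_COMPOUNDS,
                                       value_col=col, id_col="compound_no")
    comp = build_comparison(tabs["2D"], tabs["3D"], id_col="compound_no")
    return comp.merge(panel[["compound_no", "drug"]], on="compound_no")


class TestCallHits:
    def test_fixture_yields_the_four_published_hits(self, panel):
        flagged = call_hits(_fixture_comparison(panel), HitRule(),
                            control_ids=CONTROL_COMPOUNDS, id_col="compound_no")
        hits = flagged[flagged.is_hit]
        assert set(hits.drug) == {
            "XL147", "Everolimus (RAD001)", "LGK-974", "Regorafenib",
        }
        # sorted by descending linear distance
        assert list(hits.drug) == [
            "Regorafenib", "Everolimus (RAD001)", "LGK-974", "XL147",
        ]

    def test_empty_input_gives_empty_hits(self):
        empty = pd.DataFrame(columns=["compound_no", "z2d", "z3d", "ld"])
        flagged = call_hits(empty, HitRule(), id_col="compound_no")
        assert flagged.empty

    def test_lowering_ld_threshold_admits_lapatinib_and_bez235(self, panel):
        # brute-force over all 72 rows: at ld > 0.85 two more drugs qualify
        flagged = call_hits(_fixture_comparison(panel), HitRule(ld_min=0.85),
                            control_ids=CONTROL_COMPOUNDS, id_col="compound_no")
        hits = set(flagged[flagged.is_hit].drug)
        assert hits == {
            "XL147", "Everolimus (RAD001)", "LGK-974", "Regorafenib",
            "Lapatinib", "BEZ235",
        }

    def test_rule_boundaries_inclusive_z_strict_ld(self):
        comp = pd.DataFrame({
            "compound_no": [2, 3, 4],
            "z2d": [0.0, 0.0, 0.0],
            "z3d": [-1.0, -1.0, -0.99],
            "ld": [1.0, 1.0001, 1.5],
        })
        flagged = call_hits(comp, HitRule(), id_col="compound_no")
        by_id = flagged.set_index("compound_no").is_hit
        assert not by_id[2]  # ld == 1 is not > 1
        assert by_id[3]  # z3d == -1 qualifies (inclusive)
        assert not by_id[4]  # z3d > -1 fails


class TestResistanceShift:
    def test_fixture_70_of_70_more_viable_in_3d(self, panel):
        p2 = panel.rename(columns={"rv2d": "relative_viability_pct"})
        p3 = panel.rename(columns={"rv3d": "relative_viability_pct"})
        shift = resistance_shift(p2, p3, control_ids=CONTROL_COMPOUNDS,
                                 id_col="compound_no")
        assert shift.n_compounds == 70
        assert shift.n_higher_3d == 70
        assert shift.slope_through_origin > 1.0

    def test_identical_panels(self):
        p = _viab([10.0, 20.0, 30.0])
        shift = resistance_shift(p, p, control_ids=())
        assert shift.n_higher_3d == 0
        assert shift.slope_through_origin == pytest.approx(1.0)

    def test_exact_proportionality(self):
        p2 = _viab([10.0, 20.0, 30.0])
        p3 = p2.copy()
        p3["relative_viability_pct"] = p3.relative_viability_pct * 2
        shift = resistance_shift(p2, p3, control_ids=())
        assert shift.slope_through_origin == pytest.approx(2.0)

    def test_mismatched_compounds_reported(self):
        p2 = _viab([10.0, 20.0], ids=[1, 2])
        p3 = _viab([10.0, 20.0], ids=[1, 3])
        with pytest.raises(ValueError, match=r"only-2D=\[2\].*only-3D=\[3\]"):
            resistance_shift(p2, p3, control_ids=())


class TestAffineInvariance:
    @settings(derandomize=True, max_examples=30)
    @given(st.floats(-50, 200), st.floats(0.05, 20))
    def test_hits_invariant_under_affine_rescaling(self, shift_c, scale_k):
        # adding a constant or scaling all viabilities leaves z, ld, hits unchanged
        rng = np.random.default_rng(42)
        base2 = rng.uniform(0, 100, 30)
        base3 = rng.uniform(20, 150, 30)

        def pipeline(v2, v3):
            t2, _ = panel_zscores(_viab(v2))
            t3, _ = panel_zscores(_viab(v3))
            comp = call_hits(build_comparison(t2, t3), HitRule(), control_ids=())
            return comp.sort_values("region_id").reset_index(drop=True)

        a = pipeline(base2, base3)
        b = pipeline(base2 * scale_k + shift_c, base3 * scale_k + shift_c)
        np.testing.assert_allclose(b.z2d, a.z2d, atol=1e-8)
        np.testing.assert_allclose(b.z3d, a.z3d, atol=1e-8)
        np.testing.assert_allclose(b.ld, a.ld, atol=1e-8)
        assert (b.is_hit == a.is_hit).all()
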