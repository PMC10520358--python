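"""Subculture proliferation-rate QC.

One passage's proliferation rate is the number of live cells recovered
after a 4-day culture as a percentage of the cells seeded.  Stability of
a subculture protocol over repeated passages is certified by the mean,
sample SD (n-1 divisor) and coefficient of variation (CV = 100 x SD/mean)
of the per-passage rates; a CV below ~5% is taken as stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .fixtures import PRINTED_SUBCULTURE_SUMMARY, load_subculture_rates


def proliferation_rate(seeded: float, recovered: float) -> float:
    """Recovered live cells as a percentage of seeded cells."""
    if seeded <= 0:
        raise ValueError(f"seeded cell count must be > 0, got {seeded}")
    if recovered < 0:
        raise ValueError(f"recovered cell count must be >= 0, got {recovered}")
    return 100.0 * recovered / seeded


@dataclass(frozen=True)
class SubcultureSummary:
    """Mean/SD/CV of per-passage proliferation rates for one scaffold."""

    ecm: str
    n_passages: int
    mean_rate: float  # %
    sd_rate: float  # %, sample SD (n-1)
    cv_pct: float  # 100 x sd/mean

    def rounded(self, ndigits: int = 1) -> "SubcultureSummary":
        """Report-style copy with values rounded half-up."""
        return SubcultureSummary(
            self.ecm,
            self.n_passages,
            round_half_up(self.mean_rate, ndigits),
            round_half_up(self.sd_rate, ndigits),
            round_half_up(self.cv_pct, ndigits),
        )


def summarize_passages(rates: Sequence[float], ecm: str = "") -> SubcultureSummary:
    """Summarize a series of per-passage proliferation rates.

    Uses the sample SD (n-1 divisor); requires at least two passages.
    Values are kept at full precision — reports round separately.
    """
    r = np.asarray(list(rates), dtype=float)
    if len(r) < 2:
        raise ValueError(f"need >= 2 passage rates, got {len(r)}")
    mean = float(r.mean())
    sd = float(r.std(ddof=1))
    return SubcultureSummary(
        ecm=ecm,
        n_passages=len(r),
        mean_rate=mean,
        sd_rate=sd,
        cv_pct=100.0 * sd / mean,
    )


def compare_to_published(tolerance: float = 0.1) -> pd.DataFrame:
    """Recompute the per-scaffold summaries and compare to the printed rows.

    For each scaffold and statistic (mean, SD, CV) the computed value is
    compared against the published one; ``reproduced`` is true when the
    absolute deviation is below one unit of the last printed digit
    (default 0.1, accommodating the publication's truncate-vs-round
    ambiguity at 1 dp).  The published Matrigel STDEV (5.4) and CV (0.8)
    are *not* reproduced by the sample SD of the printed rates (~7.7 /
    ~1.2) and are flagged here rather than force-matched; the printed 5.4
    coincides with the mean absolute deviation of the rates (~5.47),
    suggesting a different dispersion statistic was used for that row.
    """
    df = load_subculture_rates()
    rows = []
    for ecm, printed in PRINTED_SUBCULTURE_SUMMARY.items():
        rates = df.loc[df.ecm == ecm].sort_values("passage_index").rate_pct.tolist()
        s = summarize_passages(rates, ecm)
        for stat, computed, pub in zip(
            ("mean", "sd", "cv"), (s.mean_rate, s.sd_rate, s.cv_pct), printed
        ):
            rows.append(
                {
                    "ecm": ecm,
                    "statistic": stat,
                    "computed": computed,
                    "published": pub,
                    "abs_dev": abs(computed - pub),
                    "reproduced": abs(computed - pub) < tolerance,
                }
            )
    return pd.DataFrame(rows)
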