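"""Regrowth antagonistic-pleiotropy screen (three-sample pilot design).

Alleles that help a non-dividing cell survive aging often hurt it during
proliferative growth.  The pilot design measures, per locus, the
allele-frequency change across the aging time course (lifespan dAF =
AF(day 6) - AF(day 0)) and across regrowth of the aged sample (growth dAF
= AF(day 6 regrown) - AF(day 6)).  Loci whose two changes both exceed a
cutoff (default 0.15) with opposite signs are classified antagonistic,
and the genome-wide Pearson correlation between the two changes
summarizes the overall pleiotropy pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator


def delta_af(day0, day6, day6_regrown, min_depth: int = 10) -> pd.DataFrame:
    """Per-marker lifespan and growth allele-frequency changes.

    Each argument is a ``(k, n)`` pair of arrays over the shared marker
    list.  A marker is informative only when all three samples meet
    ``min_depth``; non-informative rows keep NaN changes.
    """
    (k0, n0), (k6, n6), (kr, nr) = day0, day6, day6_regrown
    arrs = [np.asarray(a, dtype=float) for a in (k0, n0, k6, n6, kr, nr)]
    k0, n0, k6, n6, kr, nr = arrs
    with np.errstate(invalid="ignore", divide="ignore"):
        af0 = np.where(n0 > 0, k0 / np.maximum(n0, 1), np.nan)
        af6 = np.where(n6 > 0, k6 / np.maximum(n6, 1), np.nan)
        afr = np.where(nr > 0, kr / np.maximum(nr, 1), np.nan)
    informative = (n0 >= min_depth) & (n6 >= min_depth) & (nr >= min_depth)
    df = pd.DataFrame(
        {
            "af_day0": af0,
            "af_day6": af6,
            "af_regrown": afr,
            "lifespan_daf": np.where(informative, af6 - af0, np.nan),
            "growth_daf": np.where(informative, afr - af6, np.nan),
            "informative": informative,
        }
    )
    return df


@dataclass
class PleiotropySummary:
    """Fractions of changed loci and the antagonistic call set."""

    n_informative: int
    frac_lifespan_changed: float
    frac_growth_changed: float
    frac_antagonistic: float
    frac_joint_changed: float  # both axes exceed the cutoff, any signs
    antagonistic_index: np.ndarray


def classify(records: pd.DataFrame, cutoff: float = 0.15) -> PleiotropySummary:
    """Classify informative loci by |dAF| exceedance and sign discordance.

    Antagonistic = |lifespan dAF| > cutoff and |growth dAF| > cutoff with
    opposite signs.  The joint-exceedance fraction (no sign requirement)
    is reported alongside.
    """
    rec = records[records["informative"]]
    if len(rec) == 0:
        raise ValueError("no informative records to classify")
    life = rec["lifespan_daf"].to_numpy(dtype=float)
    grow = rec["growth_daf"].to_numpy(dtype=float)
    life_big = np.abs(life) > cutoff
    grow_big = np.abs(grow) > cutoff
    joint = life_big & grow_big
    antag = joint & (life * grow < 0)
    return PleiotropySummary(
        n_informative=len(rec),
        frac_lifespan_changed=float(life_big.mean()),
        frac_growth_changed=float(grow_big.mean()),
        frac_antagonistic=float(antag.mean()),
        frac_joint_changed=float(joint.mean()),
        antagonistic_index=rec.index.to_numpy()[antag],
    )


def correlate(records: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of growth dAF vs lifespan dAF (informative loci)."""
    rec = records[records["informative"]]
    x = rec["lifespan_daf"].to_numpy(dtype=float)
    y = rec["growth_daf"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("correlation needs at least three informative records")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in delta-AF records")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


class RegrowthScreen(BaseEstimator):
    """End-to-end pleiotropy screen over a three-sample count set.

    Parameters: ``cutoff`` on |dAF| (default 0.15) and ``min_depth``
    required at all three samples (default 10).  After
    ``fit(day0, day6, day6_regrown)``: ``records_`` (per-marker frame),
    ``summary_`` (:class:`PleiotropySummary`), ``r_`` and ``p_``.
    """

    def __init__(self, cutoff: float = 0.15, min_depth: int = 10):
        self.cutoff = cutoff
        self.min_depth = min_depth

    def fit(self, day0, day6, day6_regrown):
        self.records_ = delta_af(day0, day6, day6_regrown, self.min_depth)
        self.summary_ = classify(self.records_, self.cutoff)
        self.r_, self.p_ = correlate(self.records_)
        return self
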