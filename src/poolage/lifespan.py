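"""Chronological-lifespan curve statistics.

Viability is the colony-forming-unit (CFU) count at day *d* normalized to
day 0 (cultures sampled in triplicate).  Derived statistics: median
lifespan (first linear-interpolated crossing of 50% viability), maximal
lifespan (last day above a small viability floor), the survival integral
(trapezoidal area under the viability curve), and the phloxine-staining
correction used to keep the number of live cells sampled constant as a
culture dies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression


@dataclass
class StainCount:
    """Phloxine-B staining tally: dead cells stain; live fraction = 1 - stained/total."""

    stained: int
    total: int = 500

    def __post_init__(self):
        if not 0 <= self.stained <= self.total:
            raise ValueError("stained count must lie in [0, total]")

    @property
    def live_fraction(self) -> float:
        return 1.0 - self.stained / self.total


def sampling_volume(target_live: float, density: float, stain: StainCount) -> float:
    """Culture volume holding ``target_live`` live cells.

    ``density`` is total cells per volume unit; the live fraction comes
    from the stain.  volume = L / (D * f).
    """
    if density <= 0:
        raise ValueError("culture density must be positive")
    f = stain.live_fraction
    if f <= 0:
        raise ValueError("no live cells in the stained sample")
    return target_live / (density * f)


@dataclass
class LifespanCurve:
    """Per-day viability of an aging culture, normalized to day 0.

    ``cfu`` (optional) holds the raw triplicate plate counts the curve was
    derived from; ``viability_sd`` is the first-order propagated SD of the
    normalized viability.
    """

    days: np.ndarray
    viability: np.ndarray
    viability_sd: np.ndarray | None = None
    cfu: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.days.shape != self.viability.shape:
            raise ValueError("days and viability must align")
        if self.days.size and self.days[0] != 0:
            raise ValueError("curves must start at day 0")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.viability < 0):
            raise ValueError("viability cannot be negative")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_cfu(cls, days, cfu, label: str = "") -> "LifespanCurve":
        """Normalize triplicate CFU counts to the day-0 mean.

        v_d = mean(counts_d) / mean(counts_0); v_0 = 1 by construction.
        SDs propagate to the normalized scale:
        sd(v_d) ~= v_d * sqrt(cv_d^2 + cv_0^2) (sd_d/mean_0 when mean_d = 0).
        """
        cfu = np.asarray(cfu, dtype=float)
        if cfu.ndim != 2:
            raise ValueError("cfu must be (days x replicates)")
        mean = cfu.mean(axis=1)
        sd = cfu.std(axis=1, ddof=1)
        if mean[0] <= 0:
            raise ValueError("day-0 mean CFU count must be positive")
        v = mean / mean[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1), 0.0)
        v_sd = np.where(
            mean > 0,
            v * np.sqrt(cv**2 + cv[0] ** 2),
            sd / mean[0],
        )
        return cls(np.asarray(days, float), v, v_sd, cfu=cfu, label=label)

    # -- statistics ---------------------------------------------------------

    def median_lifespan(self) -> float | None:
        """First day at which linearly interpolated viability crosses 0.5.

        None when the curve never reaches 0.5 (undefined, signalled rather
        than extrapolated).
        """
        v, d = self.viability, self.days
        for i in range(len(v)):
            if v[i] <= 0.5:
                if v[i] == 0.5 or i == 0:
                    return float(d[i])
                # linear interpolation on the segment that crosses 0.5
                frac = (v[i - 1] - 0.5) / (v[i - 1] - v[i])
                return float(d[i - 1] + frac * (d[i] - d[i - 1]))
        return None

    def maximal_lifespan(self, floor: float = 0.01) -> float:
        """Last observed day with viability above ``floor``."""
        above = np.flatnonzero(self.viability > floor)
        return float(self.days[above[-1]]) if above.size else float(self.days[0])

    def survival_integral(self) -> float:
        """Trapezoidal area under the viability curve (day x fraction)."""
        if len(self.days) < 2:
            raise ValueError("survival integral needs at least two days")
        return float(np.trapezoid(self.viability, self.days))

    def isotonic_viability(self) -> np.ndarray:
        """Non-increasing cleanup of plating noise (least-squares isotonic fit)."""
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        return iso.fit_transform(self.days, self.viability)


def viability(days, cfu, label: str = "") -> LifespanCurve:
    """Functional alias for :meth:`LifespanCurve.from_cfu`."""
    return LifespanCurve.from_cfu(days, cfu, label=label)


def lifespan_stats(curve: LifespanCurve, floor: float = 0.01) -> dict:
    """Median/maximal lifespan and survival integral as a plain dict."""
    return {
        "label": curve.label,
        "median_lifespan": curve.median_lifespan(),
        "maximal_lifespan": curve.maximal_lifespan(floor),
        "survival_integral": curve.survival_integral(),
    }
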