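"""Binomial likelihood-ratio scoring of allele-frequency trajectories.

For one locus in one replicate pool, the observed counts ``(k_t, n_t)``
across time points are scored under two binomial models:

* a **null** model with a single shared allele frequency, whose maximum-
  likelihood estimate is the pooled fraction ``p_hat = sum k_t / sum n_t``;
* a **saturated** model where each time point gets its own frequency
  ``k_t / n_t``.

The score ``S_r = logL_saturated - logL_null >= 0`` measures how far the
trajectory departs from the best no-change line.  Replicate pools are
independent, so the combined per-locus score is the sum of the defined
per-replicate scores.  A neighbor-support filter then removes isolated
high-scoring spikes: with genuine selection, linkage ("hitchhiking")
produces runs of elevated scores, so a locus whose score differs from both
of its genomic neighbors by more than the population interquartile range
is treated as an artifact.

Quantile convention throughout: linear interpolation between order
statistics (numpy default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .core import MarkerMap, TrajectoryTable

# ---------------------------------------------------------------------------
# single-trajectory primitives
# ---------------------------------------------------------------------------


def null_loglik(k, n) -> tuple[float, float]:
    """Pooled-frequency MLE and its binomial log-likelihood.

    ``p_hat = sum(k)/sum(n)`` over informative (n>0) time points; the MLE
    of a shared binomial frequency.  Raises when every depth is zero.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    use = n > 0
    if not use.any():
        raise ValueError("all depths are zero: null frequency undefined")
    p_hat = k[use].sum() / n[use].sum()
    logl = float(stats.binom.logpmf(k[use], n[use], p_hat).sum())
    return float(p_hat), logl


def saturated_loglik(k, n) -> float:
    """Log-likelihood with a free frequency per time point (k_t/n_t).

    Boundary terms (k_t in {0, n_t}) evaluate with 0*log(0) = 0, i.e. a
    log-pmf of exactly zero.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    use = n > 0
    if not use.any():
        raise ValueError("all depths are zero: saturated likelihood undefined")
    p = k[use] / n[use]
    return float(stats.binom.logpmf(k[use], n[use], p).sum())


def score_trajectory(k, n, min_informative: int = 2) -> float:
    """LR score of one trajectory; NaN when too few informative time points."""
    n_arr = np.asarray(n)
    if int((n_arr > 0).sum()) < min_informative:
        return float("nan")
    _, l0 = null_loglik(k, n)
    l1 = saturated_loglik(k, n)
    return max(l1 - l0, 0.0)


def combine_replicates(scores) -> tuple[float, int]:
    """Sum of the defined per-replicate scores and how many contributed.

    Independence across replicate pools makes the joint likelihood ratio
    the sum of per-replicate log-likelihood differences.
    """
    scores = np.asarray(scores, dtype=float)
    ok = np.isfinite(scores)
    if not ok.any():
        raise ValueError("no replicate has a defined score")
    return float(scores[ok].sum()), int(ok.sum())


# ---------------------------------------------------------------------------
# vectorized table scoring
# ---------------------------------------------------------------------------


def _score_arrays(k: np.ndarray, n: np.ndarray, min_depth: int, min_informative: int,
                  p_sat: np.ndarray | None = None) -> np.ndarray:
    """Per-(marker, replicate) LR scores; NaN where undefined.

    ``p_sat`` optionally overrides the saturated-model frequencies (e.g. a
    genome-smoothed estimate); the null MLE is always the pooled fraction.
    """
    kf = k.astype(float)
    nf = n.astype(float)
    use = n >= max(min_depth, 1)
    n_inf = use.sum(axis=-1)
    ntot = np.where(use, nf, 0.0).sum(axis=-1)
    ktot = np.where(use, kf, 0.0).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(ntot > 0, ktot / np.maximum(ntot, 1), 0.5)
        if p_sat is None:
            p1 = np.where(use, kf / np.maximum(nf, 1), 0.5)
        else:
            p1 = np.clip(p_sat, 0.0, 1.0)
    l0 = np.where(use, stats.binom.logpmf(kf, nf, p0[..., None]), 0.0).sum(axis=-1)
    l1 = np.where(use, stats.binom.logpmf(kf, nf, p1), 0.0).sum(axis=-1)
    s = np.maximum(l1 - l0, 0.0)
    return np.where(n_inf >= min_informative, s, np.nan)


def smooth_allele_frequencies(table: TrajectoryTable, bandwidth: float = 10_000.0) -> np.ndarray:
    """Gaussian-kernel smoothing of raw frequencies along the genome.

    A simple, documented stand-in for probabilistic frequency smoothing:
    for each (replicate, day), the frequency at a marker is the depth- and
    distance-weighted average of raw frequencies at nearby markers on the
    same chromosome (kernel sd = ``bandwidth`` bp).  Returns an array of
    shape ``(markers, replicates, days)``.
    """
    af = np.where(table.n > 0, table.k / np.maximum(table.n, 1), np.nan)
    out = np.full_like(af, np.nan, dtype=float)
    for chrom in table.markers.chromosomes:
        sl = table.markers.chrom_slice(chrom)
        pos = table.markers.df["pos"].to_numpy()[sl].astype(float)
        d2 = (pos[:, None] - pos[None, :]) ** 2
        W = np.exp(-0.5 * d2 / bandwidth**2)
        n_c = table.n[sl].astype(float)
        af_c = np.nan_to_num(af[sl])
        wsum = np.einsum("ij,jrt->irt", W, n_c)
        out[sl] = np.einsum("ij,jrt->irt", W, af_c * n_c) / np.maximum(wsum, 1e-300)
        out[sl][wsum == 0] = np.nan
    return out


class TrajectoryScorer(BaseEstimator, TransformerMixin):
    """Score every locus x replicate trajectory of a TrajectoryTable.

    Parameters
    ----------
    min_depth:
        Minimum depth for a time point to count as informative (default 1).
    min_informative:
        Minimum informative time points for a defined score (default 2; a
        one-point trajectory cannot deviate from its own null).
    use_smoothed_af:
        If True, the saturated model evaluates genome-smoothed frequencies
        (see :func:`smooth_allele_frequencies`) instead of raw ``k_t/n_t``.
        Off by default: the scorer is count-based.
    smoothing_bandwidth:
        Kernel sd in bp for the optional smoothing mode.

    After ``fit``, ``scores_`` holds a genome-ordered frame with one
    ``score_<rep>`` column per replicate, the combined ``score`` (sum over
    defined replicates), and ``n_replicates`` contributing.
    """

    def __init__(
        self,
        min_depth: int = 1,
        min_informative: int = 2,
        use_smoothed_af: bool = False,
        smoothing_bandwidth: float = 10_000.0,
    ):
        self.min_depth = min_depth
        self.min_informative = min_informative
        self.use_smoothed_af = use_smoothed_af
        self.smoothing_bandwidth = smoothing_bandwidth

    def fit(self, X: TrajectoryTable, y=None):
        if not isinstance(X, TrajectoryTable):
            raise TypeError("TrajectoryScorer expects a TrajectoryTable")
        p_sat = (
            smooth_allele_frequencies(X, self.smoothing_bandwidth)
            if self.use_smoothed_af
            else None
        )
        per_rep = _score_arrays(X.k, X.n, self.min_depth, self.min_informative, p_sat)
        df = X.markers.df[["chrom", "pos"]].copy()
        for j, rep in enumerate(X.replicates):
            df[f"score_{rep}"] = per_rep[:, j]
        ok = np.isfinite(per_rep)
        df["score"] = np.where(ok.any(axis=1), np.nansum(per_rep, axis=1), np.nan)
        df["n_replicates"] = ok.sum(axis=1)
        self.per_replicate_ = per_rep
        self.scores_ = df
        return self

    def transform(self, X: TrajectoryTable) -> pd.DataFrame:
        return self.fit(X).scores_


def score_table(table: TrajectoryTable, **params) -> pd.DataFrame:
    """Functional wrapper over :class:`TrajectoryScorer`."""
    return TrajectoryScorer(**params).fit(table).scores_


# ---------------------------------------------------------------------------
# neighbor-support outlier filter
# ---------------------------------------------------------------------------


class NeighborOutlierFilter(BaseEstimator, TransformerMixin):
    """Flag isolated score spikes lacking neighbor (hitchhiking) support.

    The interquartile range is computed over all defined combined scores
    genome-wide.  Under the default ``rule='both'`` a locus is filtered when
    its score differs from *both* genomic neighbors by more than the IQR
    (isolated spikes); ``rule='either'`` is the stricter at-least-one-
    neighbor variant.  Chromosome-terminal loci are compared to their single
    neighbor.

    ``fit`` computes ``iqr_``; ``transform`` returns the frame with a
    boolean ``filtered`` column.
    """

    def __init__(self, rule: str = "both"):
        self.rule = rule

    def fit(self, X: pd.DataFrame, y=None):
        if self.rule not in ("both", "either"):
            raise ValueError("rule must be 'both' or 'either'")
        s = X["score"].to_numpy(dtype=float)
        s = s[np.isfinite(s)]
        if s.size == 0:
            raise ValueError("no defined scores to filter")
        q1, q3 = np.percentile(s, [25, 75])
        self.iqr_ = float(q3 - q1)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.reset_index(drop=True).copy()
        filt = np.zeros(len(out), dtype=bool)
        chroms = out["chrom"].to_numpy()
        scores = out["score"].to_numpy(dtype=float)
        for chrom in dict.fromkeys(chroms):
            pos_idx = np.flatnonzero((chroms == chrom) & np.isfinite(scores))
            s = scores[pos_idx]
            if len(s) < 2:
                continue
            dprev = np.abs(np.diff(s, prepend=np.nan))
            dnext = np.abs(np.diff(s, append=np.nan))
            far_prev = dprev > self.iqr_
            far_next = dnext > self.iqr_
            if self.rule == "both":
                flag = np.where(
                    np.isnan(dprev), far_next, np.where(np.isnan(dnext), far_prev, far_prev & far_next)
                )
            else:
                flag = far_prev & ~np.isnan(dprev)
                flag |= far_next & ~np.isnan(dnext)
            filt[pos_idx] = flag
        out["filtered"] = filt
        return out

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).transform(X)


def neighbor_filter(track: pd.DataFrame, rule: str = "both") -> pd.DataFrame:
    """Functional wrapper over :class:`NeighborOutlierFilter`."""
    return NeighborOutlierFilter(rule=rule).fit_transform(track)
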