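"""Genome scan: sliding-median smoothing, empirical threshold, peak calls.

The per-locus combined scores are smoothed with a physical (bp-based)
sliding median — at each marker, the median score of all unfiltered
markers within a centered window on the same chromosome.  An empirical
threshold tau = Q3 + m * IQR (default m = 1.5) is computed on the
unsmoothed, neighbor-filtered scores; regions are maximal runs of markers
whose smoothed value exceeds tau (merged across sub-window gaps), while
individual candidate variants inside a region are those whose unsmoothed
score exceeds tau.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


def sliding_median(pos: np.ndarray, values: np.ndarray, window: float) -> np.ndarray:
    """Centered sliding median over a physical window on one chromosome.

    Window bounds are inclusive: value_i = median of values at positions in
    ``[pos_i - window/2, pos_i + window/2]``.  A locus alone in its window
    keeps its own value.
    """
    pos = np.asarray(pos, dtype=float)
    values = np.asarray(values, dtype=float)
    half = window / 2.0
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    return np.array([np.median(values[a:b]) for a, b in zip(lo, hi)])


def call_threshold(scores, multiplier: float = 1.5) -> float:
    """Empirical outlier threshold tau = Q3 + multiplier * (Q3 - Q1).

    Quantiles use linear interpolation between order statistics.  Requires
    at least four finite scores.
    """
    s = np.asarray(scores, dtype=float)
    s = s[np.isfinite(s)]
    if s.size < 4:
        raise ValueError("threshold needs at least four finite scores")
    q1, q3 = np.percentile(s, [25, 75])
    return float(q3 + multiplier * (q3 - q1))


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs (inclusive) of maximal True runs."""
    runs = []
    in_run = False
    for i, m in enumerate(mask):
        if m and not in_run:
            start, in_run = i, True
        elif not m and in_run:
            runs.append((start, i - 1))
            in_run = False
    if in_run:
        runs.append((start, len(mask) - 1))
    return runs


def call_peaks(
    track: pd.DataFrame,
    threshold: float,
    window: float = 50_000.0,
    merge_gap: float | None = None,
) -> pd.DataFrame:
    """Peak regions from the smoothed track plus per-region candidates.

    ``track`` needs columns chrom, pos, score, smoothed, filtered.  Runs of
    consecutive unfiltered loci with ``smoothed > threshold`` become peaks;
    runs on the same chromosome separated by less than ``merge_gap`` bp
    (default: the smoothing window, since sub-window gaps are unresolvable
    at the smoothing scale) are merged.  Candidates are member loci with
    unsmoothed ``score > threshold``.  Peaks are ranked by their maximum
    smoothed score.
    """
    if merge_gap is None:
        merge_gap = window
    peaks = []
    for chrom in dict.fromkeys(track["chrom"]):
        sub = track[(track["chrom"] == chrom) & (~track["filtered"])]
        sub = sub[np.isfinite(sub["score"].astype(float))]
        pos = sub["pos"].to_numpy(dtype=float)
        smoothed = sub["smoothed"].to_numpy(dtype=float)
        raw = sub["score"].to_numpy(dtype=float)
        runs = _runs_above(smoothed > threshold)
        merged: list[list[int]] = []
        for a, b in runs:
            if merged and pos[a] - pos[merged[-1][1]] < merge_gap:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            members = slice(a, b + 1)
            cand = np.flatnonzero(raw[members] > threshold) + a
            peaks.append(
                {
                    "chrom": chrom,
                    "start": int(pos[a]),
                    "end": int(pos[b]),
                    "n_markers": b - a + 1,
                    "max_smoothed": float(smoothed[members].max()),
                    "n_candidates": int(cand.size),
                    "candidate_pos": [int(p) for p in pos[cand]],
                }
            )
    out = pd.DataFrame(
        peaks,
        columns=["chrom", "start", "end", "n_markers", "max_smoothed", "n_candidates", "candidate_pos"],
    )
    if len(out):
        out = out.sort_values("max_smoothed", ascending=False).reset_index(drop=True)
        out["rank"] = np.arange(1, len(out) + 1)
    else:
        out["rank"] = pd.Series(dtype=int)
    return out


class GenomeScanner(BaseEstimator):
    """Smooth, threshold, and call peaks on a neighbor-filtered score track.

    Parameters
    ----------
    window:
        Physical smoothing window in bp (default 50 kb).
    iqr_multiplier:
        m in tau = Q3 + m * IQR (default 1.5).
    per_chromosome:
        Compute the threshold per chromosome instead of genome-wide.
    merge_gap:
        Gap (bp) under which adjacent above-threshold runs merge; defaults
        to ``window``.

    Fitted attributes: ``threshold_`` (float, or dict per chromosome),
    ``track_`` (input plus ``smoothed``/``above_threshold``/``peak_id``
    columns), ``peaks_`` (ranked region table).
    """

    def __init__(
        self,
        window: float = 50_000.0,
        iqr_multiplier: float = 1.5,
        per_chromosome: bool = False,
        merge_gap: float | None = None,
    ):
        self.window = window
        self.iqr_multiplier = iqr_multiplier
        self.per_chromosome = per_chromosome
        self.merge_gap = merge_gap

    def fit(self, X: pd.DataFrame, y=None):
        if self.window <= 0 or self.iqr_multiplier <= 0:
            raise ValueError("window and iqr_multiplier must be positive")
        if "filtered" not in X.columns:
            raise ValueError("expected a neighbor-filtered track (missing 'filtered')")
        track = X.reset_index(drop=True).copy()
        scores = track["score"].to_numpy(dtype=float)
        keep = (~track["filtered"].to_numpy()) & np.isfinite(scores)

        smoothed = np.full(len(track), np.nan)
        for chrom in dict.fromkeys(track["chrom"]):
            m = keep & (track["chrom"] == chrom).to_numpy()
            if m.any():
                smoothed[m] = sliding_median(
                    track.loc[m, "pos"].to_numpy(), scores[m], self.window
                )
        track["smoothed"] = smoothed

        if self.per_chromosome:
            self.threshold_ = {
                chrom: call_threshold(scores[keep & (track["chrom"] == chrom).to_numpy()],
                                      self.iqr_multiplier)
                for chrom in dict.fromkeys(track["chrom"])
            }
            track["above_threshold"] = [
                bool(np.isfinite(s) and s > self.threshold_[c])
                for s, c in zip(scores, track["chrom"])
            ]
            pieces = []
            for chrom, tau in self.threshold_.items():
                pieces.append(
                    call_peaks(track[track["chrom"] == chrom], tau, self.window, self.merge_gap)
                )
            peaks = pd.concat(pieces, ignore_index=True)
            if len(peaks):
                peaks = peaks.sort_values("max_smoothed", ascending=False).reset_index(drop=True)
                peaks["rank"] = np.arange(1, len(peaks) + 1)
        else:
            self.threshold_ = call_threshold(scores[keep], self.iqr_multiplier)
            track["above_threshold"] = keep & (scores > self.threshold_)
            peaks = call_peaks(track, self.threshold_, self.window, self.merge_gap)

        peak_id = np.full(len(track), -1)
        for row in peaks.itertuples(index=False):
            inside = (
                (track["chrom"] == row.chrom)
                & (track["pos"] >= row.start)
                & (track["pos"] <= row.end)
            ).to_numpy()
            peak_id[inside & (peak_id == -1)] = row.rank
        track["peak_id"] = peak_id
        self.track_ = track
        self.peaks_ = peaks
        return self


def genome_scan(track: pd.DataFrame, **params) -> GenomeScanner:
    """Fit a :class:`GenomeScanner` and return it."""
    return GenomeScanner(**params).fit(track)
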