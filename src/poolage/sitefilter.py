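"""Declarative site filtering: raw caller output -> segregating-marker list.

Variant calling itself happens upstream (external callers); this module
only owns the downstream vetting: combining two call lists, applying
depth / alternate-fraction / mapping-quality / repeat / proximity rules,
and recording why each rejected site failed.  Independent rules commute;
the proximity rule (which removes *both* members of any too-close pair)
is applied last by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MarkerMap

SITE_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass
class FilterPolicy:
    """Thresholds for the marker vetting rules; ``None`` disables a rule.

    The >0.99 alternate-fraction criterion is the only published value;
    the remaining defaults (min depth 10, max depth 5x the median, min
    inter-site distance 10 bp, max bad-read fraction 0.1) are explicit,
    overridable stand-ins.  ``max_depth=None`` with ``max_depth_from_median``
    set resolves to that multiple of the median site depth.
    """

    min_depth: float | None = 10
    max_depth: float | None = None
    max_depth_from_median: float | None = 5.0
    min_alt_fraction: float | None = 0.99
    max_bad_read_fraction: float | None = 0.1
    min_distance: int | None = 10
    repeat_intervals: pd.DataFrame | None = None  # BED convention: 0-based half-open

    def __post_init__(self):
        for frac in (self.min_alt_fraction, self.max_bad_read_fraction):
            if frac is not None and not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if (
            self.min_depth is not None
            and self.max_depth is not None
            and self.min_depth > self.max_depth
        ):
            raise ValueError("min_depth must not exceed max_depth")

    @classmethod
    def disabled(cls) -> "FilterPolicy":
        """Everything off: apply_filters becomes the identity."""
        return cls(
            min_depth=None,
            max_depth=None,
            max_depth_from_median=None,
            min_alt_fraction=None,
            max_bad_read_fraction=None,
            min_distance=None,
            repeat_intervals=None,
        )


def combine_callsets(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    mode: str = "union",
    labels: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Merge two variant tables keyed by (chrom, pos, ref, alt).

    ``union`` (default) keeps any site in either list; ``intersection``
    keeps shared sites.  A ``source`` column records provenance.  Two
    callsets reporting different REF alleles at the same position indicate
    an upstream inconsistency and raise.
    """
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    a = calls_a.copy()
    b = calls_b.copy()
    for df in (a, b):
        missing = [c for c in SITE_KEY if c not in df.columns]
        if missing:
            raise ValueError(f"callset missing key columns: {missing}")
        df["chrom"] = df["chrom"].astype(str)
    ref_a = a.set_index(["chrom", "pos"])["ref"]
    ref_b = b.set_index(["chrom", "pos"])["ref"]
    shared_pos = ref_a.index.intersection(ref_b.index)
    conflict = shared_pos[(ref_a.loc[shared_pos] != ref_b.loc[shared_pos]).to_numpy()]
    if len(conflict):
        sites = ", ".join(f"{c}:{p}" for c, p in conflict[:10])
        raise ValueError(f"conflicting REF alleles at: {sites}")

    merged = a.merge(
        b, on=SITE_KEY, how="outer" if mode == "union" else "inner",
        suffixes=("", f"_{labels[1]}"), indicator=True,
    )
    src = {"left_only": labels[0], "right_only": labels[1], "both": "both"}
    merged["source"] = merged.pop("_merge").map(src)
    # prefer annotation values from A, fall back to B's
    for col in ("depth", "alt_fraction", "bad_read_fraction"):
        other = f"{col}_{labels[1]}"
        if col in merged.columns and other in merged.columns:
            merged[col] = merged[col].astype(float).fillna(merged[other].astype(float))
            merged = merged.drop(columns=other)
        elif other in merged.columns:
            merged = merged.rename(columns={other: col})
    return merged.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _in_repeat(sites: pd.DataFrame, bed: pd.DataFrame) -> np.ndarray:
    flag = np.zeros(len(sites), dtype=bool)
    for chrom, iv in bed.groupby("chrom"):
        iv = iv.sort_values("start")
        starts = iv["start"].to_numpy()
        ends = iv["end"].to_numpy()
        mask = (sites["chrom"] == str(chrom)).to_numpy()
        pos0 = sites.loc[mask, "pos"].to_numpy() - 1  # to 0-based
        i = np.searchsorted(starts, pos0, side="right") - 1
        hit = (i >= 0) & (pos0 < ends[np.clip(i, 0, None)])
        flag[np.flatnonzero(mask)] = hit
    return flag


def apply_filters(
    sites: pd.DataFrame, policy: FilterPolicy
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vet candidate sites; return (survivors, rejections).

    Every survivor passes all active rules.  Rejections carry the first
    failing rule (evaluation order: depth_min, depth_max, alt_fraction,
    bad_reads, repeat, proximity), so reasons partition the rejected set.
    The proximity rule considers distances among *all* input sites and
    removes both members of any pair closer than ``min_distance`` bp.
    A rule whose required annotation column is absent or all-NaN raises.
    """
    sites = sites.sort_values(["chrom", "pos"]).reset_index(drop=True)
    reason = np.array([""] * len(sites), dtype=object)

    def need(col: str, rule: str) -> np.ndarray:
        if col not in sites.columns:
            raise ValueError(f"rule {rule!r} requires annotation column {col!r}")
        vals = sites[col].to_numpy(dtype=float)
        if np.isnan(vals).all() and len(vals):
            raise ValueError(f"rule {rule!r} requires annotation column {col!r} (all missing)")
        return vals

    if policy.min_depth is not None:
        d = need("depth", "depth_min")
        bad = d < policy.min_depth
        reason[(reason == "") & bad] = "depth_min"
    max_depth = policy.max_depth
    if max_depth is None and policy.max_depth_from_median is not None:
        if "depth" in sites.columns and np.isfinite(sites["depth"]).any():
            max_depth = policy.max_depth_from_median * np.nanmedian(sites["depth"])
    if max_depth is not None:
        d = need("depth", "depth_max")
        reason[(reason == "") & (d > max_depth)] = "depth_max"
    if policy.min_alt_fraction is not None:
        f = need("alt_fraction", "alt_fraction")
        reason[(reason == "") & ~(f > policy.min_alt_fraction - 1e-12)] = "alt_fraction"
    if policy.max_bad_read_fraction is not None:
        f = need("bad_read_fraction", "bad_reads")
        reason[(reason == "") & (f > policy.max_bad_read_fraction)] = "bad_reads"
    if policy.repeat_intervals is not None:
        hit = _in_repeat(sites, policy.repeat_intervals)
        reason[(reason == "") & hit] = "repeat"
    if policy.min_distance is not None:
        pos = sites["pos"].to_numpy()
        same_chrom_prev = sites["chrom"].to_numpy()[1:] == sites["chrom"].to_numpy()[:-1]
        close_prev = np.concatenate([[False], same_chrom_prev & (np.diff(pos) < policy.min_distance)])
        close = close_prev | np.concatenate([close_prev[1:], [False]])
        reason[(reason == "") & close] = "proximity"

    passed = sites[reason == ""].reset_index(drop=True)
    rejected = sites[reason != ""].copy().reset_index(drop=True)
    rejected["reason"] = reason[reason != ""]
    return passed, rejected


def sites_to_marker_map(
    sites: pd.DataFrame,
    alt_is_long: bool = True,
    chrom_lengths: dict[str, int] | None = None,
    **marker_kwargs,
) -> MarkerMap:
    """Orient vetted sites into a MarkerMap.

    ``alt_is_long`` states whether the callset's ALT allele is the
    long-lived parent's (the usual case when variants were called on the
    long-lived parent against a lab-strain-like reference).
    """
    short = sites["ref" if alt_is_long else "alt"].astype(str)
    long_ = sites["alt" if alt_is_long else "ref"].astype(str)
    kind = np.where(short.str.len().to_numpy() == long_.str.len().to_numpy(), "SNP", "indel")
    df = pd.DataFrame(
        {
            "chrom": sites["chrom"].astype(str),
            "pos": sites["pos"].astype(int),
            "short_allele": short.to_numpy(),
            "long_allele": long_.to_numpy(),
            "kind": kind,
        }
    )
    return MarkerMap(df, chrom_lengths=chrom_lengths, **marker_kwargs)
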