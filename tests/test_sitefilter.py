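"""Callset combination and declarative marker vetting."""

import numpy as np
import pandas as pd
import pytest

from poolage.sitefilter import (
    FilterPolicy,
    apply_filters,
    combine_callsets,
    sites_to_marker_map,
)


def sites(*rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "depth", "alt_fraction", "bad_read_fraction"]
    )


S1 = ("I", 100, "A", "G", 30.0, 1.0, 0.0)
S2 = ("I", 500, "C", "T", 25.0, 1.0, 0.0)
S3 = ("II", 40, "G", "GA", 28.0, 1.0, 0.0)


class TestCombine:
    def test_union_keeps_everything_with_provenance(self):
        out = combine_callsets(sites(S1, S2), sites(S2, S3))
        assert len(out) == 3
        src = dict(zip(zip(out["chrom"], out["pos"]), out["source"]))
        assert src[("I", 100)] == "a" and src[("II", 40)] == "b" and src[("I", 500)] == "both"

    def test_intersection_keeps_shared(self):
        out = combine_callsets(sites(S1, S2), sites(S2, S3), mode="intersection")
        assert len(out) == 1 and out["pos"].iloc[0] == 500

    def test_empty_left_is_identity_under_union(self):
        out = combine_callsets(sites(), sites(S2, S3))
        assert len(out) == 2 and set(out["source"]) == {"b"}

    def test_conflicting_ref_alleles_raise(self):
        with pytest.raises(ValueError, match="I:100"):
            combine_callsets(sites(S1), sites(("I", 100, "T", "G", 9.0, 1.0, 0.0)))


class TestFilters:
    def test_alt_fraction_rule(self):
        df = sites(("I", 100, "A", "G", 30.0, 0.95, 0.0))
        passed, rejected = apply_filters(df, FilterPolicy(min_depth=None, min_distance=None,
                                                          max_bad_read_fraction=None,
                                                          max_depth_from_median=None))
        assert len(passed) == 0
        assert rejected["reason"].iloc[0] == "alt_fraction"

    def test_toy_five_sites_two_survivors(self):
        # one site in a repeat interval; two sites 3 bp apart with min distance 10
        df = sites(
            ("I", 100, "A", "G", 30.0, 1.0, 0.0),
            ("I", 200, "C", "T", 30.0, 1.0, 0.0),   # inside repeat [150, 250)
            ("I", 300, "G", "A", 30.0, 1.0, 0.0),
            ("I", 400, "T", "C", 30.0, 1.0, 0.0),   # proximity pair
            ("I", 403, "A", "G", 30.0, 1.0, 0.0),   # proximity pair
        )
        repeats = pd.DataFrame({"chrom": ["I"], "start": [149], "end": [250]})
        policy = FilterPolicy(min_depth=10, max_depth_from_median=None, min_alt_fraction=0.99,
                              max_bad_read_fraction=0.1, min_distance=10,
                              repeat_intervals=repeats)
        passed, rejected = apply_filters(df, policy)
        assert passed["pos"].tolist() == [100, 300]
        reasons = dict(zip(rejected["pos"], rejected["reason"]))
        assert reasons == {200: "repeat", 400: "proximity", 403: "proximity"}

    def test_disabled_policy_is_identity(self):
        df = sites(S1, S2, S3)
        passed, rejected = apply_filters(df, FilterPolicy.disabled())
        assert len(passed) == 3 and len(rejected) == 0

    def test_rejection_reasons_partition_rejects(self):
        df = sites(
            ("I", 10, "A", "G", 2.0, 1.0, 0.0),      # low depth
            ("I", 100, "C", "T", 30.0, 0.5, 0.0),    # low alt fraction
            ("I", 200, "G", "A", 30.0, 1.0, 0.5),    # bad reads
            ("I", 300, "T", "C", 30.0, 1.0, 0.0),    # pass
        )
        policy = FilterPolicy(max_depth_from_median=None)
        passed, rejected = apply_filters(df, policy)
        assert len(passed) + len(rejected) == 4
        assert rejected["reason"].tolist() == ["depth_min", "alt_fraction", "bad_reads"]

    def test_max_depth_from_median(self):
        rows = [("I", 100 * (i + 1), "A", "G", 30.0, 1.0, 0.0) for i in range(5)]
        rows.append(("I", 10_000, "C", "T", 400.0, 1.0, 0.0))
        passed, rejected = apply_filters(sites(*rows), FilterPolicy())
        assert rejected["reason"].tolist() == ["depth_max"]

    def test_active_rule_with_missing_annotation_raises(self):
        df = pd.DataFrame({"chrom": ["I"], "pos": [1], "ref": ["A"], "alt": ["G"]})
        with pytest.raises(ValueError, match="depth"):
            apply_filters(df, FilterPolicy(min_alt_fraction=None, max_bad_read_fraction=None,
                                           min_distance=None, max_depth_from_median=None))

    def test_invalid_policy(self):
        with pytest.raises(ValueError):
            FilterPolicy(min_alt_fraction=1.5)
        with pytest.raises(ValueError):
            FilterPolicy(min_depth=50, max_depth=10)


class TestMarkerMapConstruction:
    def test_orientation_and_kind(self):
        passed = sites(S1, S3)
        mm = sites_to_marker_map(passed, alt_is_long=True)
        assert mm.df["short_allele"].tolist() == ["A", "G"]
        assert mm.df["long_allele"].tolist() == ["G", "GA"]
        assert mm.df["kind"].tolist() == ["SNP", "indel"]
        flipped = sites_to_marker_map(passed, alt_is_long=False)
        assert flipped.df["long_allele"].tolist() == ["A", "G"]
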