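"""Readers and writers for the pipeline's file formats.

Conventions: marker coordinates are 1-based inclusive (VCF convention);
BED intervals are 0-based half-open and converted only at this boundary.
Allele-depth VCFs carry per-sample ``AD`` (ref,alt) and ``DP`` fields with
samples named like ``rep1_day0``.  Missing observations are kept as depth
0, never dropped at ingest.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
import pysam

from .core import MarkerMap, TrajectoryTable

DEFAULT_SAMPLE_PATTERN = r"rep(?P<replicate>\d+)_day(?P<day>\d+)"

SCORE_COLUMNS = ["chrom", "pos", "score", "n_replicates", "filtered",
                 "smoothed", "above_threshold", "peak_id"]


# ---------------------------------------------------------------------------
# counts VCF
# ---------------------------------------------------------------------------


def write_counts_vcf(table: TrajectoryTable, path) -> None:
    """Minimal VCF 4.2 with per-sample AD/DP, one sample per replicate x day.

    REF is the short-lived parent's allele, ALT the long-lived parent's, so
    the alt depth equals the oriented count ``k``.
    """
    header = pysam.VariantHeader()
    for chrom in table.markers.chromosomes:
        header.contigs.add(chrom, length=int(table.markers.chrom_lengths[chrom]))
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref,alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    samples = [
        f"rep{i + 1}_day{d}" if not str(r).startswith("rep") else f"{r}_day{d}"
        for i, r in enumerate(table.replicates)
        for d in table.days
    ]
    for s in samples:
        header.add_sample(s)
    mk = table.markers.df
    M, R, T = table.shape
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for m in range(M):
            rec = vf.new_record(
                contig=str(mk["chrom"].iloc[m]),
                start=int(mk["pos"].iloc[m]) - 1,
                alleles=(str(mk["short_allele"].iloc[m]), str(mk["long_allele"].iloc[m])),
            )
            rec.stop = rec.start + len(str(mk["short_allele"].iloc[m]))
            i = 0
            for r in range(R):
                for t in range(T):
                    n, k = int(table.n[m, r, t]), int(table.k[m, r, t])
                    rec.samples[samples[i]]["AD"] = (n - k, k)
                    rec.samples[samples[i]]["DP"] = n
                    i += 1
            vf.write(rec)


def read_counts_vcf(
    path,
    markers: MarkerMap,
    sample_pattern: str = DEFAULT_SAMPLE_PATTERN,
) -> TrajectoryTable:
    """Ingest an allele-depth VCF into an oriented TrajectoryTable.

    Sample names must parse to (replicate, day) under ``sample_pattern``.
    Counts are oriented so that the "alt" count is the long-lived parent's
    allele: when the record's ALT is the marker's short-parent allele the
    AD pair is swapped.  Records at positions absent from the marker map
    (or with alleles matching neither orientation) are skipped with a
    warning.  Records lacking AD raise.
    """
    pat = re.compile(sample_pattern)
    with pysam.VariantFile(str(path)) as vf:
        parsed = []
        for s in vf.header.samples:
            m = pat.search(s)
            if not m:
                raise ValueError(f"sample name {s!r} does not match pattern {sample_pattern!r}")
            parsed.append((s, int(m.group("replicate")), int(m.group("day"))))
        reps = sorted({r for _, r, _ in parsed})
        days = sorted({d for _, _, d in parsed})
        ridx = {r: i for i, r in enumerate(reps)}
        didx = {d: i for i, d in enumerate(days)}
        M = markers.n_markers
        k = np.zeros((M, len(reps), len(days)), dtype=np.int64)
        n = np.zeros((M, len(reps), len(days)), dtype=np.int64)
        key = {
            (c, p): i
            for i, (c, p) in enumerate(zip(markers.df["chrom"], markers.df["pos"]))
        }
        alleles = list(zip(markers.df["short_allele"].astype(str), markers.df["long_allele"].astype(str)))
        for rec in vf:
            mi = key.get((str(rec.chrom), int(rec.pos)))
            if mi is None:
                warnings.warn(f"marker {rec.chrom}:{rec.pos} not in marker map; skipped")
                continue
            short, long_ = alleles[mi]
            alt = rec.alts[0] if rec.alts else ""
            if (rec.ref, alt) == (short, long_):
                swap = False
            elif (rec.ref, alt) == (long_, short):
                swap = True
            else:
                warnings.warn(
                    f"alleles at {rec.chrom}:{rec.pos} match neither parental orientation; skipped"
                )
                continue
            for s, r, d in parsed:
                ad = rec.samples[s].get("AD")
                if ad is None:
                    raise ValueError(f"record {rec.chrom}:{rec.pos} sample {s} lacks AD")
                ref_n, alt_n = (int(a) if a is not None else 0 for a in ad[:2])
                if swap:
                    ref_n, alt_n = alt_n, ref_n
                k[mi, ridx[r], didx[d]] = alt_n
                n[mi, ridx[r], didx[d]] = ref_n + alt_n
    return TrajectoryTable(markers, k, n, replicates=[f"rep{r}" for r in reps], days=days)


# ---------------------------------------------------------------------------
# counts TSV (long format)
# ---------------------------------------------------------------------------


def write_counts_tsv(table: TrajectoryTable, path) -> None:
    table.to_long_dataframe().to_csv(path, sep="\t", index=False)


def read_counts_tsv(path, markers: MarkerMap) -> TrajectoryTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return TrajectoryTable.from_long_dataframe(markers, df)


# ---------------------------------------------------------------------------
# score tracks
# ---------------------------------------------------------------------------


def write_scores(track: pd.DataFrame, path) -> None:
    """Score track to TSV at full float precision (round-trip exact)."""
    track.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    for col in ("filtered", "above_threshold"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


# ---------------------------------------------------------------------------
# BED intervals and peak output
# ---------------------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """BED3 intervals (0-based half-open) as a chrom/start/end frame."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={0: str}, comment="#",
    )
    return df


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """Peak regions as BED (start converted to 0-based half-open)."""
    with open(path, "w") as fh:
        for row in peaks.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\tpeak_{row.rank}\t"
                     f"{row.max_smoothed:.6g}\n")


# ---------------------------------------------------------------------------
# caller-output VCFs for marker derivation
# ---------------------------------------------------------------------------


def read_vcf_sites(path, bad_reads_tag: str | None = None) -> pd.DataFrame:
    """Variant sites with the annotations the marker filters consume.

    Extracts per site: depth (INFO/DP, else the first sample's summed AD),
    alternate-allele fraction (first sample's AD when present), and
    optionally a bad/split-read fraction from ``INFO/<bad_reads_tag>``.
    Missing annotations become NaN; filters requiring them will raise.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        has_samples = len(vf.header.samples) > 0
        for rec in vf:
            depth = rec.info.get("DP")
            alt_frac = np.nan
            if has_samples:
                ad = rec.samples[0].get("AD")
                if ad is not None and all(a is not None for a in ad[:2]):
                    tot = sum(int(a) for a in ad)
                    if depth is None:
                        depth = tot
                    if tot > 0:
                        alt_frac = sum(int(a) for a in ad[1:]) / tot
            if alt_frac != alt_frac and "AF" in rec.info:
                af = rec.info["AF"]
                alt_frac = float(af[0] if isinstance(af, tuple) else af)
            bad = np.nan
            if bad_reads_tag and bad_reads_tag in rec.info:
                bad = float(rec.info[bad_reads_tag])
            rows.append(
                {
                    "chrom": str(rec.chrom),
                    "pos": int(rec.pos),
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else "",
                    "depth": np.nan if depth is None else float(depth),
                    "alt_fraction": alt_frac,
                    "bad_read_fraction": bad,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "depth", "alt_fraction", "bad_read_fraction"]
    )
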