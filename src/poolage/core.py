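"""Core data containers: the marker map and the per-locus count table.

The analysis tracks two parental alleles at a set of segregating sites
("markers") in pooled, haploid segregants.  Counts are always oriented so
that the "alt" allele is the long-lived parent's allele; a frequency of 1
at a marker means the pool is fixed for the long-lived parent there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Chromosome names and lengths (bp) used by the default simulated genome.
#: These mirror the three nuclear chromosomes of *Schizosaccharomyces pombe*.
DEFAULT_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("I", 5_579_133),
    ("II", 4_539_804),
    ("III", 2_452_883),
)

#: Default genetic-map density, cM per kb.  Fission yeast's genetic map is
#: roughly 2300 cM over 12.6 Mb, i.e. ~0.18 cM/kb (about 1 cM per 5.5 kb);
#: this sets the width of the hitchhiking blocks the neighbor filter and
#: the sliding-median scan rely on.
DEFAULT_CM_PER_KB: float = 0.18

MARKER_COLUMNS = ["chrom", "pos", "short_allele", "long_allele", "kind"]


class MarkerMap:
    """Ordered list of segregating sites between the two parental strains.

    Parameters
    ----------
    df:
        One row per marker with columns ``chrom`` (label), ``pos``
        (1-based bp), ``short_allele``, ``long_allele`` (the short- and
        long-lived parent's alleles) and ``kind`` (``SNP`` or ``indel``).
        Optional columns: ``cm`` (genetic position, centimorgans) and
        ``is_repeat`` (flag).
    chrom_lengths:
        Optional mapping of chromosome label to physical length in bp;
        defaults to the last marker position per chromosome.
    cm_per_kb:
        Map density used to derive genetic positions when no ``cm``
        column is given.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        chrom_lengths: dict[str, int] | None = None,
        cm_per_kb: float = DEFAULT_CM_PER_KB,
        validate: bool = True,
    ):
        df = df.reset_index(drop=True).copy()
        missing = [c for c in MARKER_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"marker table missing columns: {missing}")
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        if "cm" not in df.columns:
            df["cm"] = df["pos"] / 1000.0 * cm_per_kb
        if "is_repeat" not in df.columns:
            df["is_repeat"] = False
        self.df = df
        self.cm_per_kb = float(cm_per_kb)
        self.chromosomes: list[str] = list(dict.fromkeys(df["chrom"]))
        if chrom_lengths is None:
            chrom_lengths = {
                c: int(df.loc[df["chrom"] == c, "pos"].max()) for c in self.chromosomes
            }
        self.chrom_lengths = dict(chrom_lengths)
        if validate:
            self._validate()

    def _validate(self) -> None:
        for chrom, sub in self.df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            cm = sub["cm"].to_numpy()
            if not np.all(np.diff(cm) >= 0):
                raise ValueError(f"genetic positions decreasing on {chrom}")
        same = self.df["short_allele"].astype(str) == self.df["long_allele"].astype(str)
        if same.any():
            raise ValueError("parental alleles identical at some markers")

    # -- basic introspection ------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_markers(self) -> int:
        return len(self.df)

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous row slice of a chromosome (markers are genome-ordered)."""
        idx = np.flatnonzero((self.df["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chrom_slices(self) -> dict[str, slice]:
        return {c: self.chrom_slice(c) for c in self.chromosomes}

    def morgans(self, chrom: str) -> np.ndarray:
        """Genetic positions of a chromosome's markers, in Morgans."""
        return self.df["cm"].to_numpy()[self.chrom_slice(chrom)] / 100.0

    def chrom_map_length(self, chrom: str) -> float:
        """Total genetic length of a chromosome in Morgans.

        Derived from the physical length and the map density, so crossover
        counts include end segments beyond the terminal markers.
        """
        return self.chrom_lengths[chrom] / 1000.0 * self.cm_per_kb / 100.0

    def index_of(self, chrom: str, pos: int) -> int:
        hit = np.flatnonzero(
            ((self.df["chrom"] == str(chrom)) & (self.df["pos"] == int(pos))).to_numpy()
        )
        if hit.size == 0:
            raise KeyError(f"no marker at {chrom}:{pos}")
        return int(hit[0])

    # -- IO -----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "MarkerMap":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df, **kwargs)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MarkerMap({self.n_markers} markers, {len(self.chromosomes)} chromosomes)"


@dataclass
class TrajectoryTable:
    """Per-locus ref/alt read counts across replicates and time points.

    ``k`` and ``n`` are integer arrays of shape ``(n_markers, n_replicates,
    n_timepoints)`` giving the long-parent-allele read count and the total
    depth.  Missing observations are encoded as ``n == 0`` and never
    dropped at ingest; downstream minimum-depth rules own exclusion.
    """

    markers: MarkerMap
    k: np.ndarray
    n: np.ndarray
    replicates: list = field(default_factory=list)
    days: list = field(default_factory=list)

    def __post_init__(self):
        self.k = np.asarray(self.k, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        M, R, T = self.k.shape
        if self.n.shape != (M, R, T):
            raise ValueError("k and n shapes differ")
        if M != self.markers.n_markers:
            raise ValueError("marker count mismatch")
        if not self.replicates:
            self.replicates = list(range(1, R + 1))
        if not self.days:
            self.days = list(range(T))
        if len(self.replicates) != R or len(self.days) != T:
            raise ValueError("replicate/day labels do not match count dimensions")
        if (self.k < 0).any() or (self.n < 0).any() or (self.k > self.n).any():
            raise ValueError("require 0 <= k <= n at every observation")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.k.shape

    def allele_frequency(self) -> np.ndarray:
        """k/n with NaN where depth is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(self.n > 0, self.k / np.maximum(self.n, 1), np.nan)
        return af

    def to_long_dataframe(self) -> pd.DataFrame:
        M, R, T = self.shape
        mk = self.markers.df
        rows = {
            "chrom": np.repeat(mk["chrom"].to_numpy(), R * T),
            "pos": np.repeat(mk["pos"].to_numpy(), R * T),
            "replicate": np.tile(np.repeat(self.replicates, T), M),
            "day": np.tile(self.days, M * R),
            "alt_count": self.k.reshape(-1),
            "depth": self.n.reshape(-1),
        }
        return pd.DataFrame(rows)

    @classmethod
    def from_long_dataframe(cls, markers: MarkerMap, df: pd.DataFrame) -> "TrajectoryTable":
        reps = sorted(df["replicate"].unique())
        days = sorted(df["day"].unique())
        M, R, T = markers.n_markers, len(reps), len(days)
        k = np.zeros((M, R, T), dtype=np.int64)
        n = np.zeros((M, R, T), dtype=np.int64)
        ridx = {r: i for i, r in enumerate(reps)}
        didx = {d: i for i, d in enumerate(days)}
        key = {(c, p): i for i, (c, p) in enumerate(zip(markers.df["chrom"], markers.df["pos"]))}
        for row in df.itertuples(index=False):
            m = key[(str(row.chrom), int(row.pos))]
            k[m, ridx[row.replicate], didx[row.day]] = row.alt_count
            n[m, ridx[row.replicate], didx[row.day]] = row.depth
        return cls(markers, k, n, replicates=list(reps), days=list(days))
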