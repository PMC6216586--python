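"""Forward simulator of advanced intercross lines (AILs) and aging pools.

Emulates the experimental design the analysis assumes: two haploid parents
are intercrossed for several generations (meiosis with Poisson crossovers
on a genetic map, then fitness-proportional resampling that can impose
growth selection), replicate pools of the resulting segregants enter
stationary phase and age without division, and per-locus survival effects
drive allele-frequency change among the shrinking set of survivors.
Pool-seq read sampling (Poisson depth, binomial allele counts) turns true
allele frequencies into a :class:`~poolage.core.TrajectoryTable`.

Mortality model: each individual survives each day independently with
probability ``logistic(beta0 + sum_j s_j x_j)`` where ``x_j`` indicates the
long-lived parent's allele at marker ``j``.  Growth selection acts as
multinomial resampling with weights ``exp(sum_j g_j x_j)``.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import DEFAULT_CHROMOSOMES, DEFAULT_CM_PER_KB, MarkerMap, TrajectoryTable
from .lifespan import LifespanCurve

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# model dataclasses
# ---------------------------------------------------------------------------


@dataclass
class SelectionModel:
    """Per-marker growth and survival effects plus the baseline death rate.

    ``growth[j]`` is the log-fitness advantage of the long-parent allele
    during proliferative growth; ``survival[j]`` its additive effect on the
    daily survival logit during stationary-phase aging.  ``beta0`` is the
    baseline daily survival logit of an individual carrying no effect
    alleles; the default 1.0 gives ~73% daily survival, i.e. ~20% viability
    after five days of aging, matching the viability range the main
    experiment's pools were sampled over.
    """

    n_markers: int
    growth: np.ndarray | None = None
    survival: np.ndarray | None = None
    beta0: float = 1.0

    def __post_init__(self):
        if self.growth is None:
            self.growth = np.zeros(self.n_markers)
        if self.survival is None:
            self.survival = np.zeros(self.n_markers)
        self.growth = np.asarray(self.growth, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        for name, arr in (("growth", self.growth), ("survival", self.survival)):
            if arr.shape != (self.n_markers,):
                raise ValueError(f"{name} effects must have one entry per marker")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} effects must be finite")
        if not np.isfinite(self.beta0):
            raise ValueError("beta0 must be finite")

    @property
    def has_growth_effects(self) -> bool:
        return bool(np.any(self.growth != 0.0))


@dataclass
class SequencingModel:
    """Pool-seq model: per-locus depth ~ Poisson(mean_depth)."""

    mean_depth: float = 100.0

    def __post_init__(self):
        if not self.mean_depth > 0:
            raise ValueError("mean depth must be positive")


@dataclass
class SegregantPool:
    """A pool of haploid segregants as binary haplotypes over the markers.

    ``haplotypes`` has shape ``(n_individuals, n_markers)``; entry 1 means
    the long-lived parent's allele.  ``alive`` flags survivors during aging.
    """

    haplotypes: np.ndarray
    generation: int = 0
    alive: np.ndarray | None = None

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=bool)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D (individuals x markers) array")
        if self.alive is None:
            self.alive = np.ones(self.haplotypes.shape[0], dtype=bool)
        self.alive = np.asarray(self.alive, dtype=bool)

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def allele_frequency(self, among_alive: bool = True) -> np.ndarray:
        """Per-marker frequency of the long-parent allele; NaN if no survivors."""
        X = self.haplotypes[self.alive] if among_alive else self.haplotypes
        if X.shape[0] == 0:
            return np.full(self.n_markers, np.nan)
        return X.mean(axis=0)


# ---------------------------------------------------------------------------
# marker map and founders
# ---------------------------------------------------------------------------


def build_marker_map(
    n_markers: int = 4500,
    chromosomes: Sequence[tuple[str, int]] = DEFAULT_CHROMOSOMES,
    cm_per_kb: float = DEFAULT_CM_PER_KB,
    indel_fraction: float = 0.1,
    rng: np.random.Generator | None = None,
) -> MarkerMap:
    """Simulate a marker map with near-even physical spacing.

    Markers are allocated to chromosomes proportionally to physical length
    and placed on an even grid with uniform jitter, echoing the "fairly even
    distribution throughout the genome" expected of a vetted marker list.
    """
    rng = np.random.default_rng(rng)
    lengths = np.array([L for _, L in chromosomes], dtype=float)
    counts = np.maximum(2, np.round(n_markers * lengths / lengths.sum()).astype(int))
    rows = []
    for (chrom, L), m in zip(chromosomes, counts):
        spacing = L / (m + 1)
        base = np.arange(1, m + 1) * spacing
        jitter = rng.uniform(-0.3, 0.3, size=m) * spacing
        pos = np.unique(np.clip(np.round(base + jitter), 1, L).astype(np.int64))
        ref = _BASES[rng.integers(0, 4, size=pos.size)]
        alt = _BASES[(np.char.find("ACGT", ref) + rng.integers(1, 4, size=pos.size)) % 4]
        kind = np.where(rng.random(pos.size) < indel_fraction, "indel", "SNP")
        alt = np.where(kind == "indel", np.char.add(ref, alt), alt)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "short_allele": ref,
                    "long_allele": alt,
                    "kind": kind,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    return MarkerMap(df, chrom_lengths=dict(chromosomes), cm_per_kb=cm_per_kb)


def founder_pool(markers: MarkerMap, size: int) -> SegregantPool:
    """Half short-parent, half long-parent clonal founders."""
    if size < 2:
        raise ValueError("founder pool needs at least two individuals")
    X = np.zeros((size, markers.n_markers), dtype=bool)
    X[size // 2 :, :] = True
    return SegregantPool(X, generation=0)


# ---------------------------------------------------------------------------
# meiosis and intercrossing
# ---------------------------------------------------------------------------


def meiosis_batch(
    pool: SegregantPool,
    parents_a: np.ndarray,
    parents_b: np.ndarray,
    markers: MarkerMap,
    rng: np.random.Generator,
    return_crossovers: bool = False,
):
    """Recombinant haploid offspring from paired parents.

    Crossovers per chromosome are Poisson with mean equal to the map length
    in Morgans, positions uniform on the genetic map.  Counts are drawn per
    inter-marker interval (the Poisson process restricted to each interval),
    and the parental origin switches wherever the interval count is odd; end
    segments beyond the terminal markers contribute to the crossover tally
    but cannot switch any marker.
    """
    X = pool.haplotypes
    Xa, Xb = X[parents_a], X[parents_b]
    n_off = len(parents_a)
    off = np.empty_like(Xa)
    xo_counts = np.zeros(n_off, dtype=np.int64) if return_crossovers else None
    for chrom in markers.chromosomes:
        sl = markers.chrom_slice(chrom)
        gpos = markers.morgans(chrom)
        total_len = max(markers.chrom_map_length(chrom), gpos[-1])
        gaps = np.diff(gpos)
        counts = rng.poisson(gaps, size=(n_off, gaps.size))
        start_b = rng.integers(0, 2, size=n_off, dtype=bool)
        ind = np.concatenate([start_b[:, None], counts % 2 == 1], axis=1)
        from_b = np.logical_xor.accumulate(ind, axis=1)
        off[:, sl] = np.where(from_b, Xb[:, sl], Xa[:, sl])
        if return_crossovers:
            ends = gpos[0] + (total_len - gpos[-1])
            xo_counts += counts.sum(axis=1) + rng.poisson(ends, size=n_off)
    if return_crossovers:
        return off, xo_counts
    return off


def intercross(
    pool: SegregantPool,
    n_generations: int,
    offspring_per_generation: int,
    model: SelectionModel,
    markers: MarkerMap,
    rng: np.random.Generator | int | None = None,
) -> SegregantPool:
    """Repeated rounds of random pairing, meiosis, and growth selection.

    Each generation pairs random individuals, produces recombinant haploid
    offspring, then resamples the offspring with weights proportional to
    ``exp(sum_j g_j x_j)`` — the competitive-growth step that skews allele
    frequencies toward fitter haplotypes across intercross generations.
    """
    if pool.n_individuals < 2:
        raise ValueError("intercross requires at least two individuals")
    if n_generations < 0:
        raise ValueError("n_generations must be non-negative")
    rng = np.random.default_rng(rng)
    X = pool.haplotypes
    for _ in range(n_generations):
        cur = X.shape[0]
        pa = rng.integers(0, cur, size=offspring_per_generation)
        pb = rng.integers(0, cur, size=offspring_per_generation)
        off = meiosis_batch(SegregantPool(X), pa, pb, markers, rng)
        logw = off @ model.growth
        w = np.exp(logw - logw.max())
        w /= w.sum()
        idx = rng.choice(offspring_per_generation, size=offspring_per_generation, p=w)
        X = off[idx]
    return SegregantPool(X, generation=pool.generation + n_generations)


def grow(
    pool: SegregantPool,
    model: SelectionModel,
    rounds: int,
    rng: np.random.Generator | int | None = None,
    out_size: int | None = None,
) -> SegregantPool:
    """Clonal regrowth under competitive growth selection (no meiosis).

    Each round resamples the living individuals with weights
    ``exp(g . x)``; used to emulate regrowing an aged sample in rich medium,
    where growth-deleterious longevity alleles are purged.
    """
    rng = np.random.default_rng(rng)
    X = pool.haplotypes[pool.alive]
    if X.shape[0] == 0:
        raise ValueError("cannot regrow a pool with no survivors")
    size = out_size or pool.n_individuals
    for _ in range(rounds):
        logw = X @ model.growth
        w = np.exp(logw - logw.max())
        w /= w.sum()
        X = X[rng.choice(X.shape[0], size=size, p=w)]
    return SegregantPool(X, generation=pool.generation)


# ---------------------------------------------------------------------------
# aging
# ---------------------------------------------------------------------------


@dataclass
class AgingResult:
    """Day-indexed record of an aging (stationary-phase) pool.

    Attributes hold, for days ``0..days``: the surviving fraction relative
    to day 0, the surviving individual count, the true long-parent allele
    frequency among survivors (NaN once no survivors remain), and the alive
    masks needed to re-seed pools from a given sampling day.
    """

    days: np.ndarray
    viability: np.ndarray
    survivors: np.ndarray
    af: np.ndarray
    alive_history: np.ndarray
    pool: SegregantPool

    def survivor_pool(self, day: int) -> SegregantPool:
        """Fresh pool made of the individuals alive on the given day."""
        mask = self.alive_history[int(day)]
        if mask.sum() == 0:
            raise ValueError(f"no survivors on day {day}")
        return SegregantPool(self.pool.haplotypes[mask].copy(), self.pool.generation)

    def lifespan_curve(
        self,
        plate_count: float = 200.0,
        rng: np.random.Generator | int | None = None,
        label: str = "",
    ) -> LifespanCurve:
        """CFU-style lifespan curve; triplicate Poisson plating counts."""
        rng = np.random.default_rng(rng)
        cfu = rng.poisson(plate_count * self.viability[:, None], size=(len(self.days), 3))
        return LifespanCurve.from_cfu(self.days, cfu, label=label)


def age_pool(
    pool: SegregantPool,
    model: SelectionModel,
    days: int,
    rng: np.random.Generator | int | None = None,
) -> AgingResult:
    """Age a non-dividing pool for ``days`` days.

    Each individual survives each day independently with probability
    ``logistic(beta0 + s . x)``.  No division occurs; the surviving count is
    non-increasing by construction.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(rng)
    X = pool.haplotypes
    alive = pool.alive.copy()
    n0 = alive.sum()
    if n0 == 0:
        raise ValueError("pool has no living individuals at day 0")
    p_surv = expit(model.beta0 + X @ model.survival)
    hist = np.zeros((days + 1, X.shape[0]), dtype=bool)
    af = np.full((days + 1, X.shape[1]), np.nan)
    surv = np.zeros(days + 1, dtype=np.int64)
    hist[0] = alive
    surv[0] = n0
    af[0] = X[alive].mean(axis=0)
    for d in range(1, days + 1):
        alive = alive & (rng.random(X.shape[0]) < p_surv)
        hist[d] = alive
        surv[d] = alive.sum()
        if surv[d] > 0:
            af[d] = X[alive].mean(axis=0)
    return AgingResult(
        days=np.arange(days + 1),
        viability=surv / n0,
        survivors=surv,
        af=af,
        alive_history=hist,
        pool=pool,
    )


# ---------------------------------------------------------------------------
# sequencing
# ---------------------------------------------------------------------------


def sample_reads(
    true_af: np.ndarray,
    model: SequencingModel,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool-seq counts: depth ~ Poisson(mean), alt count ~ Binomial(depth, af).

    Markers with undefined frequency (NaN, e.g. an extinct pool) yield
    ``(k, n) = (0, 0)`` — a retained, flagged-missing observation.
    """
    rng = np.random.default_rng(rng)
    true_af = np.asarray(true_af, dtype=float)
    ok = np.isfinite(true_af)
    if np.any((true_af[ok] < 0) | (true_af[ok] > 1)):
        raise ValueError("true allele frequencies must lie in [0, 1]")
    n = rng.poisson(model.mean_depth, size=true_af.shape)
    n = np.where(ok, n, 0)
    k = rng.binomial(n, np.where(ok, true_af, 0.0))
    return k.astype(np.int64), n.astype(np.int64)


# ---------------------------------------------------------------------------
# full experiment generation
# ---------------------------------------------------------------------------


@dataclass
class CausalLocus:
    """A causal marker: survival effect ``s`` (log-odds/day) and growth
    effect ``g`` (log-fitness/generation).  ``index`` selects the marker;
    None places it at a random marker when the experiment is generated."""

    s: float = 0.0
    g: float = 0.0
    index: int | None = None


@dataclass
class SimConfig:
    """Study-design parameters for a simulated aging-pool experiment.

    Defaults mirror the main study design: ~4500 segregating markers on
    three chromosomes, an F6 advanced intercross, eight replicate pools,
    six daily time points starting at day 0 (growth arrest), and deep
    sequencing (~100x).  ``pool_size`` is the simulated census size of each
    pool, a computational stand-in for macroscopic cultures.
    """

    n_markers: int = 4500
    chromosomes: tuple = DEFAULT_CHROMOSOMES
    cm_per_kb: float = DEFAULT_CM_PER_KB
    pool_size: int = 2000
    generations: int = 6
    replicates: int = 8
    timepoints: int = 6
    mean_depth: float = 100.0
    beta0: float = 1.0
    plate_count: float = 200.0
    indel_fraction: float = 0.1
    causal: list[CausalLocus] = field(default_factory=list)

    def __post_init__(self):
        if self.replicates < 1 or self.timepoints < 2:
            raise ValueError("need >=1 replicate and >=2 timepoints")
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")
        if self.n_markers < 2 * len(self.chromosomes):
            raise ValueError("need at least 2 markers per chromosome")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        causal = [CausalLocus(**c) for c in d.pop("causal", [])]
        chroms = d.pop("chromosomes", DEFAULT_CHROMOSOMES)
        chroms = tuple((str(c[0]), int(c[1])) for c in chroms)
        known = {f for f in cls.__dataclass_fields__ if f not in ("causal", "chromosomes")}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(causal=causal, chromosomes=chroms, **d)


@dataclass
class SimulatedExperiment:
    """A complete synthetic dataset plus its ground truth."""

    config: SimConfig
    seed: int
    markers: MarkerMap
    table: TrajectoryTable
    truth: pd.DataFrame
    true_af: np.ndarray  # (n_markers, replicates, timepoints)
    curves: list[LifespanCurve]
    model: SelectionModel

    def write(self, outdir) -> dict[str, str]:
        from . import io as pio
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "markers": os.path.join(outdir, "markers.tsv"),
            "counts_vcf": os.path.join(outdir, "counts.vcf"),
            "truth": os.path.join(outdir, "truth.tsv"),
            "lifespan": os.path.join(outdir, "lifespan.tsv"),
        }
        self.markers.to_tsv(paths["markers"])
        pio.write_counts_vcf(self.table, paths["counts_vcf"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        rows = []
        for rep, curve in zip(self.table.replicates, self.curves):
            for d, counts in zip(curve.days, curve.cfu):
                rows.append([rep, int(d), *counts.tolist()])
        pd.DataFrame(rows, columns=["replicate", "day", "cfu1", "cfu2", "cfu3"]).to_csv(
            paths["lifespan"], sep="\t", index=False
        )
        return paths


def _resolve_model(config: SimConfig, markers: MarkerMap, rng) -> tuple[SelectionModel, pd.DataFrame]:
    M = markers.n_markers
    g = np.zeros(M)
    s = np.zeros(M)
    taken: list[int] = []
    rows = []
    for c in config.causal:
        idx = c.index
        if idx is None:
            choices = np.setdiff1d(np.arange(M), np.array(taken, dtype=int))
            idx = int(rng.choice(choices))
        taken.append(int(idx))
        g[idx] += c.g
        s[idx] += c.s
        rows.append(
            {
                "chrom": markers.df["chrom"].iloc[idx],
                "pos": int(markers.df["pos"].iloc[idx]),
                "marker_index": int(idx),
                "s": c.s,
                "g": c.g,
            }
        )
    truth = pd.DataFrame(rows, columns=["chrom", "pos", "marker_index", "s", "g"])
    return SelectionModel(M, growth=g, survival=s, beta0=config.beta0), truth


def simulate_experiment(config: SimConfig, seed: int) -> SimulatedExperiment:
    """Generate the full main-design dataset: AIL, aged pools, Pool-seq reads.

    A single advanced intercross line is simulated from the two parents,
    replicate pools are bootstrapped from the final intercross generation,
    each is aged independently, and reads are drawn at every (replicate,
    day).  Deterministic given ``(config, seed)``.
    """
    rng = np.random.default_rng(seed)
    markers = build_marker_map(
        config.n_markers, config.chromosomes, config.cm_per_kb, config.indel_fraction, rng
    )
    model, truth = _resolve_model(config, markers, rng)
    founders = founder_pool(markers, config.pool_size)
    ail = intercross(founders, config.generations, config.pool_size, model, markers, rng)
    M, R, T = markers.n_markers, config.replicates, config.timepoints
    k = np.zeros((M, R, T), dtype=np.int64)
    n = np.zeros((M, R, T), dtype=np.int64)
    true_af = np.full((M, R, T), np.nan)
    seq = SequencingModel(config.mean_depth)
    curves = []
    for r in range(R):
        idx = rng.integers(0, ail.n_individuals, size=config.pool_size)
        rep_pool = SegregantPool(ail.haplotypes[idx], ail.generation)
        aging = age_pool(rep_pool, model, days=T - 1, rng=rng)
        for t in range(T):
            true_af[:, r, t] = aging.af[t]
            k[:, r, t], n[:, r, t] = sample_reads(aging.af[t], seq, rng)
        curves.append(aging.lifespan_curve(config.plate_count, rng, label=f"rep{r + 1}"))
    table = TrajectoryTable(
        markers, k, n, replicates=[f"rep{r + 1}" for r in range(R)], days=list(range(T))
    )
    return SimulatedExperiment(config, seed, markers, table, truth, true_af, curves, model)


# ---------------------------------------------------------------------------
# the regrowth pilot design
# ---------------------------------------------------------------------------


@dataclass
class PilotResult:
    """Three-sample pilot per replicate pool: day 0, day 6, day 6 regrown."""

    markers: MarkerMap
    truth: pd.DataFrame
    counts: dict  # (pool_index, sample) -> (k, n); sample in {day0, day6, day6_regrown}
    true_af: dict


def simulate_pilot(
    config: SimConfig,
    seed: int,
    n_pools: int = 2,
    aging_days: int = 6,
    growth_rounds: int = 8,
) -> PilotResult:
    """Emulate the pilot: age pools, sequence day 0 / day 6 / day 6 regrown.

    Regrowth is ``growth_rounds`` rounds of competitive clonal resampling of
    the day-6 survivors, so growth-deleterious alleles drop in frequency.
    The pilot used shallow (~10x) coverage; set ``config.mean_depth``
    accordingly.
    """
    rng = np.random.default_rng(seed)
    markers = build_marker_map(
        config.n_markers, config.chromosomes, config.cm_per_kb, config.indel_fraction, rng
    )
    model, truth = _resolve_model(config, markers, rng)
    founders = founder_pool(markers, config.pool_size)
    ail = intercross(founders, config.generations, config.pool_size, model, markers, rng)
    seq = SequencingModel(config.mean_depth)
    counts, true_af = {}, {}
    for p in range(n_pools):
        idx = rng.integers(0, ail.n_individuals, size=config.pool_size)
        pool = SegregantPool(ail.haplotypes[idx], ail.generation)
        aging = age_pool(pool, model, days=aging_days, rng=rng)
        regrown = grow(aging.survivor_pool(aging_days), model, growth_rounds, rng)
        afs = {
            "day0": aging.af[0],
            f"day{aging_days}": aging.af[aging_days],
            f"day{aging_days}_regrown": regrown.allele_frequency(),
        }
        for name, af in afs.items():
            counts[(p, name)] = sample_reads(af, seq, rng)
            true_af[(p, name)] = af
    return PilotResult(markers, truth, counts, true_af)
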