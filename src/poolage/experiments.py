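"""Seeded end-to-end study designs used for power analysis and validation.

Each driver generates a synthetic dataset with the forward simulator, runs
the corresponding analysis exactly as the pipeline would, and reports the
quantities a study-design question asks about: false-peak rates under
neutrality, recovery of a causal survival locus by the genome scan,
recovery of an antagonistic locus by the regrowth screen, and the
survival-integral trend across re-seeded pools.

Problem sizes default to a desk-scale version of the main design (2000
markers, pools of 1000 individuals, 8 replicates, 6 time points,
depth 100).
"""

from __future__ import annotations

import numpy as np

from .lifespan import LifespanCurve
from .regrowth import RegrowthScreen
from .scan import GenomeScanner
from .scoring import NeighborOutlierFilter, TrajectoryScorer
from .simulate import (
    CausalLocus,
    SimConfig,
    age_pool,
    simulate_experiment,
    simulate_pilot,
)


def scan_experiment(
    seed: int,
    s: float = 0.0,
    g: float = 0.0,
    n_markers: int = 2000,
    depth: float = 100.0,
    pool_size: int = 1000,
    replicates: int = 8,
    timepoints: int = 6,
    window: float = 50_000.0,
    iqr_multiplier: float = 1.5,
) -> dict:
    """Simulate the main design and run score -> filter -> scan.

    With ``s == g == 0`` no causal locus is planted (the null design);
    otherwise one causal locus with the given effects is placed at a
    random marker.  Returns the peak table plus recovery indicators.
    """
    causal = [] if (s == 0.0 and g == 0.0) else [CausalLocus(s=s, g=g)]
    config = SimConfig(
        n_markers=n_markers,
        pool_size=pool_size,
        replicates=replicates,
        timepoints=timepoints,
        mean_depth=depth,
        causal=causal,
    )
    exp = simulate_experiment(config, seed)
    track = TrajectoryScorer().fit(exp.table).scores_
    track = NeighborOutlierFilter().fit_transform(track)
    scanner = GenomeScanner(window=window, iqr_multiplier=iqr_multiplier).fit(track)
    peaks = scanner.peaks_
    out = {
        "peaks": peaks,
        "threshold": scanner.threshold_,
        "track": scanner.track_,
        "truth": exp.truth,
        "n_peaks": len(peaks),
        "causal_in_top_peak": False,
        "causal_score": np.nan,
    }
    if len(exp.truth) and len(peaks):
        top = peaks.iloc[0]
        c = exp.truth.iloc[0]
        out["causal_in_top_peak"] = bool(
            top["chrom"] == c["chrom"] and top["start"] <= c["pos"] <= top["end"]
        )
    if len(exp.truth):
        idx = int(exp.truth["marker_index"].iloc[0])
        out["causal_score"] = float(track["score"].iloc[idx])
    return out


def pilot_experiment(
    seed: int,
    s: float = 2.0,
    g: float = -0.3,
    n_markers: int = 2000,
    depth: float = 100.0,
    pool_size: int = 1000,
    cutoff: float = 0.15,
    min_depth: int = 10,
    growth_rounds: int = 8,
) -> dict:
    """Three-sample pilot with one antagonistic locus; run the dAF screen.

    Records from the two replicate pools are concatenated (one record per
    pool x marker).  Recovery = the causal marker classified antagonistic
    in at least one pool.
    """
    config = SimConfig(
        n_markers=n_markers,
        pool_size=pool_size,
        mean_depth=depth,
        causal=[CausalLocus(s=s, g=g)],
    )
    pilot = simulate_pilot(config, seed, growth_rounds=growth_rounds)
    idx = int(pilot.truth["marker_index"].iloc[0])
    import pandas as pd

    from .regrowth import classify, correlate, delta_af

    records = []
    for p in (0, 1):
        rec = delta_af(
            pilot.counts[(p, "day0")],
            pilot.counts[(p, "day6")],
            pilot.counts[(p, "day6_regrown")],
            min_depth=min_depth,
        )
        rec["marker_index"] = np.arange(len(rec))
        records.append(rec)
    records = pd.concat(records, ignore_index=True)
    summary = classify(records, cutoff)
    r, p_val = correlate(records)
    antag_markers = set(records.loc[summary.antagonistic_index, "marker_index"])
    return {
        "records": records,
        "summary": summary,
        "r": r,
        "p": p_val,
        "causal_index": idx,
        "causal_antagonistic": idx in antag_markers,
    }


def reseeding_experiment(
    seed: int,
    n_causal: int = 40,
    s: float = 0.4,
    n_markers: int = 1000,
    pool_size: int = 1000,
    seeding_days: tuple[int, ...] = (0, 3, 6),
    followup_days: int = 10,
) -> list[float]:
    """Age a selected pool, re-seed from successive sampling days, and
    measure each re-seeded pool's survival integral.

    Many weak-effect survival loci give the pool heritable lifespan
    variation, so survivors sampled later are enriched for long-lived
    genotypes and their re-seeded pools should show larger survival
    integrals.  Returns one integral per seeding day.

    The baseline logit is centered so that an individual carrying the
    average allele load (half the causal alleles) keeps the standard
    daily survival logit of 1 — the pool-level death rate stays in the
    observed range while genotypes spread around it.
    """
    from .simulate import SegregantPool, build_marker_map, founder_pool, intercross
    from .simulate import SelectionModel

    rng = np.random.default_rng(seed)
    markers = build_marker_map(n_markers, rng=rng)
    causal_idx = rng.choice(n_markers, size=n_causal, replace=False)
    surv = np.zeros(n_markers)
    surv[causal_idx] = s
    model = SelectionModel(n_markers, survival=surv, beta0=1.0 - n_causal * s / 2.0)
    ail = intercross(founder_pool(markers, pool_size), 6, pool_size, model, markers, rng)
    aging = age_pool(ail, model, days=max(seeding_days), rng=rng)
    integrals = []
    for day in seeding_days:
        reseeded = aging.survivor_pool(day)
        boot = rng.integers(0, reseeded.n_individuals, size=pool_size)
        pool = SegregantPool(reseeded.haplotypes[boot])
        follow = age_pool(pool, model, days=followup_days, rng=rng)
        curve = LifespanCurve(follow.days, follow.viability)
        integrals.append(curve.survival_integral())
    return integrals
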