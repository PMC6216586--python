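import math

import numpy as np
import pandas as pd
import pytest

from poolage.core import MarkerMap


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_track(scores, chrom="I", spacing=1000, start=1000):
    """Genome-ordered score frame from a list of combined scores."""
    scores = list(scores)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start + spacing * np.arange(len(scores)),
            "score": np.asarray(scores, dtype=float),
            "n_replicates": 1,
        }
    )


def toy_marker_map(n=5, chrom="I", spacing=1000):
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": spacing * np.arange(1, n + 1),
            "short_allele": "A",
            "long_allele": "G",
            "kind": "SNP",
        }
    )
    return MarkerMap(df)


# ---------------------------------------------------------------------------
# independent brute-force scoring oracle (lgamma pmf + grid-search MLE)
# ---------------------------------------------------------------------------


def oracle_log_pmf(k: int, n: int, p: float) -> float:
    """Binomial log-pmf from first principles, 0*log0 treated as 0."""
    comb = math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    term_k = 0.0 if k == 0 else k * math.log(p) if p > 0 else -math.inf
    term_nk = 0.0 if k == n else (n - k) * math.log(1 - p) if p < 1 else -math.inf
    return comb + term_k + term_nk


def _grid_total_loglik(k, n, grid):
    """Sum over time points of the binomial log-pmf at each grid frequency."""
    k = np.asarray(k, dtype=float)[:, None]
    n = np.asarray(n, dtype=float)[:, None]
    comb = (
        np.vectorize(math.lgamma)(n + 1)
        - np.vectorize(math.lgamma)(k + 1)
        - np.vectorize(math.lgamma)(n - k + 1)
    )
    p = np.asarray(grid, dtype=float)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        term_k = np.where(k > 0, k * np.log(p), 0.0)
        term_nk = np.where(n - k > 0, (n - k) * np.log(1 - p), 0.0)
    return (comb + term_k + term_nk).sum(axis=0)


def oracle_null_loglik(k, n, step=1e-4):
    """Grid-search MLE of a shared frequency, refined by two local zooms."""
    k = np.asarray(k)
    n = np.asarray(n)
    use = n > 0
    k, n = k[use], n[use]
    lo, hi, h = 0.0, 1.0, step
    best = None
    for _ in range(3):
        grid = np.arange(lo, hi + h / 2, h)
        vals = _grid_total_loglik(k, n, grid)
        best = float(grid[int(np.argmax(vals))])
        lo, hi, h = max(0.0, best - h), min(1.0, best + h), h / 100
    logl = sum(oracle_log_pmf(int(ki), int(ni), best) for ki, ni in zip(k, n))
    return best, logl


def oracle_score(k, n):
    """Brute-force trajectory score: saturated minus grid-searched null."""
    _, l0 = oracle_null_loglik(k, n)
    l1 = sum(
        oracle_log_pmf(ki, ni, ki / ni) for ki, ni in zip(k, n) if ni > 0
    )
    return l1 - l0
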