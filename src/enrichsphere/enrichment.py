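"""Exact hypergeometric enrichment of features against biomes.

The null model for a feature f and biome b is sampling without replacement:
the biome's n reads are a draw from the pooled urn of N reads, of which K
belong to f.  A feature is over-represented in the biome when the observed
in-biome count k sits far in the upper tail:

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

The tail is summed exactly in log space (no normal approximation), so
p-values like 1e-300 remain meaningful -- with millions of pooled reads the
interesting signals are that extreme.  Enrichment is called by strict
p < alpha (default alpha = 0.01), one-sided: under-representation is not
tested.  No multiplicity correction is applied by default;
Benjamini-Hochberg q-values are available via :func:`adjust_bh`.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import hypergeom as _hypergeom

from enrichsphere.core_io import BiomeCounts

# stop summing once a whole chunk is below exp(-40) of the running total
_LOG_NEGLIGIBLE = 40.0
# below this the closed-form sf underflows; switch to the log-space sum
_SF_FLOOR = 1e-250


@dataclass
class EnrichmentResult:
    """One feature x biome test: the urn quantities, p-value and the call."""

    feature_id: str
    biome: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    enriched: bool
    fold: float
    q_value: float | None = None
    skipped: bool = False


def _log_binom(a, b):
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def _log_pmf(x: np.ndarray, K: int, n: int, N: int) -> np.ndarray:
    return (
        _log_binom(float(K), x)
        + _log_binom(float(N - K), n - x)
        - _log_binom(float(N), float(n))
    )


def hypergeom_tail(k: int, K: int, n: int, N: int, log: bool = False) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    Parameters follow the urn convention: N items total, K of them successes,
    n drawn, k successes observed.  The sum over the support is accumulated
    in log space and truncated once further terms are numerically negligible,
    so the result is exact to double precision even deep in the tail.  With
    ``log=True`` the natural log of the tail is returned, which stays finite
    for tails far below the smallest positive float.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v:
            raise ValueError(f"{name} must be an integer, got {v!r}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if N < 1:
        raise ValueError(f"N must be >= 1, got N={N}")
    if not 0 <= K <= N:
        raise ValueError(f"K out of bounds: K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"n out of bounds: n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"k out of bounds: k={k}, min(K, n)={min(K, n)}")

    lo = max(0, n + K - N)  # lower end of the support
    hi = min(K, n)
    if k <= lo:
        return 0.0 if log else 1.0

    # fast path: closed-form survival function while it has headroom
    sf = float(_hypergeom.sf(k - 1, N, K, n))
    if sf >= _SF_FLOOR:
        sf = min(1.0, sf)
        return math.log(sf) if log else sf

    # deep tail (k far above the mode): truncated log-space sum, growing chunks
    mode = (n + 1) * (K + 1) // (N + 2)
    total = -np.inf
    start = k
    width = 512
    while start <= hi:
        stop = min(start + width, hi + 1)
        xs = np.arange(start, stop, dtype=float)
        chunk = logsumexp(_log_pmf(xs, K, n, N))
        total = np.logaddexp(total, chunk)
        # past the mode the pmf decays monotonically: safe to truncate
        if stop > mode and chunk < total - _LOG_NEGLIGIBLE:
            break
        start = stop
        width *= 2
    if log:
        return float(min(0.0, total))
    return float(min(1.0, np.exp(total)))


def scan_enrichment(counts: BiomeCounts, alpha: float = 0.01) -> list[EnrichmentResult]:
    """Test every (feature, biome) cell for over-representation.

    Returns one result per pair in deterministic order (feature order x biome
    order).  Features with zero counts everywhere have an undefined test and
    are recorded with p = 1.0 and ``skipped=True``.  Fold is the abundance
    ratio (k/n)/(K/N), 0 when K = 0.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    N = counts.grand_total
    if N == 0:
        raise ValueError("all counts are zero (N = 0); nothing to test")
    K_f = counts.totals_per_feature
    n_b = counts.totals_per_biome
    out: list[EnrichmentResult] = []
    for i, feature in enumerate(counts.feature_ids):
        K = int(K_f[i])
        for j, biome in enumerate(counts.biomes):
            k = int(counts.counts[i, j])
            n = int(n_b[j])
            if K == 0:
                out.append(
                    EnrichmentResult(
                        feature_id=feature,
                        biome=biome,
                        k=k,
                        K=K,
                        n=n,
                        N=N,
                        p_value=1.0,
                        enriched=False,
                        fold=0.0,
                        skipped=True,
                    )
                )
                continue
            p = hypergeom_tail(k, K, n, N)
            fold = (k / n) / (K / N) if n > 0 else 0.0
            out.append(
                EnrichmentResult(
                    feature_id=feature,
                    biome=biome,
                    k=k,
                    K=K,
                    n=n,
                    N=N,
                    p_value=p,
                    enriched=p < alpha,
                    fold=fold,
                )
            )
    return out


def adjust_bh(
    results: list[EnrichmentResult], alpha: float = 0.01, recall: bool = False
) -> list[EnrichmentResult]:
    """Attach Benjamini-Hochberg q-values over all tests jointly.

    The enriched flag is left as called on raw p-values unless ``recall=True``,
    in which case it is re-derived as q < alpha.  Skipped tests participate
    with their recorded p = 1.0.
    """
    from statsmodels.stats.multitest import multipletests

    if not results:
        return results
    pvals = np.array([r.p_value for r in results])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(results, qvals):
        r.q_value = float(q)
        if recall and not r.skipped:
            r.enriched = bool(q < alpha)
    return results
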