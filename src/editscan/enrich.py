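"""Gene-set over-representation against declared baselines.

Enrichment of a gene list in a named set is assessed with the two-sided
Fisher exact test on the 2x2 table (hits in set / hits out of set /
non-hits in set / non-hits out of set). Results carry fold enrichment
(k/n) / (K/N), the odds ratio, and the set's baseline percentage
100*K/N — e.g. a nucleolar-proteome baseline of 3,490/19,670 = 17.7% or
a high-confidence TP53-target baseline of 343/43,768 = 0.8%. The
reporting filter mirrors the STRING-style cutoff: fold enrichment
strictly greater than 2 and p < 0.05. No multiple-testing correction is
applied by default; Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int                 # hits in set
    n: int                 # hits total
    K: int                 # set size in universe
    N: int                 # universe size
    fold: float
    odds_ratio: float
    p_value: float
    reported: bool         # passes fold > 2 and p < alpha

    @property
    def baseline_percent(self) -> float:
        return 100.0 * self.K / self.N


def set_fraction_baseline(K: int, N: int, decimals: int | None = 1) -> float:
    """Baseline percentage 100*K/N, rounded for reporting."""
    if not 0 < K <= N:
        raise ValueError("require 0 < K <= N")
    percent = 100.0 * K / N
    return round(percent, decimals) if decimals is not None else percent


def fisher_enrichment(k: int, n: int, K: int, N: int, alpha: float = 0.05,
                      min_fold: float = 2.0, set_name: str = "") -> EnrichmentResult:
    """Two-sided Fisher exact test for k-of-n hits against a K-of-N set."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(
            f"inconsistent contingency counts k={k}, n={n}, K={K}, N={N}"
        )
    if K == 0 or n == 0:
        raise ValueError("empty gene set or empty hit list")
    table = [[k, n - k], [K - k, N - n - (K - k)]]
    if min(min(row) for row in table) < 0:
        raise ValueError("inconsistent contingency counts (negative cell)")
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    fold = (k / n) / (K / N)
    return EnrichmentResult(
        set_name=set_name, k=k, n=n, K=K, N=N, fold=fold,
        odds_ratio=float(odds_ratio), p_value=float(p),
        reported=fold > min_fold and p < alpha,
    )


def ora(genes: Iterable[str], gene_sets: Mapping[str, set[str]],
        universe: Iterable[str], alpha: float = 0.05, min_fold: float = 2.0,
        fdr: bool = False) -> list[EnrichmentResult]:
    """Over-representation of a gene list in each named set.

    The universe defaults to the annotated genes of the run; every
    result is returned, with the ``reported`` flag marking those passing
    fold > min_fold and p < alpha (on BH-adjusted p-values when ``fdr``).
    """
    universe = set(universe)
    genes = set(genes)
    if not genes <= universe:
        raise ValueError("gene list must be a subset of the universe")
    if not genes:
        raise ValueError("empty gene list")
    results = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        if not members:
            raise ValueError(f"gene set {name!r} has no members in the universe")
        results.append(fisher_enrichment(
            k=len(genes & members), n=len(genes), K=len(members),
            N=len(universe), alpha=alpha, min_fold=min_fold, set_name=name,
        ))
    if fdr and results:
        m = len(results)
        order = sorted(range(m), key=lambda i: results[i].p_value)
        adjusted = [0.0] * m
        prev = 1.0
        for rank, i in list(enumerate(order, start=1))[::-1]:
            prev = min(prev, results[i].p_value * m / rank)
            adjusted[i] = prev
        results = [
            EnrichmentResult(
                r.set_name, r.k, r.n, r.K, r.N, r.fold, r.odds_ratio, adj,
                reported=r.fold > min_fold and adj < alpha,
            )
            for r, adj in zip(results, adjusted)
        ]
    return results
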