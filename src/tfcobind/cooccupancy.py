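"""Co-binding statistics for two transcription-factor peak sets.

Given peak sets A and B and a universe of regions (promoters, enhancers, or
domains), this module computes binarized binding calls, the 2x2 co-binding
table, its upper-tail hypergeometric enrichment p-value (evaluated in log
space so that p ~ 1e-222 survives), nearest-peak distance profiles, and the
"co-bound or proximal" breakdown used when one factor binds near, but not
inside, a region bound by the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .intervals import GenomicInterval, RegionSet

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class CobindingTable:
    """Counts underlying a two-factor co-binding test.

    N: universe size (number of regions); K: regions bound by factor A;
    n: regions bound by factor B; k: regions bound by both.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.k <= min(self.K, self.n)
            and self.K <= self.N
            and self.n <= self.N
            and self.k >= max(0, self.K + self.n - self.N)
            and self.N >= 0
        )
        if not ok:
            raise ValueError(f"inconsistent co-binding table N={self.N} K={self.K} n={self.n} k={self.k}")

    @property
    def frac_a_cobound(self) -> float:
        """Fraction of A-bound regions also bound by B (k/K); nan when K=0."""
        return self.k / self.K if self.K else float("nan")

    @property
    def frac_universe_a(self) -> float:
        """Fraction of the universe bound by A (K/N); nan when N=0."""
        return self.K / self.N if self.N else float("nan")

    @property
    def pct_a_cobound(self) -> float:
        return 100.0 * self.frac_a_cobound

    @property
    def pct_universe_a(self) -> float:
        return 100.0 * self.frac_universe_a

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "K": self.K,
            "n": self.n,
            "k": self.k,
            "pct_a_cobound": self.pct_a_cobound,
            "pct_universe_a": self.pct_universe_a,
        }


@dataclass(frozen=True)
class EnrichmentResult:
    """A co-binding table with its upper-tail hypergeometric p-value."""

    table: CobindingTable
    p_hyper: float
    neg_log10_p: float

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(),
            "p_hyper": self.p_hyper,
            "neg_log10_p": self.neg_log10_p,
        }


def log_hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Natural log of P(X >= k), X ~ Hypergeometric(N, K, n).

    Evaluated as a log-sum-exp over the log pmf so the result is finite even
    when the probability underflows double precision.
    """
    CobindingTable(N, K, n, k)  # validate
    if k <= max(0, K + n - N):
        return 0.0
    i = np.arange(k, min(K, n) + 1, dtype=float)
    log_pmf = (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(N - K + 1) - gammaln(n - i + 1) - gammaln(N - K - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(0.0, logsumexp(log_pmf)))


def hypergeometric_pvalue(table: CobindingTable) -> EnrichmentResult:
    """Upper-tail (enrichment) hypergeometric test on a co-binding table.

    ``p_hyper`` may underflow to 0.0 for astronomically small tails; the
    log-scale ``neg_log10_p`` is always finite and is the quantity to report.
    """
    logp = log_hypergeom_tail(table.N, table.K, table.n, table.k)
    return EnrichmentResult(
        table=table, p_hyper=float(np.exp(logp)), neg_log10_p=(-logp / _LN10) + 0.0
    )


def regions_bound(peaks: RegionSet, regions: RegionSet) -> set[str]:
    """Labels of regions overlapped by at least one peak (binarized binding).

    A peak may bind several regions; a region with several peaks counts once.
    """
    return {region.key for region in regions if peaks.any_overlap(region)}


def cobinding_table(peaks_a: RegionSet, peaks_b: RegionSet, regions: RegionSet) -> CobindingTable:
    """2x2 co-binding counts of two peak sets over a region universe."""
    bound_a = regions_bound(peaks_a, regions)
    bound_b = regions_bound(peaks_b, regions)
    return CobindingTable(
        N=len(regions), K=len(bound_a), n=len(bound_b), k=len(bound_a & bound_b)
    )


def cobinding_enrichment(
    peaks_a: RegionSet, peaks_b: RegionSet, regions: RegionSet
) -> EnrichmentResult:
    return hypergeometric_pvalue(cobinding_table(peaks_a, peaks_b, regions))


# ---------------------------------------------------------------------------
# Distance profiles


def nearest_gap_distances(
    queries: Sequence[GenomicInterval] | RegionSet,
    targets: RegionSet,
) -> np.ndarray:
    """Minimum gap from each query interval to any target on its chromosome.

    0 for overlap/abutment; ``inf`` when the chromosome holds no target.
    Result is aligned with the iteration order of ``queries``.
    """
    query_list = list(queries)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in targets.chromosomes():
        ivs = sorted(targets.by_chrom(chrom), key=lambda iv: iv.start)
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        by_chrom[chrom] = (starts, np.maximum.accumulate(ends))
    out = np.full(len(query_list), np.inf)
    for qi, q in enumerate(query_list):
        pair = by_chrom.get(q.chrom)
        if pair is None:
            continue
        starts, prefmax_end = pair
        j = int(np.searchsorted(starts, q.end, side="left"))
        best = math.inf
        if j < len(starts):
            best = starts[j] - q.end  # nearest target fully to the right
        if j > 0:
            pm = prefmax_end[j - 1]
            if pm > q.start:
                best = 0  # overlap with a target starting before q.end
            else:
                best = min(best, q.start - pm)
        out[qi] = best
    return out


@dataclass(frozen=True)
class DistanceProfile:
    """Cumulative fraction of A peaks whose nearest B peak lies within each edge."""

    bin_edges: tuple[int, ...]
    cumulative_fraction: tuple[float, ...]
    n_query: int

    def __post_init__(self) -> None:
        fr = self.cumulative_fraction
        if any(b - a < 0 for a, b in zip(fr, fr[1:])) or any(not 0 <= f <= 1 for f in fr):
            raise ValueError("cumulative fractions must be non-decreasing within [0, 1]")


def distance_profile(
    peaks_a: RegionSet,
    peaks_b: RegionSet,
    bin_edges: Sequence[int],
) -> DistanceProfile:
    """Distance profile of factor-A peaks to their nearest factor-B peak.

    For each A peak the minimum edge-to-edge gap to any same-chromosome B peak
    is taken (0 on overlap). A peaks on chromosomes with no B peak fall in no
    bin but stay in the denominator.
    """
    edges = list(bin_edges)
    if not edges or any(e < 0 for e in edges) or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be non-negative and strictly increasing")
    if len(peaks_a) == 0:
        raise ValueError("no query peaks")
    dists = nearest_gap_distances(peaks_a, peaks_b)
    fractions = tuple(float(np.mean(dists <= e)) for e in edges)
    return DistanceProfile(tuple(int(e) for e in edges), fractions, n_query=len(peaks_a))


# ---------------------------------------------------------------------------
# Co-bound or proximal breakdown


@dataclass(frozen=True)
class ProximityCobinding:
    """Co-binding plus near-miss binding within ``max_gap`` of an A-bound region.

    Among regions bound by A but not by B, ``n_proximal`` counts those whose
    nearest B peak lies within ``max_gap`` bp of the region. Because the
    natural denominator is ambiguous, both fractions are reported: over all
    A-bound regions and over the non-co-bound remainder.
    """

    table: CobindingTable
    max_gap: int
    n_proximal: int
    frac_of_a_bound: float
    frac_of_noncobound: float

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(),
            "max_gap": self.max_gap,
            "n_proximal": self.n_proximal,
            "frac_of_a_bound": self.frac_of_a_bound,
            "frac_of_noncobound": self.frac_of_noncobound,
        }


def proximity_cobinding(
    peaks_a: RegionSet,
    peaks_b: RegionSet,
    regions: RegionSet,
    max_gap: int = 10_000,
) -> ProximityCobinding:
    bound_a = regions_bound(peaks_a, regions)
    bound_b = regions_bound(peaks_b, regions)
    table = CobindingTable(
        N=len(regions), K=len(bound_a), n=len(bound_b), k=len(bound_a & bound_b)
    )
    only_a = [r for r in regions if r.key in bound_a and r.key not in bound_b]
    if only_a:
        dists = nearest_gap_distances(only_a, peaks_b)
        n_proximal = int(np.sum(dists <= max_gap))
    else:
        n_proximal = 0
    return ProximityCobinding(
        table=table,
        max_gap=max_gap,
        n_proximal=n_proximal,
        frac_of_a_bound=n_proximal / table.K if table.K else float("nan"),
        frac_of_noncobound=(
            n_proximal / (table.K - table.k) if table.K > table.k else float("nan")
        ),
    )


def binding_calls(
    peaks_a: RegionSet, peaks_b: RegionSet, regions: RegionSet
) -> list[dict]:
    """Per-region binding calls, preserving region order (for TSV reports)."""
    bound_a = regions_bound(peaks_a, regions)
    bound_b = regions_bound(peaks_b, regions)
    return [
        {
            "region": r.key,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "bound_a": int(r.key in bound_a),
            "bound_b": int(r.key in bound_b),
        }
        for r in regions
    ]
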