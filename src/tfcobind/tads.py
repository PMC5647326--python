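"""Two-factor co-occupancy enrichment within Hi-C topological domains.

Peaks are assigned to the unique domain containing their midpoint; enrichment
of domains carrying both factors is scored two ways, as in the source
analysis: an upper-tail hypergeometric test on the binarized occupancy table,
and a length-stratified permutation test that shuffles the per-domain peak
counts only among domains of similar length, preserving the length-count
relationship of the observed data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cooccupancy import CobindingTable, EnrichmentResult, hypergeometric_pvalue
from .intervals import GenomicInterval, RegionSet, has_overlaps


@dataclass(frozen=True)
class DomainOccupancy:
    """Per-domain peak counts for two factors plus the domain's length stratum."""

    domain: GenomicInterval
    count_a: int
    count_b: int
    length_group: int

    def __post_init__(self) -> None:
        if self.count_a < 0 or self.count_b < 0:
            raise ValueError("peak counts must be non-negative")


def assign_peaks_to_domains(peaks: RegionSet, domains: RegionSet) -> np.ndarray:
    """Count peaks per domain by midpoint containment.

    Requires an overlap-free domain set (run ``remove_overlapping_keep_shortest``
    first) so that each midpoint lands in at most one domain. Peaks whose
    midpoint falls in no domain are dropped from the analysis.
    """
    if has_overlaps(domains):
        raise ValueError(
            "domains overlap; de-overlap first with remove_overlapping_keep_shortest"
        )
    index = {iv: i for i, iv in enumerate(domains)}
    counts = np.zeros(len(domains), dtype=np.int64)
    for peak in peaks:
        hits = domains.at_point(peak.chrom, peak.midpoint)
        if hits:
            counts[index[hits[0]]] += 1
    return counts


def length_strata(domains: RegionSet, n_bins: int) -> np.ndarray:
    """Quantile length strata: ``n_bins`` groups whose sizes differ by at most 1.

    Length ties are broken by (chrom, start) so the partition is deterministic.
    Returns the stratum index of each domain in iteration order.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(domains) < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} domains, got {len(domains)}")
    order = sorted(range(len(domains)),
                   key=lambda i: (domains.intervals[i].length,
                                  domains.intervals[i].chrom,
                                  domains.intervals[i].start))
    strata = np.empty(len(domains), dtype=np.int64)
    for g, chunk in enumerate(np.array_split(np.asarray(order), n_bins)):
        strata[chunk] = g
    return strata


def domain_occupancy(
    peaks_a: RegionSet,
    peaks_b: RegionSet,
    domains: RegionSet,
    n_bins: int = 10,
) -> list[DomainOccupancy]:
    """Assign both peak sets to domains and attach length strata."""
    counts_a = assign_peaks_to_domains(peaks_a, domains)
    counts_b = assign_peaks_to_domains(peaks_b, domains)
    strata = length_strata(domains, n_bins)
    return [
        DomainOccupancy(domain=d, count_a=int(a), count_b=int(b), length_group=int(g))
        for d, a, b, g in zip(domains, counts_a, counts_b, strata)
    ]


@dataclass(frozen=True)
class PermutationResult:
    """Observed both-bound domain count against its length-stratified null."""

    observed_both: int
    null_draws: tuple[int, ...]
    n_perm: int
    p_empirical: float
    seed: int

    def to_dict(self, include_null: bool = False) -> dict:
        d = {
            "observed_both": self.observed_both,
            "n_perm": self.n_perm,
            "p_empirical": self.p_empirical,
            "seed": self.seed,
            "null_mean": float(np.mean(self.null_draws)),
            "null_sd": float(np.std(self.null_draws)),
        }
        if include_null:
            d["null_draws"] = list(self.null_draws)
        return d


def permutation_test(
    occupancy: Sequence[DomainOccupancy],
    n_perm: int = 10_000,
    seed: int = 0,
    check_conservation: bool = False,
) -> PermutationResult:
    """Length-stratified permutation test for two-factor domain co-occupancy.

    The statistic is the number of domains with at least one peak of each
    factor. Each iteration independently permutes the vector of factor-A
    counts among domains within each length stratum, and likewise the
    factor-B counts, then recomputes the statistic. The empirical p-value
    uses the add-one formula ``(1 + #{null >= observed}) / (1 + n_perm)`` so
    it is never zero. ``check_conservation`` asserts, inside the loop, that
    each shuffle preserves the per-stratum count multisets (for small runs).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.array([o.count_a for o in occupancy], dtype=np.int64)
    b = np.array([o.count_b for o in occupancy], dtype=np.int64)
    strata = np.array([o.length_group for o in occupancy], dtype=np.int64)
    observed = int(np.count_nonzero((a > 0) & (b > 0)))
    groups = [np.flatnonzero(strata == g) for g in np.unique(strata)]
    rng = np.random.default_rng(seed)
    a_perm = a.copy()
    b_perm = b.copy()
    null = np.empty(n_perm, dtype=np.int64)
    for it in range(n_perm):
        for idx in groups:
            a_perm[idx] = a[idx[rng.permutation(len(idx))]]
            b_perm[idx] = b[idx[rng.permutation(len(idx))]]
        if check_conservation:
            for idx in groups:
                assert np.array_equal(np.sort(a_perm[idx]), np.sort(a[idx]))
                assert np.array_equal(np.sort(b_perm[idx]), np.sort(b[idx]))
        null[it] = np.count_nonzero((a_perm > 0) & (b_perm > 0))
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return PermutationResult(
        observed_both=observed,
        null_draws=tuple(int(x) for x in null),
        n_perm=n_perm,
        p_empirical=p,
        seed=seed,
    )


def tad_hypergeometric(occupancy: Sequence[DomainOccupancy]) -> EnrichmentResult:
    """Hypergeometric enrichment on binarized domain occupancy."""
    a = np.array([o.count_a for o in occupancy])
    b = np.array([o.count_b for o in occupancy])
    table = CobindingTable(
        N=len(occupancy),
        K=int(np.count_nonzero(a > 0)),
        n=int(np.count_nonzero(b > 0)),
        k=int(np.count_nonzero((a > 0) & (b > 0))),
    )
    return hypergeometric_pvalue(table)
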