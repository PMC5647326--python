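"""Synthetic inputs with the statistical structure the analyses assume.

Three generators cover every input the pipeline consumes:

* ``generate_regions`` — non-overlapping domains with log-uniform heterogeneous
  lengths (so length stratification is exercised), strand-mixed TSS records
  with their promoter windows, and enhancer intervals;
* ``generate_cooccupying_peaks`` — two peak sets where factor B co-occupies
  factor A's domains (or flanks A peaks) with tunable strength ``rho``;
* ``generate_expression`` — exon count matrices for four sample groups
  (source fibroblast-like, untreated knock-in, induced knock-in, target
  lineage) in which the induced group's mean profile is the mixture
  ``(1 - w) * source + w * target`` with negative-binomial noise.

Everything is driven by a single :class:`SyntheticConfig` and is
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .intervals import (
    GenomicInterval,
    RegionSet,
    TssRecord,
    make_promoters,
    write_bed6,
    write_tss_table,
)
from .transcriptome import ExonCountMatrix

GROUPS = ("source", "knockin_untreated", "knockin_induced", "target")

_BIOTYPE_CHOICES = ("protein_coding", "lincRNA", "pseudogene", "rRNA", "miRNA")
_BIOTYPE_PROBS = (0.80, 0.07, 0.05, 0.04, 0.04)


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator parameters; defaults define the study conditions.

    ``rho`` is the co-occupancy strength (probability a B peak is planted in
    a domain carrying an A peak); ``w`` is the expression mixture weight of
    the induced group; ``nb_dispersion`` is the negative-binomial dispersion
    (variance = mu + dispersion * mu^2).
    """

    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 60_000_000, "chr2": 60_000_000, "chr3": 60_000_000}
    )
    n_domains: int = 200
    domain_length_range: tuple = (50_000, 2_000_000)
    n_promoters: int = 2000
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    n_enhancers: int = 1000
    enhancer_length: int = 1000
    n_peaks_a: int = 150
    n_peaks_b: int = 150
    peak_length: int = 400
    rho: float = 0.8
    cooccupancy_mode: str = "domain"  # or "near"
    near_window: int = 10_000
    w: float = 0.25
    nb_dispersion: float = 0.1
    n_exons: int = 2000
    exons_per_gene: int = 5
    n_samples_per_group: int = 2
    frac_differential: float = 0.2
    frac_silent: float = 0.4
    differential_ratio: float = 8.0
    exon_length_range: tuple = (200, 2000)
    base_mean: float = 100.0
    base_log_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.cooccupancy_mode not in ("domain", "near"):
            raise ValueError("cooccupancy_mode must be 'domain' or 'near'")
        for name in ("n_domains", "n_promoters", "n_enhancers", "n_peaks_a", "n_peaks_b",
                     "peak_length", "n_exons", "exons_per_gene", "n_samples_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.domain_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("domain_length_range must be positive and ordered")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("frac_differential must be in [0, 1]")
        if not 0.0 <= self.frac_silent <= 1.0:
            raise ValueError("frac_silent must be in [0, 1]")
        if self.frac_differential + self.frac_silent > 1.0:
            raise ValueError("frac_differential + frac_silent must be <= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["domain_length_range"] = list(self.domain_length_range)
        d["exon_length_range"] = list(self.exon_length_range)
        return d

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("domain_length_range", "exon_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimulatedRegions:
    domains: RegionSet
    promoters: RegionSet
    tss_records: list
    enhancers: RegionSet


# stream offsets: independent substreams per generator so outputs compose
_STREAM_REGIONS, _STREAM_PEAKS, _STREAM_EXPR = 0, 1, 2


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _choose_chroms(rng, chrom_sizes: dict, n: int) -> list[str]:
    names = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in names], dtype=float)
    return [names[i] for i in rng.choice(len(names), size=n, p=sizes / sizes.sum())]


def generate_regions(config: SyntheticConfig) -> SimulatedRegions:
    """Domains tiling the chromosomes with random gaps, plus promoters/enhancers.

    Domain lengths are log-uniform over ``domain_length_range`` so that
    max/min length ratios of an order of magnitude or more are typical and
    length stratification has real work to do. Raises when the requested
    domains cannot be packed into the chromosomes.
    """
    rng = _rng(config, _STREAM_REGIONS)
    lo, hi = config.domain_length_range
    lengths = np.exp(rng.uniform(math.log(lo), math.log(hi), config.n_domains)).astype(np.int64)
    genome = sum(config.chrom_sizes.values())
    total = int(lengths.sum())
    if total > 0.9 * genome:
        raise ValueError(
            f"infeasible packing: {config.n_domains} domains need {total} bp "
            f"but the genome has {genome} bp"
        )
    mean_gap = (genome - total) / (config.n_domains + len(config.chrom_sizes)) / 2.0
    chroms = list(config.chrom_sizes.items())
    domains: list[GenomicInterval] = []
    ci, pos = 0, 0
    for di, length in enumerate(lengths):
        length = int(length)
        placed = False
        while ci < len(chroms):
            cname, csize = chroms[ci]
            gap = int(rng.exponential(mean_gap))
            if pos + gap + length <= csize:
                start = pos + gap
            elif pos + length <= csize:
                start = pos
            else:
                ci += 1
                pos = 0
                continue
            domains.append(GenomicInterval(cname, start, start + length, label=f"dom{di:04d}"))
            pos = start + length
            placed = True
            break
        if not placed:
            raise ValueError("infeasible packing: ran out of chromosomes")

    margin = config.promoter_upstream + config.promoter_downstream
    tss_records = []
    for gi, chrom in enumerate(_choose_chroms(rng, config.chrom_sizes, config.n_promoters)):
        size = config.chrom_sizes[chrom]
        pos_t = int(rng.integers(margin, size - margin))
        strand = "+" if rng.random() < 0.5 else "-"
        tss_records.append(TssRecord(f"gene{gi:05d}", chrom, pos_t, strand))
    promoters = make_promoters(
        tss_records, config.promoter_upstream, config.promoter_downstream
    )

    enhancers = []
    for ei, chrom in enumerate(_choose_chroms(rng, config.chrom_sizes, config.n_enhancers)):
        size = config.chrom_sizes[chrom]
        start = int(rng.integers(0, size - config.enhancer_length))
        enhancers.append(
            GenomicInterval(chrom, start, start + config.enhancer_length, label=f"enh{ei:05d}")
        )
    return SimulatedRegions(
        domains=RegionSet("domains", domains),
        promoters=promoters,
        tss_records=tss_records,
        enhancers=RegionSet("enhancers", enhancers),
    )


def _uniform_peak(rng, config, chrom: str, label: str) -> GenomicInterval:
    size = config.chrom_sizes[chrom]
    start = int(rng.integers(0, size - config.peak_length))
    return GenomicInterval(chrom, start, start + config.peak_length, label=label)


def generate_cooccupying_peaks(
    config: SyntheticConfig, regions: SimulatedRegions
) -> tuple[RegionSet, RegionSet]:
    """Peak sets with planted co-occupancy of strength ``rho``.

    A peaks are uniform over the genome. Each B peak is, with probability
    ``rho``, planted relative to a random A peak — inside the domain holding
    that A peak's midpoint (mode ``"domain"``) or within ``near_window`` bp of
    the A peak (mode ``"near"``) — and otherwise placed uniformly.
    """
    rng = _rng(config, _STREAM_PEAKS)
    chroms_a = _choose_chroms(rng, config.chrom_sizes, config.n_peaks_a)
    peaks_a = [
        _uniform_peak(rng, config, chrom, f"peakA_{i:05d}") for i, chrom in enumerate(chroms_a)
    ]
    # A peaks anchored inside a domain (midpoint containment), for planting
    anchors: list[tuple[GenomicInterval, GenomicInterval]] = []
    for pk in peaks_a:
        hits = regions.domains.at_point(pk.chrom, pk.midpoint)
        if hits:
            anchors.append((pk, hits[0]))
    chroms_b = _choose_chroms(rng, config.chrom_sizes, config.n_peaks_b)
    peaks_b = []
    for i in range(config.n_peaks_b):
        label = f"peakB_{i:05d}"
        planted = anchors and rng.random() < config.rho
        if planted and config.cooccupancy_mode == "domain":
            _, dom = anchors[int(rng.integers(len(anchors)))]
            start = int(rng.integers(dom.start, dom.end - config.peak_length))
            peaks_b.append(GenomicInterval(dom.chrom, start, start + config.peak_length, label=label))
        elif planted:  # "near": within near_window of the anchor A peak
            anchor, _ = anchors[int(rng.integers(len(anchors)))]
            lo = max(0, anchor.start - config.near_window)
            hi = min(
                config.chrom_sizes[anchor.chrom] - config.peak_length,
                anchor.end + config.near_window - config.peak_length,
            )
            start = int(rng.integers(lo, max(lo + 1, hi)))
            peaks_b.append(
                GenomicInterval(anchor.chrom, start, start + config.peak_length, label=label)
            )
        else:
            peaks_b.append(_uniform_peak(rng, config, chroms_b[i], label))
    return RegionSet("peaks_A", peaks_a), RegionSet("peaks_B", peaks_b)


def generate_expression_with_truth(config: SyntheticConfig) -> tuple:
    """Like :func:`generate_expression` but also returns the ground truth.

    The truth DataFrame (indexed like the count matrix) carries the noiseless
    per-exon group means (``mu_source``, ``mu_target``, ``mu_induced``) and
    the planted ``is_differential`` / ``is_silent`` flags, for recovery tests.
    """
    return _generate_expression_impl(config)


def generate_expression(config: SyntheticConfig) -> ExonCountMatrix:
    """Four-group exon count matrix with a mixture-structured induced group.

    Per-exon base means are log-normal; a fraction ``frac_silent`` of exons is
    near-silent in every group (so the expression filter has realistic work).
    A fraction ``frac_differential`` of exons (drawn among the active ones)
    gets a true mean ratio of ``differential_ratio`` (half up, half down)
    between the source and target profiles; the rest have identical means, so
    a noiseless fold-change filter at any cut below the ratio retains exactly
    the planted exons. The induced group's mean traverses fraction ``w`` of
    each exon's log fold change: ``mu_induced = mu_source^(1-w) *
    mu_target^w``, which places it symmetrically for induced and repressed
    exons and reduces to the source (w=0) or target (w=1) profile at the
    endpoints. Counts are negative-binomial around mean x a mild per-sample
    size factor.
    """
    ecm, _ = _generate_expression_impl(config)
    return ecm


def _generate_expression_impl(config: SyntheticConfig) -> tuple:
    rng = _rng(config, _STREAM_EXPR)
    n = config.n_exons
    epg = config.exons_per_gene
    gene_ids = np.array([f"gene{i // epg:05d}" for i in range(n)])
    lo, hi = config.exon_length_range
    lengths = rng.integers(lo, hi + 1, n)

    mu_source = rng.lognormal(math.log(config.base_mean), config.base_log_sigma, n)
    n_silent = int(round(config.frac_silent * n))
    order = rng.permutation(n)
    silent_idx, active_idx = order[:n_silent], order[n_silent:]
    mu_source[silent_idx] *= 1e-3
    mu_target = mu_source.copy()
    n_diff = int(round(config.frac_differential * n))
    diff_idx = active_idx[:n_diff]  # order already random
    up = rng.random(n_diff) < 0.5
    mu_target[diff_idx[up]] *= config.differential_ratio
    mu_target[diff_idx[~up]] /= config.differential_ratio
    mu_induced = mu_source ** (1.0 - config.w) * mu_target ** config.w
    group_mu = {
        "source": mu_source,
        "knockin_untreated": mu_source,
        "knockin_induced": mu_induced,
        "target": mu_target,
    }

    nb_n = 1.0 / config.nb_dispersion
    sample_names, sample_groups, columns = [], [], {}
    for group in GROUPS:
        for r in range(1, config.n_samples_per_group + 1):
            name = f"{group}_{r}"
            sf = rng.lognormal(0.0, 0.1)
            mu = np.maximum(group_mu[group] * sf, 1e-8)
            columns[name] = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
            sample_names.append(name)
            sample_groups.append(group)

    # biotype per gene; a small non-retained fraction exercises the biotype filter
    n_genes = (n + epg - 1) // epg
    gene_biotypes = rng.choice(_BIOTYPE_CHOICES, size=n_genes, p=_BIOTYPE_PROBS)
    biotypes = gene_biotypes[np.arange(n) // epg]

    # synthetic coordinates: exons laid out sequentially with 500 bp spacers
    chrom_names = list(config.chrom_sizes)
    chroms, starts = [], []
    ci, pos = 0, 1000
    for L in lengths:
        if pos + int(L) + 500 > config.chrom_sizes[chrom_names[ci]]:
            ci = (ci + 1) % len(chrom_names)
            pos = 1000
        chroms.append(chrom_names[ci])
        starts.append(pos)
        pos += int(L) + 500
    starts = np.array(starts)

    exon_ids = pd.Index([f"exon{i:06d}" for i in range(n)], name="exon_id")
    exons = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chroms,
            "start": starts,
            "end": starts + lengths,
            "length": lengths,
            "biotype": biotypes,
        },
        index=exon_ids,
    )
    counts = pd.DataFrame(columns, index=exon_ids).astype(np.int64)
    groups = pd.Series(sample_groups, index=sample_names, name="group")
    is_diff = np.zeros(n, dtype=bool)
    is_diff[diff_idx] = True
    is_silent = np.zeros(n, dtype=bool)
    is_silent[silent_idx] = True
    truth = pd.DataFrame(
        {
            "mu_source": mu_source,
            "mu_target": mu_target,
            "mu_induced": mu_induced,
            "is_differential": is_diff,
            "is_silent": is_silent,
        },
        index=exon_ids,
    )
    return ExonCountMatrix(exons=exons, counts=counts, groups=groups), truth


@dataclass
class SimulatedData:
    config: SyntheticConfig
    regions: SimulatedRegions
    peaks_a: RegionSet
    peaks_b: RegionSet
    expression: ExonCountMatrix


def generate_all(config: SyntheticConfig) -> SimulatedData:
    regions = generate_regions(config)
    peaks_a, peaks_b = generate_cooccupying_peaks(config, regions)
    expression = generate_expression(config)
    return SimulatedData(
        config=config, regions=regions, peaks_a=peaks_a, peaks_b=peaks_b, expression=expression
    )


def write_dataset(data: SimulatedData, out_dir) -> dict:
    """Write every pipeline input to ``out_dir``; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "domains": os.path.join(out_dir, "domains.bed"),
        "peaks_a": os.path.join(out_dir, "peaks_A.bed"),
        "peaks_b": os.path.join(out_dir, "peaks_B.bed"),
        "enhancers": os.path.join(out_dir, "enhancers.bed"),
        "tss": os.path.join(out_dir, "tss.tsv"),
        "counts": os.path.join(out_dir, "counts.tsv"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "config": os.path.join(out_dir, "config.json"),
    }
    write_bed6(data.regions.domains, paths["domains"])
    write_bed6(data.peaks_a, paths["peaks_a"])
    write_bed6(data.peaks_b, paths["peaks_b"])
    write_bed6(data.regions.enhancers, paths["enhancers"])
    write_tss_table(data.regions.tss_records, paths["tss"])
    data.expression.to_tsv(paths["counts"], paths["samples"])
    with open(paths["config"], "w") as fh:
        json.dump(data.config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
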