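"""Genomic interval primitives and region-set containers.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention —
everywhere inside the package. Any 1-based input dialect must be converted at
the reader boundary. Strand is carried but ignored by every operation except
promoter construction, which is the only strand-dependent object in the
pipeline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open coordinate span on a named chromosome.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``strand`` is one of
    ``"+"``, ``"-"`` or ``"."`` (unspecified). ``label`` is an optional
    identifier (peak name, gene, domain id).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def key(self) -> str:
        """Stable identifier: the label if present, else coordinates."""
        if self.label is not None:
            return self.label
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: gene id, chromosome, 0-based position, strand."""

    gene: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene}: strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene}: negative TSS position {self.tss}")


class RegionSet:
    """A named collection of intervals with a per-chromosome overlap index.

    Plays the role of peak sets, promoter sets, enhancer sets and domain sets.
    Input order is preserved for iteration; overlap queries go through an
    interval tree per chromosome.
    """

    def __init__(self, name: str, intervals: Iterable[GenomicInterval]):
        self.name = name
        self._intervals: list[GenomicInterval] = list(intervals)
        self._trees: dict[str, IntervalTree] = {}
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in self._by_chrom.items():
            tree = IntervalTree()
            for iv in ivs:
                tree.addi(iv.start, iv.end, iv)
            self._trees[chrom] = tree

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    @property
    def intervals(self) -> Sequence[GenomicInterval]:
        return tuple(self._intervals)

    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def by_chrom(self, chrom: str) -> Sequence[GenomicInterval]:
        return tuple(self._by_chrom.get(chrom, ()))

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All member intervals intersecting ``query`` (half-open semantics)."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(query.start, query.end)]

    def any_overlap(self, query: GenomicInterval) -> bool:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return False
        return tree.overlaps(query.start, query.end)

    def at_point(self, chrom: str, pos: int) -> list[GenomicInterval]:
        """Member intervals containing the single base ``pos`` (start <= pos < end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.at(pos)]


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base (half-open; strand ignored)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Bases strictly between two intervals; 0 when overlapping or abutting.

    Returns ``None`` ("unreachable") when the intervals sit on different
    chromosomes.
    """
    if a.chrom != b.chrom:
        return None
    if overlaps(a, b):
        return 0
    return max(a.start, b.start) - min(a.end, b.end)


def make_promoters(
    tss_records: Iterable[TssRecord],
    upstream: int = 2000,
    downstream: int = 500,
    name: str = "promoters",
) -> RegionSet:
    """Build strand-aware promoter windows around TSS positions.

    For a ``+`` gene the promoter is ``[tss - upstream, tss + downstream)``;
    for a ``-`` gene, ``[tss - downstream, tss + upstream)``. Starts are
    clipped at 0. One region per gene, labeled by the gene id.
    """
    if upstream < 0 or downstream < 0 or upstream + downstream <= 0:
        raise ValueError("require upstream >= 0, downstream >= 0, upstream + downstream > 0")
    promoters = []
    for rec in tss_records:
        if rec.strand == "+":
            start, end = rec.tss - upstream, rec.tss + downstream
        elif rec.strand == "-":
            start, end = rec.tss - downstream, rec.tss + upstream
        else:  # pragma: no cover - TssRecord already validates
            raise ValueError(f"gene {rec.gene}: unknown strand {rec.strand!r}")
        start = max(0, start)
        promoters.append(
            GenomicInterval(rec.chrom, start, end, strand=rec.strand, label=rec.gene)
        )
    return RegionSet(name, promoters)


def has_overlaps(regions: RegionSet) -> bool:
    """True if any two member intervals on the same chromosome intersect."""
    for chrom in regions.chromosomes():
        ivs = sorted(regions.by_chrom(chrom), key=lambda iv: (iv.start, iv.end))
        max_end = -1
        for iv in ivs:
            if iv.start < max_end:
                return True
            max_end = max(max_end, iv.end)
    return False


def remove_overlapping_keep_shortest(domains: RegionSet) -> RegionSet:
    """De-overlap a domain set, preferentially keeping the shortest members.

    While any overlap remains, the longest interval currently involved in an
    overlap is discarded (ties broken by discarding the larger start, so the
    leftmost survives). The result is overlap-free and the operation is
    idempotent.
    """
    kept: list[GenomicInterval] = []
    for chrom in domains.chromosomes():
        alive = list(domains.by_chrom(chrom))
        while True:
            alive.sort(key=lambda iv: (iv.start, iv.end))
            involved: set[int] = set()
            active: list[tuple[int, int]] = []  # (end, index into alive)
            for i, iv in enumerate(alive):
                active = [(e, j) for (e, j) in active if e > iv.start]
                if active:
                    involved.add(i)
                    involved.update(j for _, j in active)
                active.append((iv.end, i))
            if not involved:
                break
            victim = max(involved, key=lambda i: (alive[i].length, alive[i].start))
            del alive[victim]
        kept.extend(alive)
    return RegionSet(domains.name, kept)


# ---------------------------------------------------------------------------
# Readers / writers


_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | os.PathLike, format: str = "bed3plus", name: str | None = None) -> RegionSet:
    """Read a BED3+ or narrowPeak file into a :class:`RegionSet`.

    Columns beyond the third are ignored except the name (column 4) and strand
    (column 6, when it is ``+`` or ``-``). Records on unplaced contigs are
    retained. Malformed lines raise with the 1-based line number.
    """
    if format not in ("bed3plus", "narrowPeak"):
        raise ValueError(f"unknown BED format {format!r}")
    min_fields = 10 if format == "narrowPeak" else 3
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= {min_fields} tab-separated "
                    f"fields, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"invalid interval at line {lineno}: {chrom}:{start}-{end}")
            label = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            intervals.append(GenomicInterval(chrom, start, end, strand=strand, label=label))
    if name is None:
        name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return RegionSet(name, intervals)


def read_tss_table(path: str | os.PathLike) -> list[TssRecord]:
    """Read a TSS table: tab-separated with header ``gene chrom tss strand``."""
    records: list[TssRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["gene", "chrom", "tss", "strand"]
        if [c.strip() for c in header[:4]] != required:
            raise ValueError(f"{path}: expected header columns {required}, got {header[:4]}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 fields")
            try:
                tss = int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer TSS") from exc
            records.append(TssRecord(fields[0], fields[1], tss, fields[3]))
    return records


def write_bed6(regions: RegionSet | Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Write intervals as BED6 (score 0; strand ``.`` when unspecified)."""
    with open(path, "w") as fh:
        for iv in regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.key}\t0\t{iv.strand}\n")


def write_tss_table(records: Iterable[TssRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchrom\ttss\tstrand\n")
        for rec in records:
            fh.write(f"{rec.gene}\t{rec.chrom}\t{rec.tss}\t{rec.strand}\n")
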