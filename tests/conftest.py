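"""Shared fixtures: the hand-built exon count matrix and small region helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tfcobind import GenomicInterval, RegionSet
from tfcobind.transcriptome import ExonCountMatrix

# ---------------------------------------------------------------------------
# Hand-built 40-exon / 12-gene / 4-sample count matrix.
#
# All exon lengths are 500 bp and the tests pass explicit library sizes of
# 1e6 reads per sample, so RPKM = 2 x count and every filter outcome can be
# enumerated by hand. Samples: mef_1/mef_2 (group "source"), mel_1/mel_2
# (group "target"). Counts are (mef_1, mef_2, mel_1, mel_2).

HAND_TABLE = [
    # exon, gene, biotype, counts
    ("e01", "g01", "protein_coding", (2, 2, 100, 110)),
    ("e02", "g01", "protein_coding", (3, 1, 80, 90)),
    ("e03", "g01", "protein_coding", (0, 0, 50, 60)),
    ("e04", "g01", "protein_coding", (1, 1, 6, 6)),       # ratio 13/3 just above 4
    ("e05", "g02", "protein_coding", (100, 100, 2, 2)),
    ("e06", "g02", "protein_coding", (50, 60, 0, 1)),
    ("e07", "g02", "protein_coding", (6, 6, 1, 1)),       # ratio 3/13 just below 1/4
    ("e08", "g03", "protein_coding", (20, 20, 30, 30)),
    ("e09", "g03", "protein_coding", (50, 50, 40, 40)),
    ("e10", "g03", "protein_coding", (10, 10, 10, 10)),
    ("e11", "g03", "protein_coding", (7, 7, 8, 8)),
    ("e12", "g04", "protein_coding", (1, 2, 3, 4)),       # never above RPKM 10
    ("e13", "g04", "protein_coding", (0, 0, 5, 5)),       # RPKM exactly 10: dropped
    ("e14", "g04", "protein_coding", (2, 2, 2, 2)),
    ("e15", "g05", "protein_coding", (2, 2, 40, 40)),
    ("e16", "g05", "protein_coding", (15, 15, 20, 20)),
    ("e17", "g05", "protein_coding", (0, 1, 0, 1)),
    ("e18", "g05", "protein_coding", (3, 3, 30, 34)),
    ("e19", "g06", "protein_coding", (4, 5, 19, 20)),     # ratio exactly 4: dropped
    ("e20", "g06", "protein_coding", (19, 20, 4, 5)),     # ratio exactly 1/4: dropped
    ("e21", "g07", "rRNA", (100, 100, 100, 100)),         # biotype-filtered out
    ("e22", "g07", "rRNA", (2, 2, 200, 200)),             # would be differential if kept
    ("e23", "g08", "miRNA", (50, 50, 1, 1)),
    ("e24", "g08", "miRNA", (3, 3, 3, 3)),
    ("e25", "g09", "pseudogene", (1, 1, 30, 30)),
    ("e26", "g09", "pseudogene", (0, 0, 0, 0)),
    ("e27", "g10", "lincRNA", (30, 30, 25, 25)),
    ("e28", "g10", "lincRNA", (8, 8, 9, 9)),
    ("e29", "g10", "lincRNA", (1, 1, 1, 2)),
    ("e30", "g11", "protein_coding", (40, 40, 1, 1)),
    ("e31", "g11", "protein_coding", (25, 35, 2, 2)),
    ("e32", "g11", "protein_coding", (9, 9, 9, 9)),
    ("e33", "g11", "protein_coding", (6, 8, 0, 0)),
    ("e34", "g11", "protein_coding", (0, 0, 3, 3)),
    ("e35", "g12", "protein_coding", (2, 2, 2, 2)),
    ("e36", "g12", "protein_coding", (12, 12, 70, 74)),
    ("e37", "g12", "protein_coding", (18, 22, 20, 20)),
    ("e38", "g12", "protein_coding", (0, 0, 8, 8)),
    ("e39", "g12", "protein_coding", (5, 5, 5, 5)),       # RPKM exactly 10: dropped
    ("e40", "g12", "protein_coding", (60, 60, 10, 14)),
]

HAND_SAMPLES = ["mef_1", "mef_2", "mel_1", "mel_2"]
HAND_GROUPS = ["source", "source", "target", "target"]
HAND_LIBSIZES = {s: 1_000_000.0 for s in HAND_SAMPLES}

# Hand-enumerated expectations (RPKM = 2 x count, pseudocount 1, fc 4):
EXPECTED_BIOTYPE_KEPT = 36
EXPECTED_EXPRESSED = [
    "e01", "e02", "e03", "e04", "e05", "e06", "e07", "e08", "e09", "e10", "e11",
    "e15", "e16", "e18", "e19", "e20", "e25", "e27", "e28", "e30", "e31", "e32",
    "e33", "e36", "e37", "e38", "e40",
]
EXPECTED_EXPRESSED_GENES = ["g01", "g02", "g03", "g05", "g06", "g09", "g10", "g11", "g12"]
EXPECTED_DIFFERENTIAL = [
    "e01", "e02", "e03", "e04", "e05", "e06", "e07", "e15", "e18", "e25",
    "e30", "e31", "e33", "e36", "e38", "e40",
]
EXPECTED_DIFFERENTIAL_GENES = ["g01", "g02", "g05", "g09", "g11", "g12"]


@pytest.fixture
def hand_ecm() -> ExonCountMatrix:
    exon_ids = pd.Index([row[0] for row in HAND_TABLE], name="exon_id")
    exons = pd.DataFrame(
        {
            "gene_id": [row[1] for row in HAND_TABLE],
            "chrom": "chr1",
            "start": np.arange(len(HAND_TABLE)) * 1000,
            "end": np.arange(len(HAND_TABLE)) * 1000 + 500,
            "length": 500,
            "biotype": [row[2] for row in HAND_TABLE],
        },
        index=exon_ids,
    )
    counts = pd.DataFrame(
        [row[3] for row in HAND_TABLE], index=exon_ids, columns=HAND_SAMPLES
    ).astype(np.int64)
    groups = pd.Series(HAND_GROUPS, index=HAND_SAMPLES, name="group")
    return ExonCountMatrix(exons=exons, counts=counts, groups=groups)


def make_regions(name: str, triples, labels=None) -> RegionSet:
    """Build a RegionSet from (chrom, start, end) triples."""
    ivs = [
        GenomicInterval(c, s, e, label=(labels[i] if labels else None))
        for i, (c, s, e) in enumerate(triples)
    ]
    return RegionSet(name, ivs)


def random_regions(rng, n, name="set", chroms=("chr1", "chr2"), span=100_000, max_len=5_000):
    """Random interval set for brute-force comparison tests."""
    ivs = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, start + length, label=f"{name}_{i}"))
    return RegionSet(name, ivs)
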