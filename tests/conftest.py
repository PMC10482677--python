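"""Shared fixtures: hand-built gene models, sites with known classifications,
and an independent brute-force read-placement oracle."""

from __future__ import annotations

import numpy as np
import pytest

from trapscreen.annotation import (
    EXON,
    FIVE_PRIME_UTR,
    INTRON,
    THREE_PRIME_UTR,
    GeneModel,
)
from trapscreen.mapping import InsertionSite, reverse_complement


@pytest.fixture(scope="session")
def three_gene_models() -> list[GeneModel]:
    """Three genes on two chromosomes, both strands, all region kinds."""
    gene_a = GeneModel(
        gene_id="geneA", chromosome="chr1", strand="+", start=100, end=200,
        regions=(
            (100, 110, FIVE_PRIME_UTR),
            (110, 140, EXON),
            (140, 160, INTRON),
            (160, 190, EXON),
            (190, 200, THREE_PRIME_UTR),
        ),
    )
    gene_b = GeneModel(  # minus strand: 3' UTR leftmost in genomic coordinates
        gene_id="geneB", chromosome="chr1", strand="-", start=300, end=400,
        regions=(
            (300, 310, THREE_PRIME_UTR),
            (310, 350, EXON),
            (350, 370, INTRON),
            (370, 390, EXON),
            (390, 400, FIVE_PRIME_UTR),
        ),
    )
    gene_c = GeneModel(
        gene_id="geneC", chromosome="chr2", strand="+", start=50, end=120,
        regions=((50, 60, FIVE_PRIME_UTR), (60, 110, EXON), (110, 120, THREE_PRIME_UTR)),
    )
    return [gene_a, gene_b, gene_c]


@pytest.fixture(scope="session")
def twelve_sites() -> tuple[list[InsertionSite], list[InsertionSite]]:
    """Twelve sites whose classifications were enumerated by hand.

    High: disruptive geneA x2, geneB x1, geneC x1 (H = 4), plus a 3' UTR
    sense hit, two antisense hits and an intergenic site.
    Low: disruptive geneA x1 and geneC x1 (L = 2), plus antisense hits.
    """
    high = [
        InsertionSite("chr1", 120, "forward", "high"),   # geneA exon, sense -> disruptive
        InsertionSite("chr1", 145, "forward", "high"),   # geneA intron, sense -> disruptive
        InsertionSite("chr1", 105, "reverse", "high"),   # geneA 5'UTR, antisense
        InsertionSite("chr1", 195, "forward", "high"),   # geneA 3'UTR, sense -> NOT disruptive
        InsertionSite("chr1", 320, "reverse", "high"),   # geneB exon, sense -> disruptive
        InsertionSite("chr1", 305, "reverse", "high"),   # geneB 3'UTR, sense -> NOT disruptive
        InsertionSite("chr2", 70, "forward", "high"),    # geneC exon, sense -> disruptive
        InsertionSite("chr1", 250, "forward", "high"),   # intergenic
    ]
    low = [
        InsertionSite("chr1", 130, "forward", "low"),    # geneA exon, sense -> disruptive
        InsertionSite("chr1", 375, "forward", "low"),    # geneB exon, antisense
        InsertionSite("chr2", 55, "forward", "low"),     # geneC 5'UTR, sense -> disruptive
        InsertionSite("chr2", 115, "reverse", "low"),    # geneC 3'UTR, antisense
    ]
    return high, low


def naive_map_oracle(read: str, reference: dict[str, str], max_mismatches: int = 1):
    """All-positions Hamming scan over both strands (vectorized but literal).

    Returns (status, chrom, pos, orient, d) with status in
    {"unique", "ambiguous", "unmapped"}.
    """
    best: list[tuple[str, int, str]] = []
    best_d = max_mismatches + 1
    L = len(read)
    for chrom, seq in reference.items():
        if L > len(seq):
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        for orient, query in (("forward", read), ("reverse", reverse_complement(read))):
            q = np.frombuffer(query.encode(), dtype=np.uint8)
            d = ((windows != q) | (q == ord("N"))).sum(axis=1)
            for pos in np.flatnonzero(d <= max_mismatches):
                dd = int(d[pos])
                if dd < best_d:
                    best_d = dd
                    best = [(chrom, int(pos), orient)]
                elif dd == best_d:
                    best.append((chrom, int(pos), orient))
    if not best:
        return ("unmapped", None, None, None, None)
    if len(best) > 1:
        return ("ambiguous", None, None, None, best_d)
    chrom, pos, orient = best[0]
    return ("unique", chrom, pos, orient, best_d)
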