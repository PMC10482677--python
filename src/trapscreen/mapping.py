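"""One-mismatch read mapping and unique insertion-site collapsing.

Gene-trap junction reads are placed on the reference by exact matching that
tolerates at most one substitution (Hamming distance; no indels).  A read is
reported only when a single placement achieves the minimal distance among all
placements within the tolerance; ties are discarded as ambiguous, reads with
no placement within tolerance are unmapped.  The search relies on the
pigeonhole principle: a placement with at most one mismatch must match one
half of the read exactly, so candidate loci are found by exact substring
search of each half on both strands and verified by full Hamming distance.

The reported position is the 0-based coordinate of the leftmost reference
base of the matched window on the forward strand, for both orientations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MapStatus(Enum):
    UNIQUE = "unique"
    AMBIGUOUS = "ambiguous"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class InsertionSite:
    """A unique mapped gene-trap integration.

    ``position`` is the 0-based forward-strand coordinate of the integration
    window's leftmost base; ``orientation`` is the strand the cassette
    integrated on ("forward"/"reverse"); ``support`` counts the reads that
    collapsed into this site.
    """

    chromosome: str
    position: int
    orientation: str
    population: str = ""
    support: int = 1

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be 'forward' or 'reverse', got {self.orientation!r}")
        if self.position < 0:
            raise ValueError(f"negative position {self.position}")
        if self.support < 1:
            raise ValueError(f"support must be >= 1, got {self.support}")


@dataclass(frozen=True)
class MappingResult:
    status: MapStatus
    chromosome: str | None = None
    position: int | None = None
    orientation: str | None = None
    mismatches: int | None = None


def _hamming_leq(a: str, b: str, limit: int) -> int | None:
    """Hamming distance of equal-length strings, or None when it exceeds limit.

    'N' never matches anything, including another 'N'.
    """
    d = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            d += 1
            if d > limit:
                return None
    return d


def _find_all(haystack: str, needle: str, start_offset: int) -> Iterable[int]:
    """Candidate window starts such that `needle` occurs at window+offset."""
    if not needle or "N" in needle:
        return
    i = haystack.find(needle)
    while i != -1:
        yield i - start_offset
        i = haystack.find(needle, i + 1)


def map_read(
    read: str,
    reference: Mapping[str, str],
    max_mismatches: int = 1,
) -> MappingResult:
    """Place a read on the reference tolerating ``max_mismatches`` substitutions.

    Parameters
    ----------
    read:
        Read sequence over A/C/G/T/N ('N' counts as a mismatch everywhere).
    reference:
        Mapping of chromosome name to forward-strand sequence (e.g.
        ``ToyGenome.chromosomes``).
    max_mismatches:
        Maximum tolerated Hamming distance (default one mismatch).

    Returns a :class:`MappingResult`: the unique minimal-distance placement,
    ``AMBIGUOUS`` when two or more placements tie at the minimal distance, or
    ``UNMAPPED`` when no placement is within tolerance (including reads longer
    than every chromosome).
    """
    read = read.upper()
    if not read:
        raise ValueError("empty read")
    if set(read) - set("ACGTN"):
        raise ValueError(f"read contains characters outside A/C/G/T/N: {read!r}")
    L = len(read)
    # pigeonhole halves require each half to be informative; tiny reads and
    # looser tolerances use the plain scan
    if max_mismatches > 1 or L < 2 * (max_mismatches + 1) or L < 8:
        return _map_read_scan(read, reference, max_mismatches)

    half = L // 2
    rc = reverse_complement(read)
    # (query, orientation): the forward-strand window must match `query`
    candidates: set[tuple[str, int, str]] = set()
    for query, orient in ((read, "forward"), (rc, "reverse")):
        parts = ((query[:half], 0), (query[half:], half))
        for chrom, seq in reference.items():
            if L > len(seq):
                continue
            for part, off in parts:
                for pos in _find_all(seq, part, off):
                    if 0 <= pos <= len(seq) - L:
                        candidates.add((chrom, pos, orient))
    return _resolve(read, rc, reference, candidates, max_mismatches)


def _map_read_scan(read: str, reference: Mapping[str, str], max_mismatches: int) -> MappingResult:
    # fallback for tolerances above one mismatch: full scan
    L = len(read)
    rc = reverse_complement(read)
    candidates = {
        (chrom, pos, orient)
        for chrom, seq in reference.items()
        if L <= len(seq)
        for pos in range(len(seq) - L + 1)
        for orient in ("forward", "reverse")
    }
    return _resolve(read, rc, reference, candidates, max_mismatches)


def _resolve(
    read: str,
    rc: str,
    reference: Mapping[str, str],
    candidates: Iterable[tuple[str, int, str]],
    max_mismatches: int,
) -> MappingResult:
    L = len(read)
    best: list[tuple[str, int, str]] = []
    best_d = max_mismatches + 1
    for chrom, pos, orient in candidates:
        window = reference[chrom][pos : pos + L]
        query = read if orient == "forward" else rc
        d = _hamming_leq(query, window, max_mismatches)
        if d is None:
            continue
        if d < best_d:
            best_d = d
            best = [(chrom, pos, orient)]
        elif d == best_d:
            best.append((chrom, pos, orient))
    if not best:
        return MappingResult(MapStatus.UNMAPPED)
    if len(best) > 1:
        return MappingResult(MapStatus.AMBIGUOUS, mismatches=best_d)
    chrom, pos, orient = best[0]
    return MappingResult(MapStatus.UNIQUE, chrom, pos, orient, best_d)


def collapse_sites(
    mappings: Iterable[MappingResult | tuple[str, int, str]],
    population: str,
) -> list[InsertionSite]:
    """Collapse unique read placements to unique insertion sites.

    Groups by (chromosome, position, orientation); ``support`` is the group
    size.  Idempotent and order-independent; output sorted by coordinate.
    """
    counter: Counter[tuple[str, int, str]] = Counter()
    for m in mappings:
        if isinstance(m, MappingResult):
            if m.status is not MapStatus.UNIQUE:
                raise ValueError("collapse_sites expects unique mappings only")
            key = (m.chromosome, m.position, m.orientation)
        else:
            key = tuple(m)  # type: ignore[assignment]
        counter[key] += 1
    return [
        InsertionSite(chromosome=c, position=p, orientation=o, population=population, support=n)
        for (c, p, o), n in sorted(counter.items())
    ]


@dataclass(frozen=True)
class MappingReport:
    """Per-population tally of read fates."""

    n_reads: int
    n_unique: int
    n_ambiguous: int
    n_unmapped: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_reads": self.n_reads,
            "n_unique": self.n_unique,
            "n_ambiguous": self.n_ambiguous,
            "n_unmapped": self.n_unmapped,
        }


def map_reads(
    reads: Iterable[tuple[str, str]],
    reference: Mapping[str, str],
    population: str,
    max_mismatches: int = 1,
) -> tuple[list[InsertionSite], MappingReport]:
    """Map (name, sequence) reads and collapse to unique sites."""
    unique: list[MappingResult] = []
    n = amb = unm = 0
    for _, seq in reads:
        res = map_read(seq, reference, max_mismatches=max_mismatches)
        n += 1
        if res.status is MapStatus.UNIQUE:
            unique.append(res)
        elif res.status is MapStatus.AMBIGUOUS:
            amb += 1
        else:
            unm += 1
    sites = collapse_sites(unique, population)
    return sites, MappingReport(n, len(unique), amb, unm)
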