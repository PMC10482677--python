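"""Gene models and insertion-site classification.

A gene-trap cassette disrupts a gene only when it integrates in the *sense*
orientation (cassette strand equals the gene's transcriptional strand) within
the gene body, where the gene body is the union of the 5' UTR, exons and
introns.  Integrations in the 3' UTR are annotated but never counted as
disruptive, and antisense or intergenic integrations are carried through the
bookkeeping with zero weight.

Coordinates are 0-based half-open throughout; GTF input (1-based inclusive)
is converted on read.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .mapping import InsertionSite

logger = logging.getLogger(__name__)

FIVE_PRIME_UTR = "five_prime_utr"
EXON = "exon"
INTRON = "intron"
THREE_PRIME_UTR = "three_prime_utr"
REGION_KINDS = (FIVE_PRIME_UTR, EXON, INTRON, THREE_PRIME_UTR)

#: region kinds whose sense disruption inactivates the gene
DISRUPTIVE_REGIONS = frozenset({FIVE_PRIME_UTR, EXON, INTRON})


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene body tiled by UTR/exon/intron regions.

    ``regions`` are ``(start, end, kind)`` triples in 0-based half-open
    coordinates; they must be disjoint and their union must equal
    ``[start, end)``.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    regions: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.gene_id}: empty or negative gene body [{self.start}, {self.end})")
        regions = sorted(self.regions)
        if not regions:
            raise ValueError(f"{self.gene_id}: gene has no regions")
        cursor = self.start
        for rs, re_, kind in regions:
            if kind not in REGION_KINDS:
                raise ValueError(f"{self.gene_id}: unknown region kind {kind!r}")
            if rs != cursor or re_ <= rs:
                raise ValueError(
                    f"{self.gene_id}: regions must tile the gene body without gaps or overlap "
                    f"(expected region start {cursor}, got [{rs}, {re_}))"
                )
            cursor = re_
        if cursor != self.end:
            raise ValueError(f"{self.gene_id}: regions end at {cursor}, gene body ends at {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def region_at(self, position: int) -> str | None:
        """Region kind containing ``position``, or None when outside the body."""
        if not self.start <= position < self.end:
            return None
        starts = [r[0] for r in sorted(self.regions)]
        regs = sorted(self.regions)
        i = bisect_right(starts, position) - 1
        return regs[i][2]


@dataclass(frozen=True)
class GeneHit:
    """One gene overlapped by a site: region kind, sense and disruptive flags."""

    gene_id: str
    region: str
    sense: bool
    disruptive: bool


@dataclass(frozen=True)
class SiteAnnotation:
    """An insertion site with its per-gene classifications (empty = intergenic)."""

    site: InsertionSite
    hits: tuple[GeneHit, ...] = field(default_factory=tuple)

    @property
    def intergenic(self) -> bool:
        return not self.hits

    @property
    def disruptive_genes(self) -> tuple[str, ...]:
        return tuple(h.gene_id for h in self.hits if h.disruptive)


def _orientation_to_strand(orientation: str) -> str:
    return {"forward": "+", "+": "+", "reverse": "-", "-": "-"}[orientation]


def classify_sites(
    sites: Iterable[InsertionSite], models: Sequence[GeneModel]
) -> list[SiteAnnotation]:
    """Classify each site against every overlapping gene body.

    Containment is half-open on the site's single integration coordinate.
    A hit is *sense* when the cassette orientation equals the gene strand and
    *disruptive* when additionally the region is a 5' UTR, exon or intron.
    Sites on chromosomes absent from the annotation are classified intergenic
    with a logged warning.
    """
    trees: dict[str, IntervalTree] = {}
    for m in models:
        trees.setdefault(m.chromosome, IntervalTree()).addi(m.start, m.end, m)

    out: list[SiteAnnotation] = []
    missing_chroms: set[str] = set()
    for site in sites:
        tree = trees.get(site.chromosome)
        if tree is None:
            if site.chromosome not in missing_chroms:
                missing_chroms.add(site.chromosome)
                logger.warning(
                    "chromosome %r absent from annotation; its sites are classified intergenic",
                    site.chromosome,
                )
            out.append(SiteAnnotation(site=site, hits=()))
            continue
        hits = []
        for iv in sorted(tree[site.position], key=lambda iv: iv.data.gene_id):
            gene: GeneModel = iv.data
            region = gene.region_at(site.position)
            assert region is not None
            sense = _orientation_to_strand(site.orientation) == gene.strand
            disruptive = sense and region in DISRUPTIVE_REGIONS
            hits.append(GeneHit(gene.gene_id, region, sense, disruptive))
        out.append(SiteAnnotation(site=site, hits=tuple(hits)))
    return out


def _check_single_population(annotations: Sequence[SiteAnnotation], which: str) -> None:
    labels = {a.site.population for a in annotations}
    if len(labels) > 1:
        raise ValueError(f"mixed population labels {sorted(labels)} in the {which} input")


def tabulate_counts(
    annotations_high: Sequence[SiteAnnotation],
    annotations_low: Sequence[SiteAnnotation],
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build the per-gene 2x2 count table underlying MI and Fisher's test.

    For each gene ``a`` (``b``) is the number of unique disruptive sites in
    the high (low) population; ``H`` (``L``) is the total number of unique
    disruptive sites across all genes.  A site disruptive for k overlapping
    genes contributes k to the per-gene tallies but exactly 1 to the total,
    so with disjoint gene models sum(a) == H holds.  Genes with a == b == 0
    are retained when listed in ``gene_ids``.
    """
    _check_single_population(annotations_high, "high")
    _check_single_population(annotations_low, "low")

    universe: list[str] = list(gene_ids) if gene_ids is not None else []
    seen = set(universe)

    def tally(annotations: Sequence[SiteAnnotation]) -> tuple[dict[str, int], int]:
        per_gene: dict[str, int] = {}
        total = 0
        for ann in annotations:
            genes = ann.disruptive_genes
            if genes:
                total += 1
            for g in genes:
                per_gene[g] = per_gene.get(g, 0) + 1
                if g not in seen:
                    seen.add(g)
                    universe.append(g)
        return per_gene, total

    a_counts, H = tally(annotations_high)
    b_counts, L = tally(annotations_low)
    rows = [
        {"gene_id": g, "a": a_counts.get(g, 0), "b": b_counts.get(g, 0), "H": H, "L": L}
        for g in universe
    ]
    return pd.DataFrame(rows, columns=["gene_id", "a", "b", "H", "L"])


# ---------------------------------------------------------------------------
# annotation I/O

_GTF_KIND = {
    "five_prime_utr": FIVE_PRIME_UTR,
    "exon": EXON,
    "intron": INTRON,
    "three_prime_utr": THREE_PRIME_UTR,
}


def write_gtf(models: Sequence[GeneModel], path) -> None:
    """Write gene models as GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}";'
            fh.write(
                "\t".join(
                    [m.chromosome, "trapscreen", "gene", str(m.start + 1), str(m.end), ".", m.strand, ".", attrs]
                )
                + "\n"
            )
            for rs, re_, kind in sorted(m.regions):
                fh.write(
                    "\t".join(
                        [m.chromosome, "trapscreen", kind, str(rs + 1), str(re_), ".", m.strand, ".", attrs]
                    )
                    + "\n"
                )


def read_gtf(path) -> list[GeneModel]:
    """Read gene models from a GTF written by :func:`write_gtf` (or alike)."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            gid = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gid = part.split(None, 1)[1].strip('"')
            if gid is None:
                raise ValueError(f"{path}: line {lineno}: missing gene_id attribute")
            rec = genes.setdefault(gid, {"chromosome": chrom, "strand": strand, "regions": [], "body": None})
            s0, e0 = int(start) - 1, int(end)  # GTF 1-based inclusive -> half-open
            if feature == "gene":
                rec["body"] = (s0, e0)
            elif feature in _GTF_KIND:
                rec["regions"].append((s0, e0, _GTF_KIND[feature]))
    models = []
    for gid, rec in genes.items():
        if rec["body"] is None:
            regions = sorted(rec["regions"])
            rec["body"] = (regions[0][0], regions[-1][1])
        models.append(
            GeneModel(
                gene_id=gid,
                chromosome=rec["chromosome"],
                strand=rec["strand"],
                start=rec["body"][0],
                end=rec["body"][1],
                regions=tuple(sorted(rec["regions"])),
            )
        )
    models.sort(key=lambda m: (m.chromosome, m.start))
    return models


def write_annotation_tsv(models: Sequence[GeneModel], path) -> None:
    """Simplified 0-based half-open region table (one row per region)."""
    rows = []
    for m in models:
        for rs, re_, kind in sorted(m.regions):
            rows.append(
                {"gene_id": m.gene_id, "chromosome": m.chromosome, "strand": m.strand,
                 "start": rs, "end": re_, "kind": kind}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    models = []
    for (gid,), grp in df.groupby(["gene_id"], sort=True):
        grp = grp.sort_values("start")
        regions = tuple((int(r.start), int(r.end), str(r.kind)) for r in grp.itertuples())
        models.append(
            GeneModel(
                gene_id=str(gid),
                chromosome=str(grp.iloc[0]["chromosome"]),
                strand=str(grp.iloc[0]["strand"]),
                start=int(grp["start"].min()),
                end=int(grp["end"].max()),
                regions=regions,
            )
        )
    models.sort(key=lambda m: (m.chromosome, m.start))
    return models


def write_site_annotations(annotations: Sequence[SiteAnnotation], path) -> None:
    rows = []
    for ann in annotations:
        s = ann.site
        if not ann.hits:
            rows.append(
                {"chromosome": s.chromosome, "position": s.position, "orientation": s.orientation,
                 "population": s.population, "gene_id": ".", "region": ".", "sense": ".", "disruptive": "."}
            )
        for h in ann.hits:
            rows.append(
                {"chromosome": s.chromosome, "position": s.position, "orientation": s.orientation,
                 "population": s.population, "gene_id": h.gene_id, "region": h.region,
                 "sense": int(h.sense), "disruptive": int(h.disruptive)}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
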