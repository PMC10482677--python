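"""Synthetic phenotype-sorted gene-trap screens.

This module generates every input the screen analysis consumes — a toy
reference genome with stranded gene models, a mutagenized cell library, the
two FACS-sorted tail populations, and gene-trap junction reads — so that the
whole pipeline is testable without external data.

The generative model mirrors a haploid gene-trap screen read out by
fluorescence sorting: each cell carries exactly one insertion at a uniform
genomic position and random cassette orientation; a cell's fluorescence is a
Gaussian baseline plus an additive shift when (and only when) its insertion
disrupts a gene carrying a phenotype effect (sense orientation, inside the
gene body, outside the 3' UTR); cells are ranked by fluorescence and the top
and bottom tails (default 5%, as in a BODIPY-stained sort) become the "high"
and "low" populations, from which a fixed number of cells is sampled without
replacement and collapsed to unique insertion sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    EXON,
    FIVE_PRIME_UTR,
    INTRON,
    THREE_PRIME_UTR,
    GeneModel,
)
from .errors import ConfigurationError, CoordinateError, SimulationError
from .mapping import InsertionSite, reverse_complement

_MIN_GENE_LENGTH = 40


@dataclass(frozen=True)
class SortedScreenConfig:
    """Generative parameters of a synthetic sorted screen.

    Defaults emulate the statistical structure of a genome-wide haploid
    screen at desk scale: on the order of a hundred disruptive insertions
    per gene per sorted population, a 5% sorting tail, and even sense /
    antisense cassette orientations.
    """

    n_genes: int = 100
    genome_length: int = 400_000
    gene_length_range: tuple[int, int] = (1_500, 3_000)
    n_cells: int = 1_500_000
    tail_fraction: float = 0.05
    cells_sorted_per_tail: int = 70_000
    phenotype_noise_sd: float = 1.0
    gene_effects: Mapping[str, float] = field(default_factory=dict)
    intergenic_fraction: float | None = None
    orientation_prob_sense: float = 0.5
    read_length: int = 40
    mismatch_rate: tuple[float, float, float] = (1.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not 0.0 < self.tail_fraction < 0.5:
            raise ConfigurationError(
                f"tail_fraction must lie strictly between 0 and 0.5, got {self.tail_fraction}"
            )
        if self.cells_sorted_per_tail < 1:
            raise ConfigurationError("cells_sorted_per_tail must be >= 1")
        if self.cells_sorted_per_tail > self.tail_fraction * self.n_cells:
            raise ConfigurationError(
                f"cells_sorted_per_tail={self.cells_sorted_per_tail} exceeds the tail size "
                f"{self.tail_fraction} x {self.n_cells}"
            )
        lo, hi = self.gene_length_range
        if not _MIN_GENE_LENGTH <= lo <= hi:
            raise ConfigurationError(
                f"gene_length_range must satisfy {_MIN_GENE_LENGTH} <= lo <= hi, got {self.gene_length_range}"
            )
        if hi * self.n_genes > self.genome_length:
            raise ConfigurationError(
                f"{self.n_genes} genes of up to {hi} bases cannot fit in a "
                f"{self.genome_length}-base genome"
            )
        if not 0.0 <= self.orientation_prob_sense <= 1.0:
            raise ConfigurationError("orientation_prob_sense must be a probability")
        if self.intergenic_fraction is not None and not 0.0 <= self.intergenic_fraction < 1.0:
            raise ConfigurationError("intergenic_fraction must lie in [0, 1)")
        if self.phenotype_noise_sd <= 0:
            raise ConfigurationError("phenotype_noise_sd must be positive")
        if self.read_length < 1:
            raise ConfigurationError("read_length must be >= 1")
        if len(self.mismatch_rate) != 3 or any(p < 0 for p in self.mismatch_rate):
            raise ConfigurationError("mismatch_rate must be three non-negative probabilities")
        if abs(sum(self.mismatch_rate) - 1.0) > 1e-9:
            raise ConfigurationError("mismatch_rate probabilities must sum to 1")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in self.__dict__.items():
                if key == "gene_effects":
                    value = ",".join(f"{g}:{e}" for g, e in value.items())
                elif isinstance(value, tuple):
                    value = ",".join(str(v) for v in value)
                fh.write(f"{key} = {value}\n")

    @classmethod
    def from_file(cls, path) -> "SortedScreenConfig":
        kwargs: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key == "gene_effects":
                    effects = {}
                    for item in filter(None, value.split(",")):
                        g, _, e = item.partition(":")
                        effects[g.strip()] = float(e)
                    kwargs[key] = effects
                elif key == "gene_length_range":
                    lo, hi = value.split(",")
                    kwargs[key] = (int(lo), int(hi))
                elif key == "mismatch_rate":
                    kwargs[key] = tuple(float(v) for v in value.split(","))
                elif key == "intergenic_fraction":
                    kwargs[key] = None if value == "None" else float(value)
                elif key in ("tail_fraction", "phenotype_noise_sd", "orientation_prob_sense"):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = int(value)
        return cls(**kwargs)


@dataclass(frozen=True)
class ToyGenome:
    """A toy reference: chromosome sequences plus stranded gene models."""

    chromosomes: Mapping[str, str]
    annotation: tuple[GeneModel, ...]

    def chromosome_length(self, name: str) -> int:
        return len(self.chromosomes[name])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return alphabet[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _gene_regions(rng: np.random.Generator, start: int, end: int, strand: str):
    """Tile [start, end) with 5'UTR, exons, introns and 3'UTR in genomic order."""
    length = end - start
    utr5 = max(4, int(round(0.10 * length)))
    utr3 = max(4, int(round(0.10 * length)))
    inner = length - utr5 - utr3
    n_exons = int(rng.integers(1, 4))
    n_parts = 2 * n_exons - 1  # exons and introns alternate, exon first and last
    # random positive partition of the transcribed core
    cuts = np.sort(rng.choice(np.arange(1, inner), size=n_parts - 1, replace=False)) if n_parts > 1 else np.array([], dtype=int)
    sizes = np.diff(np.concatenate([[0], cuts, [inner]]))
    kinds = [EXON if i % 2 == 0 else INTRON for i in range(n_parts)]
    if strand == "+":
        ordered = [(utr5, FIVE_PRIME_UTR)] + list(zip(sizes, kinds)) + [(utr3, THREE_PRIME_UTR)]
    else:
        ordered = [(utr3, THREE_PRIME_UTR)] + list(zip(sizes, kinds)) + [(utr5, FIVE_PRIME_UTR)]
    regions = []
    cursor = start
    for size, kind in ordered:
        regions.append((cursor, cursor + int(size), kind))
        cursor += int(size)
    assert cursor == end
    return tuple(regions)


def build_toy_genome(config: SortedScreenConfig) -> ToyGenome:
    """Build a deterministic toy genome with disjoint stranded gene models.

    Genes are packed left to right on a single chromosome with random
    intergenic gaps; every gene has an explicit 5' UTR, at least one exon,
    and an explicit 3' UTR so the disruptive-region rule is exercised.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    total = int(lengths.sum())
    slack = config.genome_length - total
    if slack < 0:
        raise ConfigurationError(
            f"gene lengths total {total} bases but the genome is only {config.genome_length}"
        )
    # distribute the intergenic slack over n_genes + 1 gaps
    gap_cuts = np.sort(rng.integers(0, slack + 1, size=config.n_genes)) if slack > 0 else np.zeros(config.n_genes, dtype=int)
    gaps = np.diff(np.concatenate([[0], gap_cuts, [slack]]))
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")

    models = []
    cursor = 0
    width = len(str(config.n_genes - 1)) if config.n_genes > 1 else 1
    for i in range(config.n_genes):
        cursor += int(gaps[i])
        start, end = cursor, cursor + int(lengths[i])
        strand = str(strands[i])
        models.append(
            GeneModel(
                gene_id=f"gene{i:0{width}d}",
                chromosome="chr1",
                strand=strand,
                start=start,
                end=end,
                regions=_gene_regions(rng, start, end, strand),
            )
        )
        cursor = end
    sequence = _random_sequence(rng, config.genome_length)
    return ToyGenome(chromosomes={"chr1": sequence}, annotation=tuple(models))


def _genome_masks(genome: ToyGenome, chrom: str):
    """Per-base gene index (-1 intergenic), disruptive-region and strand arrays."""
    n = genome.chromosome_length(chrom)
    gene_index = np.full(n, -1, dtype=np.int32)
    disruptive = np.zeros(n, dtype=bool)
    strand = np.zeros(n, dtype=np.int8)  # +1 forward, -1 reverse, 0 intergenic
    gene_ids = []
    for gi, m in enumerate(g for g in genome.annotation if g.chromosome == chrom):
        gene_ids.append(m.gene_id)
        gene_index[m.start : m.end] = gi
        strand[m.start : m.end] = 1 if m.strand == "+" else -1
        for rs, re_, kind in m.regions:
            if kind != THREE_PRIME_UTR:
                disruptive[rs:re_] = True
    return gene_index, disruptive, strand, gene_ids


def simulate_sorted_screen(
    genome: ToyGenome, config: SortedScreenConfig
) -> tuple[list[InsertionSite], list[InsertionSite], pd.DataFrame]:
    """Simulate mutagenesis, fluorescence sorting and tail recovery.

    Returns the deduplicated insertion sites recovered from the high and low
    tails and a truth table (gene_id, effect, sign) recording which genes
    carry nonzero phenotype effects.
    """
    if len(genome.chromosomes) != 1:
        raise SimulationError("the simulator currently expects a single-chromosome toy genome")
    chrom = next(iter(genome.chromosomes))
    n = genome.chromosome_length(chrom)
    rng = np.random.default_rng(config.seed)

    gene_index, disruptive_base, strand, gene_ids = _genome_masks(genome, chrom)
    unknown = set(config.gene_effects) - set(gene_ids)
    if unknown:
        raise ConfigurationError(f"gene_effects name genes absent from the genome: {sorted(unknown)}")
    effect_by_gene = np.zeros(len(gene_ids))
    for g, e in config.gene_effects.items():
        effect_by_gene[gene_ids.index(g)] = e

    # one insertion per cell: uniform position (optionally stratified by the
    # configured intergenic fraction), orientation sense with the configured
    # probability inside genes
    if config.intergenic_fraction is None:
        positions = rng.integers(0, n, size=config.n_cells)
    else:
        genic_pos = np.flatnonzero(gene_index >= 0)
        inter_pos = np.flatnonzero(gene_index < 0)
        if inter_pos.size == 0 or genic_pos.size == 0:
            raise SimulationError("stratified sampling requires both genic and intergenic bases")
        in_gene = rng.random(config.n_cells) >= config.intergenic_fraction
        positions = np.where(
            in_gene,
            genic_pos[rng.integers(0, genic_pos.size, size=config.n_cells)],
            inter_pos[rng.integers(0, inter_pos.size, size=config.n_cells)],
        )
    site_strand = strand[positions]
    sense_draw = rng.random(config.n_cells) < config.orientation_prob_sense
    # forward orientation encoded as +1; intergenic insertions are forward
    # with probability 1/2 irrespective of orientation_prob_sense
    coin = rng.random(config.n_cells) < 0.5
    orient = np.where(
        site_strand != 0,
        np.where(sense_draw, site_strand, -site_strand),
        np.where(coin, 1, -1),
    ).astype(np.int8)

    disrupts = (gene_index[positions] >= 0) & disruptive_base[positions] & (orient == site_strand)
    shift = np.where(disrupts, effect_by_gene[np.where(disrupts, gene_index[positions], 0)], 0.0)
    phenotype = shift + rng.normal(0.0, config.phenotype_noise_sd, size=config.n_cells)

    tail_n = int(config.tail_fraction * config.n_cells)
    if tail_n < 1:
        raise SimulationError("tail is empty: tail_fraction x n_cells < 1")
    order = np.argpartition(phenotype, (tail_n - 1, config.n_cells - tail_n))
    low_pool = order[:tail_n]
    high_pool = order[config.n_cells - tail_n :]

    def recover(pool: np.ndarray, label: str) -> list[InsertionSite]:
        chosen = rng.choice(pool, size=config.cells_sorted_per_tail, replace=False)
        pos = positions[chosen]
        ori = orient[chosen]
        key = pos.astype(np.int64) * 2 + (ori > 0)
        uniq, counts = np.unique(key, return_counts=True)
        return [
            InsertionSite(
                chromosome=chrom,
                position=int(k >> 1),
                orientation="forward" if (k & 1) else "reverse",
                population=label,
                support=int(c),
            )
            for k, c in zip(uniq, counts)
        ]

    high = recover(high_pool, "high")
    low = recover(low_pool, "low")
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "effect": effect_by_gene,
            "sign": np.sign(effect_by_gene).astype(int),
        }
    )
    return high, low, truth


def emit_junction_reads(
    sites: Sequence[InsertionSite],
    genome: ToyGenome,
    config: SortedScreenConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Emit one junction read per site as (name, sequence) records.

    The read covers ``read_length`` bases starting at the site position on
    the forward strand; reverse-orientation reads are the reverse complement
    of that window.  0, 1 or 2 substitutions are injected with the configured
    probabilities, and the read name encodes the true site and the injected
    mismatch count for round-trip checks
    (``read<i>|<chrom>|<position>|<orientation>|<n_mismatches>``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.read_length
    reads = []
    bases = "ACGT"
    for i, site in enumerate(sites):
        seq = genome.chromosomes[site.chromosome]
        if L > len(seq):
            raise CoordinateError(f"read_length {L} exceeds chromosome {site.chromosome}")
        if not 0 <= site.position <= len(seq) - L:
            raise CoordinateError(
                f"site {site.chromosome}:{site.position} leaves no room for a {L}-base read"
            )
        window = seq[site.position : site.position + L]
        read = window if site.orientation == "forward" else reverse_complement(window)
        k = int(rng.choice(3, p=config.mismatch_rate))
        if k:
            read_arr = list(read)
            for j in rng.choice(L, size=k, replace=False):
                alternatives = [b for b in bases if b != read_arr[j]]
                read_arr[int(j)] = alternatives[int(rng.integers(0, 3))]
            read = "".join(read_arr)
        name = f"read{i}|{site.chromosome}|{site.position}|{site.orientation}|{k}"
        reads.append((name, read))
    return reads
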