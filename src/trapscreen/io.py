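"""Readers and writers for the plain-text interchange formats.

FASTA and FASTQ go through Biopython; insertion sites travel as BED6 with
``name`` = population, ``score`` = 0 and ``strand`` = cassette orientation.
All tables are tab-separated.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .mapping import InsertionSite

_STRAND = {"forward": "+", "reverse": "-"}
_ORIENTATION = {"+": "forward", "-": "reverse"}


def write_fasta(chromosomes, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in chromosomes.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    records = []
    for name, seq in reads:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fastq")]


def write_bed(sites: Sequence[InsertionSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chromosome}\t{s.position}\t{s.position + 1}\t{s.population}\t0\t{_STRAND[s.orientation]}\n"
            )


def read_bed(path) -> list[InsertionSite]:
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise InputError(f"{path}: line {lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise InputError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end_i != start_i + 1:
                raise InputError(
                    f"{path}: line {lineno}: insertion sites are single-base intervals"
                )
            if strand not in _ORIENTATION:
                raise InputError(f"{path}: line {lineno}: strand must be '+' or '-'")
            sites.append(
                InsertionSite(
                    chromosome=chrom,
                    position=start_i,
                    orientation=_ORIENTATION[strand],
                    population=name,
                )
            )
    return sites
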