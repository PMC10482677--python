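"""The synthetic sorted-screen generator: determinism, structure, recovery."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from trapscreen.annotation import (
    EXON,
    FIVE_PRIME_UTR,
    THREE_PRIME_UTR,
    classify_sites,
    tabulate_counts,
)
from trapscreen.errors import ConfigurationError, CoordinateError
from trapscreen.io import read_fasta, write_fasta
from trapscreen.mapping import MapStatus, map_read
from trapscreen.stats import analyze_screen
from trapscreen.synthetic import (
    SortedScreenConfig,
    build_toy_genome,
    emit_junction_reads,
    simulate_sorted_screen,
)

SMALL = dict(
    n_genes=8,
    genome_length=60_000,
    gene_length_range=(1_500, 3_000),
    n_cells=60_000,
    cells_sorted_per_tail=2_500,
)


def small_config(**kw) -> SortedScreenConfig:
    return SortedScreenConfig(**{**SMALL, **kw})


class TestConfig:
    def test_degenerate_tail_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(tail_fraction=0.5, seed=0)

    def test_oversampled_tail_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(cells_sorted_per_tail=10_000, tail_fraction=0.05, seed=0)

    def test_incompatible_gene_lengths_rejected(self):
        with pytest.raises(ConfigurationError):
            SortedScreenConfig(n_genes=100, genome_length=10_000, gene_length_range=(1500, 3000), seed=0)

    def test_mismatch_rate_must_be_distribution(self):
        with pytest.raises(ConfigurationError):
            small_config(mismatch_rate=(0.5, 0.2, 0.2), seed=0)

    def test_file_round_trip(self, tmp_path):
        cfg = small_config(seed=11, gene_effects={"gene3": 4.5}, intergenic_fraction=0.3)
        path = tmp_path / "config.txt"
        cfg.to_file(path)
        assert SortedScreenConfig.from_file(path) == cfg


class TestBuildToyGenome:
    def test_single_gene_minimal(self):
        cfg = SortedScreenConfig(
            n_genes=1, genome_length=200, gene_length_range=(40, 60),
            n_cells=1000, cells_sorted_per_tail=10, seed=0,
        )
        genome = build_toy_genome(cfg)
        assert len(genome.annotation) == 1
        assert set(genome.chromosomes["chr1"]) <= set("ACGT")

    def test_deterministic_fasta_bytes(self, tmp_path):
        for i in (1, 2):
            genome = build_toy_genome(small_config(seed=7))
            write_fasta(genome.chromosomes, tmp_path / f"ref{i}.fa")
        assert (tmp_path / "ref1.fa").read_bytes() == (tmp_path / "ref2.fa").read_bytes()

    def test_fifty_genes_pairwise_disjoint(self):
        cfg = SortedScreenConfig(
            n_genes=50, genome_length=200_000, n_cells=10_000, cells_sorted_per_tail=400, seed=1
        )
        genes = build_toy_genome(cfg).annotation
        intervals = sorted((m.start, m.end) for m in genes)
        assert len(intervals) == 50
        # exhaustive pairwise overlap scan
        for (s1, e1) in intervals:
            for (s2, e2) in intervals:
                if (s1, e1) < (s2, e2):
                    assert e1 <= s2 or e2 <= s1

    def test_every_gene_has_utrs_and_exon(self):
        genes = build_toy_genome(small_config(seed=3)).annotation
        for m in genes:
            kinds = {k for _, _, k in m.regions}
            assert FIVE_PRIME_UTR in kinds and THREE_PRIME_UTR in kinds and EXON in kinds
            if m.strand == "+":
                assert sorted(m.regions)[0][2] == FIVE_PRIME_UTR
            else:
                assert sorted(m.regions)[0][2] == THREE_PRIME_UTR


class TestSimulateSortedScreen:
    def test_deterministic_for_fixed_seed(self):
        genome = build_toy_genome(small_config(seed=5))
        out1 = simulate_sorted_screen(genome, small_config(seed=5))
        out2 = simulate_sorted_screen(genome, small_config(seed=5))
        assert out1[0] == out2[0] and out1[1] == out2[1]

    def test_no_duplicate_sites_within_population(self):
        genome = build_toy_genome(small_config(seed=6))
        high, low, _ = simulate_sorted_screen(genome, small_config(seed=6))
        for pop in (high, low):
            keys = [(s.chromosome, s.position, s.orientation) for s in pop]
            assert len(keys) == len(set(keys))

    def test_truth_table_records_effects(self):
        cfg = small_config(seed=7, gene_effects={"gene2": 8.0, "gene5": -3.0})
        genome = build_toy_genome(cfg)
        _, _, truth = simulate_sorted_screen(genome, cfg)
        truth = truth.set_index("gene_id")
        assert truth.loc["gene2", "sign"] == 1
        assert truth.loc["gene5", "sign"] == -1
        assert (truth.drop(["gene2", "gene5"])["sign"] == 0).all()

    def test_unknown_effect_gene_rejected(self):
        cfg = small_config(seed=7, gene_effects={"nope": 1.0})
        genome = build_toy_genome(small_config(seed=7))
        with pytest.raises(ConfigurationError):
            simulate_sorted_screen(genome, cfg)

    def test_strong_positive_effect_enriches_high(self):
        """+8 SD phenotype shift drives sense insertions into the high tail."""
        cfg = small_config(seed=8, gene_effects={"gene4": 8.0})
        genome = build_toy_genome(cfg)
        high, low, _ = simulate_sorted_screen(genome, cfg)
        counts = tabulate_counts(
            classify_sites(high, genome.annotation),
            classify_sites(low, genome.annotation),
            gene_ids=[m.gene_id for m in genome.annotation],
        )
        res = analyze_screen(counts).set_index("gene_id")
        row = res.loc["gene4"]
        assert row["a"] + row["b"] >= 30
        assert row["mi"] > 1 and row["significant"]

    def test_intergenic_fraction_stratification(self):
        cfg = small_config(seed=9, intergenic_fraction=0.9)
        genome = build_toy_genome(cfg)
        high, low, _ = simulate_sorted_screen(genome, cfg)
        ann = classify_sites(high + low, genome.annotation)
        frac_intergenic = sum(a.intergenic for a in ann) / len(ann)
        assert frac_intergenic > 0.8


class TestEmitJunctionReads:
    def test_zero_mismatch_reads_are_exact_substrings(self):
        cfg = small_config(seed=10)
        genome = build_toy_genome(cfg)
        high, _, _ = simulate_sorted_screen(genome, cfg)
        sites = [s for s in high if s.position <= cfg.genome_length - cfg.read_length][:50]
        seq = genome.chromosomes["chr1"]
        from trapscreen.mapping import reverse_complement

        for name, read in emit_junction_reads(sites, genome, cfg):
            probe = read if name.split("|")[3] == "forward" else reverse_complement(read)
            assert probe in seq

    def test_single_substitution_round_trips_through_mapper(self):
        cfg = small_config(seed=11, mismatch_rate=(0.0, 1.0, 0.0))
        genome = build_toy_genome(cfg)
        high, _, _ = simulate_sorted_screen(genome, cfg)
        sites = [s for s in high if s.position <= cfg.genome_length - cfg.read_length][:40]
        for (name, read), site in zip(emit_junction_reads(sites, genome, cfg), sites):
            res = map_read(read, genome.chromosomes)
            assert res.status is MapStatus.UNIQUE
            assert (res.position, res.orientation) == (site.position, site.orientation)
            assert res.mismatches == 1

    def test_double_substitution_reads_never_map(self):
        cfg = small_config(seed=12, mismatch_rate=(0.0, 0.0, 1.0))
        genome = build_toy_genome(cfg)
        high, _, _ = simulate_sorted_screen(genome, cfg)
        sites = [s for s in high if s.position <= cfg.genome_length - cfg.read_length][:40]
        for name, read in emit_junction_reads(sites, genome, cfg):
            assert map_read(read, genome.chromosomes).status is MapStatus.UNMAPPED

    def test_site_without_room_for_read_rejected(self):
        cfg = small_config(seed=13)
        genome = build_toy_genome(cfg)
        from trapscreen.mapping import InsertionSite

        bad = InsertionSite("chr1", cfg.genome_length - 5, "forward", "high")
        with pytest.raises(CoordinateError):
            emit_junction_reads([bad], genome, cfg)

    def test_deterministic_reads_for_fixed_seed(self):
        cfg = small_config(seed=14, mismatch_rate=(0.6, 0.3, 0.1))
        genome = build_toy_genome(cfg)
        high, _, _ = simulate_sorted_screen(genome, cfg)
        sites = [s for s in high if s.position <= cfg.genome_length - cfg.read_length][:30]
        assert emit_junction_reads(sites, genome, cfg) == emit_junction_reads(sites, genome, cfg)
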