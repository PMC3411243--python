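from collections import Counter

import numpy as np
import pytest

from conect.datamodel import revcomp, transcript_database
from conect.masker import select_candidates, TranscriptMasker
from conect.simulate import (
    generate_genome_and_genes,
    paperlike_fixture,
    plant_novel_features,
    simulate_fragments,
    simulate_probe_panel,
    simulate_quant_reads,
)


class TestGenomeGenerator:
    def test_same_seed_reproduces_byte_identical_fixture(self):
        g1, genes1 = generate_genome_and_genes(seed=11)
        g2, genes2 = generate_genome_and_genes(seed=11)
        assert g1.sequences == g2.sequences
        assert [(g.gene_id, g.exons, g.transcripts) for g in genes1] == [
            (g.gene_id, g.exons, g.transcripts) for g in genes2
        ]

    def test_gene_count_matches_request(self):
        _, genes = generate_genome_and_genes(n_genes=25, seed=2)
        assert len(genes) == 25

    def test_all_annotated_introns_canonical_on_transcribed_strand(self):
        genome, genes = generate_genome_and_genes(seed=2)
        for g in genes:
            ex = g.exons_genomic
            for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
                intron = genome.fetch(g.chrom, e1, s2)
                if g.strand == "-":
                    intron = revcomp(intron)
                assert intron[:2] == "GT" and intron[-2:] == "AG"

    def test_capacity_exceeded_raises(self):
        with pytest.raises(ValueError, match="capacity"):
            generate_genome_and_genes(n_chrom=1, chrom_len=20_000, n_genes=50, seed=1)


class TestPlanting:
    def test_truth_table_has_k_rows_per_category(self, fixture17):
        counts = Counter(p.category for p in fixture17.truth.planted)
        assert len(counts) == 7
        assert all(v == 5 for v in counts.values())

    def test_extensions_share_a_boundary_novel_exons_do_not(self, fixture17):
        genes = {g.gene_id: g for g in fixture17.genes}
        for p in fixture17.truth.planted:
            if p.category == "gene_fusion":
                continue
            gene = genes[p.gene_ids[0]]
            (iv,) = p.intervals
            touches = any(e[1] == iv[0] or iv[1] == e[0] for e in gene.exons)
            if p.category.endswith("_extension"):
                assert touches
            else:
                assert not touches

    def test_planted_intron_splice_sites_are_canonical(self, fixture17):
        genome, genes = fixture17.genome, {g.gene_id: g for g in fixture17.genes}
        for p in fixture17.truth.planted:
            if not p.category.endswith("_novel_exon"):
                continue
            for left, right in zip(p.pieces, p.pieces[1:]):
                lo, hi = (left, right) if left[0] < right[0] else (right, left)
                intron = genome.fetch(p.chrom, lo[1], hi[0])
                if p.strand == "-":
                    intron = revcomp(intron)
                assert intron[:2] == "GT" and intron[-2:] == "AG"

    def test_novel_seed_kmers_are_collision_free(self):
        fx = paperlike_fixture(seed=9, chrom_len=120_000, n_genes=30, k_per_category=2, n_background=0)
        k = 16
        text = "".join(fx.genome.sequences[c] for c in fx.genome.chrom_names)
        for p in fx.truth.planted:
            if p.category == "gene_fusion":
                continue
            (iv,) = p.intervals
            sub = fx.genome.fetch(p.chrom, iv[0], iv[1])
            for i in range(len(sub) - k + 1):
                kmer = sub[i : i + k]
                assert text.count(kmer) == 1
                assert text.count(revcomp(kmer)) == 0


class TestFragments:
    def test_fixed_seed_reproduces_identical_fragments(self, fixture17):
        again = simulate_fragments(
            fixture17.genome, fixture17.genes, fixture17.truth,
            n_background=60, seed=17,
        )
        assert [(f.fragment_id, f.sequence) for f in again] == [
            (f.fragment_id, f.sequence) for f in fixture17.fragments
        ]

    def test_background_only_run_is_fully_masked(self, fixture17):
        db = transcript_database(fixture17.genes, fixture17.genome)
        masker = TranscriptMasker(db)
        bg = [f for f in fixture17.fragments if f.fragment_id.startswith("bg_")]
        assert bg
        for frag in bg[:30]:
            assert masker.mask(frag).status == "fully_masked"

    def test_every_truth_fragment_reaches_round_two(self, fixture17, classified17):
        truth_ids = {fid for p in fixture17.truth.planted for fid in p.fragment_ids}
        by_id = {m.fragment_id: m for m in classified17.mask_results}
        for fid in truth_ids:
            res = by_id[fid]
            has_candidates = bool(select_candidates(res))
            fusion_suspect = res.status == "fully_masked" and len(res.masked_gene_ids) >= 2
            assert has_candidates or fusion_suspect


class TestProbePanel:
    def test_three_replicates_always_emitted(self, tiling_sim):
        _, _, panel, _ = tiling_sim
        assert panel.n_replicates == 3

    def test_zero_snr_yields_no_present_calls(self):
        from conect.tiling import tiling_pipeline

        genome, genes = generate_genome_and_genes(seed=4, n_genes=20, chrom_len=100_000)
        labels = {g.gene_id: (i % 2 == 0) for i, g in enumerate(genes)}
        panel = simulate_probe_panel(genome, genes, labels, snr=0.0, seed=4)
        result = tiling_pipeline(panel, genes)
        assert sum(bool(c.consensus_present) for c in result.calls) == 0

    def test_negative_snr_rejected(self, fixture17):
        with pytest.raises(ValueError):
            simulate_probe_panel(fixture17.genome, fixture17.genes, {}, snr=-1.0)


class TestQuantReads:
    def test_untargeted_transcript_receives_zero_reads(self, rng):
        txs = {f"t{i}": "".join(rng.choice(list("ACGT"), size=600)) for i in range(5)}
        ab = {t: 0.2 for t in txs}
        reads, truth = simulate_quant_reads(txs, ab, 200, untargeted_ids={"t0"}, seed=3)
        assert truth["t0"] == 0
        assert sum(truth.values()) == 200

    def test_error_free_reads_reassign_to_truth_counts(self, rng):
        from conect.quant import assign_reads

        txs = {f"t{i}": "".join(rng.choice(list("ACGT"), size=800)) for i in range(4)}
        ab = {t: 0.25 for t in txs}
        reads, truth = simulate_quant_reads(txs, ab, 120, seed=5)
        counts, unassigned, _ = assign_reads(reads, txs)
        assert unassigned == 0
        assert counts == truth

    def test_bad_abundances_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_quant_reads({"t": "ACGT" * 100}, {"t": 0.5}, 10)
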