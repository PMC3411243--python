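from collections import Counter

import numpy as np
import pytest

from conect.classifier import (
    GenomePlacer,
    NovelFeature,
    map_p_elements,
    percent,
    summarize_run,
    validate_splice_sites,
)
from conect.datamodel import (
    GeneModel,
    GenomeSequence,
    PElementInsertion,
    TranscriptFragment,
    revcomp,
)
from conect.pipeline import run_classification
from conect.simulate import paperlike_fixture


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# Splice-consensus validation


class TestSpliceValidation:
    def _genome(self, intron: str, flank=50):
        seq = "T" * flank + intron + "T" * flank
        return GenomeSequence(["c"], {"c": seq}), (0, flank), (flank + len(intron), flank * 2 + len(intron))

    def test_canonical_gt_ag_plus_strand(self):
        genome, left, right = self._genome("GT" + "C" * 60 + "AG")
        ok, reason = validate_splice_sites(genome, "c", left, right, "+")
        assert ok

    def test_gc_ag_rejected_by_default_accepted_when_configured(self):
        genome, left, right = self._genome("GC" + "C" * 60 + "AG")
        assert not validate_splice_sites(genome, "c", left, right, "+")[0]
        assert validate_splice_sites(genome, "c", left, right, "+", donors=("GT", "GC"))[0]

    def test_minus_strand_reads_reverse_complement(self):
        # CT..AC forward is GT..AG on the transcribed minus strand
        genome, left, right = self._genome("CT" + "C" * 60 + "AC")
        assert validate_splice_sites(genome, "c", left, right, "-")[0]
        assert not validate_splice_sites(genome, "c", left, right, "+")[0]

    def test_short_gap_is_micro_gap_not_intron(self):
        genome, left, right = self._genome("GT" + "C" * 10 + "AG")
        ok, reason = validate_splice_sites(genome, "c", left, right, "+")
        assert not ok and reason == "micro-gap"


# ---------------------------------------------------------------------------
# Genome placement


class TestPlacement:
    def test_exact_substring_places_as_single_block(self, rng):
        genome = GenomeSequence(["c"], {"c": _random_seq(rng, 5000)})
        placer = GenomePlacer(genome)
        frag = genome.fetch("c", 1200, 1600)
        placement = placer.place("f", frag)
        assert placement.status == "placed"
        assert [(b.gstart, b.gend) for b in placement.blocks] == [(1200, 1600)]

    def test_spliced_fragment_yields_intron_separated_blocks(self, rng):
        genome = GenomeSequence(["c"], {"c": _random_seq(rng, 5000)})
        placer = GenomePlacer(genome)
        frag = genome.fetch("c", 1000, 1200) + genome.fetch("c", 2000, 2300)
        placement = placer.place("f", frag)
        assert placement.status == "placed"
        blocks = [(b.gstart, b.gend) for b in placement.blocks]
        assert blocks[0][0] == 1000 and blocks[-1][1] == 2300
        assert len(blocks) == 2

    def test_randomized_sequence_is_unplaced(self, rng):
        genome = GenomeSequence(["c"], {"c": _random_seq(rng, 5000)})
        other = np.random.default_rng(4242)
        placement = GenomePlacer(genome).place("f", _random_seq(other, 150))
        assert placement.status == "unplaced"

    def test_duplicated_locus_is_flagged_ambiguous(self, rng):
        segment = _random_seq(rng, 200)
        filler = [_random_seq(rng, 800) for _ in range(3)]
        genome = GenomeSequence(["c"], {"c": filler[0] + segment + filler[1] + segment + filler[2]})
        placement = GenomePlacer(genome).place("f", segment)
        assert placement.status == "ambiguous"

    def test_minus_strand_placement(self, rng):
        genome = GenomeSequence(["c"], {"c": _random_seq(rng, 4000)})
        frag = revcomp(genome.fetch("c", 500, 900))
        placement = GenomePlacer(genome).place("f", frag)
        assert placement.status == "placed"
        assert placement.strand == "-"
        assert (placement.blocks[0].gstart, placement.blocks[0].gend) == (500, 900)


# ---------------------------------------------------------------------------
# Classification on a handcrafted locus


class TestClassifyMini:
    @pytest.fixture()
    def locus(self, rng):
        seq = list(_random_seq(rng, 6000))
        # gene: two exons (2000,2200) and (2400,2600), plus strand
        seq[2200:2202] = "GT"
        seq[2398:2400] = "AG"
        genome = GenomeSequence(["c"], {"c": "".join(seq)})
        gene = GeneModel("gX", "c", "+", [(2000, 2200), (2400, 2600)], [("gX.t1", [0, 1])])
        return genome, [gene]

    def test_contiguous_upstream_candidate_is_five_prime_extension(self, locus):
        genome, genes = locus
        frag_seq = genome.fetch("c", 1950, 2200) + genome.fetch("c", 2400, 2600)
        run = run_classification(genome, genes, [TranscriptFragment("f", frag_seq)])
        cats = [(f.category, tuple(f.intervals)) for f in run.features]
        assert ("five_prime_extension", ((1950, 2000),)) in cats

    def test_spliced_upstream_candidate_is_five_prime_novel_exon(self, locus):
        genome, genes = locus
        seq = list(genome.sequences["c"])
        seq[1130:1132] = "GT"
        seq[1998:2000] = "AG"
        genome = GenomeSequence(["c"], {"c": "".join(seq)})
        frag_seq = (
            genome.fetch("c", 1000, 1130)
            + genome.fetch("c", 2000, 2200)
            + genome.fetch("c", 2400, 2600)
        )
        run = run_classification(genome, genes, [TranscriptFragment("f", frag_seq)])
        novel = [f for f in run.features if f.category == "five_prime_novel_exon"]
        assert len(novel) == 1
        assert novel[0].intervals == [(1000, 1130)]
        assert novel[0].splice_valid is True

    def test_far_candidate_is_intergenic_unlinked(self, rng):
        from conect.config import RunConfig

        genome = GenomeSequence(["c"], {"c": _random_seq(rng, 9000)})
        gene = GeneModel("gY", "c", "+", [(8000, 8200)], [("gY.t1", [0])])
        cfg = RunConfig(max_link_dist=1000)
        frag_seq = genome.fetch("c", 100, 400) + genome.fetch("c", 8000, 8200)
        run = run_classification(genome, [gene], [TranscriptFragment("f", frag_seq)], cfg)
        assert any(f.category == "intergenic_unlinked" for f in run.features)


# ---------------------------------------------------------------------------
# Whole-fixture invariants


class TestFixtureInvariants:
    def test_every_candidate_block_receives_exactly_one_verdict(self, classified17):
        allowed = {
            "five_prime_novel_exon", "five_prime_extension", "three_prime_novel_exon",
            "three_prime_extension", "internal_novel_exon", "internal_extension",
            "gene_fusion", "intergenic_unlinked",
        }
        assert {f.category for f in classified17.features} <= allowed

    def test_extensions_skip_splice_validation_novel_exons_carry_it(self, classified17):
        for f in classified17.features:
            if f.category.endswith("_extension") or f.category == "gene_fusion":
                assert f.splice_valid is None
            elif f.category.endswith("_novel_exon"):
                assert isinstance(f.splice_valid, bool)

    def test_strand_symmetry_of_category_counts(self):
        fx = paperlike_fixture(seed=5, chrom_len=150_000, n_genes=36, k_per_category=2, n_background=0)
        run = run_classification(fx.genome, fx.genes, fx.fragments)
        flipped_genome, flipped_genes = _flip(fx.genome, fx.genes)
        run2 = run_classification(flipped_genome, flipped_genes, fx.fragments)
        c1 = Counter(f.category for f in run.features)
        c2 = Counter(f.category for f in run2.features)
        assert c1 == c2


def _flip(genome: GenomeSequence, genes: list[GeneModel]):
    """Reverse-complement the whole fixture; annotation coordinates mirror."""
    lengths = {c: len(genome.sequences[c]) for c in genome.chrom_names}
    flipped = GenomeSequence(
        list(genome.chrom_names), {c: revcomp(genome.sequences[c]) for c in genome.chrom_names}
    )
    new_genes = []
    for g in genes:
        L = lengths[g.chrom]
        exons = [(L - e, L - s) for s, e in g.exons]
        new_genes.append(
            GeneModel(g.gene_id, g.chrom, "-" if g.strand == "+" else "+", exons,
                      [(tid, list(idx)) for tid, idx in g.transcripts])
        )
    return flipped, new_genes


# ---------------------------------------------------------------------------
# P-element mapping and run summary


class TestPElements:
    def _feature(self):
        return NovelFeature("five_prime_novel_exon", ("g1",), "chr1", "+", [(100, 200)], "f", True, 150)

    def test_insertion_inside_feature_reported(self):
        table = map_p_elements([PElementInsertion("P1", "chr1", 150)], [self._feature()])
        assert list(table["element_id"]) == ["P1"]
        assert list(table["category"]) == ["five_prime_novel_exon"]

    def test_half_open_end_excluded(self):
        table = map_p_elements([PElementInsertion("P1", "chr1", 200)], [self._feature()])
        assert table.empty

    def test_no_insertions_empty_table(self):
        assert map_p_elements([], [self._feature()]).empty


class TestSummary:
    def test_percent_matches_printed_precision(self):
        assert percent(543_373, 549_729) == 98.8
        assert percent(696_274, 703_613) == 99.0

    def test_zero_fragments_report_na(self):
        df = summarize_run([], [], [])
        row = df[df["item"] == "fragments_total"].iloc[0]
        assert row["count"] == 0 and row["percent"] == "NA"
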