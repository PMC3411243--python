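"""Round-2 screening: genomic placement and seven-category novelty calls.

Fragments that survive round-1 masking with candidate (unmasked) segments are
placed on the genome by chaining seed-and-extend hits into a co-linear block
structure.  Each candidate segment is then mapped through its placement to a
genomic interval and classified relative to the linked annotated gene:

* ``five_prime_extension`` / ``three_prime_extension`` / ``internal_extension``
  — the candidate block shares a boundary with an annotated exon (no intron);
* ``five_prime_novel_exon`` / ``three_prime_novel_exon`` /
  ``internal_novel_exon`` — the candidate block is separated from the
  annotated structure by an intron, which must carry perfect splice consensus
  dinucleotides (GT..AG on the transcribed strand) for the call to validate;
* ``gene_fusion`` — one placement whose known blocks match exons of two or
  more distinct annotated genes.

Candidates overlapping no gene within ``max_link_dist`` are reported as
``intergenic_unlinked`` — outside the seven categories, but never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .datamodel import GeneModel, GenomeSequence, PElementInsertion, revcomp
from .masker import CandidateSegment, Hit, KmerIndex, MaskResult

logger = logging.getLogger(__name__)

DEFAULT_MIN_INTRON_LEN = 40
DEFAULT_MAX_LINK_DIST = 50_000

CATEGORIES = (
    "five_prime_novel_exon",
    "five_prime_extension",
    "three_prime_novel_exon",
    "three_prime_extension",
    "internal_novel_exon",
    "internal_extension",
    "gene_fusion",
)


@dataclass
class PlacedBlock:
    """One ungapped block of a genomic placement."""

    gstart: int
    gend: int
    fstart: int  # oriented-fragment coordinates
    fend: int


@dataclass
class GenomePlacement:
    fragment_id: str
    status: str  # placed | unplaced | ambiguous
    chrom: str = ""
    strand: str = "+"
    blocks: list[PlacedBlock] = field(default_factory=list)  # ascending genomic order
    score: int = 0

    def frag_to_genomic(self, start: int, end: int) -> list[tuple[int, int]]:
        """Map an oriented-fragment interval onto genomic intervals.

        The interval may span several blocks (e.g. a candidate containing two
        novel exons); one genomic interval per overlapped block is returned,
        in ascending genomic order.
        """
        out = []
        for b in self.blocks:
            lo, hi = max(start, b.fstart), min(end, b.fend)
            if lo >= hi:
                continue
            if self.strand == "+":
                out.append((b.gstart + (lo - b.fstart), b.gstart + (hi - b.fstart)))
            else:
                out.append((b.gend - (hi - b.fstart), b.gend - (lo - b.fstart)))
        return sorted(out)


@dataclass
class NovelFeature:
    """A classified novelty supported by one fragment."""

    category: str
    gene_ids: tuple[str, ...]
    chrom: str
    strand: str
    intervals: list[tuple[int, int]]
    fragment_id: str
    splice_valid: bool | None  # None for extensions and fusions
    distance_to_exon: int


class GenomePlacer:
    """Places oriented fragment sequences on the genome by hit chaining."""

    def __init__(
        self,
        genome: GenomeSequence,
        kmer_size: int = 16,
        min_identity: float = 0.95,
        min_hit_len: int = 20,
        max_intron: int = DEFAULT_MAX_LINK_DIST,
    ):
        self.genome = genome
        self.index = KmerIndex(dict(genome.sequences), k=kmer_size)
        self.min_identity = min_identity
        self.min_hit_len = min_hit_len
        self.max_intron = max_intron

    def place(self, fragment_id: str, oriented_seq: str) -> GenomePlacement:
        """Best co-linear placement of the sequence; ambiguity is flagged.

        Both orientations are searched (a fragment whose masked orientation
        reads antisense to the genome places on the minus strand).
        """
        chains: list[tuple[int, str, str, list[Hit]]] = []  # (score, chrom, strand, hits)
        for strand, seq in (("+", oriented_seq), ("-", revcomp(oriented_seq))):
            hits = self.index.find_hits(seq, self.min_identity, self.min_hit_len)
            by_chrom: dict[str, list[Hit]] = {}
            for h in hits:
                by_chrom.setdefault(h.target_id, []).append(h)
            for chrom, chrom_hits in by_chrom.items():
                for chain in _chain_hits(chrom_hits, self.max_intron):
                    score = sum(h.matches for h in chain)
                    chains.append((score, chrom, strand, chain))
        if not chains:
            return GenomePlacement(fragment_id, "unplaced")
        chains.sort(key=lambda c: -c[0])
        if len(chains) > 1 and chains[1][0] == chains[0][0]:
            return GenomePlacement(fragment_id, "ambiguous")
        score, chrom, strand, chain = chains[0]
        blocks = _chain_to_blocks(chain, strand, len(oriented_seq))
        return GenomePlacement(fragment_id, "placed", chrom, strand, blocks, score)


def _chain_hits(hits: list[Hit], max_intron: int) -> list[list[Hit]]:
    """Greedy co-linear chaining of same-chromosome hits.

    Hits are first merged along shared diagonals (bridging short mismatch
    runs), then chained left to right when both query and genomic coordinates
    advance and the genomic gap stays below ``max_intron``.  Each hit seeds at
    most one chain; distinct loci therefore yield distinct chains, letting the
    caller detect ambiguous placements by score ties.
    """
    hits = sorted(hits, key=lambda h: (h.qstart, h.tstart))
    merged: list[Hit] = []
    for h in hits:
        if merged:
            p = merged[-1]
            same_diag = (h.tstart - h.qstart) == (p.tstart - p.qstart)
            if same_diag and 0 <= h.qstart - p.qend <= 10:
                merged[-1] = Hit(
                    p.target_id, p.qstart, h.qend, p.tstart, h.tend, p.matches + h.matches
                )
                continue
        merged.append(h)

    chains: list[list[Hit]] = []
    used = [False] * len(merged)
    for i, h in enumerate(merged):
        if used[i]:
            continue
        chain = [h]
        used[i] = True
        for j in range(i + 1, len(merged)):
            if used[j]:
                continue
            nxt, cur = merged[j], chain[-1]
            if (
                nxt.qstart >= cur.qend - 12
                and nxt.tstart >= cur.tend
                and nxt.tstart - cur.tend <= max_intron
            ):
                chain.append(nxt)
                used[j] = True
        chains.append(chain)
    return chains


def _chain_to_blocks(chain: list[Hit], strand: str, frag_len: int) -> list[PlacedBlock]:
    blocks = []
    for h in chain:
        if strand == "+":
            fs, fe = h.qstart, h.qend
        else:  # hit coordinates are on the reverse complement of the oriented fragment
            fs, fe = frag_len - h.qend, frag_len - h.qstart
        blocks.append(PlacedBlock(h.tstart, h.tend, fs, fe))
    return sorted(blocks, key=lambda b: b.gstart)


# ---------------------------------------------------------------------------
# Splice-consensus validation


def validate_splice_sites(
    genome: GenomeSequence,
    chrom: str,
    left_block: tuple[int, int],
    right_block: tuple[int, int],
    strand: str,
    min_intron_len: int = DEFAULT_MIN_INTRON_LEN,
    donors: tuple[str, ...] = ("GT",),
    acceptor: str = "AG",
) -> tuple[bool, str]:
    """Check the intron between two genomic blocks for perfect splice consensus.

    On the transcribed strand the intron must begin with a donor dinucleotide
    (GT by default; GC optionally) and end with the acceptor (AG).  Gaps
    shorter than ``min_intron_len`` are treated as micro-gaps, not introns.
    """
    intron_start, intron_end = left_block[1], right_block[0]
    if intron_end - intron_start < min_intron_len:
        return False, "micro-gap"
    intron = genome.fetch(chrom, intron_start, intron_end)
    if strand == "-":
        intron = revcomp(intron)
    if intron[:2] in donors and intron[-2:] == acceptor:
        return True, "ok"
    return False, f"non-consensus {intron[:2]}..{intron[-2:]}"


# ---------------------------------------------------------------------------
# Classification


class NoveltyClassifier:
    def __init__(
        self,
        genes: list[GeneModel],
        genome: GenomeSequence,
        min_intron_len: int = DEFAULT_MIN_INTRON_LEN,
        max_link_dist: int = DEFAULT_MAX_LINK_DIST,
        donors: tuple[str, ...] = ("GT",),
    ):
        self.genome = genome
        self.min_intron_len = min_intron_len
        self.max_link_dist = max_link_dist
        self.donors = donors
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)

    def classify(
        self, placement: GenomePlacement, candidates: list[CandidateSegment]
    ) -> list[NovelFeature]:
        """Assign every candidate block of a placement to a category.

        Also emits one ``gene_fusion`` row when the placement's known blocks
        match exons of two or more distinct genes.
        """
        if placement.status != "placed":
            return []
        placement = _reconcile_placement(placement, candidates)
        chrom = placement.chrom
        features: list[NovelFeature] = []

        cand_blocks: list[tuple[int, int]] = []
        for cand in candidates:
            cand_blocks.extend(placement.frag_to_genomic(cand.start, cand.end))

        known_blocks = _subtract_intervals(
            [(b.gstart, b.gend) for b in placement.blocks], cand_blocks
        )
        linked = self._genes_hit_by(chrom, known_blocks)

        if len(linked) >= 2:
            # report the annotated exons the placement joins, not raw blocks
            fusion_blocks = sorted(
                {
                    tuple(sorted(exon))
                    for g in linked
                    for exon in g.exons
                    if any(_overlaps(tuple(sorted(exon)), kb) for kb in known_blocks)
                }
            )
            features.append(
                NovelFeature(
                    "gene_fusion",
                    tuple(sorted(g.gene_id for g in linked)),
                    chrom,
                    placement.strand,
                    fusion_blocks,
                    placement.fragment_id,
                    None,
                    0,
                )
            )

        for cb in cand_blocks:
            features.append(self._classify_block(placement, cb, linked))
        return features

    def _genes_hit_by(self, chrom: str, blocks: list[tuple[int, int]]) -> list[GeneModel]:
        out = []
        for g in self.by_chrom.get(chrom, []):
            for s, e in blocks:
                if any(max(s, xs) < min(e, xe) for xs, xe in g.exons):
                    out.append(g)
                    break
        return out

    def _classify_block(
        self,
        placement: GenomePlacement,
        block: tuple[int, int],
        linked: list[GeneModel],
    ) -> NovelFeature:
        chrom = placement.chrom
        gene = self._nearest_gene(chrom, block, linked)
        if gene is None:
            return NovelFeature(
                "intergenic_unlinked", (), chrom, placement.strand, [block],
                placement.fragment_id, None, -1,
            )

        dist = min(_gap(block, exon) for exon in gene.exons)
        contiguous = any(exon[1] == block[0] or block[1] == exon[0] for exon in gene.exons)

        # position relative to the gene body, in transcription orientation
        if block[1] <= gene.start:
            side = "five_prime" if gene.strand == "+" else "three_prime"
        elif block[0] >= gene.end:
            side = "three_prime" if gene.strand == "+" else "five_prime"
        else:
            side = "internal"

        if contiguous:
            return NovelFeature(
                f"{side}_extension", (gene.gene_id,), chrom, gene.strand, [block],
                placement.fragment_id, None, 0,
            )

        valid = self._junctions_valid(placement, block, gene)
        return NovelFeature(
            f"{side}_novel_exon", (gene.gene_id,), chrom, gene.strand, [block],
            placement.fragment_id, valid, dist,
        )

    def _nearest_gene(
        self, chrom: str, block: tuple[int, int], linked: list[GeneModel]
    ) -> GeneModel | None:
        pool = linked if linked else self.by_chrom.get(chrom, [])
        best, best_d = None, self.max_link_dist + 1
        for g in pool:
            d = _gap(block, (g.start, g.end))
            if d < best_d:
                best, best_d = g, d
        return best if best_d <= self.max_link_dist else None

    def _junctions_valid(
        self, placement: GenomePlacement, block: tuple[int, int], gene: GeneModel
    ) -> bool:
        """Validate the splice junction(s) flanking a putative novel exon.

        Junction partners are the placement blocks adjacent to the candidate
        block (the observed exon-intron structure of the supporting fragment);
        when the candidate has no placed neighbour on the gene side, the
        nearest annotated exon boundary stands in.
        """
        left = right = None
        for b in placement.blocks:
            iv = (b.gstart, b.gend)
            if iv[1] <= block[0] and not _overlaps(iv, block):
                if left is None or iv[1] > left[1]:
                    left = iv
            elif iv[0] >= block[1] and not _overlaps(iv, block):
                if right is None or iv[0] < right[0]:
                    right = iv
        if left is None and right is None:
            # fall back to the nearest annotated exon as junction partner
            exon = min(gene.exons, key=lambda x: _gap(block, x))
            if exon[1] <= block[0]:
                left = exon
            else:
                right = exon

        verdicts = []
        if left is not None:
            ok, _ = validate_splice_sites(
                self.genome, placement.chrom, left, block, gene.strand,
                self.min_intron_len, self.donors,
            )
            verdicts.append(ok)
        if right is not None:
            ok, _ = validate_splice_sites(
                self.genome, placement.chrom, block, right, gene.strand,
                self.min_intron_len, self.donors,
            )
            verdicts.append(ok)
        return bool(verdicts) and all(verdicts)


def _reconcile_placement(
    placement: GenomePlacement, candidates: list[CandidateSegment]
) -> GenomePlacement:
    """Resolve fragment-coordinate overlaps between chained blocks.

    Ungapped extension may carry a block a few bases past a junction when the
    genome happens to agree with the fragment there; the neighbouring block
    then claims the same fragment bases.  The masking step already fixed the
    true novel/known junction, so overlaps are cut at a candidate-segment
    boundary when one falls inside the overlap, otherwise at the left block's
    end.  Genomic coordinates are adjusted along each block's own diagonal.
    """
    boundaries = sorted({c.start for c in candidates} | {c.end for c in candidates})
    blocks = sorted(
        (PlacedBlock(b.gstart, b.gend, b.fstart, b.fend) for b in placement.blocks),
        key=lambda b: b.fstart,
    )
    plus = placement.strand == "+"
    for a, b in zip(blocks, blocks[1:]):
        overlap = a.fend - b.fstart
        if overlap <= 0:
            continue
        cuts = [x for x in boundaries if b.fstart <= x <= a.fend]
        cut = cuts[0] if cuts else a.fend
        d = a.fend - cut
        if d > 0:
            a.fend = cut
            if plus:
                a.gend -= d
            else:
                a.gstart += d
        d = cut - b.fstart
        if d > 0:
            b.fstart = cut
            if plus:
                b.gstart += d
            else:
                b.gend -= d
    blocks = [b for b in blocks if b.fend > b.fstart]
    return GenomePlacement(
        placement.fragment_id, "placed", placement.chrom, placement.strand,
        sorted(blocks, key=lambda b: b.gstart), placement.score,
    )


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """bp between two intervals; 0 when they touch or overlap."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])


def _subtract_intervals(
    blocks: list[tuple[int, int]], minus: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for s, e in blocks:
        pieces = [(s, e)]
        for ms, me in minus:
            nxt = []
            for ps, pe in pieces:
                if me <= ps or ms >= pe:
                    nxt.append((ps, pe))
                else:
                    if ps < ms:
                        nxt.append((ps, ms))
                    if me < pe:
                        nxt.append((me, pe))
            pieces = nxt
        out.extend(p for p in pieces if p[1] > p[0])
    return sorted(out)


# ---------------------------------------------------------------------------
# P-element overlap and run summary


def map_p_elements(
    insertions: list[PElementInsertion], features: list[NovelFeature]
) -> pd.DataFrame:
    """Insertions falling inside (half-open) any classified feature interval."""
    rows = []
    for ins in insertions:
        for f in features:
            if f.chrom != ins.chrom:
                continue
            for s, e in f.intervals:
                if s <= ins.position < e:
                    rows.append(
                        {
                            "element_id": ins.element_id,
                            "category": f.category,
                            "gene_id": ",".join(f.gene_ids),
                            "fragment_id": f.fragment_id,
                            "start": s,
                            "end": e,
                        }
                    )
    return pd.DataFrame(rows, columns=["element_id", "category", "gene_id", "fragment_id", "start", "end"])


def percent(part: int | float, whole: int | float, ndigits: int = 1) -> float | str:
    """100*part/whole rounded; 'NA' on an empty denominator."""
    if whole == 0:
        return "NA"
    return round(100.0 * part / whole, ndigits)


def summarize_run(
    mask_results: list[MaskResult],
    placements: list[GenomePlacement],
    features: list[NovelFeature],
) -> pd.DataFrame:
    """Run-level counts: per-category features, known/unplaced/ambiguous tallies."""
    n_frag = len(mask_results)
    n_known = sum(1 for m in mask_results if m.status == "fully_masked")
    n_partial = sum(1 for m in mask_results if m.status == "partially_masked")
    n_unmasked = sum(1 for m in mask_results if m.status == "fully_unmasked")
    n_unplaced = sum(1 for p in placements if p.status == "unplaced")
    n_ambiguous = sum(1 for p in placements if p.status == "ambiguous")

    rows = [
        ("fragments_total", n_frag, percent(n_frag, n_frag)),
        ("fully_masked_known", n_known, percent(n_known, n_frag)),
        ("partially_masked", n_partial, percent(n_partial, n_frag)),
        ("fully_unmasked", n_unmasked, percent(n_unmasked, n_frag)),
        ("unplaced", n_unplaced, percent(n_unplaced, n_frag)),
        ("ambiguous", n_ambiguous, percent(n_ambiguous, n_frag)),
    ]
    n_feat = len(features)
    for cat in CATEGORIES + ("intergenic_unlinked",):
        n = sum(1 for f in features if f.category == cat)
        rows.append((cat, n, percent(n, n_feat)))
    return pd.DataFrame(rows, columns=["item", "count", "percent"])


def write_features_gff(features: list[NovelFeature], path) -> None:
    """GFF3 track of classified features: category in the type column."""
    lines = ["##gff-version 3"]
    for i, f in enumerate(features):
        attrs = f"ID=novel{i};fragment_id={f.fragment_id};genes={','.join(f.gene_ids)}"
        if f.splice_valid is not None:
            attrs += f";splice_valid={str(f.splice_valid).lower()}"
        for s, e in f.intervals:
            lines.append(
                "\t".join(
                    [f.chrom, "conect", f.category, str(s + 1), str(e), ".", f.strand, ".", attrs]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
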