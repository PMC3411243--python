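"""Core domain types shared by every pipeline stage.

Coordinates are 0-based half-open throughout the package; GFF3 I/O converts
to and from the 1-based inclusive convention at the file boundary, and BED is
consumed natively.  Gene exons are stored in *transcription* order, so a
minus-strand gene lists its exons from high to low genomic coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str, name: str) -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{name}: invalid characters {sorted(bad)}")


@dataclass
class GenomeSequence:
    """A genome as an ordered set of named chromosome sequences."""

    chrom_names: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        for name in self.chrom_names:
            seq = self.sequences[name].upper()
            _check_alphabet(seq, name)
            self.sequences[name] = seq

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``[start, end)`` on the forward strand."""
        seq = self.sequences[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"interval [{start},{end}) outside {chrom}")
        return seq[start:end]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


@dataclass
class GeneModel:
    """An annotated gene: strand, exons and transcript isoform structures.

    ``exons`` are 0-based half-open genomic intervals listed in transcription
    order (5' to 3' on the transcribed strand).  ``transcripts`` maps each
    isoform to an ordered list of exon indices.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    transcripts: list[tuple[str, list[int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError(f"{self.gene_id}: exons not in transcription order")
        n = len(self.exons)
        for tid, idx in self.transcripts:
            if any(i < 0 or i >= n for i in idx):
                raise ValueError(f"{self.gene_id}/{tid}: exon index out of range")

    # -- genomic geometry -------------------------------------------------

    @property
    def exons_genomic(self) -> list[tuple[int, int]]:
        """Exons sorted by ascending genomic start."""
        return sorted(self.exons)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start: left edge on +, right edge on -."""
        return self.start if self.strand == "+" else self.end

    def transcript_exons(self, transcript_id: str) -> list[tuple[int, int]]:
        for tid, idx in self.transcripts:
            if tid == transcript_id:
                return [self.exons[i] for i in idx]
        raise KeyError(f"{self.gene_id}: no transcript {transcript_id}")

    def transcript_length(self, transcript_id: str) -> int:
        return sum(e - s for s, e in self.transcript_exons(transcript_id))

    def exon_union_length(self) -> int:
        """Length of the union of all exons (gene-level effective length)."""
        total, prev_end = 0, None
        for s, e in sorted(self.exons):
            if prev_end is None or s >= prev_end:
                total += e - s
                prev_end = e
            elif e > prev_end:
                total += e - prev_end
                prev_end = e
        return total


@dataclass
class TranscriptFragment:
    """An assembled cDNA fragment: a multi-read isotig or a lone singleton."""

    fragment_id: str
    sequence: str
    kind: str = "isotig"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"{self.fragment_id}: empty sequence")
        _check_alphabet(self.sequence, self.fragment_id)
        if self.kind not in ("isotig", "singleton"):
            raise ValueError(f"{self.fragment_id}: kind must be isotig or singleton")


@dataclass
class PElementInsertion:
    """A transposon insertion site used to map mutations to genes."""

    element_id: str
    chrom: str
    position: int


def transcript_sequence(gene: GeneModel, genome: GenomeSequence, transcript_id: str) -> str:
    """Spliced mRNA sequence of one isoform, 5' to 3'."""
    parts = [genome.fetch(gene.chrom, s, e) for s, e in sorted(gene.transcript_exons(transcript_id))]
    seq = "".join(parts)
    return seq if gene.strand == "+" else revcomp(seq)


def transcript_database(genes: list[GeneModel], genome: GenomeSequence) -> dict[str, tuple[str, str]]:
    """All spliced transcript sequences, keyed by transcript id.

    Returns ``{transcript_id: (gene_id, sequence)}`` — the in-memory analogue
    of an all-genes FASTA used for round-1 masking.
    """
    db: dict[str, tuple[str, str]] = {}
    for gene in genes:
        for tid, _ in gene.transcripts:
            if tid in db:
                raise ValueError(f"duplicate transcript id {tid}")
            db[tid] = (gene.gene_id, transcript_sequence(gene, genome, tid))
    return db
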