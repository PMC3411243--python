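"""Readers and writers for FASTA, GFF3, BED and probe/intensity tables.

FASTA goes through Biopython, GFF3 through gffutils (in-memory db).  All
readers normalise into the package's internal 0-based half-open convention.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import (
    GeneModel,
    GenomeSequence,
    PElementInsertion,
    TranscriptFragment,
)

logger = logging.getLogger(__name__)

MAX_N_FRACTION = 0.10


# ---------------------------------------------------------------------------
# FASTA


def _fasta_records(path: str | Path) -> list[SeqRecord]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
    return records


def read_genome_fasta(path: str | Path) -> GenomeSequence:
    records = _fasta_records(path)
    names = [r.id for r in records]
    return GenomeSequence(names, {r.id: str(r.seq).upper() for r in records})


def read_fragments_fasta(path: str | Path, max_n_fraction: float = MAX_N_FRACTION) -> list[TranscriptFragment]:
    """Load assembled fragments; sequences with too many N bases are dropped.

    A record whose description contains ``kind=singleton`` is loaded as a
    singleton, everything else as an isotig.
    """
    fragments = []
    for rec in _fasta_records(path):
        seq = str(rec.seq).upper()
        if seq.count("N") > max_n_fraction * len(seq):
            logger.warning("rejecting fragment %s: >%.0f%% ambiguous bases", rec.id, 100 * max_n_fraction)
            continue
        kind = "singleton" if "kind=singleton" in rec.description else "isotig"
        fragments.append(TranscriptFragment(rec.id, seq, kind))
    return fragments


def write_fasta(records: dict[str, str] | list[TranscriptFragment], path: str | Path) -> None:
    if isinstance(records, dict):
        seqrecs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    else:
        seqrecs = [SeqRecord(Seq(f.sequence), id=f.fragment_id, description=f"kind={f.kind}") for f in records]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon features into GeneModel objects.

    GFF3 coordinates (1-based inclusive) become 0-based half-open; exon lists
    follow transcription order per strand.
    """
    _prevalidate_gff(path)
    db = gffutils.create_db(str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique")
    mrna_parent: dict[str, str] = {}
    for mrna in db.features_of_type("mRNA"):
        mrna_parent[mrna.id] = mrna.attributes["Parent"][0]
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents or any(p not in mrna_parent for p in parents):
            raise ValueError(f"{path}: exon at {exon.seqid}:{exon.start}-{exon.end} without parent transcript")

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        per_tx: dict[str, list[tuple[int, int]]] = {}
        for mrna in db.children(gene, featuretype="mRNA"):
            ivals = [(e.start - 1, e.end) for e in db.children(mrna, featuretype="exon")]
            per_tx[mrna.id] = sorted(ivals, reverse=(gene.strand == "-"))
        exon_set = sorted({iv for ivals in per_tx.values() for iv in ivals},
                          reverse=(gene.strand == "-"))
        index = {iv: i for i, iv in enumerate(exon_set)}
        transcripts = [(tid, [index[iv] for iv in ivals]) for tid, ivals in sorted(per_tx.items())]
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, exon_set, transcripts))
    return genes


def _prevalidate_gff(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            start, end = int(cols[3]), int(cols[4])
            if end < start:
                raise ValueError(f"{path}:{lineno}: end {end} < start {start}")


def write_gff(genes: list[GeneModel], path: str | Path, source: str = "conect") -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(_gff_line(g.chrom, source, "gene", g.start, g.end, g.strand, f"ID={g.gene_id}"))
        exon_parents: dict[int, list[str]] = {i: [] for i in range(len(g.exons))}
        for tid, idx in g.transcripts:
            ts = min(g.exons[i][0] for i in idx)
            te = max(g.exons[i][1] for i in idx)
            lines.append(_gff_line(g.chrom, source, "mRNA", ts, te, g.strand, f"ID={tid};Parent={g.gene_id}"))
            for i in idx:
                exon_parents[i].append(tid)
        for i, (s, e) in enumerate(g.exons):
            if exon_parents[i]:
                lines.append(_gff_line(g.chrom, source, "exon", s, e, g.strand,
                                       "Parent=" + ",".join(exon_parents[i])))
    Path(path).write_text("\n".join(lines) + "\n")


def _gff_line(chrom: str, source: str, ftype: str, start: int, end: int, strand: str, attrs: str) -> str:
    # internal half-open [start, end) -> GFF3 1-based inclusive
    return "\t".join([chrom, source, ftype, str(start + 1), str(end), ".", strand, ".", attrs])


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[PElementInsertion]:
    insertions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 4:
                raise ValueError(f"{path}:{lineno}: expected at least 4 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            insertions.append(PElementInsertion(cols[3], cols[0], start))
    return insertions


def write_bed(insertions: list[PElementInsertion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ins in insertions:
            fh.write(f"{ins.chrom}\t{ins.position}\t{ins.position + 1}\t{ins.element_id}\n")


# ---------------------------------------------------------------------------
# Probe / intensity tables (TSV with header)

PROBE_COLUMNS = ["probe_id", "chrom", "start", "length", "gc_count", "is_random", "gene_id", "exon_index"]


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "gene_id": str})
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing probe columns {sorted(missing)}")
    df["is_random"] = df["is_random"].astype(bool)
    return df


def write_probe_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_intensity_table(path: str | Path) -> pd.DataFrame:
    """Intensity matrix: probe_id column plus one column per replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if df.isna().any().any():
        raise ValueError(f"{path}: intensity matrix has missing cells")
    return df


def write_intensity_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
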