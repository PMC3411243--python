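"""Truth-labelled synthetic fixtures for every pipeline stage.

The generator builds a toy genome with annotated multi-exon genes (canonical
GT..AG introns on the transcribed strand), plants novel transcript features
of all seven categories with known coordinates, and emits supporting
fragments, tiling-probe panels with intensities, and capture read sets —
each with a machine-readable truth table, so classification, calling and
quantification can be scored against ground truth without any download.

Collision control
-----------------
Planted novel sequence is drawn so that the masker's seed k-mers occur
nowhere else in the fixture (verified, and re-drawn on violation).  In
addition, the few bases flanking each planted junction are constrained so
that a local matcher cannot extend a known-sequence hit across the junction
by chance agreement: fragment bases just inside a novel region are forced to
mismatch the transcript continuation they would otherwise be compared with.
This keeps candidate-segment boundaries exact on noise-free fixtures, which
is what makes planted-truth recovery a sharp oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    GeneModel,
    GenomeSequence,
    TranscriptFragment,
    revcomp,
    transcript_database,
)
from .tiling import ProbePanel

DEFAULT_N_CHROM = 2
DEFAULT_CHROM_LEN = 250_000
DEFAULT_N_GENES = 60
DEFAULT_K_PER_CATEGORY = 5
DEFAULT_FRAG_LEN_MEAN = 700
DEFAULT_READ_LEN_MEAN = 360

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

_GUARD_DEPTH = 8  # junction bases forced to mismatch the transcript continuation


@dataclass
class PlantedFeature:
    category: str
    gene_ids: tuple[str, ...]
    chrom: str
    strand: str
    intervals: list[tuple[int, int]]  # the novel genomic interval(s); exon pair for fusions
    pieces: list[tuple[int, int]]  # transcription-ordered genomic intervals of the supporting fragment
    fragment_ids: list[str] = field(default_factory=list)
    next_exon: tuple[int, int] | None = None  # transcript continuation after the hosting exon


@dataclass
class FixtureTruth:
    planted: list[PlantedFeature]
    seed: int
    expressed_labels: dict[str, bool] = field(default_factory=dict)
    abundances: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "planted": [
                {
                    "category": f.category,
                    "gene_ids": list(f.gene_ids),
                    "chrom": f.chrom,
                    "strand": f.strand,
                    "intervals": [list(iv) for iv in f.intervals],
                    "fragment_ids": f.fragment_ids,
                }
                for f in self.planted
            ],
            "expressed_labels": self.expressed_labels,
            "abundances": self.abundances,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Genome and annotation


def generate_genome_and_genes(
    n_chrom: int = DEFAULT_N_CHROM,
    chrom_len: int = DEFAULT_CHROM_LEN,
    n_genes: int = DEFAULT_N_GENES,
    seed: int = 17,
) -> tuple[GenomeSequence, list[GeneModel]]:
    """Random genome with non-overlapping multi-exon genes on both strands.

    Genes carry 2-6 exons; every annotated intron reads GT..AG on the
    transcribed strand.  Roughly half of the genes with at least three exons
    get a second isoform skipping one internal exon.  Deterministic per seed.
    """
    if n_chrom < 1 or chrom_len < 10_000 or n_genes < 1:
        raise ValueError("parameters must be positive (chrom_len >= 10000)")
    rng = np.random.default_rng([seed, 0])
    chroms = [f"chr{i+1}" for i in range(n_chrom)]
    seqs = {
        c: bytearray(rng.choice(_BASES, size=chrom_len).tobytes()) for c in chroms
    }

    genes: list[GeneModel] = []
    cursors = {c: 3000 for c in chroms}
    ci = 0
    for gi in range(n_genes):
        placed = False
        for _ in range(n_chrom):
            chrom = chroms[ci % n_chrom]
            n_exons = int(rng.integers(2, 7))
            exon_lens = rng.integers(90, 301, n_exons)
            intron_lens = rng.integers(60, 401, max(n_exons - 1, 0))
            span = int(exon_lens.sum() + intron_lens.sum())
            start = cursors[chrom] + int(rng.integers(4000, 6001))
            if start + span > chrom_len - 3000:
                ci += 1
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            exons_genomic = []
            pos = start
            for k in range(n_exons):
                exons_genomic.append((pos, pos + int(exon_lens[k])))
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    intron = (pos, pos + int(intron_lens[k]))
                    _set_splice(seqs[chrom], intron, strand)
                    pos += int(intron_lens[k])
            cursors[chrom] = pos
            ci += 1
            gene_id = f"g{gi+1:03d}"
            tx_exons = exons_genomic if strand == "+" else exons_genomic[::-1]
            transcripts = [(f"{gene_id}.t1", list(range(n_exons)))]
            if n_exons >= 3 and rng.random() < 0.5:
                skip = int(rng.integers(1, n_exons - 1))
                transcripts.append(
                    (f"{gene_id}.t2", [i for i in range(n_exons) if i != skip])
                )
            genes.append(GeneModel(gene_id, chrom, strand, tx_exons, transcripts))
            placed = True
            break
        if not placed:
            raise ValueError(f"requested {n_genes} genes exceed genome capacity (placed {gi})")
    genome = GenomeSequence(chroms, {c: seqs[c].decode() for c in chroms})
    return genome, genes


def _set_splice(seq: bytearray, intron: tuple[int, int], strand: str) -> None:
    """Write canonical donor/acceptor dinucleotides for an intron.

    On the forward strand a plus-gene intron reads GT..AG; a minus-gene
    intron reads CT..AC (the reverse complement of GT..AG).
    """
    s, e = intron
    if strand == "+":
        seq[s : s + 2] = b"GT"
        seq[e - 2 : e] = b"AG"
    else:
        seq[s : s + 2] = b"CT"
        seq[e - 2 : e] = b"AC"


# ---------------------------------------------------------------------------
# Transcribed-strand base accessors


def _tx_pos(iv: tuple[int, int], strand: str, idx: int) -> int:
    s, e = iv
    if idx < 0:
        idx += e - s
    return s + idx if strand == "+" else e - 1 - idx


def _tx_get(seqs: dict[str, bytearray], chrom: str, strand: str, iv: tuple[int, int], idx: int) -> str:
    b = chr(seqs[chrom][_tx_pos(iv, strand, idx)])
    return b if strand == "+" else _COMP[b]


def _tx_set(seqs: dict[str, bytearray], chrom: str, strand: str, iv: tuple[int, int], idx: int, base: str) -> None:
    seqs[chrom][_tx_pos(iv, strand, idx)] = ord(base if strand == "+" else _COMP[base])


def _pick_base(rng: np.random.Generator, forbidden: set[str]) -> str:
    choices = [b for b in "ACGT" if b not in forbidden]
    return choices[int(rng.integers(len(choices)))]


def _guard(
    rng: np.random.Generator,
    seqs: dict[str, bytearray],
    chrom: str,
    strand: str,
    target_iv: tuple[int, int],
    target_idx: int,
    forbidden: set[str],
) -> None:
    cur = _tx_get(seqs, chrom, strand, target_iv, target_idx)
    if cur in forbidden:
        _tx_set(seqs, chrom, strand, target_iv, target_idx, _pick_base(rng, forbidden))


# ---------------------------------------------------------------------------
# Planting novel features


def plant_novel_features(
    genome: GenomeSequence,
    genes: list[GeneModel],
    k_per_category: int = DEFAULT_K_PER_CATEGORY,
    seed: int = 17,
    novel_exon_size: tuple[int, int] = (129, 135),
    kmer_size: int = 16,
) -> tuple[GenomeSequence, FixtureTruth]:
    """Plant k features of each of the seven categories; return mutated fixture.

    Novel exons default to 129-135 bp.  Each feature is assigned to its own
    gene (two genes for a fusion); planted intergenic/intronic sequence is
    verified collision-free at the matcher's seed size and re-drawn when a
    seed k-mer recurs anywhere else in the genome (either strand).
    """
    rng = np.random.default_rng([seed, 1])
    seqs = {c: bytearray(genome.sequences[c], "ascii") for c in genome.chrom_names}
    chrom_len = {c: len(genome.sequences[c]) for c in genome.chrom_names}

    reserved: dict[str, list[tuple[int, int, str]]] = {c: [] for c in genome.chrom_names}
    for g in genes:
        reserved[g.chrom].append((g.start - 30, g.end + 30, g.gene_id))

    def fits(chrom: str, s: int, e: int, owner: str = "") -> bool:
        if s < 50 or e > chrom_len[chrom] - 50:
            return False
        return all(
            max(s, rs) >= min(e, re_) for rs, re_, rid in reserved[chrom] if rid != owner
        )

    used: set[str] = set()
    planted: list[PlantedFeature] = []
    order = list(genes)
    rng.shuffle(order)  # type: ignore[arg-type]

    _plant_fusions(rng, genes, used, planted, k_per_category)
    _plant_internal_novel(rng, seqs, order, used, planted, k_per_category, novel_exon_size)
    _plant_internal_extensions(rng, seqs, order, used, planted, k_per_category)
    for side in ("five_prime", "three_prime"):
        _plant_terminal_novel(rng, seqs, order, used, planted, k_per_category, side, novel_exon_size, reserved, fits)
        _plant_terminal_extensions(rng, order, used, planted, k_per_category, side, reserved, fits)

    _apply_masking_guards(rng, seqs, planted)
    _ensure_collision_free(rng, seqs, planted, kmer_size)

    mutated = GenomeSequence(list(genome.chrom_names), {c: seqs[c].decode() for c in genome.chrom_names})
    return mutated, FixtureTruth(planted, seed)


def _take_gene(order: list[GeneModel], used: set[str], pred) -> GeneModel | None:
    for g in order:
        if g.gene_id not in used and pred(g):
            used.add(g.gene_id)
            return g
    return None


def _plant_fusions(rng, genes, used, planted, k) -> None:
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start))
    n = 0
    for a, b in zip(ordered, ordered[1:]):
        if n >= k:
            break
        if a.chrom != b.chrom or a.strand != b.strand:
            continue
        if a.gene_id in used or b.gene_id in used:
            continue
        used.update((a.gene_id, b.gene_id))
        if a.strand == "+":
            up, down = a, b  # transcription runs left to right
        else:
            up, down = b, a
        last_exon = up.exons[-1]  # transcription-last exon of the upstream gene
        first_exon = down.exons[0]
        planted.append(
            PlantedFeature(
                "gene_fusion",
                tuple(sorted((a.gene_id, b.gene_id))),
                a.chrom,
                a.strand,
                [tuple(sorted(last_exon)), tuple(sorted(first_exon))],
                [last_exon, first_exon],
            )
        )
        n += 1
    if n < k:
        raise ValueError(f"cannot plant {k} gene_fusion features: only {n} adjacent same-strand gene pairs")


def _genomic_introns(g: GeneModel) -> list[tuple[int, int]]:
    ex = g.exons_genomic
    return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


def _plant_internal_novel(rng, seqs, order, used, planted, k, size_range) -> None:
    n = 0
    for _ in range(k):
        L = int(rng.integers(size_range[0], size_range[1] + 1))

        def ok(g: GeneModel) -> bool:
            return len(g.transcripts) == 1 and any(ie - is_ >= L + 100 for is_, ie in _genomic_introns(g))

        g = _take_gene(order, used, ok)
        if g is None:
            break
        intron = next(iv for iv in _genomic_introns(g) if iv[1] - iv[0] >= L + 100)
        istart, iend = intron
        ns = istart + (iend - istart - L) // 2
        niv = (ns, ns + L)
        _set_splice(seqs[g.chrom], (istart, ns), g.strand)
        _set_splice(seqs[g.chrom], (ns + L, iend), g.strand)
        # transcription-ordered neighbours of the planted exon
        if g.strand == "+":
            e_before = next(e for e in g.exons if e[1] == istart)
            e_after = next(e for e in g.exons if e[0] == iend)
        else:
            e_before = next(e for e in g.exons if e[0] == iend)
            e_after = next(e for e in g.exons if e[1] == istart)
        planted.append(
            PlantedFeature(
                "internal_novel_exon", (g.gene_id,), g.chrom, g.strand,
                [niv], [e_before, niv, e_after],
            )
        )
        n += 1
    if n < k:
        raise ValueError(f"cannot plant {k} internal_novel_exon features (placed {n})")


def _plant_internal_extensions(rng, seqs, order, used, planted, k) -> None:
    n = 0
    for _ in range(k):
        L = int(rng.integers(40, 121))

        def ok(g: GeneModel) -> bool:
            if len(g.transcripts) != 1 or len(g.exons) < 3:
                return False
            return _internal_ext_site(g, L) is not None

        g = _take_gene(order, used, ok)
        if g is None:
            break
        exon, nxt, ext = _internal_ext_site(g, L)
        planted.append(
            PlantedFeature(
                "internal_extension", (g.gene_id,), g.chrom, g.strand, [ext], [exon, ext],
                next_exon=nxt,
            )
        )
        n += 1
    if n < k:
        raise ValueError(f"cannot plant {k} internal_extension features (placed {n})")


def _internal_ext_site(g: GeneModel, L: int):
    """An internal exon whose transcription-next intron can host an L bp extension."""
    for j in range(1, len(g.exons) - 1):
        exon, nxt = g.exons[j], g.exons[j + 1]
        if g.strand == "+":
            ilen = nxt[0] - exon[1]
            ext = (exon[1], exon[1] + L)
        else:
            ilen = exon[0] - nxt[1]
            ext = (exon[0] - L, exon[0])
        if ilen >= L + 50:
            return exon, nxt, ext
    return None


def _plant_terminal_novel(rng, seqs, order, used, planted, k, side, size_range, reserved, fits) -> None:
    category = f"{side}_novel_exon"
    n = 0
    for _ in range(k):
        g = _take_gene(order, used, lambda g: True)
        if g is None:
            break
        done = False
        for _try in range(40):
            L = int(rng.integers(size_range[0], size_range[1] + 1))
            gap = int(rng.integers(150, 801))
            iv, intron = _terminal_site(g, side, L, gap)
            lo = min(iv[0], intron[0])
            hi = max(iv[1], intron[1])
            if not fits(g.chrom, lo, hi, owner=g.gene_id):
                continue
            _set_splice(seqs[g.chrom], intron, g.strand)
            reserved[g.chrom].append((lo - 20, hi + 20, g.gene_id))
            pieces = [iv, g.exons[0], g.exons[1]] if side == "five_prime" else [g.exons[-2], g.exons[-1], iv]
            planted.append(PlantedFeature(category, (g.gene_id,), g.chrom, g.strand, [iv], pieces))
            done = True
            break
        if not done:
            raise ValueError(f"cannot place a {category} next to {g.gene_id}")
        n += 1
    if n < k:
        raise ValueError(f"cannot plant {k} {category} features (placed {n})")


def _terminal_site(g: GeneModel, side: str, L: int, gap: int):
    """Novel-exon interval and its intron for a terminal feature."""
    upstream = (side == "five_prime") == (g.strand == "+")
    if upstream:  # genomically left of the gene
        iv = (g.start - gap - L, g.start - gap)
        intron = (g.start - gap, g.start)
    else:  # genomically right
        iv = (g.end + gap, g.end + gap + L)
        intron = (g.end, g.end + gap)
    return iv, intron


def _plant_terminal_extensions(rng, order, used, planted, k, side, reserved, fits) -> None:
    category = f"{side}_extension"
    n = 0
    for _ in range(k):
        g = _take_gene(order, used, lambda g: True)
        if g is None:
            break
        done = False
        for _try in range(40):
            L = int(rng.integers(60, 151))
            upstream = (side == "five_prime") == (g.strand == "+")
            iv = (g.start - L, g.start) if upstream else (g.end, g.end + L)
            if not fits(g.chrom, iv[0], iv[1], owner=g.gene_id):
                continue
            reserved[g.chrom].append((iv[0] - 20, iv[1] + 20, g.gene_id))
            pieces = [iv, g.exons[0], g.exons[1]] if side == "five_prime" else [g.exons[-2], g.exons[-1], iv]
            planted.append(PlantedFeature(category, (g.gene_id,), g.chrom, g.strand, [iv], pieces))
            done = True
            break
        if not done:
            raise ValueError(f"cannot place a {category} next to {g.gene_id}")
        n += 1
    if n < k:
        raise ValueError(f"cannot plant {k} {category} features (placed {n})")


def _apply_masking_guards(rng, seqs, planted: list[PlantedFeature]) -> None:
    """Forbid chance agreement between novel sequence and transcript context.

    A local matcher masking the known part of a supporting fragment compares
    bases beyond the junction against the transcript's continuation; if those
    happened to agree the masked interval would overrun the junction.  The
    first/last _GUARD_DEPTH transcribed bases of each planted internal
    feature are therefore forced to differ from the corresponding transcript
    bases (the first junction base additionally avoids the donor G).
    """
    for f in planted:
        chrom, strand = f.chrom, f.strand
        if f.category == "internal_novel_exon":
            e_before, niv, e_after = f.pieces
            for i in range(_GUARD_DEPTH):
                forb = {_tx_get(seqs, chrom, strand, e_after, i)}
                if i == 0:
                    forb.add("G")
                _guard(rng, seqs, chrom, strand, niv, i, forb)
                forb_l = {_tx_get(seqs, chrom, strand, e_before, -1 - i)}
                if i == 0:
                    forb_l.add("G")
                _guard(rng, seqs, chrom, strand, niv, -1 - i, forb_l)
        elif f.category == "internal_extension":
            _exon, ext = f.pieces
            nxt = f.next_exon
            _guard(rng, seqs, chrom, strand, nxt, 0, {"G"})
            for i in range(2, _GUARD_DEPTH + 2):
                forb = {_tx_get(seqs, chrom, strand, nxt, i)}
                _guard(rng, seqs, chrom, strand, ext, i, forb)


def _ensure_collision_free(rng, seqs, planted: list[PlantedFeature], k: int) -> None:
    """Re-draw planted novel sequence until no seed k-mer recurs elsewhere."""
    novel = [
        (f, iv)
        for f in planted
        for iv in f.intervals
        if f.category != "gene_fusion"
    ]
    for _attempt in range(12):
        counts: dict[str, int] = {}
        for c, seq in seqs.items():
            text = seq.decode()
            for i in range(len(text) - k + 1):
                kmer = text[i : i + k]
                counts[kmer] = counts.get(kmer, 0) + 1
        bad = []
        for f, iv in novel:
            text = seqs[f.chrom].decode()
            sub = text[iv[0] : iv[1]]
            collide = any(
                counts.get(sub[i : i + k], 0) > 1 or counts.get(revcomp(sub[i : i + k]), 0) > 0
                for i in range(len(sub) - k + 1)
            )
            if collide:
                bad.append((f, iv))
        if not bad:
            return
        for f, iv in bad:
            lo = iv[0] + (2 if f.category == "internal_extension" else 0)
            fresh = rng.choice(_BASES, size=iv[1] - lo).tobytes()
            seqs[f.chrom][lo : iv[1]] = fresh
        _apply_masking_guards(rng, seqs, planted)
    raise RuntimeError("could not draw collision-free novel sequence")


# ---------------------------------------------------------------------------
# Fragments


def _piece_seq(genome: GenomeSequence, chrom: str, strand: str, iv: tuple[int, int]) -> str:
    s = genome.fetch(chrom, iv[0], iv[1])
    return s if strand == "+" else revcomp(s)


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    n_err = rng.binomial(len(arr), rate)
    for pos in rng.choice(len(arr), size=n_err, replace=False):
        arr[pos] = _pick_base(rng, {arr[pos]})
    return "".join(arr)


def simulate_fragments(
    genome: GenomeSequence,
    genes: list[GeneModel],
    truth: FixtureTruth,
    n_background: int = 200,
    frag_len_mean: float = DEFAULT_FRAG_LEN_MEAN,
    read_len_mean: float = DEFAULT_READ_LEN_MEAN,
    coverage: int = 2,
    error_rate: float = 0.0,
    seed: int = 17,
) -> list[TranscriptFragment]:
    """Supporting fragments for every planted feature plus background reads.

    Each truth feature is covered by ``coverage`` fragments spanning its novel
    and flanking annotated sequence; background fragments are windows of
    annotated transcripts (isotig-sized around ``frag_len_mean``, with a
    singleton-sized minority around ``read_len_mean``).  Half of all
    fragments are emitted reverse-complemented, as sequencing orientation is
    arbitrary.  Substitution errors are applied at ``error_rate``.
    """
    rng = np.random.default_rng([seed, 2])
    fragments: list[TranscriptFragment] = []
    for fi, f in enumerate(truth.planted):
        base = "".join(_piece_seq(genome, f.chrom, f.strand, iv) for iv in f.pieces)
        f.fragment_ids = []
        for c in range(coverage):
            fid = f"{f.category}_{fi:03d}_c{c}"
            seq = _add_errors(rng, base, error_rate)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            fragments.append(TranscriptFragment(fid, seq, "isotig"))
            f.fragment_ids.append(fid)

    db = transcript_database(genes, genome)
    tids = sorted(db)
    for i in range(n_background):
        tid = tids[int(rng.integers(len(tids)))]
        seq = db[tid][1]
        singleton = rng.random() < 0.3
        mean = read_len_mean if singleton else frag_len_mean
        length = int(np.clip(rng.normal(mean, mean * 0.2), 60, len(seq)))
        start = int(rng.integers(0, len(seq) - length + 1))
        sub = _add_errors(rng, seq[start : start + length], error_rate)
        if rng.random() < 0.5:
            sub = revcomp(sub)
        kind = "singleton" if singleton else "isotig"
        fragments.append(TranscriptFragment(f"bg_{i:04d}", sub, kind))
    return fragments


# ---------------------------------------------------------------------------
# Tiling-probe panels


def simulate_probe_panel(
    genome: GenomeSequence,
    genes: list[GeneModel],
    expressed_labels: dict[str, bool],
    n_random: int = 2000,
    snr: float = 3.0,
    gc_bias: float = 0.0,
    n_replicates: int = 3,
    probe_len: int = 50,
    spacing: int = 33,
    baseline_log2: float = 8.0,
    seed: int = 17,
) -> ProbePanel:
    """Probe panel with log-normal intensities and known expression labels.

    Probes tile every exon at ``spacing`` bp; random probes form the null.
    Null log2 intensity ~ Normal(baseline, 1); probes of expressed genes are
    shifted up by ``snr`` log2 units.  An optional linear GC bias
    (``gc_bias`` log2 units per GC base) is injected to exercise the GC
    correction.
    """
    if snr < 0:
        raise ValueError("snr must be >= 0")
    rng = np.random.default_rng([seed, 3])
    rows = []
    for g in genes:
        for ei, (s, e) in enumerate(g.exons):
            pos = s
            while pos + probe_len <= e:
                seq = genome.fetch(g.chrom, pos, pos + probe_len)
                rows.append(
                    {
                        "probe_id": f"p_{g.gene_id}_{ei}_{pos}",
                        "chrom": g.chrom,
                        "start": pos,
                        "length": probe_len,
                        "gc_count": seq.count("G") + seq.count("C"),
                        "is_random": False,
                        "gene_id": g.gene_id,
                        "exon_index": ei,
                    }
                )
                pos += spacing
    for i in range(n_random):
        rows.append(
            {
                "probe_id": f"r_{i:05d}",
                "chrom": "random",
                "start": i * 100,
                "length": probe_len,
                "gc_count": int(rng.binomial(probe_len, 0.5)),
                "is_random": True,
                "gene_id": None,
                "exon_index": -1,
            }
        )
    probes = pd.DataFrame(rows)

    gc = probes["gc_count"].to_numpy(dtype=float)
    shift = np.array(
        [
            snr if (not r.is_random and expressed_labels.get(r.gene_id, False)) else 0.0
            for r in probes.itertuples(index=False)
        ]
    )
    log2 = (
        baseline_log2
        + shift[None, :]
        + gc_bias * gc[None, :]
        + rng.normal(0.0, 1.0, size=(n_replicates, len(probes)))
    )
    return ProbePanel(probes, 2.0**log2)


# ---------------------------------------------------------------------------
# Capture read sets for quantification


def simulate_quant_reads(
    transcripts: dict[str, str],
    abundances: dict[str, float],
    n_reads: int,
    untargeted_ids: set[str] = frozenset(),
    read_len_mean: float = DEFAULT_READ_LEN_MEAN,
    error_rate: float = 0.0,
    seed: int = 17,
) -> tuple[dict[str, str], dict[str, int]]:
    """Multinomial read sampling with capture exclusion.

    Transcripts in ``untargeted_ids`` receive zero reads — emulating genes
    absent from the capture design — and the remaining abundance mass is
    renormalized.  Returns (reads, truth counts).
    """
    total = sum(abundances.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"abundances must sum to 1 (got {total:g})")
    rng = np.random.default_rng([seed, 4])
    tids = sorted(transcripts)
    probs = np.array(
        [0.0 if t in untargeted_ids else abundances.get(t, 0.0) for t in tids]
    )
    if probs.sum() <= 0:
        raise ValueError("no targeted transcript has positive abundance")
    probs /= probs.sum()
    counts = rng.multinomial(n_reads, probs)
    reads: dict[str, str] = {}
    truth = {t: int(c) for t, c in zip(tids, counts)}
    r = 0
    for tid, c in zip(tids, counts):
        seq = transcripts[tid]
        for _ in range(c):
            length = int(np.clip(rng.normal(read_len_mean, read_len_mean * 0.15), 40, len(seq)))
            start = int(rng.integers(0, len(seq) - length + 1))
            reads[f"read_{r:06d}"] = _add_errors(rng, seq[start : start + length], error_rate)
            r += 1
    return reads, truth


# ---------------------------------------------------------------------------
# Full fixture


@dataclass
class Fixture:
    genome: GenomeSequence
    genes: list[GeneModel]
    truth: FixtureTruth
    fragments: list[TranscriptFragment]


def paperlike_fixture(
    seed: int = 17,
    n_chrom: int = DEFAULT_N_CHROM,
    chrom_len: int = DEFAULT_CHROM_LEN,
    n_genes: int = DEFAULT_N_GENES,
    k_per_category: int = DEFAULT_K_PER_CATEGORY,
    n_background: int = 200,
    coverage: int = 2,
    error_rate: float = 0.0,
) -> Fixture:
    """The default desk-scale fixture: planted features of all 7 categories."""
    genome, genes = generate_genome_and_genes(n_chrom, chrom_len, n_genes, seed)
    genome, truth = plant_novel_features(genome, genes, k_per_category, seed)
    fragments = simulate_fragments(
        genome, genes, truth, n_background=n_background, coverage=coverage,
        error_rate=error_rate, seed=seed,
    )
    return Fixture(genome, genes, truth, fragments)
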