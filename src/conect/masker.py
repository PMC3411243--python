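"""Round-1 screening: mask fragments against the known-transcript database.

Each assembled fragment is compared, in both orientations, against every
known spliced transcript with a seed-and-extend local matcher (exact k-mer
seeds, ungapped x-drop extension).  Regions of the fragment covered by a
sufficiently long, sufficiently identical hit are *masked*; whatever is left
unmasked — at the 5' end, the 3' end, or internal to masked sequence — is a
potential novel transcribed region and is handed to round 2.

The matcher is deliberately simple: no gaps, no repeat library.  At the
scales this package targets (collision-free synthetic fixtures, modest
fragment sets) it recovers exact and near-exact matches, and isolated
substitutions are bridged by the x-drop extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .datamodel import TranscriptFragment, revcomp

logger = logging.getLogger(__name__)

DEFAULT_KMER = 16
DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MIN_HIT_LEN = 20
DEFAULT_MIN_TERMINAL_LEN = 10

_MATCH = 1
_MISMATCH = -3
_XDROP = 10


@dataclass(frozen=True)
class Hit:
    """One ungapped local alignment between a query and a target sequence."""

    target_id: str
    qstart: int
    qend: int
    tstart: int
    tend: int
    matches: int

    @property
    def length(self) -> int:
        return self.qend - self.qstart

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0


class KmerIndex:
    """Exact k-mer lookup over a set of named sequences."""

    def __init__(self, sequences: dict[str, str], k: int = DEFAULT_KMER):
        self.k = k
        self.sequences = sequences
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in sequences.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((name, i))

    def find_hits(
        self,
        query: str,
        min_identity: float = DEFAULT_MIN_IDENTITY,
        min_hit_len: int = DEFAULT_MIN_HIT_LEN,
    ) -> list[Hit]:
        """All seeded, extended hits of ``query`` against the index."""
        k = self.k
        hits: list[Hit] = []
        # per (target, diagonal): query end already explored, to skip redundant seeds
        explored: dict[tuple[str, int], int] = {}
        for qpos in range(len(query) - k + 1):
            seeds = self.index.get(query[qpos : qpos + k])
            if not seeds:
                continue
            for target_id, tpos in seeds:
                diag = qpos - tpos
                if explored.get((target_id, diag), -1) >= qpos:
                    continue
                target = self.sequences[target_id]
                qs, qe, ts, te, matches = _extend(query, target, qpos, tpos, k)
                explored[(target_id, diag)] = qe
                if qe - qs >= min_hit_len and matches / (qe - qs) >= min_identity:
                    hits.append(Hit(target_id, qs, qe, ts, te, matches))
        return hits


def _extend(query: str, target: str, qpos: int, tpos: int, k: int) -> tuple[int, int, int, int, int]:
    """Ungapped x-drop extension of a seed in both directions.

    Returns the trimmed-to-best-score alignment (qstart, qend, tstart, tend,
    matches).  Isolated mismatches are crossed; runs of mismatches whose score
    penalty exceeds the x-drop terminate the extension.
    """
    # right of the seed
    score = best = k * _MATCH
    best_off = 0
    off = 0
    while qpos + k + off < len(query) and tpos + k + off < len(target):
        score += _MATCH if query[qpos + k + off] == target[tpos + k + off] else _MISMATCH
        off += 1
        if score > best:
            best, best_off = score, off
        elif best - score > _XDROP:
            break
    qend, tend = qpos + k + best_off, tpos + k + best_off

    # left of the seed
    score = best
    lbest = score
    best_off = 0
    off = 0
    while qpos - off - 1 >= 0 and tpos - off - 1 >= 0:
        score += _MATCH if query[qpos - off - 1] == target[tpos - off - 1] else _MISMATCH
        off += 1
        if score > lbest:
            lbest, best_off = score, off
        elif lbest - score > _XDROP:
            break
    qstart, tstart = qpos - best_off, tpos - best_off

    matches = sum(1 for a, b in zip(query[qstart:qend], target[tstart:tend]) if a == b)
    return qstart, qend, tstart, tend, matches


# ---------------------------------------------------------------------------
# Masking


@dataclass
class MaskResult:
    """Outcome of masking one fragment against the transcript database.

    All coordinates refer to the *oriented* sequence: the fragment orientation
    (``+`` as given, ``-`` reverse-complemented) with the greater total masked
    length.  Masked and unmasked intervals tile the fragment exactly.
    """

    fragment_id: str
    length: int
    orientation: str
    sequence: str
    masked_intervals: list[tuple[int, int, tuple[str, ...]]] = field(default_factory=list)
    unmasked_segments: list[tuple[tuple[int, int], str]] = field(default_factory=list)

    @property
    def status(self) -> str:
        if not self.unmasked_segments:
            return "fully_masked"
        if not self.masked_intervals:
            return "fully_unmasked"
        return "partially_masked"

    @property
    def masked_gene_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for _, _, gids in self.masked_intervals:
            for g in gids:
                if g not in out:
                    out.append(g)
        return tuple(out)


@dataclass
class CandidateSegment:
    """An unmasked region selected for round-2 genomic screening."""

    fragment_id: str
    start: int
    end: int
    position_class: str  # end5 | end3 | internal
    flanking_genes: tuple[str, ...]
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


class TranscriptMasker:
    """Masks fragments against spliced known-transcript sequences."""

    def __init__(
        self,
        transcript_db: dict[str, tuple[str, str]],
        kmer_size: int = DEFAULT_KMER,
        min_identity: float = DEFAULT_MIN_IDENTITY,
        min_hit_len: int = DEFAULT_MIN_HIT_LEN,
    ):
        if not transcript_db:
            raise ValueError("transcript database is empty")
        self.gene_of = {tid: gid for tid, (gid, _) in transcript_db.items()}
        self.index = KmerIndex({tid: seq for tid, (_, seq) in transcript_db.items()}, k=kmer_size)
        self.min_identity = min_identity
        self.min_hit_len = min_hit_len

    def mask(self, fragment: TranscriptFragment) -> MaskResult:
        """Mask one fragment; the better-masked orientation is retained."""
        per_orient = {}
        for orient, seq in (("+", fragment.sequence), ("-", revcomp(fragment.sequence))):
            hits = self.index.find_hits(seq, self.min_identity, self.min_hit_len)
            merged = _merge_hits(hits, self.gene_of)
            per_orient[orient] = (seq, merged, sum(e - s for s, e, _ in merged))
        # greater total masked length wins; ties go to forward
        orient = "+" if per_orient["+"][2] >= per_orient["-"][2] else "-"
        seq, merged, _total = per_orient[orient]
        unmasked = _complement_segments(merged, len(seq))
        return MaskResult(fragment.fragment_id, len(seq), orient, seq, merged, unmasked)


def _merge_hits(hits: list[Hit], gene_of: dict[str, str]) -> list[tuple[int, int, tuple[str, ...]]]:
    """Union of hit intervals on the fragment; contributing genes recorded."""
    if not hits:
        return []
    spans = sorted((h.qstart, h.qend, gene_of[h.target_id]) for h in hits)
    merged: list[list] = []
    for s, e, gid in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            if gid not in merged[-1][2]:
                merged[-1][2].append(gid)
        else:
            merged.append([s, e, [gid]])
    return [(s, e, tuple(g)) for s, e, g in merged]


def _complement_segments(
    masked: list[tuple[int, int, tuple[str, ...]]], length: int
) -> list[tuple[tuple[int, int], str]]:
    """Unmasked intervals with positional class (end5/end3/internal).

    A fully unmasked fragment yields one whole-read segment, classed ``end5``
    by convention (it touches both termini).
    """
    segments = []
    prev = 0
    for s, e, _ in masked:
        if s > prev:
            segments.append((prev, s))
        prev = e
    if prev < length:
        segments.append((prev, length))
    out = []
    for s, e in segments:
        if s == 0:
            cls = "end5"
        elif e == length:
            cls = "end3"
        else:
            cls = "internal"
        out.append(((s, e), cls))
    return out


def select_candidates(
    result: MaskResult, min_terminal_len: int = DEFAULT_MIN_TERMINAL_LEN
) -> list[CandidateSegment]:
    """Apply the candidate-selection rule to a mask result.

    Terminal unmasked segments are kept only when strictly longer than
    ``min_terminal_len`` (default 10 bp); internal segments are always kept.
    Fully masked fragments yield nothing.
    """
    candidates = []
    for (s, e), cls in result.unmasked_segments:
        if cls in ("end5", "end3") and (e - s) <= min_terminal_len:
            continue
        flanking = tuple(
            g
            for ms, me, gids in result.masked_intervals
            if me == s or ms == e
            for g in gids
        )
        candidates.append(
            CandidateSegment(result.fragment_id, s, e, cls, flanking, result.sequence[s:e])
        )
    return candidates
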