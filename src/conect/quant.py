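"""Read quantification and capture-enrichment statistics.

Covers best-match read assignment, FPKM per transcript and per gene
(collapsing alternative isoforms onto the exon-union length), the
length-normalized binomial depletion test for untargeted transcripts,
set-concordance reporting between expressed-gene calls, and the
quadratic-versus-linear "compression" fit comparing log-expression scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneModel, revcomp
from .masker import KmerIndex


# ---------------------------------------------------------------------------
# Best-match read assignment


def assign_reads(
    reads: dict[str, str],
    transcripts: dict[str, str],
    kmer_size: int = 16,
    min_identity: float = 0.95,
    min_hit_len: int = 20,
) -> tuple[dict[str, int], int, dict[str, str | None]]:
    """Assign each read to its best-matching transcript.

    Every read contributes to exactly one transcript — the one with the
    highest alignment score over both read orientations — or to the
    unassigned pool when nothing matches.  Score ties (e.g. duplicated
    transcripts with identical sequence) are broken by lexicographically
    smallest transcript id, so no read is ever discarded for being ambiguous.

    Returns (counts per transcript, n_unassigned, per-read assignment).
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    index = KmerIndex(dict(transcripts), k=kmer_size)
    counts = {tid: 0 for tid in transcripts}
    assignment: dict[str, str | None] = {}
    unassigned = 0
    for read_id, seq in reads.items():
        best_tid, best_score = None, 0
        for oriented in (seq, revcomp(seq)):
            per_tid: dict[str, int] = {}
            for h in index.find_hits(oriented, min_identity, min_hit_len):
                per_tid[h.target_id] = per_tid.get(h.target_id, 0) + h.matches
            for tid, score in per_tid.items():
                if score > best_score or (score == best_score and best_tid is not None and tid < best_tid):
                    best_tid, best_score = tid, score
        assignment[read_id] = best_tid
        if best_tid is None:
            unassigned += 1
        else:
            counts[best_tid] += 1
    return counts, unassigned, assignment


# ---------------------------------------------------------------------------
# FPKM


@dataclass
class TranscriptQuant:
    transcript_id: str
    gene_id: str
    length: int
    read_count: int
    fpkm: float


def compute_fpkm(
    counts: dict[str, int],
    lengths: dict[str, int],
    total_mapped: int,
    gene_of: dict[str, str] | None = None,
) -> list[TranscriptQuant]:
    """FPKM per transcript: count x 1e9 / (length x total mapped reads)."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    quants = []
    for tid, count in counts.items():
        length = lengths[tid]
        if length <= 0:
            raise ValueError(f"{tid}: non-positive length")
        fpkm = count * 1e9 / (length * total_mapped)
        quants.append(TranscriptQuant(tid, gene_of.get(tid, tid) if gene_of else tid, length, count, fpkm))
    return quants


def collapse_to_gene(
    quants: list[TranscriptQuant], genes: list[GeneModel], total_mapped: int
) -> pd.DataFrame:
    """Gene-level FPKM: counts summed over isoforms, exon-union length.

    Collapsing alternative transcripts into one gene avoids double counting;
    the effective gene length is the length of the union of all its exons.
    """
    by_gene: dict[str, int] = {}
    for q in quants:
        by_gene[q.gene_id] = by_gene.get(q.gene_id, 0) + q.read_count
    union_len = {g.gene_id: g.exon_union_length() for g in genes}
    rows = []
    for gid, count in sorted(by_gene.items()):
        length = union_len.get(gid)
        if length is None:  # transcript without a model: fall back to longest isoform
            length = max(q.length for q in quants if q.gene_id == gid)
        rows.append(
            {"gene_id": gid, "length": length, "read_count": count,
             "fpkm": count * 1e9 / (length * total_mapped)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Depletion test


@dataclass
class DepletionTestResult:
    """Binomial test for a transcript depleted of reads by capture exclusion."""

    target_id: str
    observed: int
    n: int
    p: float  # length share of the target under the random-distribution null
    p_value: float
    median_n: int
    median_p_value: float


def depletion_test(
    counts: dict[str, int], lengths: dict[str, int], target_id: str
) -> DepletionTestResult:
    """Is the target transcript's read count lower than length-share chance?

    Under the null, reads distribute among all transcripts in proportion to
    transcript length, so the target's success probability is its relative
    length p = L_target / sum(L).  The p-value is the lower binomial tail
    P[Bin(n, p) <= observed] with n the total read count.  A second, variance
    -robust variant replaces n with (number of transcripts) x the median read
    count of the other transcripts, guarding against uneven capture efficacy.
    """
    if target_id not in counts:
        raise KeyError(f"target {target_id} not in count table")
    if len(counts) < 2:
        raise ValueError("need >= 2 transcripts")
    total_len = sum(lengths[t] for t in counts)
    p = lengths[target_id] / total_len
    if not (0.0 < p < 1.0):
        raise ValueError("target length share must lie strictly inside (0,1)")
    n = sum(counts.values())
    if n < 1:
        return DepletionTestResult(target_id, 0, 0, p, 1.0, 0, 1.0)
    observed = counts[target_id]
    p_value = float(stats.binom.cdf(observed, n, p))
    others = [c for t, c in counts.items() if t != target_id]
    median_n = int(round(float(np.median(others)) * len(counts)))
    median_p = float(stats.binom.cdf(observed, median_n, p)) if median_n >= 1 else 1.0
    return DepletionTestResult(target_id, observed, n, p, p_value, median_n, median_p)


# ---------------------------------------------------------------------------
# Concordance between expressed-gene sets


@dataclass
class ConcordanceReport:
    size_a: int
    size_b: int
    size_intersection: int
    pct_a_in_b: float | str
    pct_b_in_a: float | str
    a_only: list[str]
    b_only: list[str]


def concordance(called_a: set[str], called_b: set[str]) -> ConcordanceReport:
    """Overlap percentages between two expressed-gene sets (2-decimal)."""
    inter = called_a & called_b

    def pct(whole: set[str]) -> float | str:
        return round(100.0 * len(inter) / len(whole), 2) if whole else "NA"

    return ConcordanceReport(
        len(called_a), len(called_b), len(inter),
        pct(called_a), pct(called_b),
        sorted(called_a - called_b), sorted(called_b - called_a),
    )


# ---------------------------------------------------------------------------
# Quadratic-vs-linear compression fit


@dataclass
class CompressionFitResult:
    coef_linear: float
    coef_quadratic: float
    p_quadratic: float
    compression: bool  # negative quadratic term: high values compressed


def compression_fit(
    x: np.ndarray, y: np.ndarray, transform: str | None = "log10p1"
) -> CompressionFitResult:
    """Test whether y bends away from a straight line in x.

    Fits y ~ x and y ~ x + x^2 by ordinary least squares and reports the
    standard nested test on the quadratic coefficient (the t test, equivalent
    to the one-extra-parameter F test).  A significantly *negative* quadratic
    term means highly expressed genes are under-represented relative to a
    proportional response — the compression signature of capture sequencing.

    With the default transform both inputs are mapped through log10(1+v)
    first; pass ``transform=None`` for already-log-scaled data.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if transform == "log10p1":
        x, y = np.log10(1 + x), np.log10(1 + y)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 10:
        raise ValueError("need >= 10 paired finite observations")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    design = sm.add_constant(np.column_stack([x, x**2]))
    fit = sm.OLS(y, design).fit()
    coef_lin, coef_quad = float(fit.params[1]), float(fit.params[2])
    p_quad = float(fit.pvalues[2])
    return CompressionFitResult(coef_lin, coef_quad, p_quad, coef_quad < 0 and p_quad < 0.05)
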