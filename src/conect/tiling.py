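"""Tiling-array expression calling.

The processing order is fixed: GC correction (against the random-probe null)
→ quantile normalization across replicates → median filtering along the
genomic probe order → background thresholding at a target false discovery
rate → gene-level present/absent calls.

Random probes — array features with no genomic target — serve as the
empirical null throughout: they define the per-GC-bin correction, the FDR
threshold, and the constant subtracted when writing signal tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GeneModel

logger = logging.getLogger(__name__)

DEFAULT_FDR_Q = 0.02
DEFAULT_PRESENT_FRAC = 0.70
DEFAULT_SUBTRACTION_PERCENTILE = 0.98
MIN_RANDOM_PROBES = 100


@dataclass
class ProbePanel:
    """Tiling probes plus a replicate x probe intensity matrix.

    ``probes`` columns: probe_id, chrom, start, length, gc_count, is_random,
    gene_id, exon_index.  ``intensities`` has shape (n_replicates, n_probes),
    column i corresponding to ``probes`` row i; values are positive
    fluorescence units.
    """

    probes: pd.DataFrame
    intensities: np.ndarray
    replicate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != len(self.probes):
            raise ValueError("intensity matrix shape does not match probe table")
        if np.isnan(self.intensities).any():
            raise ValueError("intensity matrix has missing cells")
        if not self.replicate_names:
            self.replicate_names = [f"rep{i+1}" for i in range(self.intensities.shape[0])]
        genic = ~self.probes["is_random"].to_numpy()
        if self.probes.loc[genic, "gene_id"].isna().any():
            raise ValueError("genic probe without gene link")

    @property
    def n_replicates(self) -> int:
        return self.intensities.shape[0]

    @property
    def is_random(self) -> np.ndarray:
        return self.probes["is_random"].to_numpy()

    @classmethod
    def from_tables(cls, probe_df: pd.DataFrame, intensity_df: pd.DataFrame) -> "ProbePanel":
        order = {pid: i for i, pid in enumerate(probe_df["probe_id"])}
        intensity_df = intensity_df.sort_values("probe_id", key=lambda s: s.map(order))
        reps = [c for c in intensity_df.columns if c != "probe_id"]
        return cls(probe_df.reset_index(drop=True), intensity_df[reps].to_numpy().T, reps)

    def with_intensities(self, intensities: np.ndarray) -> "ProbePanel":
        return ProbePanel(self.probes, intensities, list(self.replicate_names))


# ---------------------------------------------------------------------------
# GC correction


def gc_correct(panel: ProbePanel) -> ProbePanel:
    """Remove GC-dependent intensity bias using the random-probe null.

    Within each exact GC-count bin, the median log2 intensity of the bin's
    random probes is subtracted from every probe in the bin (the grand random
    median is added back so the overall scale is preserved).  Bins with no
    random probes borrow the nearest populated bin.  Within-bin rank order is
    untouched — the correction is a per-bin constant shift.
    """
    rand = panel.is_random
    if not rand.any():
        raise ValueError("GC correction requires random probes")
    gc = panel.probes["gc_count"].to_numpy()
    log2 = np.log2(panel.intensities)
    corrected = np.empty_like(log2)
    for r in range(panel.n_replicates):
        rand_log = log2[r, rand]
        grand = np.median(rand_log)
        populated = np.unique(gc[rand])
        bin_median = {b: np.median(rand_log[gc[rand] == b]) for b in populated}
        for b in np.unique(gc):
            if b in bin_median:
                med = bin_median[b]
            else:
                nearest = populated[np.argmin(np.abs(populated - b))]
                med = bin_median[nearest]
                logger.warning("GC bin %d has no random probes; borrowing bin %d", b, nearest)
            sel = gc == b
            corrected[r, sel] = log2[r, sel] - med + grand
    return panel.with_intensities(2.0 ** corrected)


# ---------------------------------------------------------------------------
# Quantile normalization


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force every replicate onto the mean order-statistic distribution.

    After normalization the sorted values of each row are identical and equal
    to the across-replicate mean of order statistics; ties within a row are
    averaged.  Rank order within each replicate is preserved.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("quantile normalization needs >=2 replicates")
    from scipy.stats import rankdata

    reference = np.sort(matrix, axis=1).mean(axis=0)
    n = matrix.shape[1]
    out = np.empty_like(matrix)
    for r in range(matrix.shape[0]):
        ranks = rankdata(matrix[r], method="average")  # 1..n, fractional on ties
        out[r] = np.interp(ranks, np.arange(1, n + 1), reference)
    return out


# ---------------------------------------------------------------------------
# Median filtering along the genomic probe order


def _genomic_order(chroms: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.lexsort((starts, chroms))


def median_filter(
    matrix: np.ndarray,
    chroms: np.ndarray,
    starts: np.ndarray,
    cross_replicate: bool = True,
) -> np.ndarray:
    """Sliding window-of-three median along each chromosome.

    With ``cross_replicate`` the window pools all replicates (a 3x3 window of
    nine values, reduced to one value per probe); otherwise each replicate is
    filtered independently (three-value windows, matrix out).  Windows are
    truncated at chromosome boundaries, never bridged.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    order = _genomic_order(chroms, starts)
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    sorted_chroms = chroms[order]
    sorted_vals = matrix[:, order]

    n = len(order)
    if cross_replicate:
        out_sorted = np.empty(n)
    else:
        out_sorted = np.empty_like(sorted_vals)
    for i in range(n):
        lo = i - 1 if i > 0 and sorted_chroms[i - 1] == sorted_chroms[i] else i
        hi = i + 2 if i + 1 < n and sorted_chroms[i + 1] == sorted_chroms[i] else i + 1
        if cross_replicate:
            out_sorted[i] = np.median(sorted_vals[:, lo:hi])
        else:
            out_sorted[:, i] = np.median(sorted_vals[:, lo:hi], axis=1)
    if cross_replicate:
        return out_sorted[inv]
    return out_sorted[:, inv]


def median_filter_3x3(matrix: np.ndarray, chroms: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Cross-replicate 3x3 median filter: one value per probe."""
    return median_filter(matrix, chroms, starts, cross_replicate=True)


# ---------------------------------------------------------------------------
# Background threshold at a target FDR


def background_threshold(
    random_values: np.ndarray,
    genic_values: np.ndarray,
    q: float = DEFAULT_FDR_Q,
    min_random: int = MIN_RANDOM_PROBES,
) -> float:
    """Smallest intensity at which the estimated FDR drops to ``q``.

    The random probes provide the empirical null: at a cutoff t the expected
    number of false calls is (fraction of random probes >= t) x N_genic, and
    the FDR estimate divides that by the observed count of genic probes >= t
    (a tail-ratio estimator, with the usual add-one correction so an empty
    random tail is never taken as evidence of a zero FDR).  Returns +inf
    (all calls absent) when no cutoff achieves the target rate.
    """
    random_values = np.sort(np.asarray(random_values, dtype=float))
    genic_values = np.asarray(genic_values, dtype=float)
    if len(random_values) < min_random:
        raise ValueError(f"need >= {min_random} random probes, got {len(random_values)}")
    n_rand, n_genic = len(random_values), len(genic_values)
    candidates = np.unique(genic_values)
    rand_above = n_rand - np.searchsorted(random_values, candidates, side="left")
    genic_sorted = np.sort(genic_values)
    genic_above = n_genic - np.searchsorted(genic_sorted, candidates, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = ((rand_above + 1) / (n_rand + 1)) * n_genic / genic_above
    ok = np.nonzero(fdr <= q)[0]
    if len(ok) == 0:
        logger.warning("no cutoff achieves FDR <= %g; threshold set to +inf", q)
        return float("inf")
    return float(candidates[ok[0]])


# ---------------------------------------------------------------------------
# Exon / isoform levels and gene calls


def exon_and_isoform_levels(
    panel: ProbePanel, values: np.ndarray, genes: list[GeneModel]
) -> tuple[dict[tuple[str, int], float], dict[str, float]]:
    """Per-exon medians and unweighted per-isoform means of a probe signal.

    The exon level is the median over the probes covering the exon; the
    isoform level is the plain mean of its exon levels, deliberately not
    weighted by exon length.  Exons with no probes are excluded from the
    isoform mean and logged.
    """
    probes = panel.probes
    genic = ~panel.is_random
    exon_levels: dict[tuple[str, int], float] = {}
    grouped = pd.DataFrame(
        {
            "gene_id": probes.loc[genic, "gene_id"],
            "exon_index": probes.loc[genic, "exon_index"].astype(int),
            "value": np.asarray(values)[genic],
        }
    ).groupby(["gene_id", "exon_index"])["value"].median()
    for (gid, ei), v in grouped.items():
        exon_levels[(gid, ei)] = float(v)

    isoform_levels: dict[str, float] = {}
    for gene in genes:
        for tid, idx in gene.transcripts:
            levels = []
            for i in idx:
                key = (gene.gene_id, i)
                if key in exon_levels:
                    levels.append(exon_levels[key])
                else:
                    logger.info("exon %s[%d] has no probes; excluded from %s", gene.gene_id, i, tid)
            if levels:
                isoform_levels[tid] = float(np.mean(levels))
    return exon_levels, isoform_levels


@dataclass
class ExpressionCall:
    """Gene-level present/absent verdict across replicates."""

    gene_id: str
    fraction_above: list[float]
    present: list[bool]
    consensus_present: bool | None  # None for genes with no probes


def call_genes(
    panel: ProbePanel,
    values: np.ndarray,
    thresholds: list[float],
    frac: float = DEFAULT_PRESENT_FRAC,
    all_gene_ids: list[str] | None = None,
) -> list[ExpressionCall]:
    """Present/absent calls from per-replicate probe fractions.

    A gene is present in a replicate when *more than* ``frac`` of its probe
    signals are *higher than* that replicate's threshold — both comparisons
    strict.  The consensus requires presence in every replicate.  Genes in
    ``all_gene_ids`` with no probes on the panel get an NA call (consensus
    ``None``).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != len(thresholds):
        raise ValueError("one threshold per replicate required")
    probes = panel.probes
    genic = ~panel.is_random
    calls = []
    gene_ids = probes.loc[genic, "gene_id"]
    seen = set()
    for gid, idx in gene_ids.groupby(gene_ids).groups.items():
        cols = probes.index.get_indexer(idx)
        fracs, present = [], []
        for r, t in enumerate(thresholds):
            f = float(np.mean(values[r, cols] > t))
            fracs.append(f)
            present.append(f > frac)
        calls.append(ExpressionCall(str(gid), fracs, present, all(present)))
        seen.add(str(gid))
    for gid in all_gene_ids or []:
        if gid not in seen:
            logger.warning("gene %s has no probes; call is NA", gid)
            calls.append(ExpressionCall(gid, [], [], None))
    return calls


# ---------------------------------------------------------------------------
# Signal tracks


def make_signal_track(
    panel: ProbePanel,
    values: np.ndarray,
    random_values: np.ndarray,
    percentile: float = DEFAULT_SUBTRACTION_PERCENTILE,
) -> pd.DataFrame:
    """Background-subtracted per-probe scores ready for a GFF track.

    The top-``percentile`` random-probe intensity is subtracted from every
    probe; negative results are rounded to zero.
    """
    cutoff = float(np.quantile(np.asarray(random_values, dtype=float), percentile))
    scores = np.maximum(np.asarray(values, dtype=float) - cutoff, 0.0)
    probes = panel.probes
    return pd.DataFrame(
        {
            "chrom": probes["chrom"],
            "start": probes["start"] + 1,  # GFF 1-based inclusive
            "end": probes["start"] + probes["length"],
            "probe_id": probes["probe_id"],
            "score": scores,
        }
    )


def write_signal_gff(track: pd.DataFrame, path, source: str = "conect") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in track.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{source}\tprobe_signal\t{row.start}\t{row.end}\t"
                f"{row.score:.4f}\t.\t.\tID={row.probe_id}\n"
            )


# ---------------------------------------------------------------------------
# End-to-end caller


@dataclass
class TilingResult:
    panel: ProbePanel
    normalized: np.ndarray
    smoothed: np.ndarray  # per-replicate window-3 medians (genic order aware)
    combined: np.ndarray  # cross-replicate 3x3 vector
    thresholds: list[float]
    calls: list[ExpressionCall]
    exon_levels: dict[tuple[str, int], float]
    isoform_levels: dict[str, float]

    def called_genes(self) -> set[str]:
        return {c.gene_id for c in self.calls if c.consensus_present}


def tiling_pipeline(
    panel: ProbePanel,
    genes: list[GeneModel],
    q: float = DEFAULT_FDR_Q,
    frac: float = DEFAULT_PRESENT_FRAC,
) -> TilingResult:
    """Run the full caller: GC-correct, normalize, filter, threshold, call.

    The 3x3 median filter pools the replicates into one smoothed value per
    probe; presence is then judged against each replicate's own random-probe
    threshold (the replicates share the filtered signal but not the null),
    and the consensus requires presence under all of them.
    """
    panel = gc_correct(panel)
    normalized = quantile_normalize(panel.intensities)
    chroms = panel.probes["chrom"].to_numpy()
    starts = panel.probes["start"].to_numpy()
    genic = ~panel.is_random

    smoothed = normalized.copy()
    smoothed[:, genic] = median_filter(
        normalized[:, genic], chroms[genic], starts[genic], cross_replicate=False
    )
    combined = np.empty(normalized.shape[1])
    combined[genic] = median_filter_3x3(normalized[:, genic], chroms[genic], starts[genic])
    combined[~genic] = np.median(normalized[:, ~genic], axis=0)

    thresholds = [
        background_threshold(normalized[r, ~genic], combined[genic], q)
        for r in range(panel.n_replicates)
    ]
    calls = call_genes(
        panel, np.tile(combined, (panel.n_replicates, 1)), thresholds, frac
    )
    exon_levels, isoform_levels = exon_and_isoform_levels(panel, combined, genes)
    return TilingResult(
        panel, normalized, smoothed, combined, thresholds, calls, exon_levels, isoform_levels
    )
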