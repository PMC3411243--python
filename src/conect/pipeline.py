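"""End-to-end orchestration: mask -> place -> classify -> report.

Ties the per-module operations together exactly as they run individually, so
composing stages through :func:`run_classification` gives the same results
as calling each stage by hand with the same configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .classifier import (
    GenomePlacement,
    GenomePlacer,
    NovelFeature,
    NoveltyClassifier,
    summarize_run,
)
from .config import RunConfig
from .datamodel import GeneModel, GenomeSequence, TranscriptFragment, transcript_database
from .masker import CandidateSegment, MaskResult, TranscriptMasker, select_candidates
from .simulate import FixtureTruth

logger = logging.getLogger(__name__)


@dataclass
class ClassificationRun:
    mask_results: list[MaskResult]
    candidates: dict[str, list[CandidateSegment]]
    placements: list[GenomePlacement]
    features: list[NovelFeature]
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_classification(
    genome: GenomeSequence,
    genes: list[GeneModel],
    fragments: list[TranscriptFragment],
    config: RunConfig | None = None,
) -> ClassificationRun:
    """Run both screening rounds over a fragment set.

    Round 1 masks every fragment against the spliced transcript database and
    keeps candidate segments (terminal > min_terminal_len bp, internal any
    length).  Round 2 places candidate-bearing fragments — plus fully masked
    fragments whose mask was contributed by two or more genes, the fusion
    suspects — on the genome and classifies each candidate block.
    """
    config = config or RunConfig()
    db = transcript_database(genes, genome)
    masker = TranscriptMasker(
        db, kmer_size=config.kmer_size, min_identity=config.min_identity,
        min_hit_len=config.min_hit_len,
    )
    placer = GenomePlacer(
        genome, kmer_size=config.kmer_size, min_identity=config.min_identity,
        min_hit_len=config.min_hit_len, max_intron=config.max_link_dist,
    )
    clf = NoveltyClassifier(
        genes, genome, min_intron_len=config.min_intron_len,
        max_link_dist=config.max_link_dist, donors=config.donors,
    )

    mask_results: list[MaskResult] = []
    candidates: dict[str, list[CandidateSegment]] = {}
    placements: list[GenomePlacement] = []
    features: list[NovelFeature] = []
    for frag in fragments:
        res = masker.mask(frag)
        mask_results.append(res)
        cands = select_candidates(res, config.min_terminal_len)
        candidates[frag.fragment_id] = cands
        fusion_suspect = res.status == "fully_masked" and len(res.masked_gene_ids) >= 2
        if not cands and not fusion_suspect:
            continue
        placement = placer.place(frag.fragment_id, res.sequence)
        placements.append(placement)
        features.extend(clf.classify(placement, cands))

    summary = summarize_run(mask_results, placements, features)
    logger.info(
        "classified %d fragments: %d features, %d placements",
        len(fragments), len(features), len(placements),
    )
    return ClassificationRun(mask_results, candidates, placements, features, summary)


# ---------------------------------------------------------------------------
# Truth scoring


def unique_feature_keys(features: list[NovelFeature]) -> set[tuple]:
    """Collapse per-fragment feature rows to distinct genomic features."""
    return {
        (f.category, f.gene_ids, f.chrom, tuple(sorted(f.intervals)))
        for f in features
        if f.category != "intergenic_unlinked"
    }


def _truth_key(planted) -> tuple:
    return (planted.category, planted.gene_ids, planted.chrom, tuple(sorted(planted.intervals)))


def score_against_truth(features: list[NovelFeature], truth: FixtureTruth) -> pd.DataFrame:
    """Per-category precision/recall of emitted features against the plant.

    A planted feature counts as recovered when an emitted feature matches its
    category, gene set and exact genomic interval(s); novel-exon calls must
    additionally have validated splice sites to count as correct.
    """
    emitted = {
        key
        for key in unique_feature_keys(
            [f for f in features if f.splice_valid is not False]
        )
    }
    truth_keys = {_truth_key(p) for p in truth.planted}
    rows = []
    categories = sorted({p.category for p in truth.planted})
    for cat in categories:
        t = {k for k in truth_keys if k[0] == cat}
        e = {k for k in emitted if k[0] == cat}
        tp = len(t & e)
        rows.append(
            {
                "category": cat,
                "n_truth": len(t),
                "n_emitted": len(e),
                "n_correct": tp,
                "recall": tp / len(t) if t else float("nan"),
                "precision": tp / len(e) if e else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def mask_report(run: ClassificationRun) -> pd.DataFrame:
    """Per-fragment TSV-ready masking report."""
    rows = []
    for res in run.mask_results:
        rows.append(
            {
                "fragment_id": res.fragment_id,
                "status": res.status,
                "orientation": res.orientation,
                "masked_spans": ";".join(f"{s}-{e}:{','.join(g)}" for s, e, g in res.masked_intervals),
                "unmasked_spans": ";".join(f"{s}-{e}:{cls}" for (s, e), cls in res.unmasked_segments),
            }
        )
    return pd.DataFrame(rows)
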