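"""Cross-study sharing and GWAS-colocalization novelty classification.

A home-study eQTL is compared against the same gene's signal in other
studies (sharing: shared / unique / suggestive-unique), and a home-study
GWAS colocalization is classified as novel when every other study's
colocalization against the same GWAS locus is best explained by H2 or H3
(signal in GWAS only, or distinct causal variants).  The rescue scan runs
the reverse direction: genes colocalized with GWAS only in another study
are re-tested at home irrespective of home-study eQTL significance.

All posterior-probability comparisons are strict (> 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .coloc import ColocPriors, ColocResult, DEFAULT_PRIORS, coloc_abf

log = logging.getLogger(__name__)

__all__ = [
    "SharingLabel",
    "NoveltyLabel",
    "eqtl_sharing_class",
    "gwas_coloc_novelty",
    "rescue_scan",
    "PP_THRESHOLD",
]

#: colocalization call threshold (strict >)
PP_THRESHOLD = 0.5


@dataclass
class SharingLabel:
    gene_id: str
    label: str  # shared | unique | suggestive-unique | inconclusive | untestable
    supporting: list = field(default_factory=list)  # ColocResult pair ids


@dataclass
class NoveltyLabel:
    locus_id: str
    gene_id: str
    label: str  # novel | shared | rescued | not-colocalized | untestable
    cross_max_hypotheses: dict = field(default_factory=dict)  # study -> hypothesis


def eqtl_sharing_class(gene_id: str, home_vs_others: dict) -> SharingLabel:
    """Sharing class of one home-study eGene from pairwise colocalizations.

    ``home_vs_others`` maps other-study name -> ColocResult or None (gene
    not testable in that study).  Rules: shared if PP4 > 0.5 against any
    other study; unique if PP3 > 0.5 against all others with data;
    suggestive-unique if PP3 > 0.5 against exactly one and no PP4 > 0.5;
    untestable if the gene has data in no other study.
    """
    with_data = {s: r for s, r in home_vs_others.items() if r is not None}
    if not with_data:
        return SharingLabel(gene_id=gene_id, label="untestable")
    supporting = [r.pair_id for r in with_data.values()]
    pp4_hits = [s for s, r in with_data.items() if r["H4"] > PP_THRESHOLD]
    pp3_hits = [s for s, r in with_data.items() if r["H3"] > PP_THRESHOLD]
    if pp4_hits:
        return SharingLabel(gene_id, "shared", supporting)
    if len(pp3_hits) == len(with_data):
        return SharingLabel(gene_id, "unique", supporting)
    if len(pp3_hits) == 1:
        return SharingLabel(gene_id, "suggestive-unique", supporting)
    return SharingLabel(gene_id, "inconclusive", supporting)


def gwas_coloc_novelty(
    locus_id: str,
    gene_id: str,
    home_result: ColocResult,
    cross_results: dict,
) -> NoveltyLabel:
    """Novelty of a home-study GWAS colocalization from cross-study re-tests.

    Requires home PP4 > 0.5.  ``cross_results`` maps other-study name ->
    ColocResult (run regardless of eQTL significance) or None.  Novel when
    every other study's best hypothesis is H2 or H3; shared when any other
    study's best hypothesis is H4; untestable when no other study has data.
    """
    if home_result["H4"] <= PP_THRESHOLD:
        raise ValueError("home study must colocalize (PP4 > 0.5)")
    with_data = {s: r for s, r in cross_results.items() if r is not None}
    hyps = {s: r.max_hypothesis for s, r in with_data.items()}
    if not with_data:
        return NoveltyLabel(locus_id, gene_id, "untestable", hyps)
    if any(h == "H4" for h in hyps.values()):
        return NoveltyLabel(locus_id, gene_id, "shared", hyps)
    if all(h in ("H2", "H3") for h in hyps.values()):
        return NoveltyLabel(locus_id, gene_id, "novel", hyps)
    return NoveltyLabel(locus_id, gene_id, "not-colocalized", hyps)


def rescue_scan(
    other_study_unique_genes,
    home_tracks: dict,
    gwas_tracks,
    priors: ColocPriors = DEFAULT_PRIORS,
):
    """Re-test GWAS colocalization at home for genes colocalized elsewhere.

    ``home_tracks`` maps gene id -> home-study eQTL SummaryStatTrack;
    ``gwas_tracks`` maps gene id (or locus) -> GWAS SummaryStatTrack, or a
    single track used for every gene.  Returns (rescued, max_pp4_list,
    untestable): rescued genes have PP4 strictly > 0.5; the secondary list
    contains genes whose best hypothesis is H4 at any PP4.
    """
    rescued, max_h4, untestable = [], [], []
    for gene in other_study_unique_genes:
        track = home_tracks.get(gene)
        if track is None:
            untestable.append(gene)
            log.info("gene %s: no home track; untestable", gene)
            continue
        gwas = gwas_tracks.get(gene) if isinstance(gwas_tracks, dict) else gwas_tracks
        if gwas is None:
            untestable.append(gene)
            continue
        res = coloc_abf(track, gwas, priors, pair_id=f"rescue:{gene}")
        if res["H4"] > PP_THRESHOLD:
            rescued.append((gene, res))
        if res.max_hypothesis == "H4":
            max_h4.append((gene, res))
    return rescued, max_h4, untestable
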