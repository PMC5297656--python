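"""Pathway interplay between predicted lncRNA targets and DE mRNAs.

The integration asks three questions for the pathways that come out
significant in BOTH the lncRNA-target enrichment and the mRNA
enrichment: how many predicted target genes fall in those pathways, how
many DE mRNAs do, and how large is the overlap; and, for every
overlapping (lncRNA, gene) pair, whether the gene changed in the same
direction as its lncRNA (concordant) or the opposite one.  Gene-level
overlap and pair-level concordance are reported separately, together
with a cis/trans breakdown of the overlap pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .enrichment import significant_sets
from .types import (
    DEResult,
    EnrichmentResult,
    GeneSetCollection,
    TargetPair,
    ValidationError,
)

__all__ = ["common_pathways", "overlap_analysis", "mode_breakdown", "InterplayReport"]


@dataclass
class PathwayInterplay:
    """Per-pathway slice of the interplay report."""

    set_id: str
    target_genes: set[str]
    de_mrna_genes: set[str]
    overlap_genes: set[str]
    overlap_pairs: list[TargetPair]
    n_same_direction: int
    n_opposite: int
    n_cis: int
    n_trans: int


@dataclass
class InterplayReport:
    """Counts of targets, DE mRNAs, their overlap, and direction concordance
    inside the common significant pathways."""

    common_pathways: set[str]
    per_pathway: dict[str, PathwayInterplay] = field(default_factory=dict)
    n_targets: int = 0
    n_mrnas: int = 0
    n_overlap: int = 0
    n_overlap_pairs: int = 0
    n_same_direction: int = 0
    n_opposite: int = 0
    n_cis_pairs: int = 0
    n_trans_pairs: int = 0

    def validate(self) -> None:
        if self.n_overlap > min(self.n_targets, self.n_mrnas):
            raise ValidationError("overlap exceeds min(targets, mRNAs)")
        if self.n_same_direction + self.n_opposite > self.n_overlap_pairs:
            raise ValidationError("concordance counts exceed overlap pairs")
        if self.n_cis_pairs + self.n_trans_pairs != self.n_overlap_pairs:
            raise ValidationError("cis/trans tallies do not sum to overlap pairs")


def common_pathways(
    enrich_targets: list[EnrichmentResult],
    enrich_mrna: list[EnrichmentResult],
    alpha: float = 0.05,
) -> set[str]:
    """Pathways significant (permutation p < alpha) in both analyses.

    Both result lists must score the same gene-set collection.
    """
    ids_a = {r.set_id for r in enrich_targets}
    ids_b = {r.set_id for r in enrich_mrna}
    if ids_a != ids_b:
        raise ValidationError(
            "enrichment results cover different gene-set collections: "
            f"{sorted(ids_a ^ ids_b)[:5]} differ"
        )
    return significant_sets(enrich_targets, alpha) & significant_sets(enrich_mrna, alpha)


def overlap_analysis(
    common_sets: set[str],
    target_pairs: list[TargetPair],
    de_results: list[DEResult],
    genesets: GeneSetCollection,
) -> InterplayReport:
    """Count targets, DE mRNAs, overlap, and per-pair direction concordance.

    ``target_pairs`` must carry lncRNA directions (see
    :func:`lncterplay.targets.group_targets`).  A pathway gene that is a
    predicted target but absent from the DE table counts as target-only;
    an overlapping pair whose gene direction is ``unchanged`` is excluded
    from the concordance tally (direction undefined).
    """
    for p in target_pairs:
        if p.lnc_direction not in ("up", "down"):
            raise ValidationError(
                f"pair ({p.lnc_id}, {p.gene_id}) lacks a lncRNA direction"
            )
    gene_dir = {r.feature_id: r.direction for r in de_results}
    de_genes = {g for g, d in gene_dir.items() if d in ("up", "down")}
    report = InterplayReport(common_pathways=set(common_sets))
    all_targets: set[str] = set()
    all_mrnas: set[str] = set()
    all_overlap: set[str] = set()
    for sid in sorted(common_sets):
        members = genesets[sid]
        targets_here = {p.gene_id for p in target_pairs if p.gene_id in members}
        mrnas_here = de_genes & members
        overlap_here = targets_here & mrnas_here
        pairs_here = [
            p for p in target_pairs
            if p.gene_id in overlap_here
        ]
        same = opposite = 0
        for p in pairs_here:
            d = gene_dir.get(p.gene_id)
            if d not in ("up", "down"):
                continue
            if d == p.lnc_direction:
                same += 1
            else:
                opposite += 1
        entry = PathwayInterplay(
            set_id=sid,
            target_genes=targets_here,
            de_mrna_genes=mrnas_here,
            overlap_genes=overlap_here,
            overlap_pairs=pairs_here,
            n_same_direction=same,
            n_opposite=opposite,
            n_cis=sum(1 for p in pairs_here if p.mode == "cis"),
            n_trans=sum(1 for p in pairs_here if p.mode == "trans"),
        )
        report.per_pathway[sid] = entry
        all_targets |= targets_here
        all_mrnas |= mrnas_here
        all_overlap |= overlap_here
        report.n_overlap_pairs += len(pairs_here)
        report.n_same_direction += same
        report.n_opposite += opposite
        report.n_cis_pairs += entry.n_cis
        report.n_trans_pairs += entry.n_trans
    report.n_targets = len(all_targets)
    report.n_mrnas = len(all_mrnas)
    report.n_overlap = len(all_overlap)
    report.validate()
    return report


def mode_breakdown(report: InterplayReport) -> dict[str, tuple[int, int]]:
    """Per-pathway (cis, trans) tallies among overlap pairs."""
    return {
        sid: (entry.n_cis, entry.n_trans)
        for sid, entry in sorted(report.per_pathway.items())
    }
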