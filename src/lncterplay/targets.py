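"""cis and trans lncRNA target assignment.

A gene is a *cis* target of a lncRNA when the gap between their genomic
intervals on the same chromosome is at most the window (10 kbp by
default; 0 when the loci overlap; the boundary is inclusive and strand
is ignored).  A gene is a *trans* target when its transcript hybridizes
with the lncRNA below the energy cutoff AND it lies on a different
chromosome; same-chromosome hits from the duplex screen are excluded.
Targets are organized into four groups keyed by mode and by whether the
lncRNA itself is up- or downregulated.
"""

from __future__ import annotations

import logging

from .duplex import DuplexResult
from .types import Feature, FeatureAnnotation, DEResult, TargetPair, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["interval_gap", "cis_targets", "trans_targets", "group_targets"]


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap in nt between two half-open intervals; 0 if they intersect or touch."""
    if start_b >= end_a:
        return start_b - end_a
    if start_a >= end_b:
        return start_a - end_b
    return 0


def cis_targets(
    lnc_feature: Feature | str,
    annotation: FeatureAnnotation,
    window: int = 10_000,
) -> list[TargetPair]:
    """Genes within ``window`` nt of the lncRNA locus on the same chromosome.

    The window is measured from both ends of the full lncRNA locus,
    boundary inclusive, either strand.
    """
    if isinstance(lnc_feature, str):
        if lnc_feature not in annotation:
            raise ValidationError(f"lncRNA {lnc_feature!r} absent from annotation")
        lnc_feature = annotation[lnc_feature]
    pairs = []
    for gene in annotation.genes:
        if gene.chrom != lnc_feature.chrom:
            continue
        gap = interval_gap(lnc_feature.start, lnc_feature.end, gene.start, gene.end)
        if gap <= window:
            pairs.append(
                TargetPair(
                    lnc_id=lnc_feature.feature_id,
                    gene_id=gene.feature_id,
                    mode="cis",
                    distance=gap,
                )
            )
    pairs.sort(key=lambda p: (p.distance, p.gene_id))
    return pairs


def trans_targets(
    lnc_feature: Feature | str,
    screen_hits: list[tuple[str, DuplexResult]],
    annotation: FeatureAnnotation,
) -> list[TargetPair]:
    """Turn duplex-screen hits into trans pairs, dropping same-chromosome genes."""
    if isinstance(lnc_feature, str):
        if lnc_feature not in annotation:
            raise ValidationError(f"lncRNA {lnc_feature!r} absent from annotation")
        lnc_feature = annotation[lnc_feature]
    pairs = []
    n_same = 0
    for gene_id, result in screen_hits:
        if gene_id not in annotation:
            raise ValidationError(f"screen hit {gene_id!r} absent from annotation")
        if annotation[gene_id].chrom == lnc_feature.chrom:
            n_same += 1
            continue
        pairs.append(
            TargetPair(
                lnc_id=lnc_feature.feature_id,
                gene_id=gene_id,
                mode="trans",
                energy=result.energy,
            )
        )
    if n_same:
        logger.info(
            "%s: excluded %d same-chromosome duplex hit(s)",
            lnc_feature.feature_id, n_same,
        )
    pairs.sort(key=lambda p: (p.energy, p.gene_id))
    return pairs


def group_targets(
    pairs: list[TargetPair],
    de_results: list[DEResult],
) -> tuple[dict[str, set[str]], list[TargetPair]]:
    """Organize target genes into {cis,trans} x {up,down} buckets.

    Returns the four gene-id buckets plus the pair list annotated with each
    lncRNA's DE direction.  Pairs whose lncRNA is unchanged (or absent from
    the DE table) are dropped with a logged count; a gene reached through
    several lncRNAs may appear in several buckets.
    """
    direction = {r.feature_id: r.direction for r in de_results}
    buckets: dict[str, set[str]] = {
        "cis_up": set(), "cis_down": set(), "trans_up": set(), "trans_down": set()
    }
    kept: list[TargetPair] = []
    dropped = 0
    for pair in pairs:
        d = direction.get(pair.lnc_id, "unchanged")
        if d not in ("up", "down"):
            dropped += 1
            continue
        buckets[f"{pair.mode}_{d}"].add(pair.gene_id)
        kept.append(
            TargetPair(
                lnc_id=pair.lnc_id,
                gene_id=pair.gene_id,
                mode=pair.mode,
                distance=pair.distance,
                energy=pair.energy,
                lnc_direction=d,
            )
        )
    if dropped:
        logger.info("dropped %d pair(s) whose lncRNA is not deregulated", dropped)
    return buckets, kept
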