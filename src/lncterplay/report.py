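"""Summary tables (and optional bar charts) of the pipeline outputs."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .differential import DIR_DOWN, DIR_UP
from .interplay import InterplayReport
from .types import DEResult, ValidationError

__all__ = ["SummaryCounts", "summarize"]


@dataclass
class SummaryCounts:
    """Headline counts: deregulated lncRNAs/mRNAs and per-pathway bars.

    ``pathway_bars`` maps pathway id to (number of predicted target genes
    in the pathway, number of those intersecting the DE mRNAs).
    """

    n_lnc_up: int
    n_lnc_down: int
    n_mrna_up: int
    n_mrna_down: int
    pathway_bars: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.n_lnc_up, self.n_lnc_down, self.n_mrna_up, self.n_mrna_down) < 0:
            raise ValidationError("summary counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("lncRNA_up", self.n_lnc_up),
            ("lncRNA_down", self.n_lnc_down),
            ("mRNA_up", self.n_mrna_up),
            ("mRNA_down", self.n_mrna_down),
        ]
        return pd.DataFrame(rows, columns=["quantity", "count"])

    def bars_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"pathway": sid, "targets_in_pathway": a, "intersecting_targets": b}
                for sid, (a, b) in sorted(self.pathway_bars.items())
            ]
        )


def summarize(
    de_lnc: list[DEResult],
    de_mrna: list[DEResult],
    interplay_report: InterplayReport | None = None,
) -> SummaryCounts:
    """Pure summary of the DE tables and (optionally) the interplay report."""
    counts = SummaryCounts(
        n_lnc_up=sum(1 for r in de_lnc if r.direction == DIR_UP),
        n_lnc_down=sum(1 for r in de_lnc if r.direction == DIR_DOWN),
        n_mrna_up=sum(1 for r in de_mrna if r.direction == DIR_UP),
        n_mrna_down=sum(1 for r in de_mrna if r.direction == DIR_DOWN),
    )
    if interplay_report is not None:
        for sid, entry in interplay_report.per_pathway.items():
            counts.pathway_bars[sid] = (
                len(entry.target_genes),
                len(entry.overlap_genes),
            )
    return counts


def plot_summary(counts: SummaryCounts, path: str) -> None:
    """Optional bar chart of the summary counts (non-canonical output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    df = counts.to_frame()
    axes[0].bar(df["quantity"], df["count"], color=["k", "w", "k", "w"],
                edgecolor="k")
    axes[0].set_ylabel("features")
    axes[0].tick_params(axis="x", rotation=45)
    bars = counts.bars_frame()
    if len(bars):
        x = range(len(bars))
        axes[1].bar([i - 0.2 for i in x], bars["targets_in_pathway"], 0.4,
                    color="w", edgecolor="k", label="targets in pathway")
        axes[1].bar([i + 0.2 for i in x], bars["intersecting_targets"], 0.4,
                    color="k", label="intersecting targets")
        axes[1].set_xticks(list(x))
        axes[1].set_xticklabels(bars["pathway"], rotation=45, ha="right")
        axes[1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
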