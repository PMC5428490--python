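"""Model/Results front end over the trio classification pipeline.

``TrioHeterosisModel`` is built from a validated :class:`TrioExpressionSet`
(or directly from the matrix/design files); ``fit()`` classifies every gene
into the eight expression classes, tests non-additivity against the
mid-parent value, and returns a :class:`HeterosisResults` carrying the
per-gene table, the class summary, and convenience methods for class-union
counts, up/down ratios, pathway enrichment of the non-additive set, and a
text summary table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import core
from .core import ClassSummary, GeneClassification, RelationConfig
from .enrichment import EnrichmentResult, enrich
from .io import PathwayCatalog, TrioExpressionSet, read_expression

CLASS_PATTERNS = {
    1: "LP < H < HP",
    2: "LP < H = HP",
    3: "LP = H < HP",
    4: "LP = H = HP",
    5: "LP < HP < H",
    6: "LP = HP < H",
    7: "H < LP < HP",
    8: "H < LP = HP",
}


class TrioHeterosisModel:
    """Eight-class heterosis expression model for a parent/parent/hybrid trio."""

    def __init__(
        self,
        data: TrioExpressionSet,
        config: RelationConfig | None = None,
        fdr: bool = False,
    ) -> None:
        self.data = data
        self.config = config or RelationConfig()
        self.fdr = fdr

    @classmethod
    def from_files(
        cls,
        matrix_path,
        design_path,
        tissue: str | None = None,
        stage: str | None = None,
        config: RelationConfig | None = None,
        fdr: bool = False,
    ) -> "TrioHeterosisModel":
        data = read_expression(matrix_path, design_path, tissue=tissue, stage=stage)
        return cls(data, config=config, fdr=fdr)

    def fit(self) -> "HeterosisResults":
        records, summary = core.classify_transcriptome(
            self.data, self.config, fdr=self.fdr
        )
        return HeterosisResults(self, records, summary)


@dataclass
class HeterosisResults:
    """Fitted per-gene classifications and their class summary."""

    model: TrioHeterosisModel
    classifications: list[GeneClassification]
    class_summary: ClassSummary

    @property
    def gene_table(self) -> pd.DataFrame:
        """One row per gene with means, class, fold changes and the MPV test."""
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.classifications],
                "mean_pA": [g.mean_pA for g in self.classifications],
                "mean_pB": [g.mean_pB for g in self.classifications],
                "mean_H": [g.mean_H for g in self.classifications],
                "lp_parent": [g.lp_parent for g in self.classifications],
                "mean_LP": [g.mean_LP for g in self.classifications],
                "mean_HP": [g.mean_HP for g in self.classifications],
                "class_id": [g.class_id for g in self.classifications],
                "fc_H_LP": [g.fc_H_LP for g in self.classifications],
                "fc_HP_H": [g.fc_HP_H for g in self.classifications],
                "fc_HP_LP": [g.fc_HP_LP for g in self.classifications],
                "mpv": [g.mpv for g in self.classifications],
                "p_nonadditive": [g.p_nonadditive for g in self.classifications],
                "nonadditive": [g.nonadditive for g in self.classifications],
            }
        )

    @property
    def nonadditive_genes(self) -> frozenset[str]:
        return frozenset(g.gene_id for g in self.classifications if g.nonadditive)

    def union_count(self, classes) -> int:
        return core.class_union_counts(self.class_summary, classes)

    def updown_ratio(
        self, numerator_group: str, denominator_group: str, gene_set=None
    ) -> tuple[int, int, float]:
        return core.updown_ratio(
            self.model.data, numerator_group, denominator_group,
            gene_set=gene_set, cfg=self.model.config,
        )

    def enrich(self, catalog: PathwayCatalog) -> list[EnrichmentResult]:
        """Over-representation of catalog pathways among non-additive genes."""
        return enrich(self.nonadditive_genes & catalog.universe, catalog)

    def summary_frame(self) -> pd.DataFrame:
        s = self.class_summary
        return pd.DataFrame(
            {
                "class_id": list(range(1, 9)),
                "pattern": [CLASS_PATTERNS[c] for c in range(1, 9)],
                "total": [s.total_count[c] for c in range(1, 9)],
                "nonadditive": [s.nonadditive_count[c] for c in range(1, 9)],
            }
        )

    def summary(self) -> str:
        """Human-readable class-count table for one tissue/stage."""
        s = self.class_summary
        cfg = self.model.config
        lines = [
            f"Trio expression classification  [{s.tissue} {s.stage}]",
            f"fold threshold {cfg.fold_threshold:g}, pseudocount "
            f"{cfg.pseudocount:g}, alpha {cfg.alpha:g}",
            "",
            f"{'class':>5}  {'pattern':<12} {'total':>8} {'nonadditive':>12}",
        ]
        for c in range(1, 9):
            lines.append(
                f"{c:>5}  {CLASS_PATTERNS[c]:<12} {s.total_count[c]:>8} "
                f"{s.nonadditive_count[c]:>12}"
            )
        lines.append(
            f"{'total':>5}  {'':<12} {s.total_genes:>8} {s.nonadditive_total:>12}"
        )
        lines.append("")
        lines.append(
            "hybrid above at least one parent (classes 2,5,6): "
            f"{self.union_count({2, 5, 6})}"
        )
        lines.append(
            "hybrid below both/either parent (classes 7,8): "
            f"{self.union_count({7, 8})}"
        )
        return "\n".join(lines)

    def to_tsv(self, gene_path, summary_path) -> None:
        self.gene_table.to_csv(gene_path, sep="\t", index=False, float_format="%.10g")
        self.summary_frame().to_csv(summary_path, sep="\t", index=False)

    def plot_class_counts(self, ax=None):
        """Bar chart of total and non-additive gene counts per class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        frame = self.summary_frame()
        x = np.arange(1, 9)
        ax.bar(x - 0.2, frame["total"], width=0.4, label="total")
        ax.bar(x + 0.2, frame["nonadditive"], width=0.4, label="non-additive")
        ax.set_xticks(x)
        ax.set_xlabel("expression class")
        ax.set_ylabel("genes")
        ax.set_title(
            f"{self.class_summary.tissue} {self.class_summary.stage}"
        )
        ax.legend()
        return ax
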