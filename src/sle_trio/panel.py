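"""Gene panels: named gene sets with coding and promoter intervals.

Intervals are stored 0-based half-open (BED convention); variant positions
everywhere else in the package are 1-based (VCF convention).  All synthetic
contigs are named ``chrS*`` so that synthetic coordinates can never be
joined accidentally against a real reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

#: the 22 genes in which single-gene defects cause SLE or an SLE-like
#: type I interferon-pathway disease; used as the default panel gene names
MONOGENIC_SLE_GENES = (
    "TREX1", "DNASE1", "DNASE1L3", "C1QA", "C1QB", "C1QC", "C1R", "C1S",
    "C2", "C4A", "C4B", "RNASEH2A", "RNASEH2B", "RNASEH2C", "SAMHD1",
    "ADAR", "IFIH1", "ACP5", "TMEM173", "ISG15", "PRKCD", "FAS",
)


@dataclass
class Gene:
    name: str
    chrom: str
    coding: list[tuple[int, int]]          # 0-based half-open
    promoter: tuple[int, int]              # 0-based half-open

    def __post_init__(self) -> None:
        self.coding = sorted(self.coding)
        for (a0, b0), (a1, _) in zip(self.coding, self.coding[1:]):
            if a1 < b0:
                raise ValueError(f"overlapping coding intervals in {self.name}")
        if self.promoter[1] > self.coding[0][0]:
            raise ValueError(f"promoter must abut or precede the first exon of {self.name}")


@dataclass
class GenePanel:
    """A named set of genes with coding and promoter intervals."""

    genes: list[Gene]
    panel_label: str = "monogenic_sle"
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        self._trees = {}
        for gene in self.genes:
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            for start, end in gene.coding:
                tree[start:end] = (gene.name, "coding")
            p0, p1 = gene.promoter
            tree[p0:p1] = (gene.name, "promoter")

    def locate(self, chrom: str, pos: int) -> tuple[str, str] | None:
        """Return ``(gene, region)`` for a 1-based position, or None."""
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = tree[pos - 1]
        if not hits:
            return None
        # coding takes precedence should a promoter ever abut exactly
        for hit in sorted(hits, key=lambda h: h.data[1]):
            return hit.data
        return None

    def to_bed(self) -> pd.DataFrame:
        rows = []
        for gene in self.genes:
            rows.append((gene.chrom, *gene.promoter, f"{gene.name}:promoter"))
            for start, end in gene.coding:
                rows.append((gene.chrom, start, end, f"{gene.name}:coding"))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).sort_values(
            ["chrom", "start"], ignore_index=True
        )

    @classmethod
    def from_bed(cls, bed: pd.DataFrame, panel_label: str = "panel") -> "GenePanel":
        genes: dict[str, dict] = {}
        for row in bed.itertuples(index=False):
            gene_name, region = row.name.rsplit(":", 1)
            g = genes.setdefault(gene_name, {"chrom": row.chrom, "coding": [], "promoter": None})
            if region == "promoter":
                g["promoter"] = (int(row.start), int(row.end))
            else:
                g["coding"].append((int(row.start), int(row.end)))
        return cls(
            genes=[Gene(name=k, **v) for k, v in genes.items()],
            panel_label=panel_label,
        )


def default_panel(
    n_exons: int = 4,
    exon_length: int = 300,
    intron_length: int = 700,
    promoter_length: int = 1000,
    gene_spacing: int = 100_000,
    n_contigs: int = 4,
) -> GenePanel:
    """Synthetic stand-in for the 22-gene monogenic-SLE panel.

    Gene bodies are laid out deterministically on contigs chrS1..chrS4 with
    a promoter immediately upstream of the first exon.
    """
    genes = []
    for i, name in enumerate(MONOGENIC_SLE_GENES):
        chrom = f"chrS{1 + i % n_contigs}"
        offset = 10_000 + (i // n_contigs) * gene_spacing
        first_exon = offset + promoter_length
        coding = [
            (first_exon + j * (exon_length + intron_length),
             first_exon + j * (exon_length + intron_length) + exon_length)
            for j in range(n_exons)
        ]
        genes.append(Gene(name=name, chrom=chrom, coding=coding, promoter=(offset, first_exon)))
    return GenePanel(genes=genes, panel_label="monogenic_sle")
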