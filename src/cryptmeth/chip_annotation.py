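"""Assignment of ChIP peaks to genomic elements around gene models.

A peak is attributed by its summit position to one of six categories, per
gene and in precedence order:

promoter  — summit within +/-2 kb of the TSS;
exon      — summit inside an annotated exon;
intron    — summit inside the gene body but not an exon;
enhancer  — summit within the gene-oriented window [5' end - 50 kb,
            3' end + 5 kb], excluding the gene body and the promoter window;
extended_enhancer — as enhancer but with a 100 kb upstream reach; assigned
            only when no gene qualifies under a tighter definition;
intergenic — no qualifying gene.

When several genes qualify at the same precedence, the one with the smaller
absolute TSS offset wins.  TSS offsets are signed in gene orientation:
negative = upstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import ChIPPeak, GeneModel

__all__ = [
    "ElementWindows",
    "ElementAnnotation",
    "CATEGORIES",
    "tss_offset",
    "annotate_peak",
    "annotate_peaks",
    "element_distribution",
    "intersect_gene_list",
]

CATEGORIES = ("promoter", "exon", "intron", "enhancer", "extended_enhancer", "intergenic")
_RANK = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class ElementWindows:
    """Distances (bp) defining the element windows; all non-negative."""

    promoter_radius: int = 2_000
    enhancer_upstream: int = 50_000
    enhancer_downstream: int = 5_000
    extended_upstream: int = 100_000
    extended_downstream: int = 5_000

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"window distance {name} must be >= 0")


@dataclass(frozen=True)
class ElementAnnotation:
    """One peak's element assignment; gene_id/tss_offset are None for intergenic."""

    peak: ChIPPeak
    gene_id: str | None
    category: str
    tss_offset: int | None


def tss_offset(peak: ChIPPeak, gene: GeneModel) -> int:
    """Signed summit-to-TSS distance in gene orientation (negative = upstream)."""
    if gene.strand == "+":
        return peak.summit - gene.tss
    return gene.tss - peak.summit


def _category_for(peak: ChIPPeak, gene: GeneModel, windows: ElementWindows) -> str | None:
    if peak.chrom != gene.chrom:
        return None
    s = peak.summit
    offset = tss_offset(peak, gene)
    in_promoter = abs(offset) <= windows.promoter_radius
    if in_promoter:
        return "promoter"
    if gene.gene_start <= s < gene.gene_end:
        for ex_start, ex_end in gene.exons:
            if ex_start <= s < ex_end:
                return "exon"
        return "intron"
    # gene-oriented upstream/downstream reach, genomic coordinates
    if gene.strand == "+":
        enh = (gene.gene_start - windows.enhancer_upstream,
               gene.gene_end + windows.enhancer_downstream)
        ext = (gene.gene_start - windows.extended_upstream,
               gene.gene_end + windows.extended_downstream)
    else:
        enh = (gene.gene_start - windows.enhancer_downstream,
               gene.gene_end + windows.enhancer_upstream)
        ext = (gene.gene_start - windows.extended_downstream,
               gene.gene_end + windows.extended_upstream)
    if enh[0] <= s < enh[1]:
        return "enhancer"
    if ext[0] <= s < ext[1]:
        return "extended_enhancer"
    return None


def annotate_peak(
    peak: ChIPPeak,
    gene_models: Sequence[GeneModel],
    windows: ElementWindows = ElementWindows(),
) -> ElementAnnotation:
    """Assign one peak to its highest-precedence (gene, category) pair."""
    best: tuple[int, int, str, GeneModel] | None = None
    for gene in gene_models:
        category = _category_for(peak, gene, windows)
        if category is None:
            continue
        key = (_RANK[category], abs(tss_offset(peak, gene)))
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], category, gene)
    if best is None:
        return ElementAnnotation(peak, None, "intergenic", None)
    _, _, category, gene = best
    return ElementAnnotation(peak, gene.gene_id, category, tss_offset(peak, gene))


def annotate_peaks(
    peaks: Iterable[ChIPPeak],
    gene_models: Sequence[GeneModel],
    windows: ElementWindows = ElementWindows(),
) -> list[ElementAnnotation]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    return [
        annotate_peak(p, by_chrom.get(p.chrom, ()), windows) for p in peaks
    ]


def element_distribution(annotations: Sequence[ElementAnnotation]) -> pd.DataFrame:
    """Counts and percentages per category (categories with zero hits included)."""
    if not annotations:
        return pd.DataFrame(columns=["category", "count", "percent"])
    counts = Counter(a.category for a in annotations)
    total = len(annotations)
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [counts.get(c, 0) for c in CATEGORIES],
            "percent": [100.0 * counts.get(c, 0) / total for c in CATEGORIES],
        }
    )


def intersect_gene_list(
    annotations: Sequence[ElementAnnotation], gene_list: Iterable[str]
) -> pd.DataFrame:
    """Annotations whose assigned gene is in ``gene_list``, sorted by |TSS offset|."""
    wanted = set(gene_list)
    rows = [
        {
            "gene": a.gene_id,
            "chrom": a.peak.chrom,
            "summit": a.peak.summit,
            "category": a.category,
            "tss_offset": a.tss_offset,
            "group": a.peak.group_label,
        }
        for a in annotations
        if a.gene_id in wanted
    ]
    frame = pd.DataFrame(rows, columns=["gene", "chrom", "summit", "category", "tss_offset", "group"])
    if len(frame):
        frame = frame.reindex(
            frame["tss_offset"].abs().sort_values(kind="stable").index
        ).reset_index(drop=True)
    return frame
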