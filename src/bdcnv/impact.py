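"""Full/partial gene deletion–duplication classification.

A gene entirely contained in a deletion CNV is a full gene deletion; a gene
overlapping a deletion without containment is a partial gene deletion, and
likewise for duplications.  Containment is inclusive on both endpoints in
half-open arithmetic (a CNV exactly matching the gene span counts as full).
Classification is at whole-gene granularity; strand is ignored.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .types import ConsensusCnv, GeneImpact, GeneModel, ImpactClass, SvType


def classify_overlap(gene: GeneModel, cnv: ConsensusCnv) -> ImpactClass | None:
    """Classify one gene/CNV pair; None when disjoint (or different chrom)."""
    if gene.chrom != cnv.chrom or gene.end <= cnv.start or cnv.end <= gene.start:
        return None
    full = cnv.start <= gene.start and gene.end <= cnv.end
    if cnv.svtype == SvType.DEL:
        return ImpactClass.FULL_DEL if full else ImpactClass.PART_DEL
    return ImpactClass.FULL_DUP if full else ImpactClass.PART_DUP


def impact_table(
    consensus_cnvs: Iterable[ConsensusCnv], gene_models: Sequence[GeneModel]
) -> list[GeneImpact]:
    """One record per overlapping (sample, gene, CNV) pair.

    Genes are indexed per chromosome in an interval tree; a gene may carry
    several classes across CNVs and samples.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene in gene_models:
        trees[gene.chrom].addi(gene.start, gene.end, gene)
    impacts: list[GeneImpact] = []
    for cnv in consensus_cnvs:
        for iv in sorted(trees[cnv.chrom].overlap(cnv.start, cnv.end)):
            gene: GeneModel = iv.data
            cls = classify_overlap(gene, cnv)
            if cls is None:  # pragma: no cover - tree overlap implies not None
                continue
            impacts.append(
                GeneImpact(
                    sample_id=cnv.sample_id,
                    gene_id=gene.gene_id,
                    symbol=gene.symbol,
                    biotype=gene.biotype,
                    impact_class=cls,
                    cnv_ref=cnv.key(),
                    overlap_start=max(gene.start, cnv.start),
                    overlap_end=min(gene.end, cnv.end),
                )
            )
    impacts.sort(key=lambda i: (i.sample_id, i.gene_id, i.cnv_ref))
    return impacts


def per_patient_counts(
    impacts: Iterable[GeneImpact],
    class_filter: ImpactClass | SvType | None = None,
) -> dict[str, int]:
    """Distinct impacted genes per patient, optionally restricted to a class.

    ``class_filter`` may be a fine class (FULL_DEL, ...), a DEL/DUP
    superclass, or None for all impacts.
    """
    genes_by_patient: dict[str, set[str]] = defaultdict(set)
    for imp in impacts:
        if isinstance(class_filter, ImpactClass) and imp.impact_class != class_filter:
            continue
        if isinstance(class_filter, SvType) and imp.impact_class.svtype != class_filter:
            continue
        genes_by_patient[imp.sample_id].add(imp.gene_id)
    return {patient: len(genes) for patient, genes in sorted(genes_by_patient.items())}
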