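"""Case-exclusive gene discovery and cross-cohort comparison.

Identifies genes whose CNV impacts occur in BD-cancer patients but in no
BD-only patient and no healthy family control, counts recurrence across
patients, and quantifies whether genes partially hit in both case cohorts
are hit at disjoint sub-loci.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .types import Cohort, GeneImpact, ImpactClass, SampleRecord, SvType


class ExclusiveCategory(str, enum.Enum):
    """Impact-class granularity at which exclusivity is enforced.

    ANY_DEL/ANY_DUP treat full and partial impacts of one superclass
    jointly (a control duplication does not disqualify a case-exclusive
    deletion gene); the fine categories require exact-class matching.
    """

    ANY_DEL = "ANY_DEL"
    ANY_DUP = "ANY_DUP"
    FULL_DEL = "FULL_DEL"
    FULL_DUP = "FULL_DUP"
    PART_DEL = "PART_DEL"
    PART_DUP = "PART_DUP"

    def matches(self, cls: ImpactClass) -> bool:
        if self is ExclusiveCategory.ANY_DEL:
            return cls.svtype == SvType.DEL
        if self is ExclusiveCategory.ANY_DUP:
            return cls.svtype == SvType.DUP
        return cls.value == self.value


@dataclass
class ExclusiveGeneReport:
    gene_id: str
    category: ExclusiveCategory
    case_patients: frozenset[str]

    @property
    def recurrence(self) -> int:
        return len(self.case_patients)


def exclusive_genes(
    impacts: Iterable[GeneImpact],
    samples: Sequence[SampleRecord],
    category: ExclusiveCategory,
) -> list[ExclusiveGeneReport]:
    """Genes with category-matching impacts in cases only.

    A gene qualifies iff >= 1 BD-cancer patient carries a matching impact
    and no BD-only or control sample carries one.  Reports are sorted by
    recurrence descending, then gene_id.
    """
    cohort_of = {s.sample_id: s.cohort for s in samples}
    case_hits: dict[str, set[str]] = defaultdict(set)
    noncase_hit: set[str] = set()
    for imp in impacts:
        cohort = cohort_of.get(imp.sample_id)
        if cohort is None:
            raise ValueError(f"impact for unknown sample {imp.sample_id!r}")
        if not category.matches(imp.impact_class):
            continue
        if cohort == Cohort.BD_CANCER:
            case_hits[imp.gene_id].add(imp.sample_id)
        else:
            noncase_hit.add(imp.gene_id)
    reports = [
        ExclusiveGeneReport(gene_id, category, frozenset(patients))
        for gene_id, patients in case_hits.items()
        if gene_id not in noncase_hit
    ]
    reports.sort(key=lambda r: (-r.recurrence, r.gene_id))
    return reports


def recurrence_table(
    reports: Sequence[ExclusiveGeneReport], min_recurrence: int = 3
) -> list[ExclusiveGeneReport]:
    """Reports for genes recurring in at least ``min_recurrence`` case patients."""
    return [r for r in reports if r.recurrence >= min_recurrence]


def distinct_case_patients(reports: Iterable[ExclusiveGeneReport]) -> frozenset[str]:
    """All case patients appearing in any report (the 'in N patients' count)."""
    out: set[str] = set()
    for r in reports:
        out |= r.case_patients
    return frozenset(out)


@dataclass
class PartialDivergence:
    gene_id: str
    case_locus_union: list[tuple[int, int]]
    other_locus_union: list[tuple[int, int]]
    overlap_bp: int

    @property
    def different(self) -> bool:
        return self.overlap_bp == 0


def _union_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _intersection_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def partial_divergence(
    impacts: Iterable[GeneImpact],
    samples: Sequence[SampleRecord],
    gene_id: str,
    svtype: SvType,
) -> PartialDivergence:
    """Compare the partially-hit sub-loci of one gene between case cohorts.

    Requires partial impacts of the given superclass in both BD-cancer and
    BD-only patients; the hit sub-loci of each cohort are unioned and the
    base-pair overlap of the two unions computed ('different' means the
    hit parts are disjoint).
    """
    cohort_of = {s.sample_id: s.cohort for s in samples}
    part_class = ImpactClass.PART_DEL if svtype == SvType.DEL else ImpactClass.PART_DUP
    case_ivs: list[tuple[int, int]] = []
    other_ivs: list[tuple[int, int]] = []
    for imp in impacts:
        if imp.gene_id != gene_id or imp.impact_class != part_class:
            continue
        cohort = cohort_of.get(imp.sample_id)
        if cohort == Cohort.BD_CANCER:
            case_ivs.append((imp.overlap_start, imp.overlap_end))
        elif cohort == Cohort.BD_ONLY:
            other_ivs.append((imp.overlap_start, imp.overlap_end))
    if not case_ivs or not other_ivs:
        raise ValueError(
            f"gene {gene_id!r} lacks {part_class.value} impacts in both case cohorts"
        )
    case_union = _union_intervals(case_ivs)
    other_union = _union_intervals(other_ivs)
    return PartialDivergence(
        gene_id=gene_id,
        case_locus_union=case_union,
        other_locus_union=other_union,
        overlap_bp=_intersection_bp(case_union, other_union),
    )


def genes_partially_hit_in_both(
    impacts: Iterable[GeneImpact], samples: Sequence[SampleRecord], svtype: SvType
) -> list[str]:
    """Genes with partial impacts of one superclass in both BD-cancer and BD-only."""
    cohort_of = {s.sample_id: s.cohort for s in samples}
    part_class = ImpactClass.PART_DEL if svtype == SvType.DEL else ImpactClass.PART_DUP
    seen: dict[str, set[Cohort]] = defaultdict(set)
    for imp in impacts:
        if imp.impact_class == part_class:
            cohort = cohort_of.get(imp.sample_id)
            if cohort in (Cohort.BD_CANCER, Cohort.BD_ONLY):
                seen[imp.gene_id].add(cohort)
    return sorted(g for g, cohorts in seen.items() if len(cohorts) == 2)
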