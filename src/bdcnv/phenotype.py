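"""Phenotype clustering of case patients on pathway × cancer-subtype axes.

Patients are grouped along two dimensions: the enriched functional terms
their CNV-impacted genes belong to, and a seven-group pediatric cancer
subtype derived from ICD-9/ICD-10 diagnosis codes (brain/nervous, bone and
connective/soft tissue, respiratory/digestive, endocrine/gland, kidney,
eye, other).  The ICD prefix→group table ships as an editable YAML; the
default ranges are a reconstruction and documented as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .types import EnrichmentResult, GeneImpact, SampleRecord, SvType

log = logging.getLogger(__name__)

SUBTYPE_CATEGORIES = (
    "brain_nervous",
    "bone_connective_soft_tissue",
    "respiratory_digestive",
    "endocrine_gland",
    "kidney",
    "eye",
    "other",
)


@dataclass
class SubtypeMap:
    """Ordered ICD code-prefix rules mapping cancer codes to subtype groups."""

    rules: list[tuple[str, tuple[str, ...]]]  # (category, prefixes), in priority order
    fallback: str = "other"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SubtypeMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rules = [
            (cat["name"], tuple(str(p) for p in cat["prefixes"]))
            for cat in raw["categories"]
        ]
        return cls(rules=rules, fallback=raw.get("fallback", "other"))

    @classmethod
    def default(cls) -> "SubtypeMap":
        with resources.as_file(
            resources.files("bdcnv").joinpath("data", "subtype_map.yaml")
        ) as p:
            return cls.from_yaml(p)

    def categories(self) -> list[str]:
        out = [cat for cat, _ in self.rules]
        if self.fallback not in out:
            out.append(self.fallback)
        return out

    def match(self, code: str) -> str | None:
        code = code.strip().upper()
        for category, prefixes in self.rules:
            if any(code.startswith(p.upper()) for p in prefixes):
                return category
        return None


def is_cancer_code(code: str) -> bool:
    """Malignant-neoplasm code: ICD-10 C chapter or ICD-9 140-208."""
    code = code.strip().upper()
    if code.startswith("C"):
        return True
    head = code.split(".")[0]
    if head.isdigit():
        return 140 <= int(head) <= 208
    return False


def assign_subtype(
    diagnoses: Iterable[str], subtype_map: SubtypeMap | None = None
) -> tuple[str, tuple[str, ...]]:
    """Map a patient's diagnosis codes to cancer-subtype categories.

    Returns (primary, all_matches): every matching category is kept for
    multi-membership counting; the primary category is the first match in
    rule order.  A patient with no recognizable cancer code falls back to
    'other' with a warning.
    """
    subtype_map = subtype_map or SubtypeMap.default()
    cancer_codes = [c for c in diagnoses if is_cancer_code(c)]
    if not cancer_codes:
        log.warning("no cancer diagnosis code found; assigning %r", subtype_map.fallback)
        return subtype_map.fallback, (subtype_map.fallback,)
    matched: list[str] = []
    for category, prefixes in subtype_map.rules:
        for code in cancer_codes:
            if subtype_map.match(code) == category:
                if category not in matched:
                    matched.append(category)
                break
    if not matched:
        return subtype_map.fallback, (subtype_map.fallback,)
    return matched[0], tuple(matched)


@dataclass
class ClusterMatrix:
    """Patient × enriched-term incidence counts with a recorded denominator.

    ``counts`` rows are the denominator patients (those carrying at least
    one retained CNV of the requested class), columns the enriched terms;
    a cell is 1 when the patient carries an impacted gene of the term's
    overlap set.  Percentages are always 100·count/denominator.
    """

    counts: pd.DataFrame
    denominator: int
    cnv_class: str

    def column_margins(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def percentages(self) -> pd.Series:
        if self.denominator == 0:
            return self.column_margins() * 0.0
        return 100.0 * self.column_margins() / self.denominator

    def patients_with_any_hit(self) -> frozenset[str]:
        hits = self.counts.sum(axis=1)
        return frozenset(hits.index[hits > 0])


def patient_term_matrix(
    enrichment_results: Sequence[EnrichmentResult],
    impacts: Sequence[GeneImpact],
    patients: Iterable[str],
    cnv_class: SvType | None = None,
) -> ClusterMatrix:
    """Build the patient × term incidence matrix for one CNV class.

    ``patients`` is the denominator set (patients with >= 1 retained CNV of
    the class); a patient scores a term when at least one of their impacted
    genes (of the class) is in the term's overlap-gene set.
    """
    patients = sorted(set(patients))
    genes_by_patient: dict[str, set[str]] = {p: set() for p in patients}
    for imp in impacts:
        if cnv_class is not None and imp.impact_class.svtype != cnv_class:
            continue
        if imp.sample_id in genes_by_patient:
            genes_by_patient[imp.sample_id].add(imp.gene_id)
            genes_by_patient[imp.sample_id].add(imp.symbol)
    terms = [r.term_id for r in enrichment_results]
    data = {
        r.term_id: [
            int(bool(genes_by_patient[p] & set(r.overlap_genes))) for p in patients
        ]
        for r in enrichment_results
    }
    counts = pd.DataFrame(data, index=patients, columns=terms, dtype=int)
    label = cnv_class.value if cnv_class is not None else "ALL"
    return ClusterMatrix(counts=counts, denominator=len(patients), cnv_class=label)


def subtype_matrix(
    matrix: ClusterMatrix, assignments: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Aggregate the patient × term matrix to subtype × term patient counts.

    ``assignments`` maps patient → all matching subtype categories
    (multi-membership: a patient with tumors in two groups counts in both).
    """
    rows = {}
    for category in SUBTYPE_CATEGORIES:
        members = [
            p for p in matrix.counts.index if category in assignments.get(p, ())
        ]
        if members:
            rows[category] = (matrix.counts.loc[members] > 0).sum(axis=0)
        else:
            rows[category] = pd.Series(0, index=matrix.counts.columns, dtype=int)
    return pd.DataFrame(rows).T.fillna(0).astype(int)


@dataclass(frozen=True)
class SubtypeSummary:
    category: str
    n_patients: int
    n_with_hit: int

    @property
    def ratio(self) -> float:
        return self.n_with_hit / self.n_patients if self.n_patients else 0.0


def subtype_summary(
    matrix: ClusterMatrix, assignments: Mapping[str, Sequence[str]]
) -> list[SubtypeSummary]:
    """Per subtype: patients in the denominator and fraction with >= 1 term hit."""
    hit = matrix.patients_with_any_hit()
    out = []
    for category in SUBTYPE_CATEGORIES:
        members = [
            p for p in matrix.counts.index if category in assignments.get(p, ())
        ]
        out.append(
            SubtypeSummary(
                category=category,
                n_patients=len(members),
                n_with_hit=sum(1 for p in members if p in hit),
            )
        )
    return out
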