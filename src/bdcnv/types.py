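"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open internally: ``start`` is the
first affected base, ``end`` is one past the last, and event length is
``end - start``.  VCF I/O converts at the boundary (POS = start+1,
INFO/END = end).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Caller(str, enum.Enum):
    """The four whole-genome CNV callers whose output is merged."""

    MANTA = "MANTA"
    CNVNATOR = "CNVNATOR"
    DELLY = "DELLY"
    LUMPY = "LUMPY"


class SvType(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"


class Cohort(str, enum.Enum):
    BD_CANCER = "BD_CANCER"
    BD_ONLY = "BD_ONLY"
    CONTROL = "CONTROL"


class Biotype(str, enum.Enum):
    protein_coding = "protein_coding"
    lncRNA = "lncRNA"
    other_ncRNA = "other_ncRNA"


class ImpactClass(str, enum.Enum):
    FULL_DEL = "FULL_DEL"
    FULL_DUP = "FULL_DUP"
    PART_DEL = "PART_DEL"
    PART_DUP = "PART_DUP"

    @property
    def svtype(self) -> SvType:
        return SvType.DEL if self.value.endswith("DEL") else SvType.DUP

    @property
    def full(self) -> bool:
        return self.value.startswith("FULL")


@dataclass(frozen=True)
class CnvCall:
    """One caller's DEL/DUP call for one sample.

    ``quality`` is on the caller's own scale (MANTA and DELLY scores get
    floors in the filter stage; CNVnator and LUMPY scores are kept but
    unconstrained).
    """

    sample_id: str
    caller_id: Caller
    chrom: str
    start: int
    end: int
    svtype: SvType
    quality: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start ({self.chrom}:{self.start}-{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: Biotype = Biotype.protein_coding

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    cohort: Cohort
    diagnoses: frozenset[str] = frozenset()


@dataclass
class ConsensusCnv:
    """A merged per-sample CNV supported by one or more callers.

    Coordinates are the member medians (lower median for even counts);
    ``carrier_freq`` is filled by the cohort-frequency filter.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    svtype: SvType
    supporting_callers: frozenset[Caller]
    member_calls: tuple[CnvCall, ...]
    carrier_freq: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_callers(self) -> int:
        return len(self.supporting_callers)

    def key(self) -> tuple:
        """Identity by content, used for deterministic comparison."""
        return (self.sample_id, self.chrom, self.start, self.end, self.svtype.value)


@dataclass(frozen=True)
class GeneImpact:
    sample_id: str
    gene_id: str
    symbol: str
    biotype: Biotype
    impact_class: ImpactClass
    cnv_ref: tuple  # key() of the consensus event
    overlap_start: int
    overlap_end: int

    @property
    def overlap_bp(self) -> int:
        return self.overlap_end - self.overlap_start


@dataclass(frozen=True)
class TargetRecord:
    """One curated regulator→target relationship (LncTarD-style)."""

    regulator_id: str
    cnv_class: ImpactClass | None
    target_id: str
    target_type: str  # protein_coding | miRNA | lncRNA
    diseases: tuple[str, ...] = ()


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    collection: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    fdr: float = field(default=float("nan"))
    overlap_genes: tuple[str, ...] = ()
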