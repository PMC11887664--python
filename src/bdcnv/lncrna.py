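"""Mapping CNV-impacted regulators (lncRNAs and coding genes) to curated targets.

The package ships two small TSV fixtures of experimentally curated
regulator→target relationships (LncTarD-style schema); a user-supplied full
LncTarD 2.0 download with the same columns is read by the same loader.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from . import sv_io
from .types import TargetRecord


def _fixture_path(name: str):
    return resources.files("bdcnv").joinpath("data", "tables", name)


def load_lncrna_target_table() -> list[TargetRecord]:
    """Packaged fixture: CNV-impacted lncRNA regulators with curated targets."""
    with resources.as_file(_fixture_path("table1_lncrna_targets.tsv")) as p:
        return sv_io.read_target_db(p)


def load_gene_target_table() -> list[TargetRecord]:
    """Packaged fixture: CNV-impacted coding-gene regulators with curated targets."""
    with resources.as_file(_fixture_path("table2_gene_targets.tsv")) as p:
        return sv_io.read_target_db(p)


def map_targets(
    impacted_ids: Iterable[str], target_db: Sequence[TargetRecord]
) -> tuple[list[TargetRecord], list[str]]:
    """Look up impacted regulator ids in the target database.

    Returns one record per (regulator, target) pair found, preserving
    database order, plus the sorted list of impacted ids absent from the
    database.  The two lists partition the input ids.
    """
    wanted = set(impacted_ids)
    in_db = {r.regulator_id for r in target_db}
    mapped = [r for r in target_db if r.regulator_id in wanted]
    unmapped = sorted(wanted - in_db)
    return mapped, unmapped


@dataclass(frozen=True)
class TargetSummary:
    n_regulators: int
    n_coding_targets: int
    n_noncoding_targets: int


def summarize_targets(records: Sequence[TargetRecord]) -> TargetSummary:
    """Distinct-identifier counts (idempotent under row duplication)."""
    regulators = {r.regulator_id for r in records}
    coding = {r.target_id for r in records if r.target_type == "protein_coding"}
    noncoding = {r.target_id for r in records if r.target_type != "protein_coding"}
    return TargetSummary(len(regulators), len(coding), len(noncoding))
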