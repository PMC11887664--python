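"""End-to-end orchestration with file-based stage contracts.

Each stage reads and writes plain TSV/JSON so stages are independently
runnable and resumable; every output carries a ``#`` header line with the
run's config hash for provenance, and ``run_all`` records a manifest of
outputs with row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import cohorts, enrichment, impact, lncrna, phenotype, sv_io
from .consensus import MergeConfig, Rejection, run_consensus_from_vcfs
from .types import (
    Biotype, Caller, Cohort, ConsensusCnv, EnrichmentResult, GeneImpact,
    ImpactClass, SvType,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf_dir: str
    gene_models: str
    cohort: str
    gmt_dir: str
    outdir: str
    target_db: str | None = None  # None -> packaged lncRNA fixture table
    subtype_map: str | None = None  # None -> packaged default
    merge: MergeConfig = field(default_factory=MergeConfig)
    min_recurrence: int = 3
    min_term_size: int = 2
    seed: int = 0

    def config_hash(self) -> str:
        payload = {
            "vcf_dir": self.vcf_dir,
            "gene_models": self.gene_models,
            "cohort": self.cohort,
            "gmt_dir": self.gmt_dir,
            "target_db": self.target_db,
            "subtype_map": self.subtype_map,
            "merge": {
                "d_max": self.merge.d_max,
                "min_callers": self.merge.min_callers,
                "min_size": self.merge.min_size,
                "qual_floor": {k.value: v for k, v in self.merge.qual_floor.items()},
                "max_carrier_freq": self.merge.max_carrier_freq,
            },
            "min_recurrence": self.min_recurrence,
            "min_term_size": self.min_term_size,
            "seed": self.seed,
        }
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode())
        return digest.hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: str | Path, config_hash: str) -> int:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# bdcnv config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)
    return len(df)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# stage serialization


def consensus_to_frame(events: Sequence[ConsensusCnv]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": ev.sample_id,
                "chrom": ev.chrom,
                "start": ev.start,
                "end": ev.end,
                "svtype": ev.svtype.value,
                "n_callers": ev.n_callers,
                "callers": ",".join(sorted(c.value for c in ev.supporting_callers)),
                "carrier_freq": ev.carrier_freq,
            }
            for ev in events
        ],
        columns=[
            "sample_id", "chrom", "start", "end", "svtype", "n_callers",
            "callers", "carrier_freq",
        ],
    )


def consensus_from_frame(df: pd.DataFrame) -> list[ConsensusCnv]:
    events = []
    for row in df.itertuples(index=False):
        callers = frozenset(Caller(c) for c in str(row.callers).split(",") if c)
        events.append(
            ConsensusCnv(
                sample_id=str(row.sample_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                svtype=SvType(row.svtype),
                supporting_callers=callers,
                member_calls=(),
                carrier_freq=float(row.carrier_freq),
            )
        )
    return events


def impacts_to_frame(impacts: Sequence[GeneImpact]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": i.sample_id,
                "gene_id": i.gene_id,
                "symbol": i.symbol,
                "biotype": i.biotype.value,
                "impact_class": i.impact_class.value,
                "cnv_chrom": i.cnv_ref[1],
                "cnv_start": i.cnv_ref[2],
                "cnv_end": i.cnv_ref[3],
                "overlap_start": i.overlap_start,
                "overlap_end": i.overlap_end,
                "overlap_bp": i.overlap_bp,
            }
            for i in impacts
        ],
        columns=[
            "sample_id", "gene_id", "symbol", "biotype", "impact_class",
            "cnv_chrom", "cnv_start", "cnv_end", "overlap_start",
            "overlap_end", "overlap_bp",
        ],
    )


def impacts_from_frame(df: pd.DataFrame) -> list[GeneImpact]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            GeneImpact(
                sample_id=str(row.sample_id),
                gene_id=str(row.gene_id),
                symbol=str(row.symbol),
                biotype=Biotype(row.biotype),
                impact_class=ImpactClass(row.impact_class),
                cnv_ref=(
                    str(row.sample_id), str(row.cnv_chrom), int(row.cnv_start),
                    int(row.cnv_end), ImpactClass(row.impact_class).svtype.value,
                ),
                overlap_start=int(row.overlap_start),
                overlap_end=int(row.overlap_end),
            )
        )
    return out


def rejections_to_frame(rejections: Sequence[Rejection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.event.sample_id,
                "chrom": r.event.chrom,
                "start": r.event.start,
                "end": r.event.end,
                "svtype": r.event.svtype.value,
                "n_callers": r.event.n_callers,
                "reason": r.reason,
            }
            for r in rejections
        ],
        columns=["sample_id", "chrom", "start", "end", "svtype", "n_callers", "reason"],
    )


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "collection": r.collection,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "overlap_genes": ",".join(r.overlap_genes),
            }
            for r in results
        ],
        columns=[
            "term_id", "term_name", "collection", "k", "K", "n", "N",
            "p_value", "fdr", "overlap_genes",
        ],
    )


# ---------------------------------------------------------------------------
# in-memory analysis bundle (used by run_all and by the recovery tooling)


@dataclass
class AnalysisResult:
    consensus: list[ConsensusCnv]
    rejections: list[Rejection]
    impacts: list[GeneImpact]
    exclusive_del: list[cohorts.ExclusiveGeneReport]
    exclusive_dup: list[cohorts.ExclusiveGeneReport]
    target_records: list
    target_unmapped: list[str]
    enrichment_del: list[EnrichmentResult]
    enrichment_dup: list[EnrichmentResult]
    matrix_del: phenotype.ClusterMatrix
    matrix_dup: phenotype.ClusterMatrix
    subtype_assignments: dict[str, tuple[str, ...]]


def analyze(
    samples,
    gene_models,
    calls_by_sample,
    collections,
    merge_config: MergeConfig | None = None,
    target_db=None,
    subtype_map: phenotype.SubtypeMap | None = None,
    min_term_size: int = 2,
) -> AnalysisResult:
    """Run every analysis stage on in-memory inputs."""
    from .consensus import run_consensus

    merge_config = merge_config or MergeConfig()
    consensus, rejections = run_consensus(calls_by_sample, samples, merge_config)
    impacts = impact.impact_table(consensus, gene_models)
    excl_del = cohorts.exclusive_genes(impacts, samples, cohorts.ExclusiveCategory.ANY_DEL)
    excl_dup = cohorts.exclusive_genes(impacts, samples, cohorts.ExclusiveCategory.ANY_DUP)

    lnc_ids = {g.gene_id for g in gene_models if g.biotype == Biotype.lncRNA}
    impacted_lnc = sorted(
        {r.gene_id for r in excl_del + excl_dup if r.gene_id in lnc_ids}
    )
    db = target_db if target_db is not None else lncrna.load_lncrna_target_table()
    mapped, unmapped = lncrna.map_targets(impacted_lnc, db)

    universe = [g.gene_id for g in gene_models]
    sel_del = sorted({r.gene_id for r in excl_del})
    sel_dup = sorted({r.gene_id for r in excl_dup})
    enr_del = enrichment.run_ora(sel_del, collections, universe, min_term_size)
    enr_dup = enrichment.run_ora(sel_dup, collections, universe, min_term_size)

    subtype_map = subtype_map or phenotype.SubtypeMap.default()
    assignments: dict[str, tuple[str, ...]] = {}
    for s in samples:
        if s.cohort == Cohort.BD_CANCER:
            _, matched = phenotype.assign_subtype(s.diagnoses, subtype_map)
            assignments[s.sample_id] = matched
    case_ids = set(assignments)
    patients_del = {
        ev.sample_id for ev in consensus
        if ev.svtype == SvType.DEL and ev.sample_id in case_ids
    }
    patients_dup = {
        ev.sample_id for ev in consensus
        if ev.svtype == SvType.DUP and ev.sample_id in case_ids
    }
    matrix_del = phenotype.patient_term_matrix(enr_del, impacts, patients_del, SvType.DEL)
    matrix_dup = phenotype.patient_term_matrix(enr_dup, impacts, patients_dup, SvType.DUP)

    return AnalysisResult(
        consensus=consensus,
        rejections=rejections,
        impacts=impacts,
        exclusive_del=excl_del,
        exclusive_dup=excl_dup,
        target_records=mapped,
        target_unmapped=unmapped,
        enrichment_del=enr_del,
        enrichment_dup=enr_dup,
        matrix_del=matrix_del,
        matrix_dup=matrix_dup,
        subtype_assignments=assignments,
    )


def run_all(config: RunConfig) -> dict:
    """Execute all stages from files and write every output plus a manifest.

    Deterministic and idempotent: re-running with the same inputs and
    config overwrites byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {"config_hash": chash, "outputs": {}}

    def record(name: str, path: Path, n_rows: int) -> None:
        manifest["outputs"][name] = {"path": str(path), "rows": n_rows}

    samples = sv_io.read_cohort_table(config.cohort)
    gene_models = sv_io.read_gene_models(config.gene_models)
    collections = [
        sv_io.read_gene_sets(p) for p in sorted(Path(config.gmt_dir).glob("*.gmt"))
    ]
    calls_by_sample = {}
    for sample in samples:
        sdir = Path(config.vcf_dir) / sample.sample_id
        calls = []
        for caller in Caller:
            vcf = sdir / f"{caller.value}.vcf"
            if vcf.exists():
                calls.extend(
                    sv_io.read_caller_vcf(vcf, caller, sample_id=sample.sample_id).calls
                )
        calls_by_sample[sample.sample_id] = calls

    target_db = (
        sv_io.read_target_db(config.target_db) if config.target_db else None
    )
    subtype_map = (
        phenotype.SubtypeMap.from_yaml(config.subtype_map)
        if config.subtype_map
        else None
    )
    res = analyze(
        samples, gene_models, calls_by_sample, collections,
        merge_config=config.merge, target_db=target_db, subtype_map=subtype_map,
        min_term_size=config.min_term_size,
    )

    n = write_tsv(consensus_to_frame(res.consensus), outdir / "consensus.tsv", chash)
    record("consensus", outdir / "consensus.tsv", n)
    n = write_tsv(rejections_to_frame(res.rejections), outdir / "rejections.tsv", chash)
    record("rejections", outdir / "rejections.tsv", n)
    n = write_tsv(impacts_to_frame(res.impacts), outdir / "impacts.tsv", chash)
    record("impacts", outdir / "impacts.tsv", n)

    for name, reports in (
        ("exclusive_genes_del", res.exclusive_del),
        ("exclusive_genes_dup", res.exclusive_dup),
    ):
        df = pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "category": r.category.value,
                    "recurrence": r.recurrence,
                    "case_patients": ",".join(sorted(r.case_patients)),
                }
                for r in reports
            ],
            columns=["gene_id", "category", "recurrence", "case_patients"],
        )
        n = write_tsv(df, outdir / f"{name}.tsv", chash)
        record(name, outdir / f"{name}.tsv", n)

    recurrent = cohorts.recurrence_table(
        res.exclusive_del, config.min_recurrence
    ) + cohorts.recurrence_table(res.exclusive_dup, config.min_recurrence)
    df = pd.DataFrame(
        [
            {"gene_id": r.gene_id, "category": r.category.value, "recurrence": r.recurrence}
            for r in recurrent
        ],
        columns=["gene_id", "category", "recurrence"],
    )
    n = write_tsv(df, outdir / "recurrent_genes.tsv", chash)
    record("recurrent_genes", outdir / "recurrent_genes.tsv", n)

    df = pd.DataFrame(
        [
            {
                "regulator_id": r.regulator_id,
                "cnv_class": r.cnv_class.value if r.cnv_class else "",
                "target_id": r.target_id,
                "target_type": r.target_type,
                "diseases": ";".join(r.diseases),
            }
            for r in res.target_records
        ],
        columns=["regulator_id", "cnv_class", "target_id", "target_type", "diseases"],
    )
    n = write_tsv(df, outdir / "lncrna_targets.tsv", chash)
    record("lncrna_targets", outdir / "lncrna_targets.tsv", n)

    for name, results in (
        ("enrichment_del", res.enrichment_del),
        ("enrichment_dup", res.enrichment_dup),
    ):
        n = write_tsv(enrichment_to_frame(results), outdir / f"{name}.tsv", chash)
        record(name, outdir / f"{name}.tsv", n)

    for name, matrix in (
        ("patient_term_matrix_del", res.matrix_del),
        ("patient_term_matrix_dup", res.matrix_dup),
    ):
        df = matrix.counts.reset_index(names="sample_id")
        n = write_tsv(df, outdir / f"{name}.tsv", chash)
        record(name, outdir / f"{name}.tsv", n)
        sub = phenotype.subtype_matrix(matrix, res.subtype_assignments)
        df = sub.reset_index(names="subtype")
        n = write_tsv(df, outdir / f"subtype_term_matrix_{name[-3:]}.tsv", chash)
        record(f"subtype_term_matrix_{name[-3:]}", outdir / f"subtype_term_matrix_{name[-3:]}.tsv", n)

    summary_rows = []
    for label, matrix in (("DEL", res.matrix_del), ("DUP", res.matrix_dup)):
        for s in phenotype.subtype_summary(matrix, res.subtype_assignments):
            summary_rows.append(
                {
                    "cnv_class": label,
                    "subtype": s.category,
                    "n_patients": s.n_patients,
                    "n_with_hit": s.n_with_hit,
                    "ratio": round(s.ratio, 4),
                }
            )
    df = pd.DataFrame(
        summary_rows, columns=["cnv_class", "subtype", "n_patients", "n_with_hit", "ratio"]
    )
    n = write_tsv(df, outdir / "subtype_summary.tsv", chash)
    record("subtype_summary", outdir / "subtype_summary.tsv", n)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
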