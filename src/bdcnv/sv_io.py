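"""Reading and writing the pipeline's external formats.

Handles per-caller SV VCFs (symbolic ``<DEL>``/``<DUP>`` records with
INFO ``SVTYPE``/``END``), gene models (BED6+biotype or GFF3), cohort
tables (TSV), GMT gene-set collections and regulator→target tables.

Coordinate conventions at the boundary:

* VCF: POS is the 1-based first affected base, INFO/END the 1-based last
  affected base; internally ``start = POS - 1`` and ``end = END``.
* BED is already 0-based half-open; GFF3 (1-based inclusive) is converted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam

from .types import Biotype, Caller, CnvCall, Cohort, GeneModel, SampleRecord, SvType, TargetRecord

log = logging.getLogger(__name__)

#: GENCODE biotype strings that are non-coding RNA but not lncRNA; these map
#: to ``other_ncRNA`` silently, anything else unknown maps with a warning.
_KNOWN_NCRNA = {
    "miRNA", "snoRNA", "snRNA", "rRNA", "misc_RNA", "scaRNA", "tRNA",
    "other_ncRNA", "Mt_rRNA", "Mt_tRNA", "ribozyme", "vault_RNA",
}


class VcfParseError(ValueError):
    """Raised when a caller VCF cannot be parsed; names the offending line."""


def normalize_chrom(chrom: str, strip_prefix: bool = False) -> str:
    """Normalize chromosome naming; comparisons downstream are exact strings."""
    if strip_prefix and chrom.startswith("chr"):
        return chrom[3:]
    if not strip_prefix and not chrom.startswith("chr"):
        return f"chr{chrom}"
    return chrom


@dataclass
class VcfReadResult:
    """Calls parsed from one caller VCF plus skip accounting."""

    calls: list[CnvCall]
    n_skipped_svtype: int = 0
    n_missing_end: int = 0

    def __iter__(self) -> Iterator[CnvCall]:
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


def read_caller_vcf(
    path: str | Path,
    caller_id: Caller | str,
    sample_id: str | None = None,
    quality_field: str = "QUAL",
) -> VcfReadResult:
    """Read one caller's single-sample SV VCF into :class:`CnvCall` records.

    Only DEL/DUP records are returned; other SVTYPEs (INS, INV, BND, ...)
    are skipped and counted.  A symbolic record without a usable END
    (pysam falls back to ``stop == start + 1``) is rejected and counted.

    ``quality_field`` selects where the caller keeps its score: the QUAL
    column (default for all four supported callers) or an INFO key.
    """
    caller_id = Caller(caller_id)
    path = Path(path)
    n_records = 0
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    result = VcfReadResult(calls=[])
    with vf:
        if sample_id is None:
            samples = list(vf.header.samples)
            sample_id = samples[0] if samples else path.stem
        try:
            for rec in vf:
                n_records += 1
                svtype = rec.info.get("SVTYPE")
                if svtype is None and rec.alts:
                    alt = rec.alts[0]
                    if alt.startswith("<") and alt.endswith(">"):
                        svtype = alt[1:-1]
                if svtype not in ("DEL", "DUP"):
                    result.n_skipped_svtype += 1
                    continue
                start, end = rec.start, rec.stop
                if end <= start + 1:
                    # pysam sets stop = start + len(ref) when END is absent;
                    # a 1 bp symbolic CNV is not representable, so treat as
                    # missing END.
                    result.n_missing_end += 1
                    continue
                if quality_field == "QUAL":
                    # htslib stores QUAL as float32; round-trip through the
                    # 6-significant-digit text form the VCF actually carries
                    quality = (
                        float(f"{rec.qual:.6g}") if rec.qual is not None else float("nan")
                    )
                else:
                    raw = rec.info.get(quality_field)
                    quality = float(raw) if raw is not None else float("nan")
                result.calls.append(
                    CnvCall(
                        sample_id=sample_id,
                        caller_id=caller_id,
                        chrom=rec.chrom,
                        start=start,
                        end=end,
                        svtype=SvType(svtype),
                        quality=quality,
                    )
                )
        except (ValueError, OSError) as exc:
            raise VcfParseError(
                f"{path}: malformed VCF near data line {n_records + 1}: {exc}"
            ) from exc
    if result.n_skipped_svtype:
        log.info(
            "%s: skipped %d non-DEL/DUP record(s)", path, result.n_skipped_svtype
        )
    if result.n_missing_end:
        log.warning(
            "%s: rejected %d symbolic record(s) without END", path, result.n_missing_end
        )
    return result


def write_caller_vcf(
    calls: Sequence[CnvCall],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write calls of one (sample, caller) as a VCF 4.2 with symbolic ALTs.

    Rows are sorted by (chrom, POS).  An empty call set yields a valid
    header-only file (the sample column is still emitted when the sample id
    is known from ``calls``; for an empty set a sites-only header is
    written).
    """
    path = Path(path)
    samples = {c.sample_id for c in calls}
    callers = {c.caller_id for c in calls}
    if len(samples) > 1 or len(callers) > 1:
        raise ValueError("write_caller_vcf requires a single (sample, caller)")

    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    contigs = sorted({c.chrom for c in calls})
    lengths = contig_lengths or {}
    for chrom in sorted(set(contigs) | set(lengths)):
        if chrom in lengths:
            header.contigs.add(chrom, length=lengths[chrom])
        else:
            header.contigs.add(chrom)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("END", 1, "Integer", "End position of the variant (1-based inclusive)")
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    header.add_line('##ALT=<ID=DUP,Description="Duplication">')
    header.formats.add("GT", 1, "String", "Genotype")
    if samples:
        (sample_id,) = samples
        header.add_sample(sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for call in sorted(calls, key=lambda c: (c.chrom, c.start, c.end)):
            rec = vf.new_record(
                contig=call.chrom,
                start=call.start,
                stop=call.end,
                alleles=("N", f"<{call.svtype.value}>"),
                qual=call.quality,
            )
            rec.info["SVTYPE"] = call.svtype.value
            if samples:
                rec.samples[call.sample_id]["GT"] = (0, 1)
            vf.write(rec)


# ---------------------------------------------------------------------------
# gene models


def _map_biotype(raw: str) -> Biotype:
    if raw == "protein_coding":
        return Biotype.protein_coding
    if raw in ("lncRNA", "lincRNA"):
        return Biotype.lncRNA
    if raw not in _KNOWN_NCRNA:
        log.warning("unknown biotype %r mapped to other_ncRNA", raw)
    return Biotype.other_ncRNA


def read_gene_models(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from BED6+biotype or GFF3 (autodetected by suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    if fmt == "bed":
        return _read_gene_models_bed(path)
    if fmt == "gff3":
        return _read_gene_models_gff3(path)
    raise ValueError(f"unknown gene-model format {fmt!r}")


def _read_gene_models_bed(path: Path) -> list[GeneModel]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand", "biotype"],
        dtype={"chrom": str, "name": str, "biotype": str},
    )
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=row.name,
                symbol=row.name,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand if row.strand in ("+", "-") else ".",
                biotype=_map_biotype(str(row.biotype)),
            )
        )
    _check_unique_gene_ids(genes)
    return genes


def _read_gene_models_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("gene_id", feat.attributes.get("ID", [feat.id]))[0]
        symbol = feat.attributes.get("gene_name", feat.attributes.get("Name", [gene_id]))[0]
        biotype_raw = feat.attributes.get(
            "gene_type", feat.attributes.get("gene_biotype", ["protein_coding"])
        )[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=symbol,
                chrom=feat.seqid,
                start=feat.start - 1,  # GFF3 1-based inclusive → half-open
                end=feat.end,
                strand=feat.strand or ".",
                biotype=_map_biotype(biotype_raw),
            )
        )
    _check_unique_gene_ids(genes)
    return genes


def _check_unique_gene_ids(genes: Sequence[GeneModel]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in gene models")
        seen.add(g.gene_id)


def write_gene_models_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t.\t{g.strand}\t{g.biotype.value}\n"
            )


# ---------------------------------------------------------------------------
# cohort table


def read_cohort_table(path: str | Path) -> list[SampleRecord]:
    """Read the cohort TSV: sample_id, cohort label, semicolon-joined ICD codes."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["sample_id", "cohort", "diagnoses"], dtype=str,
    )
    if len(df) and df.iloc[0].sample_id == "sample_id":
        df = df.iloc[1:]
    records: list[SampleRecord] = []
    seen: set[str] = set()
    allowed = [c.value for c in Cohort]
    for row in df.itertuples(index=False):
        if row.sample_id in seen:
            raise ValueError(f"duplicate sample_id {row.sample_id!r} in cohort table")
        seen.add(row.sample_id)
        try:
            cohort = Cohort(row.cohort)
        except ValueError:
            raise ValueError(
                f"unknown cohort label {row.cohort!r} for sample {row.sample_id}; "
                f"allowed: {allowed}"
            ) from None
        diag = row.diagnoses if isinstance(row.diagnoses, str) else ""
        codes = frozenset(c.strip() for c in diag.split(";") if c.strip())
        records.append(SampleRecord(row.sample_id, cohort, codes))
    return records


def write_cohort_table(records: Sequence[SampleRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcohort\tdiagnoses\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.cohort.value}\t{';'.join(sorted(r.diagnoses))}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT) and target tables


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (one GMT file)."""

    name: str
    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


def read_gene_sets(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: TERM <tab> description <tab> gene1 <tab> gene2 ..."""
    path = Path(path)
    coll = GeneSetCollection(name=name or path.stem)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term, desc, genes = fields[0], fields[1], fields[2:]
            coll.sets[term] = frozenset(g for g in genes if g)
            coll.descriptions[term] = desc
    return coll


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in coll.sets:
            desc = coll.descriptions.get(term, "")
            genes = "\t".join(sorted(coll.sets[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


_CNV_CLASS_ALIASES = {
    "FULL_DEL": "FULL_DEL", "FULLY DELETION": "FULL_DEL",
    "FULL_DUP": "FULL_DUP", "FULLY DUPLICATION": "FULL_DUP",
    "PART_DEL": "PART_DEL", "PARTIALLY DELETION": "PART_DEL",
    "PART_DUP": "PART_DUP", "PARTIALLY DUPLICATION": "PART_DUP",
}


def infer_target_type(target_id: str) -> str:
    """Prefix heuristic used when a table lacks an explicit target_type."""
    up = target_id.upper()
    if up.startswith("MIR-") or up.startswith("MIR") and up[3:4].isdigit():
        return "miRNA"
    if up.startswith("LINC") or up.startswith("LNC") or up.endswith("-AS") or "-AS1" in up:
        return "lncRNA"
    return "protein_coding"


def read_target_db(path: str | Path) -> list[TargetRecord]:
    """Read a regulator→target TSV (packaged fixture or LncTarD download).

    Expected columns: regulator_id, cnv_class, target_id, then optionally
    target_type and semicolon-joined diseases.  The cnv_class column accepts
    both internal labels (FULL_DEL, ...) and the printed forms
    ("Fully deletion", ...).
    """
    from .types import ImpactClass

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"regulator_id", "target_id"}
    if not required <= set(df.columns):
        raise ValueError(f"target table must have columns {sorted(required)}")
    records: list[TargetRecord] = []
    for row in df.itertuples(index=False):
        raw_class = getattr(row, "cnv_class", "").strip()
        cnv_class = None
        if raw_class:
            normalized = _CNV_CLASS_ALIASES.get(raw_class.upper().replace("‐", "-"))
            if normalized is None:
                raise ValueError(f"unrecognized cnv_class {raw_class!r}")
            cnv_class = ImpactClass(normalized)
        target_type = getattr(row, "target_type", "").strip() or infer_target_type(row.target_id)
        diseases = tuple(
            d.strip() for d in getattr(row, "diseases", "").split(";") if d.strip()
        )
        records.append(
            TargetRecord(
                regulator_id=row.regulator_id.strip(),
                cnv_class=cnv_class,
                target_id=row.target_id.strip(),
                target_type=target_type,
                diseases=diseases,
            )
        )
    return records
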