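"""Synthetic multi-caller CNV cohorts with planted ground truth.

Emulates the data-generating process the analysis consumes: three cohorts
(BD-cancer, BD-only, family controls) of germline CNV call sets from four
callers with breakpoint jitter, caller-specific quality scales, false
positives, one polymorphic (common) CNV locus, and case-exclusive full-gene
deletions drawn mostly from one planted pathway.  Everything is
deterministic given the seed, and the ground truth needed for recovery
scoring is emitted alongside the call sets.

What the generator does *not* emulate: read-level noise, realistic human
genome coordinates or gene density, segmental-duplication artifacts, and
familial transmission between probands and their control relatives.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import sv_io
from .consensus import MergeConfig, compatible
from .sv_io import GeneSetCollection
from .types import (
    Biotype, Caller, CnvCall, Cohort, ConsensusCnv, GeneModel, SampleRecord, SvType,
)

_BD_CODES = ("742.4", "Q85.01", "745.5", "Q21.1", "749.0")
#: cancer diagnosis pool spanning the seven subtype groups
_CANCER_CODES = (
    "191.9", "192", "C71.9",            # brain / nervous system
    "170.9", "171.5", "C41.9", "C49.9", # bone / connective / soft tissue
    "162.9", "C34.9", "153.9",          # respiratory / digestive
    "193", "C73",                       # endocrine / gland
    "189.0", "C64",                     # kidney
    "190.5", "C69.2",                   # eye
    "172.9", "C43.9",                   # melanoma -> 'other'
)


@dataclass
class QualityModel:
    """Per-caller Normal score distributions for true and false calls."""

    true_mean: float
    true_sd: float
    false_mean: float
    false_sd: float


def _default_quality_models() -> dict[Caller, QualityModel]:
    return {
        Caller.MANTA: QualityModel(300, 80, 40, 20),
        Caller.DELLY: QualityModel(2000, 400, 300, 150),
        Caller.CNVNATOR: QualityModel(50, 10, 10, 5),
        Caller.LUMPY: QualityModel(50, 10, 10, 5),
    }


@dataclass
class SimConfig:
    """Study conditions of the simulated cohorts.

    Defaults describe the scaled-down cohort the test suite and the
    reproduction script run: 60/80/40 case/BD-only/control samples on a
    5 × 10 Mb genome with 800 genes (~10% lncRNA), a Poisson(8) rate of
    true CNVs per sample sized log-uniformly between 10 kb and 1 Mb,
    per-caller sensitivity 0.92, breakpoint jitter N(0, 150 bp) clipped to
    ±900 bp (inside the 1 kb merge tolerance, so jitter never breaks
    compatibility between true calls), 5 false calls per caller per sample
    (half under the 10 kb size floor), 12 planted case-exclusive full-gene
    deletions drawn 80% from one planted pathway, and one common deletion
    locus carried by exactly 10% of all samples.
    """

    seed: int = 0
    n_case: int = 60
    n_bdonly: int = 80
    n_control: int = 40
    n_chroms: int = 5
    chrom_length: int = 10_000_000
    n_genes: int = 800
    frac_lncrna: float = 0.10
    frac_other_ncrna: float = 0.025
    gene_size_range: tuple[int, int] = (2_000, 50_000)
    cnv_rate: float = 8.0
    cnv_size_range: tuple[int, int] = (10_000, 1_000_000)
    p_del: float = 0.5
    jitter_sd: float = 150.0
    jitter_clip: int = 900
    caller_sensitivity: dict[Caller, float] = field(
        default_factory=lambda: {c: 0.92 for c in Caller}
    )
    fp_rate: float = 5.0
    quality_model: dict[Caller, QualityModel] = field(
        default_factory=_default_quality_models
    )
    n_exclusive_genes: int = 12
    exclusive_carrier_prob: float = 0.08
    #: every planted gene gets at least this many case carriers so that
    #: exclusivity ground truth stays informative at desk scale
    min_exclusive_carriers: int = 3
    common_cnv_freq: float = 0.10
    common_cnv_size: int = 50_000
    planted_term_frac: float = 0.8
    n_terms: int = 20
    term_size: int = 40

    @classmethod
    def noise_free(cls, seed: int = 0, **overrides) -> "SimConfig":
        """The noise-free limit: perfect sensitivity, no FPs, no jitter,
        and degenerate (zero-variance) quality scores at the caller means."""
        qm = {
            c: QualityModel(m.true_mean, 0.0, m.false_mean, 0.0)
            for c, m in _default_quality_models().items()
        }
        # scale/cohort overrides are honored; the noise parameters define the
        # limit and are fixed here
        for noise_key in ("caller_sensitivity", "fp_rate", "jitter_sd", "quality_model"):
            overrides.pop(noise_key, None)
        return cls(
            seed=seed,
            caller_sensitivity={c: 1.0 for c in Caller},
            fp_rate=0.0,
            jitter_sd=0.0,
            quality_model=qm,
            **overrides,
        )

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_bdonly + self.n_control

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass(frozen=True)
class TrueCnv:
    sample_id: str
    chrom: str
    start: int
    end: int
    svtype: SvType
    kind: str  # background | exclusive | common
    gene_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """Ground truth serialized alongside the simulated call sets."""

    true_cnvs: list[TrueCnv]
    exclusive_genes: dict[str, list[str]]  # gene_id -> case carrier sample ids
    common_locus: tuple[str, int, int, str]
    common_carriers: list[str]
    planted_term: str

    def expected_consensus(self) -> list[TrueCnv]:
        """True CNVs expected to survive the full filter chain (the common
        locus is removed by the carrier-frequency filter by design)."""
        return [t for t in self.true_cnvs if t.kind != "common"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_cnvs": [
                {**asdict(t), "svtype": t.svtype.value} for t in self.true_cnvs
            ],
            "exclusive_genes": self.exclusive_genes,
            "common_locus": list(self.common_locus),
            "common_carriers": self.common_carriers,
            "planted_term": self.planted_term,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        raw = json.loads(Path(path).read_text())
        return cls(
            true_cnvs=[
                TrueCnv(**{**t, "svtype": SvType(t["svtype"])})
                for t in raw["true_cnvs"]
            ],
            exclusive_genes=raw["exclusive_genes"],
            common_locus=tuple(raw["common_locus"]),
            common_carriers=raw["common_carriers"],
            planted_term=raw["planted_term"],
        )


@dataclass
class SimulatedCohort:
    config: SimConfig
    samples: list[SampleRecord]
    gene_models: list[GeneModel]
    calls_by_sample: dict[str, list[CnvCall]]
    collections: list[GeneSetCollection]
    truth: TruthSet

    def write_outputs(self, outdir: str | Path) -> dict[str, str]:
        """Materialize every input the file-based pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lengths = {c: self.config.chrom_length for c in self.config.chrom_names()}
        vcf_dir = outdir / "vcfs"
        for sample in self.samples:
            sdir = vcf_dir / sample.sample_id
            sdir.mkdir(parents=True, exist_ok=True)
            calls = self.calls_by_sample[sample.sample_id]
            for caller in Caller:
                sv_io.write_caller_vcf(
                    [c for c in calls if c.caller_id == caller],
                    sdir / f"{caller.value}.vcf",
                    contig_lengths=lengths,
                )
        sv_io.write_gene_models_bed(self.gene_models, outdir / "genes.bed")
        sv_io.write_cohort_table(self.samples, outdir / "cohort.tsv")
        gmt_dir = outdir / "gmt"
        gmt_dir.mkdir(exist_ok=True)
        for coll in self.collections:
            sv_io.write_gene_sets(coll, gmt_dir / f"{coll.name}.gmt")
        truth_dir = outdir / "truth"
        truth_dir.mkdir(exist_ok=True)
        self.truth.to_json(truth_dir / "truth.json")
        return {
            "vcf_dir": str(vcf_dir),
            "gene_models": str(outdir / "genes.bed"),
            "cohort": str(outdir / "cohort.tsv"),
            "gmt_dir": str(gmt_dir),
            "truth": str(truth_dir / "truth.json"),
        }


# ---------------------------------------------------------------------------
# generation


def _place_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    chroms = config.chrom_names()
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    lo, hi = config.gene_size_range
    genes: list[GeneModel] = []
    idx = 0
    n_lnc = int(round(config.n_genes * config.frac_lncrna))
    n_other = int(round(config.n_genes * config.frac_other_ncrna))
    biotypes = np.array(
        [Biotype.lncRNA] * n_lnc
        + [Biotype.other_ncRNA] * n_other
        + [Biotype.protein_coding] * (config.n_genes - n_lnc - n_other),
        dtype=object,
    )
    rng.shuffle(biotypes)
    for chrom, n_c in zip(chroms, per_chrom):
        lengths = np.exp(rng.uniform(math.log(lo), math.log(hi), n_c)).astype(int)
        free = config.chrom_length - int(lengths.sum())
        if free <= 0:
            raise ValueError("infeasible gene placement: genome too small")
        gaps = np.sort(rng.uniform(0, free, n_c)).astype(int)
        offsets = gaps + np.concatenate(([0], np.cumsum(lengths[:-1])))
        for start, length in zip(offsets, lengths):
            biotype = biotypes[idx]
            prefix = {"lncRNA": "LNC", "other_ncRNA": "NCR"}.get(biotype.value, "G")
            gene_id = f"{prefix}{idx:04d}"
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    symbol=gene_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(start + length),
                    strand="+" if rng.random() < 0.5 else "-",
                    biotype=biotype,
                )
            )
            idx += 1
    return genes


def _make_collections(
    config: SimConfig, genes: Sequence[GeneModel], rng: np.random.Generator
) -> tuple[list[GeneSetCollection], str]:
    coding = [g.gene_id for g in genes if g.biotype == Biotype.protein_coding]
    pathways = GeneSetCollection(name="pathways")
    for i in range(config.n_terms):
        term = f"TERM{i + 1:02d}"
        members = rng.choice(coding, size=min(config.term_size, len(coding)), replace=False)
        pathways.sets[term] = frozenset(members.tolist())
        pathways.descriptions[term] = f"synthetic pathway {i + 1}"
    go = GeneSetCollection(name="go_slim")
    for i in range(max(5, config.n_terms // 2)):
        term = f"GO{i + 1:04d}"
        members = rng.choice(
            coding, size=min(max(10, config.term_size // 2), len(coding)), replace=False
        )
        go.sets[term] = frozenset(members.tolist())
        go.descriptions[term] = f"synthetic GO term {i + 1}"
    return [pathways, go], "TERM01"


def _too_close(a: tuple[str, int, int, SvType], b: tuple[str, int, int, SvType],
               margin: int) -> bool:
    """Overlapping, or same-type breakpoints within ``margin`` (events that
    could entangle during merging)."""
    if a[0] != b[0]:
        return False
    overlap = a[1] < b[2] and b[1] < a[2]
    same_type_near = (
        a[3] == b[3] and abs(a[1] - b[1]) <= margin and abs(a[2] - b[2]) <= margin
    )
    return overlap or same_type_near


def simulate_cohort(config: SimConfig | None = None) -> SimulatedCohort:
    """Generate one cohort: samples, gene models, truth CNVs, caller call sets."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    chroms = config.chrom_names()

    genes = _place_genes(config, rng)
    collections, planted_term = _make_collections(config, genes, rng)

    # samples and diagnoses -------------------------------------------------
    samples: list[SampleRecord] = []
    for i in range(config.n_case):
        codes = set(rng.choice(_BD_CODES, size=rng.integers(1, 3), replace=False))
        codes.add(str(rng.choice(_CANCER_CODES)))
        if rng.random() < 0.2:
            codes.add(str(rng.choice(_CANCER_CODES)))
        samples.append(SampleRecord(f"CASE{i:03d}", Cohort.BD_CANCER, frozenset(codes)))
    for i in range(config.n_bdonly):
        codes = frozenset(rng.choice(_BD_CODES, size=rng.integers(1, 3), replace=False))
        samples.append(SampleRecord(f"BDON{i:03d}", Cohort.BD_ONLY, codes))
    for i in range(config.n_control):
        samples.append(SampleRecord(f"CTRL{i:03d}", Cohort.CONTROL, frozenset()))
    case_ids = [s.sample_id for s in samples if s.cohort == Cohort.BD_CANCER]
    all_ids = [s.sample_id for s in samples]

    # planted exclusive genes ----------------------------------------------
    coding_by_id = {g.gene_id: g for g in genes if g.biotype == Biotype.protein_coding}
    term_genes = sorted(
        set(collections[0].sets[planted_term]) & set(coding_by_id)
    )
    other_genes = sorted(set(coding_by_id) - set(term_genes))
    n_from_term = int(round(config.planted_term_frac * config.n_exclusive_genes))
    exclusive: list[str] = []

    def far_enough(gene: GeneModel) -> bool:
        for gid in exclusive:
            g2 = coding_by_id[gid]
            if gene.chrom == g2.chrom and abs(gene.start - g2.start) < 200_000:
                return False
        return True

    for gid in list(rng.permutation(term_genes)):
        if len(exclusive) >= n_from_term:
            break
        if far_enough(coding_by_id[gid]):
            exclusive.append(gid)
    for gid in list(rng.permutation(other_genes)):
        if len(exclusive) >= config.n_exclusive_genes:
            break
        if far_enough(coding_by_id[gid]):
            exclusive.append(gid)
    exclusive_spans = [
        (coding_by_id[g].chrom, coding_by_id[g].start, coding_by_id[g].end)
        for g in exclusive
    ]

    # common CNV locus (placed clear of the planted genes) -------------------
    while True:
        chrom = chroms[int(rng.integers(0, config.n_chroms))]
        start = int(rng.integers(0, config.chrom_length - config.common_cnv_size))
        end = start + config.common_cnv_size
        if not any(
            c == chrom and start < e2 + 5_000 and s2 - 5_000 < end
            for c, s2, e2 in exclusive_spans
        ):
            break
    common_locus = (chrom, start, end, SvType.DEL.value)
    n_common = int(round(config.common_cnv_freq * config.n_samples))
    common_carriers = sorted(
        rng.choice(all_ids, size=n_common, replace=False).tolist()
    )

    # truth CNVs ------------------------------------------------------------
    truths_by_sample: dict[str, list[TrueCnv]] = {sid: [] for sid in all_ids}
    for sid in common_carriers:
        truths_by_sample[sid].append(
            TrueCnv(sid, common_locus[0], common_locus[1], common_locus[2],
                    SvType.DEL, "common")
        )

    exclusive_carriers: dict[str, list[str]] = {}
    for gid in exclusive:
        gene = coding_by_id[gid]
        forced = rng.choice(
            case_ids, size=min(config.min_exclusive_carriers, len(case_ids)),
            replace=False,
        ).tolist()
        carriers = set(forced)
        for sid in case_ids:
            if sid not in carriers and rng.random() < config.exclusive_carrier_prob:
                carriers.add(sid)
        exclusive_carriers[gid] = sorted(carriers)
        planted_here: list[tuple[int, int]] = []
        for sid in exclusive_carriers[gid]:
            for _ in range(200):
                pad_l = int(rng.integers(5_000, 30_000))
                pad_r = int(rng.integers(5_000, 30_000))
                start = max(0, gene.start - pad_l)
                end = min(config.chrom_length, gene.end + pad_r)
                cand = (gene.chrom, start, end, SvType.DEL)
                if any(
                    _too_close(cand, (t.chrom, t.start, t.end, t.svtype), 3_000)
                    for t in truths_by_sample[sid]
                ):
                    continue
                # carriers of the same gene must stay breakpoint-incompatible,
                # or the rare-variant frequency filter would cluster them
                if any(
                    abs(start - s) <= 3_000 and abs(end - e) <= 3_000
                    for s, e in planted_here
                ):
                    continue
                truths_by_sample[sid].append(
                    TrueCnv(sid, gene.chrom, start, end, SvType.DEL,
                            "exclusive", gene_id=gid)
                )
                planted_here.append((start, end))
                break

    lo, hi = config.cnv_size_range
    chrom_weights = np.full(config.n_chroms, 1.0 / config.n_chroms)
    for sample in samples:
        sid = sample.sample_id
        avoid_exclusive = sample.cohort != Cohort.BD_CANCER
        n_bg = int(rng.poisson(config.cnv_rate))
        for _ in range(n_bg):
            for _attempt in range(100):
                chrom = chroms[int(rng.choice(config.n_chroms, p=chrom_weights))]
                size = int(np.exp(rng.uniform(math.log(lo), math.log(hi))))
                start = int(rng.integers(0, max(1, config.chrom_length - size)))
                end = start + size
                svtype = SvType.DEL if rng.random() < config.p_del else SvType.DUP
                cand = (chrom, start, end, svtype)
                if avoid_exclusive and any(
                    c == chrom and start < e2 and s2 < end
                    for c, s2, e2 in exclusive_spans
                ):
                    continue
                # stay breakpoint-clear of the common locus so its planted
                # carrier frequency is exact
                if (
                    chrom == common_locus[0]
                    and abs(start - common_locus[1]) <= 3_000
                    and abs(end - common_locus[2]) <= 3_000
                ):
                    continue
                if any(
                    _too_close(cand, (t.chrom, t.start, t.end, t.svtype), 3_000)
                    for t in truths_by_sample[sid]
                ):
                    continue
                truths_by_sample[sid].append(
                    TrueCnv(sid, chrom, start, end, svtype, "background")
                )
                break

    # caller emission -------------------------------------------------------
    calls_by_sample: dict[str, list[CnvCall]] = {}
    clip = config.jitter_clip

    def jitter(pos: int) -> int:
        if config.jitter_sd == 0:
            return pos
        delta = float(np.clip(rng.normal(0.0, config.jitter_sd), -clip, clip))
        return max(0, pos + int(round(delta)))

    for sid in all_ids:
        truths = sorted(
            truths_by_sample[sid], key=lambda t: (t.chrom, t.start, t.end)
        )
        calls: list[CnvCall] = []
        for caller in Caller:
            sens = config.caller_sensitivity[caller]
            qm = config.quality_model[caller]
            for t in truths:
                if rng.random() >= sens:
                    continue
                # 2-decimal scores survive the VCF QUAL column exactly
                qual = round(max(0.0, float(rng.normal(qm.true_mean, qm.true_sd))), 2)
                calls.append(
                    CnvCall(sid, caller, t.chrom, jitter(t.start), jitter(t.end),
                            t.svtype, qual)
                )
            n_fp = int(rng.poisson(config.fp_rate))
            for _ in range(n_fp):
                if rng.random() < 0.5:
                    size = int(np.exp(rng.uniform(math.log(1_000), math.log(lo))))
                else:
                    size = int(np.exp(rng.uniform(math.log(lo), math.log(hi))))
                chrom = chroms[int(rng.integers(0, config.n_chroms))]
                start = int(rng.integers(0, max(1, config.chrom_length - size)))
                svtype = SvType.DEL if rng.random() < 0.5 else SvType.DUP
                qual = round(max(0.0, float(rng.normal(qm.false_mean, qm.false_sd))), 2)
                calls.append(
                    CnvCall(sid, caller, chrom, start, start + size, svtype, qual)
                )
        calls_by_sample[sid] = calls

    truth = TruthSet(
        true_cnvs=[t for sid in all_ids for t in sorted(
            truths_by_sample[sid], key=lambda t: (t.chrom, t.start, t.end))],
        exclusive_genes=exclusive_carriers,
        common_locus=common_locus,
        common_carriers=common_carriers,
        planted_term=planted_term,
    )
    return SimulatedCohort(
        config=config,
        samples=samples,
        gene_models=genes,
        calls_by_sample=calls_by_sample,
        collections=collections,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# recovery scoring


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


@dataclass
class RecoveryScore:
    recall: float
    precision: float
    n_truth: int
    n_consensus: int
    exclusive_recovery: float
    n_exclusive_reported: int
    planted_term_rank: int | None
    common_cnv_retained: int

    def to_dict(self) -> dict:
        return asdict(self)


def match_consensus_to_truth(
    consensus: Sequence[ConsensusCnv],
    truth: TruthSet,
    min_reciprocal_overlap: float = 0.8,
) -> tuple[int, int, int]:
    """Greedy best-overlap matching of consensus events to expected truth.

    Returns (n_matched, n_expected_truth, n_consensus).  A pair matches
    when sample, chromosome and type agree and reciprocal overlap is at
    least the threshold.
    """
    expected = truth.expected_consensus()
    by_key: dict[tuple, list[ConsensusCnv]] = {}
    for ev in consensus:
        by_key.setdefault((ev.sample_id, ev.chrom, ev.svtype), []).append(ev)
    used: set[int] = set()
    n_matched = 0
    for t in expected:
        best, best_ro = None, 0.0
        for ev in by_key.get((t.sample_id, t.chrom, t.svtype), []):
            if id(ev) in used:
                continue
            ro = reciprocal_overlap(t.start, t.end, ev.start, ev.end)
            if ro >= min_reciprocal_overlap and ro > best_ro:
                best, best_ro = ev, ro
        if best is not None:
            used.add(id(best))
            n_matched += 1
    return n_matched, len(expected), len(consensus)


def score_recovery(
    consensus: Sequence[ConsensusCnv],
    truth: TruthSet,
    exclusive_reported: Sequence[str] = (),
    enrichment_results: Sequence = (),
    min_reciprocal_overlap: float = 0.8,
) -> RecoveryScore:
    """Compare pipeline output against the generator's ground truth."""
    n_matched, n_truth, n_cons = match_consensus_to_truth(
        consensus, truth, min_reciprocal_overlap
    )
    planted = set(truth.exclusive_genes)
    reported = set(exclusive_reported)
    excl_recovery = (
        len(reported & planted) / len(planted) if planted else float("nan")
    )
    rank = None
    ordered = sorted(enrichment_results, key=lambda r: (r.fdr, r.p_value, r.term_id))
    for i, r in enumerate(ordered, start=1):
        if r.term_id == truth.planted_term:
            rank = i
            break
    chrom, start, end, svtype = truth.common_locus
    common_retained = sum(
        1
        for ev in consensus
        if ev.chrom == chrom
        and ev.svtype.value == svtype
        and reciprocal_overlap(start, end, ev.start, ev.end) >= min_reciprocal_overlap
    )
    return RecoveryScore(
        recall=n_matched / n_truth if n_truth else float("nan"),
        precision=n_matched / n_cons if n_cons else float("nan"),
        n_truth=n_truth,
        n_consensus=n_cons,
        exclusive_recovery=excl_recovery,
        n_exclusive_reported=len(reported),
        planted_term_rank=rank,
        common_cnv_retained=common_retained,
    )
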