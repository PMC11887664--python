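"""Four-caller consensus merging of germline CNV calls.

Per sample, calls of the same (chromosome, type) are clustered as connected
components of the pairwise breakpoint-compatibility graph (both breakpoints
within ``d_max``); each cluster is collapsed to its median coordinates.
Merged events are then filtered on caller support, size and per-caller
quality floors, and finally on cohort-wide carrier frequency, leaving rare
events supported by at least three independent callers.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .types import Caller, CnvCall, ConsensusCnv, SampleRecord, SvType

log = logging.getLogger(__name__)


@dataclass
class MergeConfig:
    """Thresholds of the consensus-merge and filter stages.

    Defaults: breakpoints within 1 kb,
    support from at least 3 of the 4 callers, minimum event size 10 kb
    (inclusive), MANTA quality >= 100, DELLY quality >= 1000, and removal
    of events carried by >= 5% of all samples.  CNVnator and LUMPY carry
    no quality floor.
    """

    d_max: int = 1000
    min_callers: int = 3
    min_size: int = 10_000
    qual_floor: dict[Caller, float] = field(
        default_factory=lambda: {Caller.MANTA: 100.0, Caller.DELLY: 1000.0}
    )
    max_carrier_freq: float = 0.05

    def __post_init__(self) -> None:
        if self.d_max < 0:
            raise ValueError("d_max must be >= 0")
        if not 1 <= self.min_callers <= 4:
            raise ValueError("min_callers must be in 1..4")
        if self.min_size <= 0:
            raise ValueError("min_size must be > 0")
        if not 0 < self.max_carrier_freq <= 1:
            raise ValueError("max_carrier_freq must be in (0, 1]")
        self.qual_floor = {Caller(k): float(v) for k, v in self.qual_floor.items()}


def compatible(a: CnvCall | ConsensusCnv, b: CnvCall | ConsensusCnv, d_max: int) -> bool:
    """Breakpoint compatibility: same chrom/type, both breakpoints within d_max."""
    return (
        a.chrom == b.chrom
        and a.svtype == b.svtype
        and abs(a.start - b.start) <= d_max
        and abs(a.end - b.end) <= d_max
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _connected_components(items: Sequence, d_max: int) -> list[list]:
    """Connected components under `compatible`, via a sorted start sweep.

    Compatibility requires |Δstart| <= d_max, so only pairs within a
    d_max window of sorted starts need checking; components can still
    chain beyond d_max end-to-end.
    """
    order = sorted(range(len(items)), key=lambda i: (items[i].start, items[i].end))
    uf = _UnionFind(len(items))
    for oi, i in enumerate(order):
        for j in order[oi + 1:]:
            if items[j].start - items[i].start > d_max:
                break
            if compatible(items[i], items[j], d_max):
                uf.union(i, j)
    groups: dict[int, list] = defaultdict(list)
    for i in range(len(items)):
        groups[uf.find(i)].append(items[i])
    # deterministic order: by leftmost member
    comps = list(groups.values())
    comps.sort(key=lambda c: min((x.start, x.end) for x in c))
    return comps


def cluster_sample_calls(calls: Sequence[CnvCall], config: MergeConfig) -> list[list[CnvCall]]:
    """Cluster one sample's calls per (chrom, svtype); dedup same-caller members.

    Within a component, at most one call per caller is retained: highest
    quality wins, ties broken by leftmost start.
    """
    samples = {c.sample_id for c in calls}
    if len(samples) > 1:
        raise ValueError("cluster_sample_calls expects calls of a single sample")
    by_group: dict[tuple[str, SvType], list[CnvCall]] = defaultdict(list)
    for c in calls:
        by_group[(c.chrom, c.svtype)].append(c)
    clusters: list[list[CnvCall]] = []
    for key in sorted(by_group, key=lambda k: (k[0], k[1].value)):
        for comp in _connected_components(by_group[key], config.d_max):
            clusters.append(_dedup_callers(comp))
    return clusters


def _dedup_callers(component: list[CnvCall]) -> list[CnvCall]:
    best: dict[Caller, CnvCall] = {}
    for call in sorted(component, key=lambda c: (c.start, c.end)):
        cur = best.get(call.caller_id)
        if cur is None or call.quality > cur.quality:
            best[call.caller_id] = call
    return sorted(best.values(), key=lambda c: (c.caller_id.value,))


def _lower_median(values: Sequence[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def merge_cluster(cluster: Sequence[CnvCall]) -> ConsensusCnv:
    """Collapse a cluster to one event at the member-median breakpoints."""
    if not cluster:
        raise ValueError("cannot merge an empty cluster")
    first = cluster[0]
    return ConsensusCnv(
        sample_id=first.sample_id,
        chrom=first.chrom,
        start=_lower_median([c.start for c in cluster]),
        end=_lower_median([c.end for c in cluster]),
        svtype=first.svtype,
        supporting_callers=frozenset(c.caller_id for c in cluster),
        member_calls=tuple(cluster),
    )


@dataclass(frozen=True)
class Rejection:
    event: ConsensusCnv
    reason: str  # support | size | quality | frequency


def apply_filters(
    consensus: Iterable[ConsensusCnv], config: MergeConfig
) -> tuple[list[ConsensusCnv], list[Rejection]]:
    """Support, size and quality-floor filters; first failing rule is logged.

    A member call below its caller's quality floor invalidates the whole
    event (the stricter of the two readings; switchable by emptying
    ``qual_floor``).
    """
    retained: list[ConsensusCnv] = []
    rejected: list[Rejection] = []
    for ev in consensus:
        if ev.n_callers < config.min_callers:
            rejected.append(Rejection(ev, "support"))
        elif ev.length < config.min_size:
            rejected.append(Rejection(ev, "size"))
        elif any(
            m.quality < config.qual_floor[m.caller_id]
            for m in ev.member_calls
            if m.caller_id in config.qual_floor
        ):
            rejected.append(Rejection(ev, "quality"))
        else:
            retained.append(ev)
    return retained, rejected


def carrier_frequency_filter(
    consensus: Sequence[ConsensusCnv], config: MergeConfig, n_samples: int
) -> tuple[list[ConsensusCnv], list[Rejection]]:
    """Remove events carried by >= max_carrier_freq of all study samples.

    Events across samples are clustered with the same breakpoint
    compatibility used within samples; each cluster's carrier frequency is
    the number of distinct samples over ``n_samples`` (all cohorts).
    Retention is strict: events with carrier_freq >= threshold are removed
    in every carrier.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    by_group: dict[tuple[str, SvType], list[ConsensusCnv]] = defaultdict(list)
    for ev in consensus:
        by_group[(ev.chrom, ev.svtype)].append(ev)
    retained: list[ConsensusCnv] = []
    rejected: list[Rejection] = []
    for key in sorted(by_group, key=lambda k: (k[0], k[1].value)):
        for comp in _connected_components(by_group[key], config.d_max):
            freq = len({ev.sample_id for ev in comp}) / n_samples
            for ev in comp:
                ev.carrier_freq = freq
                if freq < config.max_carrier_freq:
                    retained.append(ev)
                else:
                    rejected.append(Rejection(ev, "frequency"))
    return retained, rejected


def run_consensus(
    calls_by_sample: Mapping[str, Sequence[CnvCall]],
    samples: Sequence[SampleRecord],
    config: MergeConfig | None = None,
) -> tuple[list[ConsensusCnv], list[Rejection]]:
    """Full consensus stage over in-memory calls of every study sample.

    Deterministic composition cluster → merge → filters → frequency filter;
    output sorted by (sample, chrom, start).  ``samples`` is the full cohort
    table; it defines the carrier-frequency denominator, and samples with
    calls from fewer than ``min_callers`` callers are warned about (their
    events can never pass the support filter).
    """
    config = config or MergeConfig()
    known = {s.sample_id for s in samples}
    unknown = set(calls_by_sample) - known
    if unknown:
        raise ValueError(f"calls for samples absent from cohort table: {sorted(unknown)}")
    merged: list[ConsensusCnv] = []
    rejections: list[Rejection] = []
    for sample_id in sorted(calls_by_sample):
        calls = calls_by_sample[sample_id]
        n_callers_present = len({c.caller_id for c in calls})
        if 0 < n_callers_present < config.min_callers:
            log.warning(
                "sample %s has calls from only %d caller(s); support filter "
                "requires %d", sample_id, n_callers_present, config.min_callers,
            )
        clusters = cluster_sample_calls(calls, config)
        events = [merge_cluster(cl) for cl in clusters]
        kept, rej = apply_filters(events, config)
        merged.extend(kept)
        rejections.extend(rej)
    final, freq_rej = carrier_frequency_filter(merged, config, n_samples=len(samples))
    rejections.extend(freq_rej)
    final.sort(key=lambda ev: (ev.sample_id, ev.chrom, ev.start, ev.end))
    return final, rejections


def run_consensus_from_vcfs(
    vcf_dir: str | Path,
    samples: Sequence[SampleRecord],
    config: MergeConfig | None = None,
    quality_field: str = "QUAL",
) -> tuple[list[ConsensusCnv], list[Rejection]]:
    """File-based entry point: reads ``<vcf_dir>/<sample>/<caller>.vcf`` layout."""
    from . import sv_io

    vcf_dir = Path(vcf_dir)
    calls_by_sample: dict[str, list[CnvCall]] = {}
    for sample in samples:
        sdir = vcf_dir / sample.sample_id
        if not sdir.is_dir():
            continue
        calls: list[CnvCall] = []
        for caller in Caller:
            vcf = sdir / f"{caller.value}.vcf"
            if vcf.exists():
                calls.extend(
                    sv_io.read_caller_vcf(
                        vcf, caller, sample_id=sample.sample_id,
                        quality_field=quality_field,
                    ).calls
                )
        calls_by_sample[sample.sample_id] = calls
    return run_consensus(calls_by_sample, samples, config)
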