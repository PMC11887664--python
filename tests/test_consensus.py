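"""Consensus merging: compatibility, clustering, filters, oracle equivalence."""

import random

import pytest

from bdcnv import consensus as cons
from bdcnv.consensus import (
    MergeConfig, apply_filters, carrier_frequency_filter, cluster_sample_calls,
    compatible, merge_cluster, run_consensus,
)
from bdcnv.types import Caller, CnvCall, Cohort, ConsensusCnv, SampleRecord, SvType

from conftest import make_call, make_consensus


# ---------------------------------------------------------------------------
# brute-force oracle, kept deliberately naive and independent of the package


def oracle_components(calls, d_max):
    """O(n²) pairwise graph + exhaustive component closure."""
    n = len(calls)
    adj = [
        [
            i != j
            and calls[i].sample_id == calls[j].sample_id
            and calls[i].chrom == calls[j].chrom
            and calls[i].svtype == calls[j].svtype
            and abs(calls[i].start - calls[j].start) <= d_max
            and abs(calls[i].end - calls[j].end) <= d_max
            for j in range(n)
        ]
        for i in range(n)
    ]
    unseen = set(range(n))
    comps = []
    while unseen:
        frontier = {unseen.pop()}
        comp = set(frontier)
        while frontier:
            i = frontier.pop()
            nbrs = {j for j in list(unseen) if adj[i][j]}
            unseen -= nbrs
            frontier |= nbrs
            comp |= nbrs
        comps.append(sorted(comp))
    return comps


def oracle_consensus(calls_by_sample, samples, config):
    """Literal re-statement of the merge + filter rules."""
    events = []
    for sid in calls_by_sample:
        calls = list(calls_by_sample[sid])
        for comp_idx in oracle_components(calls, config.d_max):
            comp = [calls[i] for i in comp_idx]
            best = {}
            for c in sorted(comp, key=lambda c: (c.start, c.end)):
                if c.caller_id not in best or c.quality > best[c.caller_id].quality:
                    best[c.caller_id] = c
            members = list(best.values())
            starts = sorted(m.start for m in members)
            ends = sorted(m.end for m in members)
            start = starts[(len(starts) - 1) // 2]
            end = ends[(len(ends) - 1) // 2]
            if len(members) < config.min_callers:
                continue
            if end - start < config.min_size:
                continue
            if any(
                m.quality < config.qual_floor[m.caller_id]
                for m in members if m.caller_id in config.qual_floor
            ):
                continue
            events.append((sid, members[0].chrom, start, end, members[0].svtype))
    # frequency filter over pseudo-events
    kept = []
    pseudo = [
        CnvCall(sid, Caller.MANTA, chrom, start, end, svtype, 0.0)
        for sid, chrom, start, end, svtype in events
    ]
    for comp_idx in oracle_components(
        [CnvCall("ALL", p.caller_id, p.chrom, p.start, p.end, p.svtype, 0.0) for p in pseudo],
        config.d_max,
    ):
        carriers = {pseudo[i].sample_id for i in comp_idx}
        freq = len(carriers) / len(samples)
        if freq < config.max_carrier_freq:
            kept.extend(events[i] for i in comp_idx)
    return sorted((sid, chrom, start, end, sv.value) for sid, chrom, start, end, sv in kept)


def random_instance(rng, n_calls, n_samples=5):
    calls_by_sample = {f"S{i}": [] for i in range(n_samples)}
    anchors = [
        (f"chr{rng.randint(1, 2)}", rng.randrange(0, 2_000_000, 100),
         rng.choice([SvType.DEL, SvType.DUP]))
        for _ in range(max(1, n_calls // 6))
    ]
    for _ in range(n_calls):
        sid = f"S{rng.randrange(n_samples)}"
        chrom, pos, svtype = rng.choice(anchors)
        start = max(0, pos + rng.randint(-1500, 1500))
        end = start + rng.choice([5_000, 9_999, 10_000, 50_000]) + rng.randint(-1500, 1500)
        caller = rng.choice(list(Caller))
        quality = rng.choice([5, 50, 99, 100, 500, 999, 1000, 2500])
        calls_by_sample[sid].append(
            CnvCall(sid, caller, chrom, start, end, svtype, float(quality))
        )
    return calls_by_sample


# ---------------------------------------------------------------------------


class TestCompatible:
    @pytest.mark.parametrize(
        "b, expected",
        [
            (dict(), True),                                    # identical
            (dict(start=101_000), True),                       # 1000 bp inclusive
            (dict(start=101_001), False),                      # 1001 bp exceeds
            (dict(end=151_001), False),                        # end breakpoint too
            (dict(svtype=SvType.DUP), False),                  # type guard
            (dict(chrom="chr2"), False),                       # chrom guard
        ],
    )
    def test_breakpoint_distance_rule(self, b, expected):
        a = make_call()
        other = make_call(**b)
        assert compatible(a, other, 1000) is expected
        assert compatible(other, a, 1000) is expected  # symmetry


class TestClustering:
    def test_identical_calls_from_three_callers_form_one_cluster(self):
        calls = [make_call(caller=c) for c in (Caller.MANTA, Caller.DELLY, Caller.LUMPY)]
        clusters = cluster_sample_calls(calls, MergeConfig())
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_chain_links_connect_breakpoints_beyond_d_max(self):
        # pairwise 100000 vs 101200 exceeds 1 kb, but the chain connects all 4
        starts = [100_000, 100_400, 100_900, 101_200]
        callers = list(Caller)
        calls = [
            make_call(caller=callers[i], start=s, end=200_000)
            for i, s in enumerate(starts)
        ]
        clusters = cluster_sample_calls(calls, MergeConfig())
        assert len(clusters) == 1 and len(clusters[0]) == 4
        # agrees with the exhaustive pairwise-graph oracle
        assert [len(c) for c in oracle_components(calls, 1000)] == [4]

    def test_same_caller_duplicates_keep_highest_quality(self):
        calls = [
            make_call(quality=50.0),
            make_call(start=100_100, quality=80.0),
            make_call(caller=Caller.DELLY, quality=1500.0),
        ]
        (cluster,) = cluster_sample_calls(calls, MergeConfig())
        manta = [c for c in cluster if c.caller_id == Caller.MANTA]
        assert len(manta) == 1 and manta[0].quality == 80.0

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError):
            cluster_sample_calls([make_call(sample="A"), make_call(sample="B")],
                                 MergeConfig())

    def test_every_call_in_exactly_one_cluster(self):
        rng = random.Random(5)
        calls = random_instance(rng, 120, n_samples=1)["S0"]
        clusters = cluster_sample_calls(calls, MergeConfig())
        # dedup may drop same-caller duplicates, never move calls between clusters
        kept = [c for cl in clusters for c in cl]
        assert len(kept) == len(set(map(id, kept)))
        assert set(map(id, kept)) <= set(map(id, calls))


class TestMergeCluster:
    def test_median_of_three_starts(self):
        calls = [
            make_call(caller=c, start=s, end=200_000)
            for c, s in zip(Caller, [100_000, 100_400, 100_900])
        ]
        assert merge_cluster(calls).start == 100_400

    def test_even_count_uses_lower_median(self):
        calls = [
            make_call(caller=c, start=s, end=200_000)
            for c, s in zip(Caller, [0, 10, 20, 30])
        ]
        assert merge_cluster(calls).start == 10

    def test_single_member_identity(self):
        ev = merge_cluster([make_call()])
        assert (ev.start, ev.end) == (100_000, 150_000)
        assert ev.supporting_callers == {Caller.MANTA}

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            merge_cluster([])


class TestApplyFilters:
    def test_insufficient_support_rejected(self):
        ev = make_consensus(callers=(Caller.MANTA, Caller.DELLY), quality=2000.0)
        kept, rej = apply_filters([ev], MergeConfig())
        assert kept == [] and rej[0].reason == "support"

    @pytest.mark.parametrize("size, retained", [(9_999, False), (10_000, True)])
    def test_size_boundary_is_inclusive(self, size, retained):
        ev = make_consensus(end=100_000 + size, quality=2000.0)
        kept, rej = apply_filters([ev], MergeConfig())
        assert bool(kept) is retained
        if not retained:
            assert rej[0].reason == "size"

    @pytest.mark.parametrize("qual, retained", [(99.0, False), (100.0, True)])
    def test_manta_quality_floor_is_100(self, qual, retained):
        members = (
            make_call(caller=Caller.MANTA, quality=qual),
            make_call(caller=Caller.CNVNATOR, quality=40.0),
            make_call(caller=Caller.LUMPY, quality=40.0),
        )
        ev = ConsensusCnv(
            sample_id="S1", chrom="chr1", start=100_000, end=150_000,
            svtype=SvType.DEL,
            supporting_callers=frozenset(m.caller_id for m in members),
            member_calls=members,
        )
        kept, rej = apply_filters([ev], MergeConfig())
        assert bool(kept) is retained

    def test_delly_quality_floor_is_1000(self):
        members = (
            make_call(caller=Caller.DELLY, quality=999.0),
            make_call(caller=Caller.CNVNATOR, quality=40.0),
            make_call(caller=Caller.LUMPY, quality=40.0),
        )
        ev = ConsensusCnv(
            sample_id="S1", chrom="chr1", start=100_000, end=150_000,
            svtype=SvType.DEL,
            supporting_callers=frozenset(m.caller_id for m in members),
            member_calls=members,
        )
        kept, rej = apply_filters([ev], MergeConfig())
        assert kept == [] and rej[0].reason == "quality"


class TestCarrierFrequencyFilter:
    def _events(self, n_carriers):
        return [make_consensus(sample=f"S{i}") for i in range(n_carriers)]

    def _samples(self, n=100):
        return [SampleRecord(f"S{i}", Cohort.CONTROL) for i in range(n)]

    def test_six_percent_removed_everywhere(self):
        kept, rej = carrier_frequency_filter(self._events(6), MergeConfig(), 100)
        assert kept == [] and len(rej) == 6
        assert all(r.event.carrier_freq == 0.06 for r in rej)

    def test_four_percent_retained(self):
        kept, _ = carrier_frequency_filter(self._events(4), MergeConfig(), 100)
        assert len(kept) == 4

    def test_exact_threshold_removed(self):
        kept, _ = carrier_frequency_filter(self._events(5), MergeConfig(), 100)
        assert kept == []  # 0.05 is not < 0.05

    def test_private_event_retained(self):
        kept, _ = carrier_frequency_filter(self._events(1), MergeConfig(), 100)
        assert len(kept) == 1 and kept[0].carrier_freq == 0.01

    def test_zero_samples_is_an_error(self):
        with pytest.raises(ValueError):
            carrier_frequency_filter([], MergeConfig(), 0)


class TestRunConsensusProperties:
    def _samples(self, n=5):
        return [SampleRecord(f"S{i}", Cohort.CONTROL) for i in range(n)]

    def test_matches_brute_force_oracle_on_random_instances(self):
        config = MergeConfig()
        for seed in range(50):
            rng = random.Random(seed)
            calls_by_sample = random_instance(rng, rng.randint(20, 160))
            samples = self._samples()
            got, _ = run_consensus(calls_by_sample, samples, config)
            got_keys = sorted(ev.key() for ev in got)
            assert got_keys == oracle_consensus(calls_by_sample, samples, config), seed

    def test_retained_events_satisfy_support_and_size_invariants(self, small_sim):
        got, _ = run_consensus(small_sim.calls_by_sample, small_sim.samples)
        assert all(ev.n_callers >= 3 and ev.length >= 10_000 for ev in got)
        assert all(0 <= ev.carrier_freq < 0.05 for ev in got)

    def test_permutation_invariance(self):
        rng = random.Random(99)
        calls_by_sample = random_instance(rng, 150)
        samples = self._samples()
        base, _ = run_consensus(calls_by_sample, samples)
        shuffled = {
            sid: random.Random(1234).sample(calls, len(calls))
            for sid, calls in calls_by_sample.items()
        }
        perm, _ = run_consensus(shuffled, samples)
        assert sorted(e.key() for e in base) == sorted(e.key() for e in perm)

    def test_raising_min_callers_never_increases_retained_count(self):
        rng = random.Random(7)
        calls_by_sample = random_instance(rng, 200)
        samples = self._samples()
        counts = []
        for mc in (1, 2, 3, 4):
            got, _ = run_consensus(calls_by_sample, samples, MergeConfig(min_callers=mc))
            counts.append(len(got))
        assert counts == sorted(counts, reverse=True)

    def test_raising_d_max_never_increases_cluster_count(self):
        rng = random.Random(13)
        calls = random_instance(rng, 100, n_samples=1)["S0"]
        n_clusters = [
            len(cluster_sample_calls(calls, MergeConfig(d_max=d)))
            for d in (0, 250, 500, 1000, 2000, 4000)
        ]
        assert n_clusters == sorted(n_clusters, reverse=True)

    def test_unknown_sample_in_calls_is_an_error(self):
        with pytest.raises(ValueError):
            run_consensus({"GHOST": [make_call(sample="GHOST")]}, self._samples())
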