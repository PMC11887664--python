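import pytest

from bdcnv.simulate import SimConfig, simulate_cohort
from bdcnv.types import Caller, CnvCall, ConsensusCnv, SvType


SMALL = dict(
    n_case=12, n_bdonly=12, n_control=8, n_chroms=2, chrom_length=3_000_000,
    n_genes=150, cnv_rate=3.0, fp_rate=2.0, n_exclusive_genes=5,
    n_terms=8, term_size=15,
)


@pytest.fixture(scope="session")
def small_sim():
    """A 32-sample cohort under default noise, small enough for unit tests."""
    return simulate_cohort(SimConfig(seed=11, **SMALL))


@pytest.fixture(scope="session")
def noise_free_sim():
    """Same scale, but perfect callers (no FP/FN/jitter, fixed qualities)."""
    return simulate_cohort(SimConfig.noise_free(seed=7, **SMALL))


def make_call(
    sample="S1", caller=Caller.MANTA, chrom="chr1", start=100_000, end=150_000,
    svtype=SvType.DEL, quality=300.0,
) -> CnvCall:
    return CnvCall(sample, caller, chrom, start, end, svtype, quality)


def make_consensus(
    sample="S1", chrom="chr1", start=100_000, end=150_000, svtype=SvType.DEL,
    callers=(Caller.MANTA, Caller.DELLY, Caller.LUMPY), quality=300.0,
) -> ConsensusCnv:
    members = tuple(
        CnvCall(sample, c, chrom, start, end, svtype, quality) for c in callers
    )
    return ConsensusCnv(
        sample_id=sample, chrom=chrom, start=start, end=end, svtype=svtype,
        supporting_callers=frozenset(callers), member_calls=members,
    )
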