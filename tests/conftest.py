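import numpy as np
import pytest
from hypothesis import settings

# deterministic property tests, no on-disk example database
settings.register_profile("repro", database=None, derandomize=True)
settings.load_profile("repro")

from ith_exome.core_model import GenomicSite, MutationRecord, SiteEvidence
from ith_exome.synthetic_cohort import CohortParams, GenomeModel, NoiseParams, simulate_cohort


def make_record(
    chrom="chr1",
    pos=1000,
    ref="C",
    alt="T",
    gene="KRAS",
    consequence="missense",
    context=None,
    patient="P1",
    normal=(50, 0, 60.0),
    central=(100, 30, 60.0),
    peripheral=(100, 30, 60.0),
    **kwargs,
):
    """Terse MutationRecord builder: evidence triples are (depth, var, mapq)."""
    evidence = {}
    for region, triple in (("normal", normal), ("central", central), ("peripheral", peripheral)):
        if triple is not None:
            evidence[region] = SiteEvidence(*triple)
    return MutationRecord(
        site=GenomicSite(chrom, pos, ref, alt),
        gene=gene,
        consequence=consequence,
        evidence=evidence,
        trinucleotide_context=context,
        patient=patient,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_genome():
    return GenomeModel(chromosomes=(("chr1", 20_000_000), ("chr2", 20_000_000)), bin_bp=100_000)


@pytest.fixture(scope="session")
def default_cohort():
    """One seed-1 default cohort shared by read-only tests."""
    return simulate_cohort(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
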