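"""Shared fixtures: small simulated trios written as real BAM/VCF files."""

import numpy as np
import pysam
import pytest

from denovotrio import simulate


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A 12-site mixed trio fixture on disk (FASTA + BAMs + VCFs)."""
    outdir = tmp_path_factory.mktemp("trio_fixture")
    mix = {"denovo": 0.5, "inherited_father": 0.25, "inherited_mother": 0.25}
    sites, reference = simulate.simulate_dataset(
        12, mix,
        base_params=simulate.SimParams(depth_mean=20.0),
        seed=42, reference_length=60_000,
        type_mix={"substitution": 0.5, "insertion": 0.25, "deletion": 0.25},
    )
    config = simulate.write_fixture(sites, reference, outdir)
    return {"config": config, "sites": sites, "reference": reference,
            "dir": outdir}


@pytest.fixture()
def denovo_site():
    """One clean heterozygous de novo substitution site."""
    params = simulate.SimParams(depth_mean=30.0, base_error_rate=0.0,
                                inheritance="denovo", rng_seed=1)
    return simulate.simulate_site(params)


def write_simple_vcf(path, records, contig="1", contig_length=100_000):
    """Write a plain VCF of (pos_1based, ref, alt) records."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_sample("s")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for pos, ref, alt in sorted(records):
            rec = vcf.new_record(contig=contig, start=pos - 1,
                                 alleles=(ref, alt))
            vcf.write(rec)
    return path
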