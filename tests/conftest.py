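"""Shared fixtures: synthetic cohorts and hand-built MADC tables.

The expensive fixtures (the simulated 4-population cohort and its dosage
calls) are session-scoped so the diversity, differentiation and
acceptance tests all reuse one simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

import tetrahap as th
from tetrahap.madc_io import HaplotypeRecord, MADCTable


@pytest.fixture(scope="session")
def small_cohort():
    """4 populations x 40 tetraploids x 500 multiallelic loci at ~100x,
    Balding-Nichols F = 0.10 — the standard test-scale cohort."""
    cfg = th.synthetic_data.small_config(seed=1)
    table, pops, truth = th.simulate_cohort(cfg)
    return cfg, table, pops, truth


@pytest.fixture(scope="session")
def small_calls(small_cohort):
    """MAP dosage calls (iterated population prior) for the cohort."""
    _cfg, table, pops, _truth = small_cohort
    return th.iterate_frequency_prior(table, th.DosageModel(), pops)


@pytest.fixture(scope="session")
def snp_calls(small_cohort):
    """Biallelic target-SNP calls for the same cohort."""
    _cfg, table, pops, _truth = small_cohort
    return th.collapse_to_target_snp(table, th.DosageModel(), pops)


def make_genotypes(dosages, ploidy=4, locus_prefix="chr1.1_", spacing=10_000):
    """GenotypeMatrix from a dict-free nested structure:
    dosages[sample][locus] = tuple of allele copy numbers (or None)."""
    n = len(dosages)
    L = len(dosages[0])
    locus_ids = [f"{locus_prefix}{(i + 1) * spacing}" for i in range(L)]
    n_alleles = [
        max(len(dosages[s][li]) for s in range(n) if dosages[s][li] is not None)
        for li in range(L)
    ]
    allele_ids = {
        locus_ids[li]: [f"{locus_ids[li]}|a{a}" for a in range(n_alleles[li])]
        for li in range(L)
    }
    calls = [
        [
            None if d is None else np.asarray(d, dtype=np.int64)
            for d in row
        ]
        for row in dosages
    ]
    return th.GenotypeMatrix(
        sample_ids=[f"s{i:03d}" for i in range(n)],
        locus_ids=locus_ids,
        allele_ids=allele_ids,
        calls=calls,
        ploidy=ploidy,
    )


def hwe_genotypes(rng, n_ind, freqs_per_locus, ploidy=4):
    """Tetrasomic Hardy-Weinberg dosages at given allele frequencies."""
    dosages = [
        [tuple(rng.multinomial(ploidy, f)) for f in freqs_per_locus]
        for _ in range(n_ind)
    ]
    return make_genotypes(dosages, ploidy)


@pytest.fixture()
def toy_madc():
    """2-locus, 3-sample MADC table with one of every haplotype class."""
    ref1 = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC"
    alt1 = ref1[:10] + "T" + ref1[11:]
    rm1 = ref1[:20] + "G" + ref1[21:]
    ref2 = "TTGCATGCATGCATGCATGCATGCATGCATGCATGCATGCATGCATGCATGCAA"
    recs = [
        HaplotypeRecord("chr1.1_1000", "chr1.1_1000|Ref", "Ref", ref1, [30, 40, 0]),
        HaplotypeRecord("chr1.1_1000", "chr1.1_1000|Alt", "Alt", alt1, [10, 0, 0]),
        HaplotypeRecord("chr1.1_1000", "chr1.1_1000|RefMatch_01", "RefMatch", rm1, [5, 5, 0]),
        HaplotypeRecord("chr2.1_2000", "chr2.1_2000|Ref", "Ref", ref2, [50, 60, 70]),
    ]
    return MADCTable(["s1", "s2", "s3"], recs)
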