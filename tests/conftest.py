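import numpy as np
import pandas as pd
import pytest

from kaspfp import (
    GenotypeMatrix,
    PlateSimConfig,
    PopulationSimConfig,
    simulate_plate,
    simulate_population,
)
from kaspfp.variants import VariantRecord


@pytest.fixture(scope="session")
def pop30():
    """Small admixed population with truth, shared across tests."""
    return simulate_population(
        PopulationSimConfig(n_accessions=30, n_markers=20, n_subpops=3, seed=1)
    )


@pytest.fixture(scope="session")
def genotype_calls_96():
    """96 genotype calls at one biallelic marker (fixed composition)."""
    rng = np.random.default_rng(42)
    return pd.Series(
        [("AA", "AG", "GG")[rng.integers(3)] for _ in range(96)],
        index=[f"s{i:02d}" for i in range(96)],
    )


def _rec(chrom, pos, genotypes, ref="A", alt="G"):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, sample_genotypes=genotypes)


@pytest.fixture()
def cascade_records():
    """Five-record screening fixture, one survivor by construction.

    r1 fails MAF (0.04), r2 fails missing rate (0.28), r3 fails PIC
    (MAF 0.20 -> PIC 0.2688), r4 passes statistics but has a neighbour 50 bp
    away (r3), r5 passes everything and is isolated.
    """
    samples = [f"s{i:02d}" for i in range(25)]

    def col(n_het, n_hom_minor, n_missing=0, ref="A", alt="G"):
        het = "".join(sorted(ref + alt))
        cells = (
            [alt + alt] * n_hom_minor
            + [het] * n_het
            + [None] * n_missing
        )
        cells += [ref + ref] * (25 - len(cells))
        return dict(zip(samples, cells))

    r1 = _rec("chr1", 1000, col(n_het=2, n_hom_minor=0))          # MAF 0.04
    r2 = _rec("chr1", 5000, col(n_het=4, n_hom_minor=1, n_missing=7))  # missing 0.28
    r3 = _rec("chr1", 9000, col(n_het=10, n_hom_minor=0))         # MAF 0.20
    r4 = _rec("chr1", 9050, col(n_het=20, n_hom_minor=0))         # MAF 0.40, neighbour r3
    r5 = _rec("chr1", 20000, col(n_het=15, n_hom_minor=0))        # MAF 0.30, isolated
    return [r1, r2, r3, r4, r5]


@pytest.fixture()
def clean_plate(genotype_calls_96):
    plate, truth = simulate_plate(
        genotype_calls_96, PlateSimConfig(noise_sd=0.05, seed=11)
    )
    return plate, truth


def make_db_frame(profiles: dict, markers: list) -> GenotypeMatrix:
    return GenotypeMatrix(pd.DataFrame(profiles, index=markers).T)
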