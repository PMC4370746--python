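"""Shared fixtures: tiny analytic fields and genotype/otolith cohorts."""

import numpy as np
import pandas as pd
import pytest

from nataltrack import make_uniform, make_gyre, RegionPartition
from nataltrack.synthetic import gen_genotypes

LOCI_12 = ["YP85", "YP78", "YP41", "YP109", "YP55", "YP110",
           "YP96", "YP60", "YP65", "YP49", "YP81", "YP99"]

# HWE-violation pattern by population-year batch (bold cells of the
# published diversity table for the 2006/2007 larval collections)
HWE_VIOLATIONS = {
    ("NS", 2006): {"YP78", "YP49"},
    ("SS", 2006): {"YP85", "YP78", "YP109", "YP65", "YP81"},
    ("NS", 2007): {"YP78", "YP109", "YP96", "YP60", "YP65", "YP49"},
    ("SS", 2007): {"YP78", "YP96", "YP60", "YP65", "YP49"},
}


@pytest.fixture(scope="session")
def hwe_flags():
    rows = []
    for (pop, year), viol in HWE_VIOLATIONS.items():
        for locus in LOCI_12:
            rows.append({"locus": locus, "population": pop, "year": year,
                         "significant": locus in viol})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def still_field():
    return make_uniform(u=0.0, v=0.0, n_hours=73)


@pytest.fixture(scope="session")
def gyre_field():
    return make_gyre(omega=1e-4, n_hours=49)


@pytest.fixture(scope="session")
def partition():
    return RegionPartition()


def make_truth(n_per_pop, regions=("NS", "SS"), role="larva"):
    rows = []
    for reg in regions:
        for k in range(n_per_pop):
            rows.append({"id": f"{reg}{k:03d}", "role": role,
                         "true_region": reg})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def divergent_table():
    """Two well-separated subpopulations (F = 0.2), 50 per pop."""
    return gen_genotypes(make_truth(50), n_loci=7, alleles_per_locus=8,
                         F=0.2, seed=11)


@pytest.fixture(scope="session")
def weak_table():
    """Weakly diverged subpopulations (F = 0.05), 60 per pop."""
    return gen_genotypes(make_truth(60), n_loci=7, alleles_per_locus=8,
                         F=0.05, seed=7)
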