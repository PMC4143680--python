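import numpy as np
import pandas as pd
import pytest

from pathkin.pedigree import Individual, Pedigree
from pathkin.regions import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def trio_ped_text(tmp_path):
    path = tmp_path / "trio.ped"
    path.write_text(
        "FAM1 DAD 0 0 1\n"
        "FAM1 MOM 0 0 2\n"
        "FAM1 KID DAD MOM 2\n"
    )
    return path


@pytest.fixture
def two_family_ped():
    """Two 3-generation families (no inter-marriage between them)."""
    inds = []
    for fam in ("A", "B"):
        inds += [
            Individual(fam, f"{fam}_gpa", None, None, 1),
            Individual(fam, f"{fam}_gma", None, None, 2),
            Individual(fam, f"{fam}_dad", f"{fam}_gpa", f"{fam}_gma", 1),
            Individual(fam, f"{fam}_unc", f"{fam}_gpa", f"{fam}_gma", 1),
            Individual(fam, f"{fam}_mom", None, None, 2),
            Individual(fam, f"{fam}_kid1", f"{fam}_dad", f"{fam}_mom", 1),
            Individual(fam, f"{fam}_kid2", f"{fam}_dad", f"{fam}_mom", 2),
        ]
    return Pedigree(inds)


def make_genotypes(dosages, samples=None, positions=None, chrom="chr1", region="sim"):
    """Small helper to build a GenotypeMatrix from a raw dosage array."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    samples = samples or [f"S{i + 1}" for i in range(n)]
    positions = positions if positions is not None else (np.arange(m) + 1) * 100
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": positions,
            "id": [f"v{j + 1}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "region": [region] * m,
        }
    )
    return GenotypeMatrix(list(samples), variants, d.copy())


@pytest.fixture
def geno_factory():
    return make_genotypes
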