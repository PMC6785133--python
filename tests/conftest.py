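import numpy as np
import pandas as pd
import pytest

from capsforge import GenotypeMatrix, SamplePanel
from capsforge.synthetic_data import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def noiseless_bundle(tmp_path_factory):
    """Zero-noise synthetic study: 24 lines (9 target, 15 other), 12
    chromosomes, 5000 SNPs, 50 planted diagnostic loci."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(SimulationConfig(seed=11), out)


@pytest.fixture(scope="session")
def small_bundle():
    """In-memory bundle small enough for repeated re-simulation."""
    return simulate_bundle(SimulationConfig(seed=3, n_snps=400, n_chromosomes=3,
                                            chromosome_length_bp=400_000,
                                            diagnostic_fraction=0.02))


def make_matrix(columns, samples=None, ref_alt=None, depth=None, chrom="Chr1"):
    """Build a GenotypeMatrix from per-variant lists of 'x/y' genotype cells."""
    from capsforge.genotype_io import parse_genotype_cell

    n_v = len(columns)
    n_s = len(columns[0])
    samples = samples or [f"s{i + 1}" for i in range(n_s)]
    aa = np.full((n_s, n_v), ".", dtype="<U1")
    ab = aa.copy()
    for j, col in enumerate(columns):
        for i, cell in enumerate(col):
            c = parse_genotype_cell(cell)
            aa[i, j], ab[i, j] = c.allele_a, c.allele_b
    ra = ref_alt or [("A", "G")] * n_v
    variants = pd.DataFrame({"chrom": chrom, "pos": np.arange(1, n_v + 1) * 100,
                             "ref": [r for r, _ in ra], "alt": [a for _, a in ra]})
    d = np.full((n_s, n_v), 10, dtype=np.int32) if depth is None else np.asarray(depth)
    d = np.where((aa == ".") & (ab == "."), 0, d)
    return GenotypeMatrix(samples, variants, aa, ab, d)


@pytest.fixture
def toy_panel():
    def build(target, other):
        return SamplePanel(pd.DataFrame({
            "sample_id": list(target) + list(other),
            "group_label": ["red"] * len(target) + ["yellow"] * len(other),
            "is_target_group": [True] * len(target) + [False] * len(other),
        }))
    return build
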