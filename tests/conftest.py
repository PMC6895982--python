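import pytest

import homeobias as hb


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic dataset at the default study conditions."""
    return hb.simulate(hb.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def quartet(default_sim):
    s = default_sim
    return s.maternal, s.paternal, s.poly_h, s.poly_c


# the published per-replicate, per-SNP homoeolog count table
# (maternal = H subtotal, paternal = C subtotal)
PUBLISHED_COUNTS = [
    ("HHCC-1", 393, 687, 959),
    ("HHCC-1", 430, 687, 805),
    ("HHCC-2", 393, 458, 603),
    ("HHCC-2", 430, 359, 439),
    ("HHCC-3", 393, 440, 660),
    ("HHCC-3", 430, 369, 558),
]

# published genotype trait means: (trait, maternal, polyploid, paternal)
PUBLISHED_TRAIT_MEANS = [
    ("rubisco_content", 1.41, 1.70, 1.77),
    ("rubisco_activity", 7.24, 6.86, 4.76),
]


@pytest.fixture(scope="session")
def published_count_table():
    table = hb.AlleleCountTable()
    reps = {}
    for rep, snp, h, c in PUBLISHED_COUNTS:
        reps.setdefault(rep, {})[snp] = hb.SnpCounts(maternal=h, paternal=c)
    for rep, per_snp in reps.items():
        table.add_replicate(rep, per_snp)
    return table
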