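import pytest
from hypothesis import HealthCheck, settings

from ecodon import CodonUsageTable, generate_fixtures

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def bundle():
    """Synthetic fixture bundle shared across the suite."""
    return generate_fixtures(FIXTURE_SEED)


@pytest.fixture(scope="session")
def table(bundle):
    return bundle.usage_table


@pytest.fixture()
def toy_table():
    """Hand-sized table with known counts for closed-form examples."""
    return CodonUsageTable(
        organism_label="toy",
        counts={
            # Gly: clear preference order
            "GGC": 60, "GGT": 30, "GGA": 6, "GGG": 4,
            # Lys: even split
            "AAA": 5, "AAG": 5,
            # Asp: both start with G
            "GAC": 7, "GAT": 3,
            # Leu: 0.5 / 0.3 / 0.2 over three codons, others zero
            "CTG": 5, "TTG": 3, "CTT": 2,
            # Ala: all four present
            "GCC": 10, "GCT": 6, "GCA": 3, "GCG": 1,
            "ATG": 9, "TGG": 4,
            # Phe for weight-0.25 style examples
            "TTC": 8, "TTT": 2,
        },
        stop_counts={"TAA": 3, "TGA": 1},
    )
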