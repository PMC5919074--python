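import numpy as np
import pytest

from ecoimmune.records import GenotypeMatrix, MouseRecord, MICROBES
from ecoimmune.simulate import SyntheticConfig, gen_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 3-site cohort, small enough for fast downstream stages."""
    cfg = SyntheticConfig(
        seed=7,
        site_sizes={"HW": 40, "BM": 25, "PF": 15},
    )
    records, truth = gen_cohort(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def flat_cohort():
    """Single-site cohort with no site structure (linear system only)."""
    cfg = SyntheticConfig(
        seed=11,
        site_sizes={"HW": 800},
        site_sd={"adaptive": 0.0, "innate": 0.0, "humoral": 0.0},
    )
    records, truth = gen_cohort(cfg)
    return cfg, records, truth


@pytest.fixture()
def tiny_genotypes():
    """2 sites x 4 individuals, 3 loci, one missing call."""
    dosages = np.array([
        [0.0, 1.0, 2.0, 1.0],
        [2.0, 2.0, 0.0, 0.0],
        [1.0, np.nan, 1.0, 2.0],
    ])
    return GenotypeMatrix(
        dosages,
        locus_ids=["l1", "l2", "l3"],
        individual_ids=["a1", "a2", "b1", "b2"],
        sites=["HW", "HW", "BM", "BM"],
        chromosomes=["1", "1", "2"],
        positions=[100, 200, 300],
    )


def make_mouse(mouse_id="m1", **kwargs):
    defaults = dict(
        site="HW",
        sex="female",
        body_mass=18.0,
        body_length=80.0,
        infection_scores={m: 0 for m in MICROBES},
    )
    defaults.update(kwargs)
    return MouseRecord(mouse_id=mouse_id, **defaults)
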