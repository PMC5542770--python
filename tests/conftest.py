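import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pdakit import (
    Alignment,
    AnnotationTable,
    PlantedMSASpec,
    make_grouped_msa,
)

settings.register_profile(
    "pdakit",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pdakit")


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment.from_records(
        [
            ("s1", "ACDEF"),
            ("s2", "ACDEG"),
            ("s3", "KLMNP"),
            ("s4", "KLMNQ"),
        ]
    )


@pytest.fixture
def toy_annotations() -> AnnotationTable:
    return AnnotationTable(
        {
            "s1": ("alpha", "org1"),
            "s2": ("alpha", "org2"),
            "s3": ("beta", "org3"),
            "s4": ("beta", "org4"),
        }
    )


@pytest.fixture(scope="session")
def small_planted():
    """Small planted fixture: 2 groups x 60 sequences, 15 positions."""
    spec = PlantedMSASpec(
        n_per_group={"alpha": 60, "beta": 60},
        n_positions=15,
        planted_triplet=(2, 7, 12),
        purity=1.0,
        seed=11,
    )
    aln, ann, truth = make_grouped_msa(spec)
    return aln, ann, truth


@pytest.fixture(scope="session")
def study_scan():
    """Exhaustive scan of a study-scale planted fixture (2 x 100, width 25)."""
    from pdakit import enumerate_triplets, scan

    spec = PlantedMSASpec(
        n_per_group={"A": 100, "B": 100},
        n_positions=25,
        planted_triplet=(3, 11, 19),
        purity=1.0,
        seed=11,
    )
    aln, ann, truth = make_grouped_msa(spec)
    table = scan(aln, ann, enumerate_triplets(aln.width))
    return table, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
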