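import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dopacycle.rbs import RBSEntry, StrengthModel
from dopacycle.synthetic import ResponseSurfaceTruth, gen_rbs_library

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_library() -> list[RBSEntry]:
    """A small two-context library with distinct, hand-set TIRs."""
    h_seqs = ["AGGAGA", "GGGGGG", "AAAAAA", "ACGTAC", "GCGCGC"]
    d_seqs = ["AGGAGA", "TTTTTT", "GGCCGC", "ATATAT", "CACAGT"]
    entries = []
    for i, s in enumerate(h_seqs):
        entries.append(RBSEntry.create(f"h{i}", s, "hpaBC", tir=1.0 + 0.7 * i))
    for i, s in enumerate(d_seqs):
        entries.append(RBSEntry.create(f"d{i}", s, "ddc", tir=0.5 + 1.3 * i))
    return entries


@pytest.fixture(scope="session")
def default_truth() -> ResponseSurfaceTruth:
    return ResponseSurfaceTruth()


@pytest.fixture(scope="session")
def seeded_library(default_truth) -> list[RBSEntry]:
    """A mid-sized generated library shared by design/synthetic tests."""
    return gen_rbs_library(
        48, default_truth.model_hpaBC, default_truth.model_ddc, seed=20240917
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
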