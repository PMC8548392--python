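import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ampcas as ac

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SPACER = "GTTCGAGCTAAGTCTAGCAT"  # 20 nt


def make_amplicon(seed: int = 42, left: int = 40, right: int = 120) -> str:
    rng = np.random.default_rng(seed)
    bases = list("ACGT")
    return (
        "".join(rng.choice(bases, left))
        + "TTC"
        + SPACER
        + "".join(rng.choice(bases, right))
    )


@pytest.fixture(scope="session")
def spacer() -> str:
    return SPACER


@pytest.fixture(scope="session")
def amplicon() -> str:
    return make_amplicon()


@pytest.fixture(scope="session")
def site(amplicon) -> ac.TargetSite:
    return ac.TargetSite.from_guide("amp1", amplicon, SPACER, "TTC", 40)


@pytest.fixture()
def flat_quals():
    def make(seq: str, q: int = 38) -> np.ndarray:
        return np.full(len(seq), q, dtype=np.uint8)

    return make


def batch_from_seqs(seqs: list[str], q: int = 38) -> ac.ReadBatch:
    return ac.ReadBatch(
        [f"r{i}" for i in range(len(seqs))],
        list(seqs),
        [np.full(len(s), q, dtype=np.uint8) for s in seqs],
    )
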