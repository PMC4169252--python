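import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kindeg import ProteinRecord, SimConfig, simulate_experiment

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: toy protein shared with the cleavage-window examples; contains the
#: IEAD tetrapeptide ending at residue 12
TOY_SEQ = "MKLPEDDSIEADILAITG"


@pytest.fixture(scope="session")
def toy_protein() -> ProteinRecord:
    return ProteinRecord("TOY1", "toy cleavage substrate", TOY_SEQ)


@pytest.fixture(scope="session")
def default_experiment():
    """One default-condition synthetic experiment (541 annotated, 9 fast, 28 slow)."""
    cfg = SimConfig(seed=20260101)
    return simulate_experiment(cfg)


def make_surrogate_with_motif(length: int, p1: int, motif: str = "IEAD",
                              seed: int = 0) -> str:
    """Synthetic surrogate protein with ``motif`` planted so its last residue is p1.

    Stands in for database proteins that are not bundled; only the motif
    coordinates are meaningful.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list("ACDEFGHKLMNPQRSTVWY"))  # no I: keeps the motif unique
    seq = ["M"] + list(rng.choice(aa, size=length - 1))
    seq[p1 - 4 : p1] = list(motif)
    return "".join(seq)
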