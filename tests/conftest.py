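import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppisite import Chain, ResidueRecord, SimulationConfig, generate_chains

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_chain(chain_id, labels, rng=None, rsa=None):
    """Small hand-buildable chain with deterministic PSSM rows."""
    rng = rng or np.random.default_rng(0)
    L = len(labels)
    residues = []
    for i in range(L):
        residues.append(
            ResidueRecord(
                chain_id=chain_id,
                position=i + 1,
                amino_acid="ACDEFGHIKLMNPQRSTVWY"[i % 20],
                pssm_row=rng.integers(-5, 6, size=20).astype(float),
                rsa=float(rsa[i]) if rsa is not None else float(rng.uniform(0, 100)),
                label=None if labels[i] is None else int(labels[i]),
            )
        )
    return Chain(chain_id=chain_id, residues=tuple(residues))


@pytest.fixture
def labeled_chain():
    return make_chain("c1", [0, 1, 1, 0, 0, 1, 0, 0, 1, 1])


@pytest.fixture
def small_chain_set():
    """Six labeled chains with mild class separation, for LOOCV plumbing."""
    cfg = SimulationConfig(
        n_chains=6,
        length_min=30,
        length_max=60,
        class_separation=1.5,
        seed=11,
    )
    return generate_chains(cfg)
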