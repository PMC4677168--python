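"""Synthetic chains and curation metadata with the structure the method assumes.

The chain generator emulates the statistical features of real residue data
that the classifier exploits, without requiring any downloads:

* labels follow a stationary two-state Markov chain — interface residues
  cluster along the sequence, with the interface self-transition probability
  (``label_persistence``) controlling run lengths and the stationary
  interface fraction pinned at ``interface_prevalence``;
* the 20 PSSM scores are integer-rounded draws from class-conditional
  Gaussians whose means differ by ``class_separation`` standard deviations;
* RSA is drawn from class-conditional normals truncated to [0, 100], with
  the interface class at the higher mean (interface residues are the more
  exposed ones).

Defaults mirror the scale of the curated training corpus the method was
developed on: 186 chains averaging ~195 residues, ~12% interface prevalence,
strongly clustered labels, weakly separated feature distributions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .curation import ComplexMetadata
from .feature_io import Chain, ResidueRecord

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; see the module docstring for the data model."""

    n_chains: int = 186
    length_min: int = 50
    length_max: int = 340
    interface_prevalence: float = 0.12
    label_persistence: float = 0.8  # P(next label = 1 | current label = 1)
    class_separation: float = 0.5  # PSSM mean gap between classes, in sd units
    pssm_sd: float = 2.0  # sd of PSSM scores within a class
    rsa_class_means: tuple[float, float] = (25.0, 40.0)  # (noninterface, interface)
    rsa_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 1 <= self.length_min <= self.length_max:
            raise ValueError("need 1 <= length_min <= length_max")
        if not 0.0 < self.interface_prevalence < 1.0:
            raise ValueError("interface_prevalence must lie in (0, 1)")
        if not 0.0 <= self.label_persistence < 1.0:
            raise ValueError("label_persistence must lie in [0, 1)")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if self.pssm_sd <= 0 or self.rsa_sd <= 0:
            raise ValueError("spread parameters must be positive")
        if self.rsa_class_means[1] < self.rsa_class_means[0]:
            raise ValueError(
                "interface RSA mean must be >= noninterface mean "
                "(interface residues are the more exposed class)"
            )

    @property
    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic label transitions with the requested stationary law.

        P(1->1) is ``label_persistence``; P(0->1) is then fixed by requiring
        the stationary interface fraction to equal ``interface_prevalence``:
        pi_1 = p01 / (p01 + p10).
        """
        p = self.interface_prevalence
        p10 = 1.0 - self.label_persistence
        p01 = p * p10 / (1.0 - p)
        if p01 > 1.0:
            raise ValueError(
                "no valid transition matrix: persistence too low for the "
                "requested prevalence"
            )
        return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


def _markov_labels(
    rng: np.random.Generator, length: int, config: SimulationConfig
) -> np.ndarray:
    T = config.transition_matrix
    labels = np.empty(length, dtype=int)
    labels[0] = int(rng.random() < config.interface_prevalence)
    u = rng.random(length - 1) if length > 1 else np.empty(0)
    for i in range(1, length):
        labels[i] = int(u[i - 1] < T[labels[i - 1], 1])
    return labels


def generate_chains(config: SimulationConfig) -> list[Chain]:
    """Generate labeled chains; byte-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    sep = config.class_separation * config.pssm_sd
    chains = []
    for idx in range(config.n_chains):
        length = int(rng.integers(config.length_min, config.length_max + 1))
        labels = _markov_labels(rng, length, config)
        letters = rng.choice(list(AMINO_ALPHABET), size=length)
        pssm_means = np.where(labels == 1, sep, 0.0)
        pssm = rng.normal(
            loc=pssm_means[:, None], scale=config.pssm_sd, size=(length, 20)
        )
        pssm = np.rint(pssm)  # PSSM log-odds are printed as integers
        rsa_means = np.where(
            labels == 1, config.rsa_class_means[1], config.rsa_class_means[0]
        )
        rsa = np.clip(rng.normal(rsa_means, config.rsa_sd), 0.0, 100.0)
        rsa = np.round(rsa, 2)  # keep text round-trips exact
        chain_id = f"syn{idx + 1:04d}"
        residues = tuple(
            ResidueRecord(
                chain_id=chain_id,
                position=i + 1,
                amino_acid=str(letters[i]),
                pssm_row=pssm[i],
                rsa=float(rsa[i]),
                label=int(labels[i]),
            )
            for i in range(length)
        )
        chains.append(Chain(chain_id=chain_id, residues=residues))
    return chains


# ---------------------------------------------------------------------------
# curation metadata fixtures
# ---------------------------------------------------------------------------

_RULE_KEYS = (
    "rule1",
    "rule2",
    "rule3",
    "rule4",
    "rule5",
    "rule6",
    "rule7",
)


def _clean_record(
    rng: np.random.Generator, idx: int
) -> ComplexMetadata:
    return ComplexMetadata(
        complex_id=f"cpx{idx:05d}",
        method="xray",
        resolution=float(np.round(rng.uniform(1.5, 2.8), 2)),
        chain_lengths=(
            int(rng.integers(60, 300)),
            int(rng.integers(60, 300)),
        ),
        uniprot_accessions=(f"UP{idx:05d}A", f"UP{idx:05d}B"),
        missing_ratio=float(np.round(rng.uniform(0.0, 0.2), 4)),
        is_transmembrane=False,
        interface_area=float(np.round(rng.uniform(600.0, 2400.0), 1)),
        is_subcomplex=False,
        cluster_ids=(f"cl{idx:05d}a", f"cl{idx:05d}b"),
    )


def generate_metadata(
    n: int, rejection_mix: dict[str, float], seed: int = 0
) -> list[ComplexMetadata]:
    """Metadata engineered to violate each curation rule in set proportions.

    ``rejection_mix`` maps rule keys (``rule1`` .. ``rule7``) to the fraction
    of the ``n`` records that should violate that rule and only that rule;
    the remainder pass every filter.  Clean records come first in input
    order, so rule-7 violators (cluster duplicates of a clean record) are
    the ones rejected.
    """
    for key in rejection_mix:
        if key not in _RULE_KEYS:
            raise ValueError(f"unknown rule key {key!r}; expected one of {_RULE_KEYS}")
    if any(f < 0 for f in rejection_mix.values()):
        raise ValueError("rejection fractions must be >= 0")
    if sum(rejection_mix.values()) > 1.0 + 1e-9:
        raise ValueError("rejection fractions must sum to at most 1")
    counts = {k: int(round(rejection_mix.get(k, 0.0) * n)) for k in _RULE_KEYS}
    n_clean = n - sum(counts.values())
    if n_clean < 0:
        raise ValueError("rounded violation counts exceed n")
    if counts["rule7"] > 0 and n_clean == 0:
        raise ValueError("rule7 violators need at least one clean record")

    rng = np.random.default_rng(seed)
    records = [_clean_record(rng, i) for i in range(n_clean)]
    idx = n_clean

    def _violator(rule: str, j: int) -> ComplexMetadata:
        base = _clean_record(rng, idx + j)
        cid = base.complex_id
        if rule == "rule1":
            if j % 2 == 0:
                return _replace(base, resolution=float(np.round(rng.uniform(3.1, 4.0), 2)))
            return _replace(base, chain_lengths=(int(rng.integers(20, 50)), base.chain_lengths[1]))
        if rule == "rule2":
            return _replace(base, uniprot_accessions=(f"UPHOM{cid}", f"UPHOM{cid}"))
        if rule == "rule3":
            return _replace(base, missing_ratio=float(np.round(rng.uniform(0.3, 0.6), 4)))
        if rule == "rule4":
            return _replace(base, is_transmembrane=True)
        if rule == "rule5":
            area = 300.0 if j % 2 == 0 else 3000.0
            return _replace(base, interface_area=area)
        if rule == "rule6":
            return _replace(base, is_subcomplex=True)
        # rule7: share a cluster with a clean record
        partner = records[j % n_clean]
        return _replace(base, cluster_ids=(partner.cluster_ids[0], base.cluster_ids[1]))

    for rule in _RULE_KEYS:
        for j in range(counts[rule]):
            records.append(_violator(rule, j))
        idx += counts[rule]
    return records


def _replace(meta: ComplexMetadata, **changes) -> ComplexMetadata:
    return dataclasses.replace(meta, **changes)
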