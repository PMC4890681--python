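from __future__ import annotations

import numpy as np
import pytest

from sporesig import SimConfig, simulate_genomes

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def random_nucleotide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NT), size=length))


def mutate(seq: str, rate: float, rng: np.random.Generator, alphabet: str = AA) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([c for c in alphabet if c != out[i]])
    return "".join(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_panel():
    """A small labelled genome panel with planted truth, shared across tests."""
    cfg = SimConfig(
        seed=11,
        n_resistant=6,
        n_sensitive=6,
        n_core_families=5,
        n_accessory_families=8,
        n_signature_families=8,
        protein_length_range=(50, 80),
    )
    genomes, truth = simulate_genomes(cfg)
    return cfg, genomes, truth
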