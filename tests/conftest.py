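"""Shared fixtures: small seeded populations reused across test modules."""

import warnings

import numpy as np
import pytest

from sweepscan.containers import HaplotypeMatrix, make_variant_table
from sweepscan.popsim import SimConfig, simulate_population

warnings.filterwarnings("ignore", category=UserWarning)


def tiny_config(seed: int, **kw) -> SimConfig:
    """A fast neutral config: 2 demes x 10 sampled diploids, ~300 SNPs."""
    base = dict(
        n_demes=2,
        deme_size=10,
        sample_size=10,
        n_generations=40,
        mutation_rate=5e-6,
        seq_length_bp=200_000,
        seed=seed,
    )
    base.update(kw)
    return SimConfig(**base)


def random_haplotypes(seed: int, n_hap: int = 20, n_sites: int = 50) -> HaplotypeMatrix:
    """Unstructured random biallelic haplotypes (not population-realistic;
    handy for algebraic identities)."""
    rng = np.random.default_rng(seed)
    hap = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.int8)
    # ensure segregating columns
    hap[0] = 0
    hap[1] = 1
    pos = np.sort(rng.choice(np.arange(1, 10_000), size=n_sites, replace=False))
    variants = make_variant_table(np.full(n_sites, "1", dtype=object), pos)
    samples = [f"s{i}" for i in range(n_hap // 2)]
    return HaplotypeMatrix(hap, variants, samples)


@pytest.fixture(scope="session")
def neutral_population():
    """One neutral two-deme population at the fixture scale."""
    hap, meta = simulate_population(tiny_config(seed=11))
    return hap, meta
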