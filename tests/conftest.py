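"""Shared fixtures: small references and mid-scale simulated datasets.

Session-scoped simulations are reused across test modules so the expensive
read-simulation work happens once.
"""

from __future__ import annotations

import numpy as np
import pytest

from varimap import simulate as sim


@pytest.fixture(scope="session")
def small_ref() -> sim.Reference:
    """One 100 kb chromosome with two 500 bp assembly gaps."""
    return sim.generate_reference(1, 100_000, 0.42, (2, 500), seed=7)


@pytest.fixture(scope="session")
def snp_bundle():
    """300 kb diploid donor with SNPs only, sequenced at 11.56x, eps=0.01."""
    ref = sim.generate_reference(1, 300_000, 0.41, (1, 500), seed=101)
    donor, truth = sim.implant_variants(ref, 1.18e-3, 1.0e-3, seed=101)
    params = sim.ReadPairParams(depth=11.56, read_len=44, seed=101)
    pairs = sim.simulate_read_pairs(donor, params)
    return ref, donor, truth, params, pairs


@pytest.fixture(scope="session")
def sv_bundle():
    """500 kb donor with 12 homozygous deletions, error-free reads."""
    ref = sim.generate_reference(1, 500_000, 0.41, (1, 500), seed=202)
    spec = sim.SvSpec(
        counts={"deletion": 12},
        length_dist="uniform",
        min_len=100,
        max_len=2000,
        het_fraction=0.0,
    )
    donor, truth = sim.implant_variants(ref, 0.0, 0.0, sv_spec=spec, seed=202)
    params = sim.ReadPairParams(
        depth=11.56, read_len=44, insert_mean=200.0, insert_sd=20.0,
        error_rate=0.0, seed=202,
    )
    pairs = sim.simulate_read_pairs(donor, params)
    return ref, donor, truth, params, pairs


@pytest.fixture(scope="session")
def gene_ref_models():
    """A 4 x 150 kb genome with ~120 synthetic gene models."""
    ref = sim.generate_reference(4, 150_000, 0.41, (1, 300), seed=11)
    models = sim.generate_gene_models(ref, 120, seed=11)
    return ref, models


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
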