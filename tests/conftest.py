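"""Shared fixtures: seeded synthetic bundles and small helpers."""

from __future__ import annotations

import numpy as np
import pytest

from lariat import synthetic
from lariat.io import CMHit, ModelType


@pytest.fixture(scope="session")
def small_bundle():
    """A noise-free 12-genome bundle with complete calls only."""
    cfg = synthetic.SyntheticConfig(
        n_genomes=12, seed=7, p_partial_call=0.0, noise_hits_per_genome=0
    )
    return synthetic.generate_bundle(cfg)


@pytest.fixture(scope="session")
def bundle_files(small_bundle, tmp_path_factory):
    return small_bundle.write(tmp_path_factory.mktemp("bundle"))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_hit(
    target="g1",
    model_type=ModelType.D1D4,
    start1=100,
    end1=900,
    strand="+",
    evalue=1e-6,
    model_name=None,
    score=50.0,
):
    """Construct a CMHit from 1-based inclusive coordinates."""
    if model_name is None:
        model_name = "group-II-D1D4-1" if model_type is ModelType.D1D4 else "RF00029"
    return CMHit(
        target_id=target,
        model_name=model_name,
        model_type=model_type,
        start=start1 - 1,
        end=end1,
        strand=strand,
        evalue=evalue,
        bit_score=score,
    )
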