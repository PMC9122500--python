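"""Shared fixtures. The stage-1 docking runs are expensive, so they are built
once per session and shared between the pipeline tests and the acceptance
checks."""
from __future__ import annotations

import numpy as np
import pytest

from dcxlattice.pipeline import StageSpec, build_stage_inputs, run_stage
from dcxlattice.sampling import SamplerConfig

STAGE1_SEED = 1
SAMPLER_SEED = 7


def desk_config(**overrides) -> SamplerConfig:
    kw = dict(n_replicas=4, n_steps=1500, n_runs=4, seed=SAMPLER_SEED)
    kw.update(overrides)
    return SamplerConfig(**kw)


@pytest.fixture(scope="session")
def stage1_clean():
    """Stage-1 docking of a single domain, 30 clean crosslinks, no EM."""
    spec = StageSpec(stage=1, restraint_subset="xl_only")
    inputs = build_stage_inputs(spec, seed=STAGE1_SEED)
    report = run_stage(spec, inputs, desk_config())
    return inputs, report


@pytest.fixture(scope="session")
def stage1_decoys():
    """Same scenario with a 20% decoy fraction added to the crosslink table."""
    spec = StageSpec(stage=1, restraint_subset="xl_only")
    inputs = build_stage_inputs(spec, seed=STAGE1_SEED, decoy_fraction=0.2)
    report = run_stage(spec, inputs, desk_config())
    return inputs, report


@pytest.fixture(scope="session")
def stage1_em():
    """Crosslinks combined with the synthetic domain density map."""
    spec = StageSpec(stage=1, restraint_subset="xl_plus_em")
    inputs = build_stage_inputs(spec, seed=STAGE1_SEED)
    report = run_stage(spec, inputs, desk_config())
    return inputs, report


@pytest.fixture(scope="session")
def toy_lattice():
    from dcxlattice.synthetic_data import make_toy_lattice

    return make_toy_lattice(3, 3, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
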