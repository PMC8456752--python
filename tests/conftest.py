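"""Shared fixtures: synthetic cohorts reused across test modules.

Heavy cohorts are session-scoped so generation cost is paid once.
"""

import numpy as np
import pytest

import connectoscramble as cs


@pytest.fixture(scope="session")
def networks():
    return cs.load_networks()


@pytest.fixture(scope="session")
def confounded_phenotypes():
    """n=2000 cohort with the default sex-shifted ICV / condition-shifted
    motion structure (no planted connectome effect)."""
    spec = cs.CohortSpec(n_subjects=2000, seed=1234)
    return cs.generate_phenotypes(spec)


@pytest.fixture(scope="session")
def planted_rest_cohort(networks):
    """n=600 cohort with a d=1.5 sex effect on the salience network's 45
    inner edges, present in rest acquisitions only (all bands)."""
    spec = cs.CohortSpec(n_subjects=600, seed=77).with_effects(
        cs.EffectEntry(nodes=networks["SAL"].nodes, condition="rest", d=1.5)
    )
    table = cs.generate_phenotypes(spec)
    stacks = cs.generate_connectomes(table, spec)
    return spec, table, stacks


@pytest.fixture(scope="session")
def small_trained_member(planted_rest_cohort):
    """One quickly trained member on the planted cohort (15 epochs)."""
    _, table, stacks = planted_rest_cohort
    cfg = cs.MemberConfig(epochs=15, seed=3)
    return cs.train_member(stacks, table["sex"].to_numpy(), cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
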