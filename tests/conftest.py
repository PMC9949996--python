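import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from ovrfsim.event_tree import EventTree
from ovrfsim.fixtures import make_genome, make_overlap_layout
from ovrfsim.genome import Annotation, Genome, Orf
from ovrfsim.rate_model import (
    DistributionSpec,
    SubstitutionParams,
    assign_site_categories,
    discretize,
)

CONSTANT_MU = DistributionSpec(family="constant", value=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20230223)


def build_tree(genome: Genome, orfs, params=None, mu_spec=CONSTANT_MU,
               seed: int = 0, orf_mu_specs=None):
    """Assemble annotation, assignments and event tree for tests."""
    ann = Annotation(genome, orfs)
    if params is None:
        params = SubstitutionParams.with_empirical_pi(genome.sequence)
    mu_set = discretize(mu_spec)
    omega_sets = {
        o.name: discretize(o.omega_spec) for o in orfs
    }
    orf_mu_sets = (
        {name: discretize(spec) for name, spec in orf_mu_specs.items()}
        if orf_mu_specs else None
    )
    assignments = assign_site_categories(
        ann, mu_set, omega_sets, np.random.default_rng(seed), orf_mu_sets)
    tree = EventTree(ann, assignments, params)
    return ann, assignments, tree


def random_orf_layout(rng, length, max_orfs=3):
    """Random overlapping single-segment ORFs for property tests."""
    n = int(rng.integers(1, max_orfs + 1))
    orfs = []
    spec = DistributionSpec(family="gamma", shape=2.0, scale=0.5, ncat=2)
    for i in range(n):
        ncod = int(rng.integers(3, max(4, length // 3)))
        start = int(rng.integers(0, max(1, length - 3 * ncod)))
        strand = "+" if rng.random() < 0.7 else "-"
        orfs.append(Orf(f"o{i}", ((start, start + 3 * ncod),), strand,
                        omega_spec=spec))
    return orfs


@pytest.fixture
def fig2_setup():
    layout = make_overlap_layout(
        "fig2", 120, DistributionSpec(family="constant", value=0.4))
    genome = make_genome(120, 0.5, seed=2)
    return genome, list(layout.orfs)
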