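import io

import numpy as np
import pandas as pd
import pytest

import piezotraj as pt
from piezotraj.synthetic import ANNOTATION_TSV, METHYL_TSV


@pytest.fixture(scope="session")
def toy_config():
    return pt.GeneratorConfig(
        seed=7, temperatures=(308.0,), pressures=(1.0, 2500.0)
    )


@pytest.fixture(scope="session")
def toy_system(toy_config):
    """Scripted toy system: 60 frames (divisible by 2, 3 and 10)."""
    topo, trajs, truth = pt.gen_toy_system(toy_config, n_frames=60)
    annotated = pt.annotate_topology(
        topo, pd.read_csv(io.StringIO(ANNOTATION_TSV), sep="\t")
    )
    for traj in trajs.values():
        traj.topology = annotated
    return annotated, trajs, truth


@pytest.fixture(scope="session")
def toy_trajectory(toy_system):
    topo, trajs, _ = toy_system
    return trajs[pt.ConditionLabel(308.0, 1.0)]


@pytest.fixture(scope="session")
def methyl_table():
    return pd.read_csv(io.StringIO(METHYL_TSV), sep="\t")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
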