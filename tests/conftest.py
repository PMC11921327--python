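import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from magcom import pipeline
from magcom.simulate import SimConfig, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic survey shared across tests."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def derep(dataset):
    return pipeline.run_dereplication(dataset.mag_records(), dataset.ani)


@pytest.fixture(scope="session")
def module_out(dataset, derep):
    return pipeline.run_module_inference(
        derep.clusters, dataset.modules, dataset.abundance, dataset.metadata,
        representative_of_cluster=derep.representative_of_cluster)


def partition(mapping):
    """Set-of-frozensets view of a {member: group} mapping."""
    groups = {}
    for member, group in mapping.items():
        groups.setdefault(group, set()).add(member)
    return {frozenset(v) for v in groups.values()}
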