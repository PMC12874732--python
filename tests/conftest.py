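import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import taxaflow as tf

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def metadata():
    """The reference 7-treatment x 3-replicate design."""
    return tf.SampleMetadata.from_design(tf.TREATMENTS, 3)


@pytest.fixture(scope="session")
def n_panel():
    return tf.load_pathway_panel("map00910")


@pytest.fixture(scope="session")
def p_panel():
    return tf.load_pathway_panel("map00440")


@pytest.fixture()
def small_table(metadata):
    """Tiny stratified table: two ECs x two genera across 21 samples."""
    rows = [
        ("6.3.1.2", tf.genus_lineage("Streptomyces").to_string()),
        ("6.3.1.2", tf.genus_lineage("Pseudomonas").to_string()),
        ("1.7.2.4", tf.genus_lineage("Pseudomonas").to_string()),
    ]
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.uniform(0.5, 5.0, size=(3, 21)),
        index=pd.MultiIndex.from_tuples(rows, names=["function_id", "lineage"]),
        columns=list(metadata.sample_ids),
    )
    return tf.StratifiedTable(data)
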