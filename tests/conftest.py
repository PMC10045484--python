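import os
import sys

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, os.path.dirname(__file__))

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ecsenesig import CellAnnotation, ExpressionMatrix, GeneSet  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20230328)


@pytest.fixture
def small_lognorm(rng):
    """12 genes x 30 cells lognorm matrix with two cell types."""
    values = rng.gamma(2.0, 1.0, size=(12, 30))
    m = ExpressionMatrix(
        gene_ids=[f"g{i:02d}" for i in range(12)],
        obs_ids=[f"c{i:02d}" for i in range(30)],
        values=values, layer="lognorm", dataset_id="fixture")
    ann = CellAnnotation(obs_ids=m.obs_ids,
                         cell_types=["TEC"] * 15 + ["Tumor"] * 15,
                         dataset_id="fixture")
    return m, ann


@pytest.fixture
def tiny_gene_set():
    return GeneSet(name="S", genes=["g01", "g03", "g07"])
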