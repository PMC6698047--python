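import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dermdeconv.io import ExpressionMatrix
from dermdeconv.signature import ReferenceDataset, build_signature
from dermdeconv.synthetic import GeneratorConfig, generate_reference


@pytest.fixture(scope="session")
def small_reference():
    """A 6-type, 400-probe synthetic reference with its ground truth."""
    cfg = GeneratorConfig(seed=42)
    return generate_reference(cfg)


@pytest.fixture(scope="session")
def small_signature(small_reference):
    ref, _ = small_reference
    return build_signature(ref, g_min=2, g_max=15)


@pytest.fixture()
def toy_matrix():
    data = pd.DataFrame(
        {"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]},
        index=["p1", "p2", "p3"],
    )
    return ExpressionMatrix(data, "log2")


def make_reference(
    n_types=3,
    n_probes=60,
    markers_per_type=5,
    reps=3,
    noise_sd=0.2,
    effect=4.0,
    seed=0,
):
    """Small parametrizable reference for targeted tests."""
    cfg = GeneratorConfig(
        n_cell_types=n_types,
        n_probes=n_probes,
        markers_per_type=markers_per_type,
        replicate_count=reps,
        replicate_noise_sd_log2=noise_sd,
        marker_log2_effect=effect,
        seed=seed,
    )
    return generate_reference(cfg)
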