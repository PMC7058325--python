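import numpy as np
import pytest

from retinavasc.classify import ClassifierConfig
from retinavasc.pipeline import PipelineConfig, run_pipeline
from retinavasc.preprocessing import PreprocessConfig
from retinavasc.segmentation import SegmenterConfig
from retinavasc.synthetic import SimulatorConfig, generate_cohort

TINY_PIPELINE = dict(
    simulator=SimulatorConfig(image_size=64, tree_depth=4, root_diameter=4.0, n_roots=3),
    preprocess=PreprocessConfig(target_side=64),
    segmenter=SegmenterConfig(depth=2, base_filters=4, patch_side=16,
                              patches_per_image=20, epochs=3, batch_size=8),
    classifier=ClassifierConfig(
        conv_filters=(4, 4, 8, 8, 8), kernel_sizes=(3,) * 5, strides=(1,) * 5,
        pool_sizes=(2, 2, 2, 1, 0), dense_units=(8, 2), dropout_rates=(0.0, 0.0),
        input_side=32, train_resize_side=40, epochs=2, batch_size=8,
        learning_rate=3e-3,
    ),
    n_per_class=10,
    n_segmenter_pairs=4,
    folds=5,
    seed=17,
)


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Two full desk-scale pipeline runs with identical config and seed."""
    outputs = []
    for name in ("run_a", "run_b"):
        out = tmp_path_factory.mktemp(name)
        summary = run_pipeline(PipelineConfig(**TINY_PIPELINE), out)
        outputs.append((out, summary))
    return outputs


@pytest.fixture(scope="session")
def unit_sim_config():
    """Small, fast simulator settings for unit tests (not the study defaults)."""
    return SimulatorConfig(image_size=64, tree_depth=4, root_diameter=4.0, n_roots=3)


@pytest.fixture(scope="session")
def small_cohort(unit_sim_config):
    return generate_cohort(unit_sim_config, 8, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
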