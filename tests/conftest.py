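import numpy as np
import pytest

from icufusion.images import BackboneConfig, ImageSpec
from icufusion.model import FusionConfig, ModelConfig
from icufusion.schema import ParameterSchema, SchemaItem, default_schema


@pytest.fixture(scope="session")
def paper_schema() -> ParameterSchema:
    return default_schema()


@pytest.fixture()
def toy_schema() -> ParameterSchema:
    """Three items: two continuous, one small categorical."""
    return ParameterSchema(
        (
            SchemaItem(name="heart rate", kind="continuous", unit="bpm",
                       default=86, missing_fraction=0.0, mean=85.0, sd=13.0),
            SchemaItem(name="fraction inspired oxygen", kind="continuous",
                       unit="FiO2", default=0.21, missing_fraction=0.26,
                       mean=0.45, sd=0.07),
            SchemaItem(name="gcs eye", kind="categorical", default=4,
                       categories=(1, 2, 3, 4), missing_fraction=0.0),
        )
    )


@pytest.fixture(scope="session")
def tiny_model_cfg() -> ModelConfig:
    """Smallest geometry that still exercises every component: 32x32 images
    (4 patch tokens), 8 hourly tokens, width 16."""
    return ModelConfig(
        image_spec=ImageSpec(height=32, width=32, patch_size=16),
        backbone=BackboneConfig(depth=1, dim=16, heads=2, mlp_ratio=2),
        fusion=FusionConfig(dim=16, depth=1, heads=2, mlp_hidden=16, mlp_ratio=2),
        n_features=5,
        T=8,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
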