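import numpy as np
import pytest

import strawseg as ss
from strawseg.dataset import SamplePair, mask_to_indices

DESK_SIZE = (64, 64)


def to_pairs(samples):
    return [SamplePair(image=s.image, target=mask_to_indices(s.mask), id=str(i))
            for i, s in enumerate(samples)]


@pytest.fixture(scope="session")
def ranges():
    return ss.RandomizationRanges()


@pytest.fixture(scope="session")
def rendered_sample(ranges):
    spec = ss.sample_plant(ranges, 7)
    view, brightness = ss.sample_view(ranges, 7)
    return ss.render_scene(spec, view, brightness, DESK_SIZE)


@pytest.fixture(scope="session")
def small_batch(ranges):
    """20 desk-size samples shared across scene-contract tests."""
    return ss.generate_samples(20, ranges, seed=101, size=DESK_SIZE)


@pytest.fixture(scope="session")
def tiny_net():
    net = ss.SwinUNet(ss.tiny_config(DESK_SIZE))
    return net, net.init_params(0)


def single_fruit_spec(stage, seed=3):
    """A plant with exactly one fruit and nothing else (no leaves/flowers)."""
    stem = ss.scene.StemSpec(
        points=((0.5, 0.9), (0.5, 0.3)),
        leaves=(),
        fruits=(ss.scene.FruitSpec(t=0.5, scale=1.2, stage=stage, depth=2.5, side=0.0),),
        flowers=(),
    )
    return ss.PlantSpec(stems=(stem,), seed=seed)
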