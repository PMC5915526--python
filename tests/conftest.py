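import logging
from types import SimpleNamespace

import numpy as np
import pytest

from neuritree.benchmark import standard_suite_specs
from neuritree.io import Image2D
from neuritree.phantom import PhantomSpec, generate_phantom
from neuritree.segmentation import segment
from neuritree.soma import detect_somas
from neuritree.trace import compute_seeds, extract_trees

logging.getLogger("neuritree").setLevel(logging.ERROR)


def run_full_pipeline(spec: PhantomSpec):
    """Phantom -> segment -> somas -> seeds -> trees, all defaults."""
    stacks, truth = generate_phantom(spec)
    img = Image2D(stacks["structural"].voxels[0], pixel_size=spec.pixel_size)
    mask = segment(img)
    somas = detect_somas(mask)
    seeds = compute_seeds(mask)
    trees, report = extract_trees(somas, mask, seeds)
    return SimpleNamespace(spec=spec, truth=truth, image=img, mask=mask,
                           somas=somas, seeds=seeds, trees=trees,
                           report=report)


@pytest.fixture(scope="session")
def standard_suite():
    """The 12-image standard phantom suite, fully processed (shared)."""
    return [run_full_pipeline(spec) for spec in standard_suite_specs()]


@pytest.fixture(scope="session")
def two_neuron_run():
    """A small two-neuron phantom processed end to end (shared)."""
    spec = PhantomSpec(shape=(512, 512), n_neurons=2,
                       neurites_per_soma=(3, 3), seed=1)
    return run_full_pipeline(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
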