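import numpy as np
import pytest

from neuritree.phantom import (PhantomError, PhantomSpec, generate_phantom,
                               render_bell_signal, render_uniform_signal)


def small_spec(**kwargs):
    defaults = dict(shape=(256, 256), n_neurons=2, seed=0,
                    poisson_noise=False)
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


class TestGeneration:
    def test_soma_only_neuron(self):
        spec = small_spec(n_neurons=1, neurites_per_soma=(0, 0))
        stacks, truth = generate_phantom(spec)
        assert len(truth.trees) == 1
        assert truth.trees[0].n_neurites == 0
        assert truth.trees[0].n_nodes == 1
        assert (truth.label_image > 0).sum() > 0

    def test_deterministic_given_seed(self):
        spec = small_spec(n_neurons=3, seed=11, poisson_noise=True)
        a, ta = generate_phantom(spec)
        b, tb = generate_phantom(small_spec(n_neurons=3, seed=11,
                                            poisson_noise=True))
        np.testing.assert_array_equal(a["structural"].voxels,
                                      b["structural"].voxels)
        np.testing.assert_array_equal(ta.label_image, tb.label_image)

    def test_forced_crossing_renders_overlap_but_trees_disjoint(self):
        spec = PhantomSpec(shape=(512, 512), n_neurons=1,
                           n_forced_crossings=1,
                           crossing_angle=(np.pi / 2, np.pi / 2), seed=4,
                           poisson_noise=False)
        stacks, truth = generate_phantom(spec)
        assert len(truth.trees) == 2
        assert len(truth.crossings) == 1
        overlap = truth.neuron_masks[0] & truth.neuron_masks[1]
        assert overlap.sum() >= 1
        a = {tuple(p) for p in truth.trees[0].all_nodes()}
        b = {tuple(p) for p in truth.trees[1].all_nodes()}
        assert not (a & b)

    def test_adding_crossings_preserves_base_trees(self):
        base = generate_phantom(PhantomSpec(shape=(512, 512), n_neurons=2,
                                            seed=5))[1]
        more = generate_phantom(PhantomSpec(shape=(512, 512), n_neurons=2,
                                            n_forced_crossings=1, seed=5))[1]
        for t0, t1 in zip(base.trees, more.trees[:2]):
            assert t0.n_neurites == t1.n_neurites
            for n0, n1 in zip(t0.neurites, t1.neurites):
                np.testing.assert_array_equal(n0.nodes, n1.nodes)

    def test_infeasible_placement_raises(self):
        spec = small_spec(shape=(96, 96), n_neurons=20)
        with pytest.raises(PhantomError):
            generate_phantom(spec)

    def test_ground_truth_trees_valid(self):
        _, truth = generate_phantom(small_spec(n_neurons=3, seed=2))
        for t in truth.trees:
            t.validate()

    def test_noise_off_zero_background_mask_equals_support(self):
        spec = small_spec(background_const=0.0, background_gradient=0.0,
                          seed=9)
        stacks, truth = generate_phantom(spec)
        img = stacks["structural"].voxels[0]
        np.testing.assert_array_equal(truth.label_image > 0, img > 0)

    def test_centerlines_inside_own_label(self):
        """Every true centerline point lies inside its neuron's mask."""
        _, truth = generate_phantom(small_spec(n_neurons=2, seed=3))
        for t, m in zip(truth.trees, truth.neuron_masks):
            for nr in t.neurites:
                rr = np.round(nr.nodes[:, 0]).astype(int)
                cc = np.round(nr.nodes[:, 1]).astype(int)
                assert m[rr, cc].all()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(crossing_angle=(0.0, 1.0)).validate()
        with pytest.raises(ValueError):
            PhantomSpec(neurite_half_width=(2.0, 1.0)).validate()
        with pytest.raises(ValueError):
            PhantomSpec(n_neurons=0).validate()


@pytest.fixture(scope="module")
def truth():
    spec = PhantomSpec(shape=(400, 400), n_neurons=1,
                       neurites_per_soma=(3, 3),
                       neurite_length=(120.0, 160.0), seed=7,
                       poisson_noise=False)
    return generate_phantom(spec)[1]


class TestSignalPainting:
    def test_zero_amplitude_is_blank(self, truth):
        img = render_bell_signal(truth, 1, 0, H=0.0, mu=35, sigma=10)
        assert img.pixels.max() == 0.0

    def test_peak_value_on_centerline(self, truth):
        neurite = truth.trees[0].neurites[0]
        img = render_bell_signal(truth, 1, 0, H=100.0, mu=35, sigma=10)
        arc = neurite.arclength
        i = int(np.argmin(np.abs(arc - 35.0)))
        r, c = np.round(neurite.nodes[i]).astype(int)
        assert img.pixels[r, c] == pytest.approx(100.0, rel=0.01)

    def test_uniform_signal_level(self, truth):
        neurite = truth.trees[0].neurites[1]
        img = render_uniform_signal(truth, 1, 1, 42.0)
        mid = neurite.nodes[len(neurite.nodes) // 2]
        r, c = np.round(mid).astype(int)
        assert img.pixels[r, c] == pytest.approx(42.0)

    def test_unknown_neurite_rejected(self, truth):
        with pytest.raises(KeyError):
            render_bell_signal(truth, 1, 99, H=1.0, mu=0, sigma=1)
        with pytest.raises(ValueError):
            render_bell_signal(truth, 1, 0, H=1.0, mu=0, sigma=0.0)
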