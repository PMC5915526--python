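import numpy as np
import pytest

from neuritree.io import Image2D
from neuritree.phantom import PhantomSpec, generate_phantom, \
    render_bell_signal
from neuritree.profiles import (AISMetrics, IntensityProfile, ais_metrics,
                                compare_groups, gaussian_area, identify_axon,
                                metrics_frame, sample_profile,
                                select_dendrites)
from neuritree.segmentation import BinaryMask


@pytest.fixture(scope="module")
def painted():
    """Single-neuron phantom with a Gaussian bell painted on its longest
    neurite over a linear background gradient (no noise)."""
    spec = PhantomSpec(shape=(400, 400), n_neurons=1,
                       neurites_per_soma=(3, 3),
                       neurite_length=(120.0, 160.0), seed=7,
                       poisson_noise=False)
    _, truth = generate_phantom(spec)
    tree = truth.trees[0]
    axon = int(np.argmax([n.length for n in tree.neurites]))
    sig = render_bell_signal(truth, 1, axon, H=100.0, mu=35.0, sigma=10.0)
    yy, xx = np.mgrid[0:400, 0:400]
    gradient = 20.0 + 10.0 * (xx / 399 + yy / 399) / 2.0
    img = Image2D(sig.pixels + gradient)
    mask = BinaryMask(truth.label_image > 0)
    profiles = [sample_profile(img, mask, tree.neurites[j], neuron_id=1,
                               neurite_id=j) for j in range(3)]
    return tree, axon, profiles


class TestSampleProfile:
    def test_constant_field_corrects_to_zero(self):
        """With a constant image, background windows read the same value
        as the neurite, so the corrected profile is identically ~0."""
        f = np.zeros((60, 120), dtype=bool)
        f[28:33, 10:110] = True
        img = Image2D(np.full((60, 120), 55.0))
        nodes = np.column_stack([np.full(100, 30.0), np.arange(10.0, 110.0)])
        p = sample_profile(img, BinaryMask(f), nodes)
        np.testing.assert_allclose(p.raw, 55.0)
        np.testing.assert_allclose(p.corrected, 0.0, atol=1e-9)

    def test_gaussian_recovered_under_gradient(self, painted):
        tree, axon, profiles = painted
        p = profiles[axon]
        i35 = int(np.argmin(np.abs(p.arclength_px - 35.0)))
        assert p.corrected[i35] == pytest.approx(100.0, rel=0.05)

    def test_gradient_background_removed(self, painted):
        """The corrected profile matches the no-background render within
        10% RMS of the signal peak."""
        tree, axon, profiles = painted
        p = profiles[axon]
        arc = p.arclength_px
        expected = 100.0 * np.exp(-((arc - 35.0) ** 2) / (2 * 10.0 ** 2))
        rms = np.sqrt(np.mean((p.corrected - expected) ** 2))
        assert rms < 0.10 * 100.0

    def test_short_neurite_gives_single_sample(self):
        f = np.zeros((30, 30), dtype=bool)
        f[15, 15] = True
        img = Image2D(np.full((30, 30), 5.0))
        p = sample_profile(img, BinaryMask(f), np.array([[15.0, 15.0]]))
        assert len(p.arclength_px) == 1

    def test_arclength_strictly_increasing(self, painted):
        _, _, profiles = painted
        for p in profiles:
            assert np.all(np.diff(p.arclength_px) > 0)
            np.testing.assert_allclose(p.arclength_um,
                                       p.arclength_px * p.pixel_size)


def synthetic_profile(values, neurite_id=0, arc=None):
    values = np.asarray(values, dtype=float)
    arc = np.arange(len(values), dtype=float) if arc is None else arc
    return IntensityProfile(neuron_id=1, neurite_id=neurite_id,
                            arclength_px=arc, raw=values,
                            background=np.zeros_like(values))


class TestAisMetrics:
    def test_exact_gaussian_recovery_and_closed_form_area(self):
        x = np.arange(0.0, 101.0)
        g = 50.0 * np.exp(-((x - 35.0) ** 2) / (2 * 12.0 ** 2))
        axon = synthetic_profile(g)
        dendrites = [synthetic_profile(np.full(101, 0.5), j) for j in (1, 2)]
        m = ais_metrics(axon, dendrites)
        assert m.fit_ok
        assert m.H == pytest.approx(50.0, abs=1e-3)
        assert m.mu == pytest.approx(35.0, abs=1e-3)
        assert m.sigma == pytest.approx(12.0, abs=1e-3)
        closed = gaussian_area(50.0, 35.0, 12.0, 70)
        assert m.A_ais == pytest.approx(closed, rel=1e-3)

    def test_all_zero_profiles_degenerate(self):
        axon = synthetic_profile(np.zeros(80))
        dendrites = [synthetic_profile(np.zeros(80), j) for j in (1, 2)]
        m = ais_metrics(axon, dendrites)
        assert m.A_ais == 0.0
        assert m.V_ais == 0.0
        assert m.R_AD is None

    def test_short_profiles_rejected(self):
        axon = synthetic_profile(np.ones(30))
        dendrites = [synthetic_profile(np.ones(80), j) for j in (1, 2)]
        with pytest.raises(ValueError):
            ais_metrics(axon, dendrites)
        with pytest.raises(ValueError):
            ais_metrics(synthetic_profile(np.ones(80)), dendrites[:1])

    def test_noisy_gaussian_amplitude_within_ten_percent(self, rng):
        x = np.arange(0.0, 101.0)
        g = 80.0 * np.exp(-((x - 35.0) ** 2) / (2 * 10.0 ** 2))
        noisy = g * rng.normal(1.0, 0.05, size=g.shape)
        axon = IntensityProfile(neuron_id=1, neurite_id=0, arclength_px=x,
                                raw=np.clip(noisy, 0, None),
                                background=np.zeros_like(x))
        dendrites = [synthetic_profile(np.full(101, 1.0), j) for j in (1, 2)]
        m = ais_metrics(axon, dendrites)
        assert abs(m.H - 80.0) / 80.0 < 0.1

    def test_axon_and_dendrite_selection(self, painted):
        tree, axon, profiles = painted
        assert identify_axon(tree, profiles) == axon
        dendrites = select_dendrites(tree, profiles, axon)
        assert len(dendrites) == 2
        assert all(p.neurite_id != axon for p in dendrites)


def fake_metrics(rng, n, h_mean, r_mean, spread=1.0):
    out = []
    for i in range(n):
        out.append(AISMetrics(
            neuron_id=i, A_ais=rng.normal(1000, 50 * spread),
            V_ais=rng.normal(500, 30 * spread),
            H=rng.normal(h_mean, spread), mu=35.0, sigma=10.0,
            A_den=300.0, R_AD=rng.normal(r_mean, 0.1 * spread), fit_ok=True))
    return out


class TestCompareGroups:
    def test_identical_groups_not_significant(self, rng):
        a = fake_metrics(rng, 10, 50.0, 2.0)
        rep = compare_groups(a, list(a))
        assert (rep["p"] > 0.99).all()
        assert np.allclose(rep["t"], 0.0)

    def test_large_separation_significant(self, rng):
        a = fake_metrics(rng, 12, 60.0, 3.0)
        b = fake_metrics(rng, 12, 50.0, 1.0)  # 10 sigma apart in H
        rep = compare_groups(a, b)
        assert rep.loc["H", "p"] < 0.001
        assert rep.loc["R_AD", "p"] < 0.001
        assert rep.loc["H", "df"] == 22

    def test_label_swap_flips_t_keeps_p(self, rng):
        a = fake_metrics(rng, 8, 55.0, 2.5)
        b = fake_metrics(rng, 9, 50.0, 1.5)
        ab = compare_groups(a, b)
        ba = compare_groups(b, a)
        np.testing.assert_allclose(ab["p"], ba["p"])
        np.testing.assert_allclose(ab["t"], -ba["t"])

    def test_too_few_neurons_rejected(self, rng):
        a = fake_metrics(rng, 1, 50.0, 2.0)
        b = fake_metrics(rng, 5, 50.0, 2.0)
        with pytest.raises(ValueError):
            compare_groups(a, b)

    def test_metrics_frame_columns(self, rng):
        df = metrics_frame(fake_metrics(rng, 3, 50.0, 2.0), group="ctrl")
        assert set(df.columns) >= {"neuron_id", "A_ais", "V_ais", "H",
                                   "R_AD", "group"}
        assert (df.group == "ctrl").all()
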