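import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuritree.evaluate import (NeuriteMatchResult, crossing_resolution_rate,
                                match_neurites, metrics, pair_somas)
from neuritree.phantom import Crossing, GroundTruth
from neuritree.tree import Neurite, NeuronTree


def straight_tree(neuron_id, root, angles, length=60.0):
    tree = NeuronTree(neuron_id=neuron_id, root=np.asarray(root, float),
                      soma_radius=8.0)
    for a in angles:
        d = np.array([np.sin(a), np.cos(a)])
        t = np.arange(8.0, 8.0 + length)
        nodes = np.asarray(root, float) + t[:, None] * d[None, :]
        tree.neurites.append(Neurite(
            nodes=nodes, arclength=t,
            radii=np.full(len(t), 1.5)))
    return tree


@pytest.fixture()
def tree_pair():
    truth = [straight_tree(1, (60, 60), [0.0, 2.0, 4.0]),
             straight_tree(2, (200, 200), [1.0, 3.0, 5.0])]
    pred = copy.deepcopy(truth)
    return pred, truth


class TestMatchNeurites:
    def test_identical_trees_are_perfect(self, tree_pair):
        pred, truth = tree_pair
        res = match_neurites(pred, truth)
        assert (res.tp, res.fp, res.fn) == (6, 0, 0)

    def test_deleted_neurite_counts_fn(self, tree_pair):
        pred, truth = tree_pair
        del pred[0].neurites[1]
        res = match_neurites(pred, truth)
        assert (res.tp, res.fp, res.fn) == (5, 0, 1)

    def test_reassigned_neurite_counts_fp_and_fn(self, tree_pair):
        pred, truth = tree_pair
        stolen = pred[0].neurites.pop(1)
        pred[1].neurites.append(stolen)
        res = match_neurites(pred, truth)
        assert res.fn == 1   # true neurite of neuron 1 uncovered by its pair
        assert res.fp == 1   # predicted neurite follows another neuron
        assert res.tp == 5

    def test_soma_pairing_failure_raises(self, tree_pair):
        pred, truth = tree_pair
        for t in pred:
            t.root = t.root + 500.0
        with pytest.raises(ValueError):
            pair_somas(pred, truth)


class TestMetrics:
    def test_backsolved_counts_reproduce_ratio_structure(self):
        """TP=172, FN=19, FP=0 gives sens 0.9005, prec 1.0, dice 0.9477."""
        res = NeuriteMatchResult(tp=172, fp=0, fn=19)
        sens, prec, dice = metrics(res)
        assert sens == pytest.approx(0.9005, abs=5e-5)
        assert prec == pytest.approx(1.0000, abs=1e-12)
        assert dice == pytest.approx(0.9477, abs=5e-5)

    def test_perfect_single_neurite(self):
        assert metrics(NeuriteMatchResult(tp=1, fp=0, fn=0)) == (1.0, 1.0, 1.0)

    def test_degenerate_all_wrong(self):
        assert metrics(NeuriteMatchResult(tp=0, fp=3, fn=5)) == (0.0, 0.0, 0.0)

    def test_no_true_neurites_rejected(self):
        with pytest.raises(ValueError):
            metrics(NeuriteMatchResult(tp=0, fp=2, fn=0))

    @settings(deadline=None, max_examples=200)
    @given(tp=st.integers(1, 500), fp=st.integers(0, 500),
           fn=st.integers(0, 500))
    def test_dice_is_harmonic_combination(self, tp, fp, fn):
        """dice == 2 * prec * sens / (prec + sens) whenever both defined."""
        sens, prec, dice = metrics(NeuriteMatchResult(tp=tp, fp=fp, fn=fn))
        assert dice == pytest.approx(
            2 * prec * sens / (prec + sens), rel=1e-12)
        assert 0.0 <= sens <= 1.0 and 0.0 <= prec <= 1.0 and 0.0 <= dice <= 1.0

    @settings(deadline=None, max_examples=100)
    @given(tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(1, 50))
    def test_converting_fn_to_tp_never_decreases_metrics(self, tp, fp, fn):
        before = metrics(NeuriteMatchResult(tp=tp, fp=fp, fn=fn)) \
            if tp + fn > 0 else (0, 0, 0)
        after = metrics(NeuriteMatchResult(tp=tp + 1, fp=fp, fn=fn - 1))
        assert all(b2 >= b1 for b1, b2 in zip(before, after))


def make_ground_truth(trees, crossings):
    return GroundTruth(trees=trees,
                       label_image=np.zeros((4, 4), dtype=np.int32),
                       soma_labels=np.zeros((4, 4), dtype=np.int32),
                       neuron_masks=[], noiseless={}, crossings=crossings)


class TestCrossingResolution:
    @pytest.fixture()
    def crossing_setup(self):
        t1 = straight_tree(1, (100, 40), [np.pi / 2])   # heading +x
        t2 = straight_tree(2, (60, 80), [np.pi])        # crosses it
        cross = Crossing(host_neuron=1, host_neurite=0, cross_neuron=2,
                         cross_neurite=0, point=np.array([100.0, 80.0]),
                         angle=np.pi / 2, host_arclength=30.0,
                         cross_arclength=30.0)
        truth = make_ground_truth([t1, t2], [cross])
        return truth

    def test_all_solved_when_prediction_matches(self, crossing_setup):
        truth = crossing_setup
        pred = copy.deepcopy(truth.trees)
        score = crossing_resolution_rate(pred, truth)
        assert score.total == 1 and score.solved == 1 and score.rate == 1.0

    def test_swapped_distal_segments_count_unsolved(self, crossing_setup):
        truth = crossing_setup
        pred = copy.deepcopy(truth.trees)
        # cut both neurites at the crossing and swap the distal parts
        for tree, arc in ((pred[0], 30.0), (pred[1], 30.0)):
            nr = tree.neurites[0]
            keep = nr.arclength < arc + 8.0
            tree.neurites[0] = Neurite(nodes=nr.nodes[keep],
                                       arclength=nr.arclength[keep],
                                       radii=nr.radii[keep])
        score = crossing_resolution_rate(pred, truth)
        assert score.total == 1 and score.solved == 0

    def test_rate_counts_fractions(self, crossing_setup):
        truth = crossing_setup
        truth.crossings = truth.crossings * 4  # 4 identical crossings
        pred = copy.deepcopy(truth.trees)
        assert crossing_resolution_rate(pred, truth).rate == 1.0

    def test_zero_crossings_flagged_undefined(self):
        t1 = straight_tree(1, (50, 50), [0.0])
        truth = make_ground_truth([t1], [])
        assert crossing_resolution_rate([copy.deepcopy(t1)], truth).rate \
            is None

    def test_invariant_to_neuron_relabeling(self, crossing_setup):
        truth = crossing_setup
        pred = copy.deepcopy(truth.trees)
        pred[0].neuron_id, pred[1].neuron_id = 7, 3
        score = crossing_resolution_rate(pred, truth)
        assert score.rate == 1.0
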