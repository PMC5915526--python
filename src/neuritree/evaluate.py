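"""Scoring of predicted neuron trees against ground truth.

A true neurite counts as a true positive when a predicted neurite of the
*same* neuron (somas paired by centroid proximity) covers enough of its
centerline within a distance tolerance; sensitivity, precision and the Dice
coefficient follow from the TP/FP/FN counts.  A recorded crossing is solved
when both involved neurites are correctly traced and assigned beyond the
crossing point.  The coverage thresholds are an automatable proxy for
expert visual assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .phantom import GroundTruth
from .tree import NeuronTree

DEFAULT_COVER_FRAC = 0.8
DEFAULT_DIST_TOL = 3.0
SOMA_MATCH_MAX_DIST = 20.0


@dataclass
class NeuriteMatch:
    """Per-neurite match record."""

    true_neuron: int
    true_neurite: int
    pred_neuron: int | None
    pred_neurite: int | None
    coverage: float
    assignment_correct: bool


@dataclass
class NeuriteMatchResult:
    """Neurite-level confusion counts plus per-neurite records."""

    tp: int
    fp: int
    fn: int
    matches: list[NeuriteMatch] = field(default_factory=list)
    soma_pairing: dict[int, int] = field(default_factory=dict)  # true -> pred


def _densify(nodes: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Resample a polyline at roughly uniform arclength spacing."""
    nodes = np.asarray(nodes, dtype=float)
    if len(nodes) < 2:
        return nodes
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return nodes[:1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    t = np.linspace(0, total, n)
    return np.column_stack([np.interp(t, arc, nodes[:, 0]),
                            np.interp(t, arc, nodes[:, 1])])


def _tree_polyline_points(tree: NeuronTree, step: float = 1.0) -> np.ndarray:
    """Densified points of all tree edges, including the root-to-neurite
    connections that are part of the rooted-tree topology."""
    pts = []
    for n in tree.neurites:
        if n.n_nodes == 0:
            continue
        nodes = n.nodes
        if n.parent is None:
            nodes = np.vstack([tree.root[None, :], nodes])
        pts.append(_densify(nodes, step))
    if not pts:
        return np.empty((0, 2))
    return np.vstack(pts)


def pair_somas(pred: list[NeuronTree], truth: list[NeuronTree],
               max_dist: float = SOMA_MATCH_MAX_DIST) -> dict[int, int]:
    """Hungarian pairing of true to predicted neurons on root distance.

    Returns {true_neuron_id: pred_neuron_id}; raises ``ValueError`` when no
    true soma can be paired at all under the tolerance.
    """
    if not pred or not truth:
        raise ValueError("both tree sets must be non-empty for soma pairing")
    cost = np.full((len(truth), len(pred)), 1e9)
    for i, t in enumerate(truth):
        for j, p in enumerate(pred):
            d = np.linalg.norm(t.root - p.root)
            if d <= max_dist:
                cost[i, j] = d
    rows, cols = linear_sum_assignment(cost)
    pairing = {truth[i].neuron_id: pred[j].neuron_id
               for i, j in zip(rows, cols) if cost[i, j] < 1e9}
    if not pairing:
        raise ValueError("soma pairing failed: no centroids within tolerance")
    return pairing


def _coverage(true_nodes: np.ndarray, pred_points: np.ndarray,
              dist_tol: float) -> float:
    """Fraction of true centerline samples within dist_tol of the prediction."""
    samples = _densify(true_nodes)
    if len(samples) == 0:
        return 0.0
    if len(pred_points) == 0:
        return 0.0
    d, _ = cKDTree(pred_points).query(samples)
    return float((d <= dist_tol).mean())


def match_neurites(pred: list[NeuronTree], truth: list[NeuronTree],
                   cover_frac: float = DEFAULT_COVER_FRAC,
                   dist_tol: float = DEFAULT_DIST_TOL) -> NeuriteMatchResult:
    """Neurite-level confusion counts between predicted and true trees.

    TP: a true neurite covered >= cover_frac (within dist_tol) by the
    predicted neurites of the paired neuron.  FN: a true neurite not so
    covered.  FP: a predicted neurite that mostly follows a *different*
    neuron's true neurite, or follows nothing.
    """
    pairing = pair_somas(pred, truth)
    pred_by_id = {t.neuron_id: t for t in pred}
    truth_by_id = {t.neuron_id: t for t in truth}

    # pooled predicted centerline points per predicted neuron
    pred_points = {t.neuron_id: _tree_polyline_points(t) for t in pred}
    # pooled true centerline points per true neuron (for FP attribution)
    true_points = {t.neuron_id: _tree_polyline_points(t) for t in truth}

    tp = fn = 0
    matches: list[NeuriteMatch] = []
    for t in truth:
        paired = pairing.get(t.neuron_id)
        pts = pred_points.get(paired, np.empty((0, 2))) if paired else \
            np.empty((0, 2))
        for j, neurite in enumerate(t.neurites):
            cov = _coverage(neurite.nodes, pts, dist_tol)
            hit = cov >= cover_frac
            tp += hit
            fn += not hit
            matches.append(NeuriteMatch(
                true_neuron=t.neuron_id, true_neurite=j,
                pred_neuron=paired if hit else None,
                pred_neurite=None, coverage=cov,
                assignment_correct=bool(hit)))

    # FP: predicted neurites that follow another neuron's true neurite, or
    # that follow no true structure at all; a truncated trace of the
    # correct neurite is penalized through the FN it leaves, not as FP
    rev_pairing = {v: k for k, v in pairing.items()}
    fp = 0
    for p in pred:
        own_true = rev_pairing.get(p.neuron_id)
        for j, neurite in enumerate(p.neurites):
            samples = _densify(neurite.nodes)
            if len(samples) == 0:
                continue
            frac_own = 0.0
            frac_other, other_id = 0.0, None
            for tid, tpts in true_points.items():
                if len(tpts) == 0:
                    continue
                d, _ = cKDTree(tpts).query(samples)
                frac = float((d <= dist_tol).mean())
                if tid == own_true:
                    frac_own = frac
                elif frac > frac_other:
                    frac_other, other_id = frac, tid
            follows_other = frac_other >= cover_frac and frac_other > frac_own
            follows_nothing = max(frac_own, frac_other) < 0.5
            if follows_other or follows_nothing:
                fp += 1
    return NeuriteMatchResult(tp=int(tp), fp=int(fp), fn=int(fn),
                              matches=matches, soma_pairing=pairing)


def metrics(result: NeuriteMatchResult) -> tuple[float, float, float]:
    """(sensitivity, precision, dice) from neurite-level counts.

    sensitivity = TP/(TP+FN); precision = TP/(TP+FP);
    dice = 2 TP/(2 TP + FN + FP).  All-zero counts are degenerate and
    return zeros.
    """
    tp, fp, fn = result.tp, result.fp, result.fn
    if tp + fn == 0:
        raise ValueError("no true neurites: sensitivity undefined")
    sensitivity = tp / (tp + fn)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    dice = 2 * tp / (2 * tp + fn + fp) if (2 * tp + fn + fp) > 0 else 0.0
    return sensitivity, precision, dice


@dataclass
class CrossingScore:
    solved: int
    total: int

    @property
    def rate(self) -> float | None:
        """Fraction solved, or None when no crossings are recorded."""
        if self.total == 0:
            return None
        return self.solved / self.total


def crossing_resolution_rate(pred: list[NeuronTree], truth: GroundTruth,
                             cover_frac: float = DEFAULT_COVER_FRAC,
                             dist_tol: float = DEFAULT_DIST_TOL) -> CrossingScore:
    """Fraction of recorded crossings where both neurites stay correctly
    assigned beyond the crossing point.

    For each crossing, the distal part (true centerline past the crossing
    arclength) of both involved neurites must be covered >= cover_frac by
    the correct neuron's predicted tree.
    """
    if not truth.crossings:
        return CrossingScore(solved=0, total=0)
    pairing = pair_somas(pred, truth.trees)
    pred_points = {t.neuron_id: _tree_polyline_points(t) for t in pred}
    solved = 0
    for cr in truth.crossings:
        ok = True
        for neuron_id, neurite_id, arc in (
                (cr.host_neuron, cr.host_neurite, cr.host_arclength),
                (cr.cross_neuron, cr.cross_neurite, cr.cross_arclength)):
            tree = truth.tree_by_id(neuron_id)
            neurite = tree.neurites[neurite_id]
            distal = neurite.nodes[neurite.arclength >= arc]
            paired = pairing.get(neuron_id)
            pts = pred_points.get(paired, np.empty((0, 2))) if paired else \
                np.empty((0, 2))
            if len(distal) < 2 or _coverage(distal, pts, dist_tol) < cover_frac:
                ok = False
                break
        solved += ok
    return CrossingScore(solved=solved, total=len(truth.crossings))
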