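"""Reference phantom suites and benchmark runs.

The *standard suite* mirrors the validation conditions the tracer is
designed for: 12 images of 512 x 512 px at 0.28 um/px holding 49 neurons in
total (2-6 per image, a few with a forced crossing at >= 45 degrees), high
SNR with Poisson noise.  The *crossing suite* isolates crossing resolution:
pairs of neurons with one forced crossing at a controlled angle.  The
*group-regime study* emulates the two pharmacological regimes seen in AIS
profiling: a bell-shaped Nav signal on the axon (control-like) versus a
flat axon signal (inhibitor-like), at matched dendritic intensity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .evaluate import crossing_resolution_rate, match_neurites, metrics
from .io import Image2D
from .phantom import (PhantomSpec, generate_phantom, render_bell_signal,
                      render_uniform_signal)
from .profiles import AISMetrics, ais_metrics, identify_axon, sample_profile, \
    select_dendrites
from .segmentation import BinaryMask, segment
from .soma import detect_somas
from .trace import TraceConfig, compute_seeds, extract_trees

logger = logging.getLogger(__name__)

# (base neurons, forced crossings) per image; totals 2-6, 49 neurons overall
STANDARD_SUITE_COMBOS = [
    (2, 0), (2, 0), (2, 1), (3, 0), (2, 1), (3, 1),
    (4, 0), (4, 1), (4, 1), (4, 1), (5, 1), (5, 1),
]


def standard_suite_specs(seed_base: int = 0) -> list[PhantomSpec]:
    """The 12 standard-suite phantom specs (deterministic given seed_base)."""
    return [
        PhantomSpec(shape=(512, 512), n_neurons=nb, n_forced_crossings=nc,
                    seed=seed_base + i)
        for i, (nb, nc) in enumerate(STANDARD_SUITE_COMBOS, start=1)
    ]


def crossing_suite_specs(angles_deg=(45.0, 60.0, 90.0), per_angle: int = 3,
                         seed_base: int = 0) -> list[PhantomSpec]:
    """Controlled crossing phantoms: one host and one crossing neuron each.

    Shallow angles make the back-ray soma placement geometrically awkward
    for some host layouts; infeasible seeds are skipped (the next seed is
    tried) so each angle contributes exactly ``per_angle`` phantoms.
    """
    from .phantom import PhantomError

    specs = []
    k = 0
    for ang in angles_deg:
        rad = math.radians(ang)
        made = 0
        while made < per_angle:
            spec = PhantomSpec(
                shape=(512, 512), n_neurons=1, n_forced_crossings=1,
                neurites_per_soma=(3, 4), crossing_angle=(rad, rad),
                seed=seed_base + 1000 + k)
            k += 1
            if k > 1000:
                raise RuntimeError("cannot realise crossing suite")
            try:
                generate_phantom(spec)
            except PhantomError:
                continue
            specs.append(spec)
            made += 1
    return specs


@dataclass
class TracingBenchmark:
    """Pooled neurite-level scores over a list of phantoms."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    crossings_solved: int = 0
    crossings_total: int = 0
    n_images: int = 0
    n_neurons: int = 0
    per_image: list[dict] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def dice(self) -> float:
        return 2 * self.tp / (2 * self.tp + self.fp + self.fn)

    @property
    def crossing_rate(self) -> float | None:
        if self.crossings_total == 0:
            return None
        return self.crossings_solved / self.crossings_total


def run_tracing_benchmark(specs: list[PhantomSpec],
                          cfg: TraceConfig | None = None) -> TracingBenchmark:
    """Run segmentation -> soma detection -> tracing on each phantom and
    score against ground truth."""
    from .phantom import PhantomError

    bench = TracingBenchmark()
    for spec in specs:
        # an unlucky seed can make soma placement infeasible; retry the
        # image with a shifted seed (deterministic given the spec)
        for shift in range(6):
            try:
                spec.seed = spec.seed + (9973 if shift else 0)
                stacks, truth = generate_phantom(spec)
                break
            except PhantomError:
                continue
        else:
            raise PhantomError(f"phantom infeasible around seed {spec.seed}")
        img = Image2D(stacks["structural"].voxels[0],
                      pixel_size=spec.pixel_size)
        mask = segment(img)
        somas = detect_somas(mask)
        seeds = compute_seeds(mask, cfg)
        trees, _report = extract_trees(somas, mask, seeds, cfg)
        res = match_neurites(trees, truth.trees)
        sens, prec, dice = metrics(res)
        cs = crossing_resolution_rate(trees, truth)
        bench.tp += res.tp
        bench.fp += res.fp
        bench.fn += res.fn
        bench.crossings_solved += cs.solved
        bench.crossings_total += cs.total
        bench.n_images += 1
        bench.n_neurons += len(truth.trees)
        bench.per_image.append({
            "seed": spec.seed, "n_neurons": len(truth.trees),
            "tp": res.tp, "fp": res.fp, "fn": res.fn,
            "sensitivity": sens, "precision": prec, "dice": dice,
            "crossings_solved": cs.solved, "crossings_total": cs.total,
        })
    return bench


# ---------------------------------------------------------------------------
# AIS group-regime study
# ---------------------------------------------------------------------------

BELL_H = 250.0
BELL_MU = 35.0
BELL_SIGMA = 10.0
DENDRITE_LEVEL = 30.0
TARGET_BACKGROUND = 15.0


def _single_neuron_spec(seed: int) -> PhantomSpec:
    return PhantomSpec(shape=(400, 400), n_neurons=1,
                       neurites_per_soma=(4, 5),
                       neurite_length=(110.0, 170.0),
                       poisson_noise=False, seed=seed)


def _regime_image(truth, axon_id: int, bell: bool, rng: np.random.Generator
                  ) -> Image2D:
    """Target-channel image: Nav-like signal plus background and noise."""
    tree = truth.trees[0]
    canvas = np.zeros(truth.label_image.shape)
    for j in range(tree.n_neurites):
        if j == axon_id and bell:
            layer = render_bell_signal(truth, tree.neuron_id, j,
                                       H=BELL_H, mu=BELL_MU, sigma=BELL_SIGMA)
        else:
            layer = render_uniform_signal(truth, tree.neuron_id, j,
                                          DENDRITE_LEVEL)
        canvas = np.maximum(canvas, layer.pixels)
    canvas = canvas + TARGET_BACKGROUND
    noisy = rng.poisson(canvas).astype(float)
    return Image2D(noisy, pixel_size=truth.pixel_size)


def run_group_regime_study(n_per_group: int = 12, seed_base: int = 0,
                           use_tracing: bool = True
                           ) -> tuple[list[AISMetrics], list[AISMetrics]]:
    """AIS metrics for bell-on-axon vs flat-axon neurons.

    Each neuron is a single-neuron phantom; the structural channel is
    traced by the full pipeline (or the ground-truth tree is used when
    ``use_tracing`` is False) and the target channel is profiled along the
    resulting neurites.  Returns (bell_metrics, flat_metrics).
    """
    groups: list[list[AISMetrics]] = [[], []]
    for gi, bell in enumerate((True, False)):
        count = 0
        attempt = 0
        while count < n_per_group:
            seed = seed_base + 5000 + gi * 1000 + attempt
            attempt += 1
            if attempt > 4 * n_per_group:
                raise RuntimeError("too many failed attempts in regime study")
            spec = _single_neuron_spec(seed)
            try:
                stacks, truth = generate_phantom(spec)
            except Exception:
                continue
            true_tree = truth.trees[0]
            long_enough = [j for j, nr in enumerate(true_tree.neurites)
                           if nr.length >= 80]
            if len(long_enough) < 3:
                continue
            axon_true = long_enough[0]
            rng = np.random.default_rng([seed, 17])
            target = _regime_image(truth, axon_true, bell, rng)
            mask = BinaryMask(truth.label_image > 0)
            if use_tracing:
                structural = Image2D(stacks["structural"].voxels[0],
                                     pixel_size=spec.pixel_size)
                seg_mask = segment(structural)
                somas = detect_somas(seg_mask)
                if len(somas) != 1:
                    continue
                trees, _ = extract_trees(somas, seg_mask,
                                         compute_seeds(seg_mask))
                tree = trees[0]
                mask = seg_mask
            else:
                tree = true_tree
            profiles = [sample_profile(target, mask, nr,
                                       neuron_id=tree.neuron_id, neurite_id=j)
                        for j, nr in enumerate(tree.neurites)]
            try:
                axon_id = identify_axon(tree, profiles)
                dendrites = select_dendrites(tree, profiles, axon_id)
                axon_profile = next(p for p in profiles
                                    if p.neurite_id == axon_id)
                m = ais_metrics(axon_profile, dendrites,
                                neuron_id=tree.neuron_id)
            except ValueError as exc:
                logger.info("regime neuron skipped (seed %d): %s", seed, exc)
                continue
            groups[gi].append(m)
            count += 1
    return groups[0], groups[1]
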