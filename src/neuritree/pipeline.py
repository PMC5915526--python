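"""End-to-end orchestration: projection, denoising, segmentation, soma
detection, tree extraction, profiling and reporting.

Stages whose outputs are supplied (a mask, soma labels) are skipped.  A run
emits per-neuron SWC files, the mask and soma label images, a profiles CSV
when a target channel is given, an overlay PNG, and a machine-readable JSON
report with per-stage counts and timings.  Runs are deterministic given the
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .io import (DEFAULT_PIXEL_SIZE_UM, Image2D, read_mask, read_tiff,
                 project_aip, project_mip, write_mask, write_profile_csv,
                 write_swc)
from .preprocess import DenoiseConfig, denoise
from .profiles import sample_profile
from .segmentation import BinaryMask, ClassifierModel, segment
from .soma import (SomaRegion, detect_somas, regions_from_label_image,
                   soma_label_image)
from .trace import TraceConfig, compute_seeds, extract_trees, tile_large_image
from .tree import NeuronTree


@dataclass
class PipelineConfig:
    """Serializable configuration of a full run."""

    image: str = ""                   # structural-channel TIFF
    target: str | None = None         # optional target-channel TIFF
    mask: str | None = None           # supplied segmentation mask (skip stage)
    somas: str | None = None          # supplied soma labels (skip stage)
    out: str = "out"
    projection: str = "mip"           # mip | aip
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    denoise_enabled: bool = True
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    segmentation_model: str | None = None
    segmentation_min_size: int = 20
    segmentation_max_hole: int = 10
    soma_filter_length: int = 15
    soma_n_orient: int = 16
    soma_dr_threshold: float = 0.6
    soma_min_area: int = 100
    trace: TraceConfig = field(default_factory=TraceConfig)
    profile_step: float = 1.0
    tile_max: int = 1024
    tile_overlap: int = 64
    tile_cluster_cutoff: float = 150.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("denoise"), dict):
            d["denoise"] = DenoiseConfig(**d["denoise"])
        if isinstance(d.get("trace"), dict):
            tr = dict(d["trace"])
            if isinstance(tr.get("dilation_rates"), list):
                tr["dilation_rates"] = tuple(tr["dilation_rates"])
            d["trace"] = TraceConfig(**tr)
        return PipelineConfig(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @staticmethod
    def load(path: str | Path) -> "PipelineConfig":
        return PipelineConfig.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    """In-memory artifacts of one run."""

    mask: BinaryMask
    somas: list[SomaRegion]
    trees: list[NeuronTree]
    report: dict


def _load_image(path: str, projection: str, pixel_size: float) -> Image2D:
    stacks = read_tiff(path, pixel_size_xy=pixel_size)
    project = project_mip if projection == "mip" else project_aip
    return project(stacks[0])


def _overlay_png(img: Image2D, trees: list[NeuronTree], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    ax.imshow(img.pixels, cmap="gray")
    cmap = plt.colormaps["tab10"]
    for t in trees:
        color = cmap(t.neuron_id % 10)
        for nr in t.neurites:
            ax.plot(nr.nodes[:, 1], nr.nodes[:, 0], color=color, lw=1.2)
        ax.plot(t.root[1], t.root[0], "o", color=color, ms=6)
        ax.annotate(str(t.neuron_id), (t.root[1], t.root[0]), color="white",
                    fontsize=8)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def run_pipeline(config: PipelineConfig,
                 image: Image2D | None = None,
                 target: Image2D | None = None,
                 mask: BinaryMask | None = None,
                 somas: list[SomaRegion] | None = None,
                 write_outputs: bool = True) -> PipelineResult:
    """Run the staged pipeline; in-memory inputs override file paths.

    Stage skipping: a supplied mask bypasses denoising and segmentation; a
    supplied soma labelling bypasses soma detection.  The JSON report
    records versions, the config hash, per-stage timings, counts and which
    stages were skipped.
    """
    out = Path(config.out)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "stages": {},
        "skipped": [],
    }

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, *exc):
                report["stages"][name] = {
                    "seconds": round(time.perf_counter() - self_.t0, 3)}
                return False
        return _Timer()

    if image is None and config.image:
        image = _load_image(config.image, config.projection, config.pixel_size)
    if target is None and config.target:
        target = _load_image(config.target, config.projection,
                             config.pixel_size)

    if mask is None and config.mask:
        mask = BinaryMask(read_mask(config.mask).astype(bool),
                          provenance="supplied")
    if mask is None:
        if image is None:
            raise ValueError("no image and no mask supplied")
        work = image
        if config.denoise_enabled:
            with stage("denoise"):
                work = denoise(work, config.denoise)
        else:
            report["skipped"].append("denoise")
        with stage("segment"):
            model = ClassifierModel.load(config.segmentation_model) \
                if config.segmentation_model else None
            mask = segment(work, model,
                           min_size=config.segmentation_min_size,
                           max_hole=config.segmentation_max_hole)
    else:
        report["skipped"] += ["denoise", "segment"]

    if somas is None and config.somas:
        somas = regions_from_label_image(read_mask(config.somas))
        report["skipped"].append("somas")
    if somas is None:
        with stage("somas"):
            somas = detect_somas(
                mask, dr_threshold=config.soma_dr_threshold,
                min_area=config.soma_min_area,
                filter_length=config.soma_filter_length,
                n_orient=config.soma_n_orient)
    report["n_somas"] = len(somas)

    with stage("seeds"):
        seeds = compute_seeds(mask, config.trace)
    report["n_seeds"] = len(seeds)

    with stage("trace"):
        trees, trace_report = extract_trees(somas, mask, seeds, config.trace)
    report["n_trees"] = len(trees)
    report["neurites_per_neuron"] = trace_report.neurites_per_neuron
    report["n_conflicts"] = len(trace_report.conflicts)
    report["conflicts"] = trace_report.conflicts[:100]

    profiles = []
    if target is not None:
        with stage("profile"):
            for t in trees:
                for j, nr in enumerate(t.neurites):
                    if nr.n_nodes < 2:
                        continue
                    profiles.append(sample_profile(
                        target, mask, nr, neuron_id=t.neuron_id,
                        neurite_id=j, step=config.profile_step))
    else:
        report["skipped"].append("profile")

    if write_outputs:
        write_mask(mask.f, out / "mask.png")
        write_mask(soma_label_image(somas, mask.shape), out / "somas.npy")
        for t in trees:
            write_swc(t, out / f"neuron_{t.neuron_id:03d}.swc",
                      pixel_size=config.pixel_size)
        if profiles:
            write_profile_csv(profiles, out / "profiles.csv")
        if image is not None:
            _overlay_png(image, trees, out / "overlay.png")
        (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return PipelineResult(mask=mask, somas=somas, trees=trees, report=report)


def run_tiled(config: PipelineConfig,
              image: Image2D | None = None,
              mask: BinaryMask | None = None,
              somas: list[SomaRegion] | None = None,
              write_outputs: bool = True) -> PipelineResult:
    """Tiled processing of a large image: somas are grouped by proximity,
    each rectangle is traced independently, and results are merged with
    globally unique neuron ids.  Trees whose nodes touch a tile border are
    flagged in the report; a soma that cannot be tiled is skipped and
    listed.
    """
    out = Path(config.out)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    if image is None and config.image:
        image = _load_image(config.image, config.projection, config.pixel_size)
    if mask is None and config.mask:
        mask = BinaryMask(read_mask(config.mask).astype(bool),
                          provenance="supplied")
    if mask is None:
        work = denoise(image, config.denoise) if config.denoise_enabled \
            else image
        model = ClassifierModel.load(config.segmentation_model) \
            if config.segmentation_model else None
        mask = segment(work, model, min_size=config.segmentation_min_size,
                       max_hole=config.segmentation_max_hole)
    if somas is None and config.somas:
        somas = regions_from_label_image(read_mask(config.somas))
    if somas is None:
        somas = detect_somas(mask, dr_threshold=config.soma_dr_threshold,
                             min_area=config.soma_min_area,
                             filter_length=config.soma_filter_length,
                             n_orient=config.soma_n_orient)

    report: dict = {"version": __version__,
                    "config_hash": config.config_hash(),
                    "tiles": [], "skipped_somas": [], "border_trees": []}
    tiles = tile_large_image(mask, somas, max_tile=config.tile_max,
                             overlap=config.tile_overlap,
                             cluster_cutoff=config.tile_cluster_cutoff)
    all_trees: list[NeuronTree] = []
    next_id = 1
    for rect, tile_somas in tiles:
        r0, r1, c0, c1 = rect
        ok_somas = []
        for s in tile_somas:
            rr, cc = np.nonzero(s.mask)
            if rr.min() < r0 or rr.max() >= r1 or cc.min() < c0 or \
                    cc.max() >= c1:
                report["skipped_somas"].append(int(s.label))
                continue
            ok_somas.append(s)
        if not ok_somas:
            continue
        sub_mask = BinaryMask(mask.f[r0:r1, c0:c1])
        shifted = []
        for s in ok_somas:
            sub = s.mask[r0:r1, c0:c1]
            shifted.append(SomaRegion.from_mask(s.label, sub))
        trees, _rep = extract_trees(shifted, sub_mask, cfg=config.trace)
        offset = np.array([r0, c0], dtype=float)
        for t in trees:
            t.root = t.root + offset
            for nr in t.neurites:
                nr.nodes = nr.nodes + offset
            t.neuron_id = next_id
            next_id += 1
            border = any(
                np.any(nr.nodes[:, 0] <= r0 + 1) or
                np.any(nr.nodes[:, 0] >= r1 - 2) or
                np.any(nr.nodes[:, 1] <= c0 + 1) or
                np.any(nr.nodes[:, 1] >= c1 - 2)
                for nr in t.neurites)
            if border and (r0 > 0 or c0 > 0 or r1 < mask.shape[0]
                           or c1 < mask.shape[1]):
                report["border_trees"].append(t.neuron_id)
            all_trees.append(t)
        report["tiles"].append({"rect": [int(v) for v in rect],
                                "n_somas": len(ok_somas)})
    report["n_trees"] = len(all_trees)
    if write_outputs:
        for t in all_trees:
            write_swc(t, out / f"neuron_{t.neuron_id:03d}.swc",
                      pixel_size=config.pixel_size)
        if image is not None:
            _overlay_png(image, all_trees, out / "overlay.png")
        (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return PipelineResult(mask=mask, somas=somas, trees=all_trees,
                          report=report)
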