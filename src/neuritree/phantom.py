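"""Synthetic multi-neuron image generator with exact ground truth.

Emulates 2D maximum-intensity projections of confocal images of sparse
neuronal cultures (512 x 512, 0.28 um/px): somas are filled ellipses,
neurites are smooth curves of finite width emanating radially from the soma
boundary, background is a constant plus a linear gradient, and photon noise
is Poisson.  Every image comes with its ground truth: per-neuron centerline
trees, a label image, soma masks and the noiseless intensity field, so each
pipeline stage can be scored without external data.

Forced crossings add dedicated *crossing neurons*: for each one, a point on
an existing neuron's neurite is chosen and the new neuron's soma is placed
on the back-ray so that its first neurite runs straight through that point
at a sampled crossing angle.  Crossing neurons are generated after, and
independently of, the base neurons, so adding crossings never alters the
base neurons' trees — only the overlap in the rendered image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import DEFAULT_PIXEL_SIZE_UM, Image2D, ImageStack
from .tree import Neurite, NeuronTree

STRUCTURAL_CHANNEL = "structural"


class PhantomError(RuntimeError):
    """Raised when a phantom spec cannot be realised (e.g. soma placement)."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic culture image.

    Ranges are inclusive ``(low, high)`` and sampled uniformly per neuron or
    per neurite.  ``curvature`` bounds the tangent-angle change per pixel of
    arclength (radians), so neurites are smooth at the scale real dendrites
    are.  ``n_forced_crossings`` adds that many crossing neurons on top of
    ``n_neurons`` base neurons.
    """

    shape: tuple[int, int] = (512, 512)
    n_neurons: int = 4
    soma_radius: tuple[float, float] = (8.0, 15.0)
    neurites_per_soma: tuple[int, int] = (3, 5)
    neurite_length: tuple[float, float] = (80.0, 200.0)
    neurite_half_width: tuple[float, float] = (1.0, 3.0)
    curvature: float = 0.03
    n_forced_crossings: int = 0
    crossing_angle: tuple[float, float] = (math.pi / 4, math.pi / 2)
    channels: dict[str, float] = field(
        default_factory=lambda: {STRUCTURAL_CHANNEL: 150.0})
    background_const: float = 20.0
    background_gradient: float = 10.0
    poisson_noise: bool = True
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def validate(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        for name, rng in [("soma_radius", self.soma_radius),
                          ("neurite_length", self.neurite_length),
                          ("neurite_half_width", self.neurite_half_width)]:
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise ValueError(f"{name} range must be positive and ordered")
        if self.neurites_per_soma[0] < 0 or \
                self.neurites_per_soma[1] < self.neurites_per_soma[0]:
            raise ValueError("neurites_per_soma range must be ordered, >= 0")
        if self.curvature < 0:
            raise ValueError("curvature bound must be >= 0")
        lo, hi = self.crossing_angle
        if not (0 < lo <= hi <= math.pi / 2):
            raise ValueError("crossing angles must lie in (0, pi/2]")
        if self.n_forced_crossings < 0:
            raise ValueError("n_forced_crossings must be >= 0")
        if not self.channels:
            raise ValueError("at least one channel is required")


@dataclass
class Crossing:
    """Record of one forced neurite crossing (ground truth for evaluation)."""

    host_neuron: int       # neuron_id of the neuron crossed through
    host_neurite: int
    cross_neuron: int      # neuron_id of the dedicated crossing neuron
    cross_neurite: int
    point: np.ndarray      # (row, col) of the intersection
    angle: float           # radians, in (0, pi/2]
    host_arclength: float  # arclength of `point` along the host neurite
    cross_arclength: float


@dataclass
class GroundTruth:
    """Exact truth for one phantom image."""

    trees: list[NeuronTree]
    label_image: np.ndarray          # int, pixel -> neuron_id (0 = background)
    soma_labels: np.ndarray          # int, pixel -> neuron_id for soma pixels
    neuron_masks: list[np.ndarray]   # per-neuron rendered boolean masks
    noiseless: dict[str, np.ndarray]  # per-channel noiseless intensity
    crossings: list[Crossing] = field(default_factory=list)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def tree_by_id(self, neuron_id: int) -> NeuronTree:
        for t in self.trees:
            if t.neuron_id == neuron_id:
                return t
        raise KeyError(f"no neuron with id {neuron_id}")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipse_mask(shape, center, a, b, angle) -> np.ndarray:
    """Filled rotated ellipse as a boolean mask (no anti-aliasing)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - center[0]
    dx = xx - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _soma_boundary_point(mask: np.ndarray, centroid, theta) -> np.ndarray:
    """March from the centroid along direction theta to the last inside pixel."""
    h, w = mask.shape
    step = np.array([math.sin(theta), math.cos(theta)])  # (drow, dcol)
    pos = np.asarray(centroid, dtype=float)
    last_inside = pos.copy()
    for _ in range(4 * max(h, w)):
        pos = pos + 0.5 * step
        r, c = int(round(pos[0])), int(round(pos[1]))
        if not (0 <= r < h and 0 <= c < w) or not mask[r, c]:
            return last_inside
        last_inside = pos.copy()
    return last_inside


def _grow_centerline(start, theta0, length, curvature, shape, rng,
                     straight_px: float = 0.0) -> np.ndarray:
    """Random smooth curve: unit steps with bounded tangent-angle increments.

    The first ``straight_px`` pixels keep the initial heading exactly (used
    to route crossing neurites straight through the intersection).  Stops at
    the image margin.
    """
    h, w = shape
    margin = 3.0
    pts = [np.asarray(start, dtype=float)]
    theta = float(theta0)
    travelled = 0.0
    while travelled < length:
        if travelled >= straight_px and curvature > 0:
            theta += rng.uniform(-curvature, curvature)
        nxt = pts[-1] + np.array([math.sin(theta), math.cos(theta)])
        if not (margin <= nxt[0] < h - margin and margin <= nxt[1] < w - margin):
            break
        pts.append(nxt)
        travelled += 1.0
    return np.asarray(pts)


def _paint_curve(canvas: np.ndarray, pts: np.ndarray, half_width: float,
                 value=True) -> None:
    """Dilate a polyline to half_width with a disk; no anti-aliasing.

    ``canvas`` may be boolean (mask painting) or float (intensity painting,
    in which case ``value`` may be an array of per-point values combined by
    max with the existing canvas).
    """
    if len(pts) == 0:
        return
    h, w = canvas.shape
    r = max(half_width, 0.5)
    ir = int(math.ceil(r))
    dy, dx = np.mgrid[-ir:ir + 1, -ir:ir + 1]
    disk = dy ** 2 + dx ** 2 <= r ** 2
    offs_y = dy[disk]
    offs_x = dx[disk]
    vals = np.broadcast_to(np.asarray(value), (len(pts),))
    # subsample the polyline at <= 0.25 px steps so the tube has no gaps
    seg = np.diff(pts, axis=0)
    seglen = np.linalg.norm(seg, axis=1) if len(pts) > 1 else np.array([])
    dense_pts = [pts[0]]
    dense_vals = [vals[0]]
    for i, L in enumerate(seglen):
        n = max(int(math.ceil(L / 0.25)), 1)
        for k in range(1, n + 1):
            t = k / n
            dense_pts.append(pts[i] * (1 - t) + pts[i + 1] * t)
            dense_vals.append(vals[i] * (1 - t) + vals[i + 1] * t)
    for p, v in zip(dense_pts, dense_vals):
        ys = np.round(p[0] + offs_y).astype(int)
        xs = np.round(p[1] + offs_x).astype(int)
        ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        if canvas.dtype == bool:
            canvas[ys[ok], xs[ok]] = True
        else:
            np.maximum.at(canvas, (ys[ok], xs[ok]), float(v))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@dataclass
class _NeuronDraft:
    neuron_id: int
    centroid: np.ndarray
    axes: tuple[float, float]
    angle: float
    soma_mask: np.ndarray
    neurites: list[np.ndarray] = field(default_factory=list)  # centerlines
    half_widths: list[float] = field(default_factory=list)


def _sample_soma(rng, spec: PhantomSpec, existing: list[_NeuronDraft],
                 center=None) -> tuple[np.ndarray, tuple[float, float], float]:
    h, w = spec.shape
    r = rng.uniform(*spec.soma_radius)
    aspect = rng.uniform(1.0, 1.5)
    a, b = r, r / aspect
    angle = rng.uniform(0, math.pi)
    if center is None:
        margin = r + 8
        center = np.array([rng.uniform(margin, h - margin),
                           rng.uniform(margin, w - margin)])
    return np.asarray(center, dtype=float), (a, b), angle


def _placement_ok(center, radius, existing: list[_NeuronDraft],
                  shape, min_gap: float = 60.0) -> bool:
    h, w = shape
    if not (radius + 4 <= center[0] < h - radius - 4
            and radius + 4 <= center[1] < w - radius - 4):
        return False
    for other in existing:
        d = np.linalg.norm(center - other.centroid)
        if d < radius + max(other.axes) + min_gap:
            return False
    return True


def _spread_directions(rng, n: int) -> list[float]:
    """n initial headings, roughly evenly spread with jitter."""
    if n == 0:
        return []
    base = rng.uniform(0, 2 * math.pi)
    gap = 2 * math.pi / n
    return [(base + i * gap + rng.uniform(-0.25, 0.25) * gap) % (2 * math.pi)
            for i in range(n)]


def _build_base_neuron(spec: PhantomSpec, idx: int,
                       existing: list[_NeuronDraft]) -> _NeuronDraft:
    rng = np.random.default_rng([spec.seed, idx])
    for _ in range(200):
        center, axes, angle = _sample_soma(rng, spec, existing)
        if _placement_ok(center, max(axes), existing, spec.shape):
            break
    else:
        raise PhantomError(
            f"could not place soma {idx + 1} after 200 attempts; "
            "reduce n_neurons or soma_radius")
    soma = _ellipse_mask(spec.shape, center, axes[0], axes[1], angle)
    draft = _NeuronDraft(idx + 1, center, axes, angle, soma)
    n_neur = int(rng.integers(spec.neurites_per_soma[0],
                              spec.neurites_per_soma[1] + 1))
    for theta in _spread_directions(rng, n_neur):
        start = _soma_boundary_point(soma, center, theta)
        length = rng.uniform(*spec.neurite_length)
        pts = _grow_centerline(start, theta, length, spec.curvature,
                               spec.shape, rng)
        if len(pts) < 10:  # ran into the border immediately; drop
            continue
        draft.neurites.append(pts)
        draft.half_widths.append(rng.uniform(*spec.neurite_half_width))
    return draft


def _build_crossing_neuron(spec: PhantomSpec, idx: int, k: int,
                           drafts: list[_NeuronDraft]) -> tuple[_NeuronDraft, Crossing]:
    """Dedicated neuron whose first neurite crosses an existing neurite."""
    rng = np.random.default_rng([spec.seed, idx, 7])
    hosts = [(d, j) for d in drafts for j in range(len(d.neurites))
             if len(d.neurites[j]) >= 60]
    if not hosts:
        raise PhantomError("no neurite long enough to host a forced crossing")
    h, w = spec.shape
    for _ in range(300):
        host, j = hosts[int(rng.integers(len(hosts)))]
        pts = host.neurites[j]
        i = int(rng.uniform(0.35, 0.7) * len(pts))
        p = pts[i]
        tang = pts[min(i + 3, len(pts) - 1)] - pts[max(i - 3, 0)]
        t_theta = math.atan2(tang[0], tang[1])
        phi = rng.uniform(*spec.crossing_angle) * (1 if rng.random() < 0.5 else -1)
        d_theta = t_theta + phi
        len_before = rng.uniform(60, 110)
        center = p - len_before * np.array([math.sin(d_theta), math.cos(d_theta)])
        cand_center, axes, angle = _sample_soma(rng, spec, drafts, center=center)
        if not _placement_ok(cand_center, max(axes), drafts, spec.shape):
            continue
        soma = _ellipse_mask(spec.shape, cand_center, axes[0], axes[1], angle)
        start = _soma_boundary_point(soma, cand_center, d_theta)
        total_len = max(rng.uniform(*spec.neurite_length), len_before + 60)
        host_w = host.half_widths[j]
        straight = len_before + 2 * host_w + 12  # clear the crossing region
        cpts = _grow_centerline(start, d_theta, total_len, spec.curvature,
                                spec.shape, rng, straight_px=straight)
        if len(cpts) < straight + 20:
            continue
        draft = _NeuronDraft(idx + 1, cand_center, axes, angle, soma)
        draft.neurites.append(cpts)
        draft.half_widths.append(rng.uniform(*spec.neurite_half_width))
        # extra ordinary neurites, headed away from the crossing direction
        n_extra = int(rng.integers(max(spec.neurites_per_soma[0] - 1, 0),
                                   spec.neurites_per_soma[1]))
        for theta in _spread_directions(rng, n_extra):
            if abs((theta - d_theta + math.pi) % (2 * math.pi) - math.pi) < 0.6:
                continue
            s2 = _soma_boundary_point(soma, cand_center, theta)
            length = rng.uniform(*spec.neurite_length)
            pts2 = _grow_centerline(s2, theta, length, spec.curvature,
                                    spec.shape, rng)
            if len(pts2) >= 10:
                draft.neurites.append(pts2)
                draft.half_widths.append(rng.uniform(*spec.neurite_half_width))
        # true intersection arclength along the crossing neurite
        dist_to_p = np.linalg.norm(cpts - p, axis=1)
        ci = int(np.argmin(dist_to_p))
        crossing = Crossing(
            host_neuron=host.neuron_id, host_neurite=j,
            cross_neuron=draft.neuron_id, cross_neurite=0,
            point=p.copy(), angle=abs(phi),
            host_arclength=float(i), cross_arclength=float(ci),
        )
        return draft, crossing
    raise PhantomError(
        f"could not place crossing neuron {k + 1} after 300 attempts")


def _draft_to_tree(draft: _NeuronDraft) -> NeuronTree:
    tree = NeuronTree(neuron_id=draft.neuron_id, root=draft.centroid,
                      soma_radius=float(np.mean(draft.axes)))
    for pts, hw in zip(draft.neurites, draft.half_widths):
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(steps)])
        tree.neurites.append(Neurite(
            nodes=pts, arclength=arc,
            radii=np.full(len(pts), hw), parent=None))
    tree.validate()
    return tree


def generate_phantom(spec: PhantomSpec) -> tuple[dict[str, ImageStack], GroundTruth]:
    """Generate one synthetic culture image per channel plus its ground truth.

    Deterministic: the same spec (including seed) yields bit-identical
    output.  Raises :class:`PhantomError` if somas cannot be placed within a
    bounded number of attempts.
    """
    spec.validate()
    drafts: list[_NeuronDraft] = []
    for i in range(spec.n_neurons):
        drafts.append(_build_base_neuron(spec, i, drafts))
    crossings: list[Crossing] = []
    for k in range(spec.n_forced_crossings):
        draft, crossing = _build_crossing_neuron(spec, spec.n_neurons + k, k,
                                                 drafts)
        drafts.append(draft)
        crossings.append(crossing)

    h, w = spec.shape
    label = np.zeros((h, w), dtype=np.int32)
    soma_labels = np.zeros((h, w), dtype=np.int32)
    neuron_masks = []
    for d in drafts:
        m = d.soma_mask.copy()
        for pts, hw in zip(d.neurites, d.half_widths):
            _paint_curve(m, pts, hw)
        neuron_masks.append(m)
        unclaimed = (label == 0) & m
        label[unclaimed] = d.neuron_id
        soma_unclaimed = (soma_labels == 0) & d.soma_mask
        soma_labels[soma_unclaimed] = d.neuron_id

    yy, xx = np.mgrid[0:h, 0:w]
    background = spec.background_const + spec.background_gradient * (
        (yy / max(h - 1, 1)) + (xx / max(w - 1, 1))) / 2.0

    noiseless: dict[str, np.ndarray] = {}
    stacks: dict[str, ImageStack] = {}
    noise_rng = np.random.default_rng([spec.seed, 999983])
    for ch, intensity in spec.channels.items():
        fg = np.zeros((h, w), dtype=float)
        for d, m in zip(drafts, neuron_masks):
            fg[m] = np.maximum(fg[m], float(intensity))
        clean = fg + background
        noiseless[ch] = clean
        img = noise_rng.poisson(clean).astype(float) if spec.poisson_noise \
            else clean.copy()
        stacks[ch] = ImageStack(img[None], channel=ch,
                                pixel_size_xy=spec.pixel_size)

    truth = GroundTruth(
        trees=[_draft_to_tree(d) for d in drafts],
        label_image=label,
        soma_labels=soma_labels,
        neuron_masks=neuron_masks,
        noiseless=noiseless,
        crossings=crossings,
        pixel_size=spec.pixel_size,
    )
    return stacks, truth


# ---------------------------------------------------------------------------
# signal painting for profiling tests
# ---------------------------------------------------------------------------

def paint_neurite_signal(truth: GroundTruth, neuron_id: int, neurite_id: int,
                         values_fn, shape=None) -> Image2D:
    """Paint an arclength-dependent signal along one true neurite.

    ``values_fn(arclength_array) -> intensity_array`` gives the centerline
    value at each true node; the tube is filled at the neurite's half-width
    and overlaps combine by max.  Returns a fresh single-channel image
    (zero elsewhere); callers add background/noise as needed.
    """
    from scipy.spatial import cKDTree

    tree = truth.tree_by_id(neuron_id)
    if not (0 <= neurite_id < tree.n_neurites):
        raise KeyError(f"neuron {neuron_id} has no neurite {neurite_id}")
    neurite = tree.neurites[neurite_id]
    shape = shape if shape is not None else truth.label_image.shape
    canvas = np.zeros(shape, dtype=float)
    # rasterize the tube, then assign each pixel the value of its nearest
    # centerline sample so the along-arclength profile on the centerline is
    # exactly values_fn(arclength) (max-combining would dilate the profile)
    tube = np.zeros(shape, dtype=bool)
    half_width = float(neurite.radii[0])
    _paint_curve(tube, neurite.nodes, half_width)
    # dense centerline samples with interpolated arclength
    seg = np.linalg.norm(np.diff(neurite.nodes, axis=0), axis=1)
    arc = neurite.arclength
    if len(neurite.nodes) > 1:
        total = arc[-1] - arc[0]
        n = max(int(math.ceil(total / 0.25)) + 1, 2)
        t = np.linspace(arc[0], arc[-1], n)
        dense = np.column_stack([
            np.interp(t, arc, neurite.nodes[:, 0]),
            np.interp(t, arc, neurite.nodes[:, 1])])
    else:
        t = arc
        dense = neurite.nodes
    vals = np.asarray(values_fn(t), dtype=float)
    rr, cc = np.nonzero(tube)
    _, idx = cKDTree(dense).query(np.column_stack([rr, cc]))
    canvas[rr, cc] = vals[idx]
    return Image2D(canvas, pixel_size=truth.pixel_size)


def render_bell_signal(truth: GroundTruth, neuron_id: int, neurite_id: int,
                       H: float, mu: float, sigma: float) -> Image2D:
    """Gaussian bell g(s) = H exp(-(s-mu)^2 / (2 sigma^2)) along a neurite.

    The inverse of the AIS amplitude fit: paints a bell-shaped fluorescence
    profile (as the Nav channel shows at the axonal initial segment) along
    one true neurite's arclength, for end-to-end profiling tests.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return paint_neurite_signal(
        truth, neuron_id, neurite_id,
        lambda s: H * np.exp(-((s - mu) ** 2) / (2.0 * sigma ** 2)))


def render_uniform_signal(truth: GroundTruth, neuron_id: int, neurite_id: int,
                          value: float) -> Image2D:
    """Constant signal along one true neurite (flat-profile regime)."""
    return paint_neurite_signal(truth, neuron_id, neurite_id,
                                lambda s: np.full_like(s, float(value)))
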