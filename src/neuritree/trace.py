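"""Tree extraction: the core tracing and sorting routine.

One directed rooted tree is extracted per soma in three steps:

(i)  *Initialization* — the soma mask is scaled about its centroid by
     factors 1.1/1.2/1.3; the symmetric differences of successive masks,
     intersected with the segmented foreground, cut each emanating neurite
     into two short stubs whose centroids give the neurite's start point
     and initial orientation.

(ii) *Seeding* — the Euclidean distance transform Df of the foreground is
     sharpened with a 3x3 center-surround kernel, normalized, and
     thresholded; surviving centerline candidates are thinned so that no
     seed lies inside another's clearance ball, and gaps along the skeleton
     are repaired by re-running the selection with locally renormalized
     responses.

(iii) *Tracing* — from each neurite start, the tracer repeatedly looks for
     the nearest alive seed inside a rectangle aligned with the expected
     orientation, fanning out by small angular steps (up to a hard limit)
     and growing the rectangle over multiple rounds.  The angular limit is
     what resolves crossings in maximum-intensity projections: continuing a
     neurite never requires turning sharply, switching to the crossing one
     would.  Seeds are consumed by the first tree that claims them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .segmentation import BinaryMask
from .soma import SomaRegion
from .tree import Neurite, NeuronTree

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi

# 3x3 sharpening kernel applied to Df: center 2, surround -1/8
SHARPEN_KERNEL = np.array([
    [-0.125, -0.125, -0.125],
    [-0.125, 2.0, -0.125],
    [-0.125, -0.125, -0.125],
])


@dataclass
class TraceConfig:
    """Tunable parameters of the tree-extraction routine.

    Defaults follow the reference experimental settings: soma dilation
    rates 1.1/1.2/1.3, seed threshold 0.16 on the normalized sharpened
    distance transform, initial search rectangle of 10 px growing by 2 px
    over up to 10 rounds, and a fan half-angle limit of 2*pi/5.
    """

    dilation_rates: tuple[float, ...] = (1.1, 1.2, 1.3)
    seed_threshold: float = 0.16
    initial_length: float = 10.0
    length_increment: float = 2.0
    max_rounds: int = 10
    max_fan_half_angle: float = TWO_PI / 5
    fan_step: float = math.pi / 16
    fan_length_decay: float = 0.95
    min_rect_width: float = 3.0
    min_root_length: float = 0.0  # optionally prune shorter soma-level traces (px)
    jump_length: float = 45.0  # corridor-jump reach after seed contention (px)
    normalize_response: bool = True  # threshold normalized vs raw response

    def validate(self) -> None:
        rates = self.dilation_rates
        if len(rates) < 3 or any(r <= 1 for r in rates) or \
                any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError("dilation_rates must be > 1 and increasing")
        if not (0 < self.seed_threshold < 1):
            raise ValueError("seed_threshold must be in (0, 1)")
        if self.initial_length <= 0:
            raise ValueError("initial_length must be > 0")
        if not (0 < self.max_fan_half_angle <= math.pi / 2):
            raise ValueError("max_fan_half_angle must be in (0, pi/2]")
        if not (0 < self.fan_step <= self.max_fan_half_angle):
            raise ValueError("fan_step must be in (0, max_fan_half_angle]")


@dataclass
class NeuriteStart:
    """Start point and initial orientation of one neurite at its soma."""

    soma_label: int
    point: np.ndarray       # (row, col) on the soma boundary
    theta0: float           # radians in [0, 2pi), pointing away from the soma

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.theta0 = float(self.theta0) % TWO_PI


@dataclass
class Seed:
    """Centerline candidate carrying its clearance radius Df."""

    position: np.ndarray    # (row, col)
    radius: float           # Df at position, px
    alive: bool = True
    index: int = -1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


# ---------------------------------------------------------------------------
# Step (ii): distance transform and seeding
# ---------------------------------------------------------------------------

def distance_map(f: BinaryMask) -> np.ndarray:
    """Exact Euclidean distance to the nearest background pixel; 0 outside."""
    if not (~f.f).any():
        raise ValueError("mask has no background pixel; Df is undefined")
    return ndi.distance_transform_edt(f.f)


def _select_candidates(df: np.ndarray, fg: np.ndarray, threshold: float,
                       normalize: bool, require_ridge: bool = True) -> np.ndarray:
    """Boolean map of candidate seeds: sharpened (optionally normalized)
    distance-transform response above threshold, foreground only.

    Candidates are additionally required to be ridge points — 3x3 local
    maxima of the response, with ties kept so plateaus survive — since the
    sought points are the local maxima of the distance transform along the
    centerline; off-ridge pixels otherwise pass the threshold on wide
    structures.
    """
    resp = ndi.convolve(df, SHARPEN_KERNEL, mode="reflect")
    if not fg.any():
        return np.zeros_like(fg)
    if require_ridge:
        ridge = resp >= ndi.maximum_filter(resp, size=3, mode="constant",
                                           cval=-np.inf)
    else:
        ridge = np.ones_like(fg)
    if normalize:
        vals = resp[fg]
        lo, hi = vals.min(), vals.max()
        if hi <= lo:
            return fg.copy()
        resp = (resp - lo) / (hi - lo)
    return fg & ridge & (resp >= threshold)


def _suppress(cands: list[tuple[float, float, float]],
              kept: list[Seed]) -> list[Seed]:
    """Greedy ball suppression: visit candidates in decreasing Df order;
    drop any candidate inside a kept seed's clearance ball."""
    out: list[Seed] = []
    existing = kept + out
    for r, y, x in sorted(cands, key=lambda t: (-t[0], t[1], t[2])):
        p = np.array([y, x])
        blocked = False
        for s in existing:
            # symmetric ball rule: within one pass (decreasing Df) this
            # equals the plain "inside s's ball" test, but across repair
            # passes a larger candidate must not crowd a smaller seed
            if np.linalg.norm(p - s.position) < max(s.radius, r):
                blocked = True
                break
        if not blocked:
            s = Seed(position=p, radius=r)
            out.append(s)
            existing.append(s)
    return out


def _skeleton_gaps(f: np.ndarray, seeds: list[Seed]) -> list[tuple]:
    """Connected runs of skeleton pixels not covered by any seed ball.

    Returns a list of bounding boxes (rmin, rmax, cmin, cmax).
    """
    skel = skeletonize(f)
    if not skel.any() or not seeds:
        return []
    pts = np.column_stack(np.nonzero(skel)).astype(float)
    tree = cKDTree(np.array([s.position for s in seeds]))
    maxr = max(s.radius for s in seeds)
    # covered: within radius of its covering seed
    dists, idx = tree.query(pts, k=min(len(seeds), 8),
                            distance_upper_bound=maxr + 1)
    dists = np.atleast_2d(dists.T).T
    idx = np.atleast_2d(idx.T).T
    radii = np.array([s.radius for s in seeds])
    covered = np.zeros(len(pts), dtype=bool)
    for k in range(dists.shape[1]):
        valid = idx[:, k] < len(seeds)
        covered[valid] |= dists[valid, k] <= radii[idx[valid, k]]
    uncovered = np.zeros_like(skel)
    up = pts[~covered].astype(int)
    uncovered[up[:, 0], up[:, 1]] = True
    labels, n = ndi.label(uncovered, structure=np.ones((3, 3)))
    boxes = []
    for obj in ndi.find_objects(labels):
        if obj is not None:
            boxes.append((obj[0].start, obj[0].stop, obj[1].start, obj[1].stop))
    return boxes


def skeleton_chain_violations(f: BinaryMask, seeds: list[Seed],
                              assign_tol: float = 3.0,
                              slack: float = math.sqrt(2.0)) -> list[tuple]:
    """Pairs of consecutive seeds along a skeleton path whose clearance
    balls fail to intersect: ||s - t|| > Df(s) + Df(t) + slack.

    ``slack`` defaults to one diagonal lattice step: on pixel-sampled
    diagonal tubes, consecutive seeds land on lattice offsets whose length
    exceeds the radius sum by up to sqrt(2) while every intermediate pixel
    already lies inside one of the two balls, so no seed can be inserted.
    Each seed is assigned to its nearest skeleton pixel (within
    ``assign_tol``); the skeleton is decomposed into degree-<=2 chains
    between endpoints/junctions, seeds on a chain are ordered by position
    along it, and consecutive pairs are checked.  Used to verify that the
    seeding gap repair leaves no uncovered stretch of centerline.
    """
    import networkx as nx

    skel = skeletonize(f.f)
    if not skel.any() or len(seeds) < 2:
        return []
    pts = np.column_stack(np.nonzero(skel))
    g = nx.Graph()
    pset = {tuple(p) for p in map(tuple, pts)}
    for (r, c) in pset:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                q = (r + dr, c + dc)
                if q in pset:
                    g.add_edge((r, c), q)
    skel_tree = cKDTree(pts.astype(float))
    d, idx = skel_tree.query(np.array([s.position for s in seeds]))
    seed_at: dict[tuple, list[Seed]] = {}
    for s, dist, i in zip(seeds, d, idx):
        if dist <= assign_tol:
            seed_at.setdefault(tuple(pts[i]), []).append(s)

    # decompose into chains between nodes of degree != 2
    junctions = {n for n in g.nodes if g.degree[n] != 2}
    visited_edges = set()
    violations = []

    def walk(start, nxt):
        chain = [start, nxt]
        while g.degree[chain[-1]] == 2 and chain[-1] not in junctions:
            a, b = list(g.neighbors(chain[-1]))
            nxt2 = b if a == chain[-2] else a
            if nxt2 == chain[-2] or nxt2 in chain[-2:]:
                break
            chain.append(nxt2)
            if nxt2 in junctions:
                break
        return chain

    starts = junctions if junctions else {next(iter(g.nodes))}
    for j in starts:
        for nb in g.neighbors(j):
            if (j, nb) in visited_edges:
                continue
            chain = walk(j, nb)
            for a, b in zip(chain, chain[1:]):
                visited_edges.add((a, b))
                visited_edges.add((b, a))
            chain_seeds = []
            for pos_idx, node in enumerate(chain):
                for s in seed_at.get(node, []):
                    chain_seeds.append((pos_idx, s))
            chain_seeds.sort(key=lambda t: t[0])
            for (_, s), (_, t) in zip(chain_seeds, chain_seeds[1:]):
                gap = np.linalg.norm(s.position - t.position)
                if gap > s.radius + t.radius + slack + 1e-9:
                    if not _ball_graph_connected(s, t, seeds, gap, slack):
                        violations.append((s, t, gap))
    return violations


def _ball_graph_connected(s: Seed, t: Seed, seeds: list[Seed], gap: float,
                          slack: float) -> bool:
    """True when a chain of pairwise-intersecting clearance balls links s
    to t through nearby seeds (chain-order assignment at junctions is
    ambiguous, so a bridged pair is not a coverage gap)."""
    mid = (s.position + t.position) / 2.0
    local = [u for u in seeds
             if np.linalg.norm(u.position - mid) <= gap + 5.0]
    frontier = [s]
    reached = {id(s)}
    while frontier:
        u = frontier.pop()
        for v in local:
            if id(v) in reached:
                continue
            if np.linalg.norm(u.position - v.position) \
                    <= u.radius + v.radius + slack:
                if v is t:
                    return True
                reached.add(id(v))
                frontier.append(v)
    return False


def compute_seeds(f: BinaryMask, cfg: TraceConfig | None = None,
                  max_repair_rounds: int = 4) -> list[Seed]:
    """Centerline seed points of a segmented image.

    The sharpened distance transform is thresholded (normalized over the
    foreground by default), candidates are thinned by ball suppression, and
    skeleton gaps are repaired by re-running selection with the response
    renormalized locally in each gap's bounding box.  Returns seeds with
    stable indices; an empty mask yields an empty list.
    """
    cfg = cfg or TraceConfig()
    cfg.validate()
    fg = f.f
    if not fg.any():
        return []
    df = distance_map(f)
    cand_map = _select_candidates(df, fg, cfg.seed_threshold,
                                  cfg.normalize_response)
    ys, xs = np.nonzero(cand_map)
    cands = [(float(df[y, x]), float(y), float(x)) for y, x in zip(ys, xs)]
    seeds = _suppress(cands, [])

    def repair_boxes(boxes, require_ridge: bool = True,
                     df_floor: float | None = None) -> int:
        added = 0
        for (r0, r1, c0, c1) in boxes:
            pad = 3
            r0, c0 = max(r0 - pad, 0), max(c0 - pad, 0)
            r1, c1 = min(r1 + pad, fg.shape[0]), min(c1 + pad, fg.shape[1])
            sub_fg = fg[r0:r1, c0:c1]
            sub_df = df[r0:r1, c0:c1]
            # chain repair drops the ridge requirement (staircase
            # transitions on discrete tubes have no strict local maxima,
            # yet need a seed) but keeps candidates near the local
            # clearance level so mask edge pixels are not seeded
            sub_map = _select_candidates(sub_df, sub_fg, cfg.seed_threshold,
                                         normalize=True,
                                         require_ridge=require_ridge)
            if not require_ridge and sub_fg.any():
                floor = df_floor if df_floor is not None \
                    else 0.7 * sub_df.max()
                sub_map &= sub_df >= floor
            ys, xs = np.nonzero(sub_map)
            sub_cands = [(float(df[y + r0, x + c0]),
                          float(y + r0), float(x + c0))
                         for y, x in zip(ys, xs)]
            new = _suppress(sub_cands, seeds)
            seeds.extend(new)
            added += len(new)
        return added

    # first repair uncovered skeleton stretches, then repair pairs of
    # consecutive chain seeds whose balls still fail to intersect
    for _ in range(max_repair_rounds):
        boxes = _skeleton_gaps(fg, seeds)
        if not boxes or repair_boxes(boxes) == 0:
            break
    for _ in range(max_repair_rounds):
        violations = skeleton_chain_violations(f, seeds)
        if not violations:
            break
        added = 0
        for s, t, _gap in violations:
            box = (int(min(s.position[0], t.position[0])),
                   int(max(s.position[0], t.position[0])) + 1,
                   int(min(s.position[1], t.position[1])),
                   int(max(s.position[1], t.position[1])) + 1)
            added += repair_boxes([box], require_ridge=False,
                                  df_floor=0.7 * min(s.radius, t.radius))
        if added == 0:
            break
    for i, s in enumerate(seeds):
        s.index = i
    return seeds


# ---------------------------------------------------------------------------
# Step (i): neurite initialization
# ---------------------------------------------------------------------------

def _scale_mask(mask: np.ndarray, centroid: np.ndarray, rate: float) -> np.ndarray:
    """Geometric scaling of a boolean mask about a point by factor ``rate``."""
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    src_y = centroid[0] + (yy - centroid[0]) / rate
    src_x = centroid[1] + (xx - centroid[1]) / rate
    return ndi.map_coordinates(mask.astype(np.uint8), [src_y, src_x],
                               order=0, mode="constant", cval=0).astype(bool)


def _region_centroids(mask: np.ndarray, min_size: int = 3) -> list[np.ndarray]:
    """Centroids of connected components, ignoring speckle below min_size."""
    labels, n = ndi.label(mask, structure=np.ones((3, 3)))
    cents = []
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() >= min_size:
            cents.append(np.asarray(ndi.center_of_mass(comp)))
    return cents


def initialize_neurites(soma: SomaRegion, f: BinaryMask,
                        cfg: TraceConfig | None = None) -> list[NeuriteStart]:
    """Find the start point and initial orientation of each neurite.

    The soma mask S0 is scaled by the three dilation rates to S1..S3; the
    ring regions (S1 xor S0) and (S3 xor S2), intersected with the
    foreground, isolate two stubs per neurite.  Mutually-nearest inner and
    outer stub centroids are paired; the inner-to-outer direction is the
    initial orientation and the S0 boundary point nearest the inner
    centroid is the start point.  Unpaired stubs are dropped with a logged
    warning.
    """
    cfg = cfg or TraceConfig()
    cfg.validate()
    s0 = soma.mask
    if not (s0 & f.f).sum() == s0.sum():
        raise ValueError("soma mask must be contained in the foreground")
    r1, r2, r3 = cfg.dilation_rates[:3]
    r_eq = soma.equivalent_radius
    # Concentric rings at the dilation rates: for a convex soma, scaling by
    # rate r offsets the boundary by about (r - 1) * radius, so the rings
    # are distance-from-soma bands.  A floor keeps them at least a couple
    # of pixels thick for small somas, where a sub-pixel ring would
    # fragment on a noisy mask.
    dist_out = ndi.distance_transform_edt(~s0)
    t1 = max((r1 - 1.0) * r_eq, 2.5)
    t2 = max((r2 - 1.0) * r_eq, 5.0)
    t3 = max((r3 - 1.0) * r_eq, 9.0)
    inner_ring = (dist_out > 0) & (dist_out <= t1) & f.f
    outer_ring = (dist_out > t2) & (dist_out <= t3) & f.f
    # an inner stub of a genuine neurite is attached to the soma boundary;
    # a foreign neurite passing through the band at a distance is not
    inner_labels, n_in = ndi.label(inner_ring, structure=np.ones((3, 3)))
    for lab in range(1, n_in + 1):
        comp = inner_labels == lab
        if dist_out[comp].min() > 1.2:
            inner_ring &= ~comp
    inner = _region_centroids(inner_ring)
    outer = _region_centroids(outer_ring)
    if not inner or not outer:
        return []

    # mutual nearest-neighbour pairing of inner and outer stub centroids,
    # measured by angle about the soma centroid: stubs of the same neurite
    # agree in angle, while crowded stubs of nearby neurites can be closer
    # in Euclidean distance than in angle
    inner_arr = np.array(inner)
    outer_arr = np.array(outer)
    ang_i = np.arctan2(inner_arr[:, 0] - soma.centroid[0],
                       inner_arr[:, 1] - soma.centroid[1])
    ang_o = np.arctan2(outer_arr[:, 0] - soma.centroid[0],
                       outer_arr[:, 1] - soma.centroid[1])
    d = np.abs((ang_i[:, None] - ang_o[None, :] + math.pi) % TWO_PI - math.pi)
    starts: list[NeuriteStart] = []
    boundary = s0 & ~ndi.binary_erosion(s0)
    brows, bcols = np.nonzero(boundary)
    bpts = np.column_stack([brows, bcols]).astype(float)
    for i in range(len(inner)):
        j = int(np.argmin(d[i]))
        if int(np.argmin(d[:, j])) != i:
            logger.warning("unpaired neurite stub near %s discarded",
                           np.round(inner_arr[i], 1))
            continue
        vec = outer_arr[j] - inner_arr[i]
        norm = np.linalg.norm(vec)
        if norm == 0:
            logger.warning("degenerate stub pair near %s discarded",
                           np.round(inner_arr[i], 1))
            continue
        theta0 = math.atan2(vec[0], vec[1]) % TWO_PI
        # a neurite leaves its soma roughly radially; a foreign neurite
        # passing tangentially yields stubs nearly perpendicular to the
        # radial direction and would otherwise steal a whole trace
        radial = inner_arr[i] - soma.centroid
        if np.linalg.norm(radial) > 0:
            radial_theta = math.atan2(radial[0], radial[1])
            dev = abs((theta0 - radial_theta + math.pi) % TWO_PI - math.pi)
            if dev > math.radians(60):
                logger.warning("non-radial stub near %s discarded (dev %.0f deg)",
                               np.round(inner_arr[i], 1), math.degrees(dev))
                continue
        k = int(np.argmin(np.linalg.norm(bpts - inner_arr[i], axis=1)))
        starts.append(NeuriteStart(soma_label=soma.label, point=bpts[k],
                                   theta0=theta0))
    return starts


# ---------------------------------------------------------------------------
# Step (iii): fan search and tracing
# ---------------------------------------------------------------------------

class SeedIndex:
    """Spatial index over seeds with alive/dead bookkeeping."""

    def __init__(self, seeds: list[Seed]):
        self.seeds = seeds
        self._tree = cKDTree(np.array([s.position for s in seeds])) \
            if seeds else None

    def query_disk(self, center: np.ndarray, radius: float) -> list[Seed]:
        if self._tree is None:
            return []
        idx = self._tree.query_ball_point(center, radius)
        return [self.seeds[i] for i in idx if self.seeds[i].alive]


def _in_rectangle(rel: np.ndarray, theta: float, length: float,
                  width: float) -> np.ndarray:
    """Boolean: which relative positions fall in the forward rectangle."""
    u = rel[:, 0] * math.sin(theta) + rel[:, 1] * math.cos(theta)
    v = -rel[:, 0] * math.cos(theta) + rel[:, 1] * math.sin(theta)
    return (u > 1e-9) & (u <= length) & (np.abs(v) <= width / 2.0)


def _round_candidates(position: np.ndarray, theta: float, length: float,
                      width: float, cfg: TraceConfig,
                      index: SeedIndex) -> list[tuple[Seed, int]]:
    """All alive seeds found in one search round, tagged by angular bin.

    The axis-aligned rectangle is bin 0; the fan pairs at +-k*fan_step use
    rectangles shortened by the decay factor per step and are bins +-k.
    Returns the contents of the *first* non-empty angular level: bin 0
    alone if it hits, else every seed found at the first level k with a
    hit (both +k and -k), matching a search that stops as soon as a seed
    is found.
    """
    reach = length + width
    nearby = index.query_disk(position, reach)
    if not nearby:
        return []
    rel = np.array([s.position for s in nearby]) - position
    # hard angular gate: a candidate deviating more than the fan limit is
    # never accepted, however close (this is what keeps a trace from
    # switching onto a crossing neurite)
    dev = np.abs((np.arctan2(rel[:, 0], rel[:, 1]) - theta + math.pi)
                 % TWO_PI - math.pi)
    ok = dev <= cfg.max_fan_half_angle + 1e-9
    if not ok.any():
        return []
    nearby = [s for s, keep in zip(nearby, ok) if keep]
    rel = rel[ok]

    hits = _in_rectangle(rel, theta, length, width)
    if hits.any():
        return [(nearby[i], 0) for i in np.nonzero(hits)[0]]
    k = 1
    cur_len = length
    while k * cfg.fan_step <= cfg.max_fan_half_angle:
        cur_len *= cfg.fan_length_decay
        found: list[tuple[Seed, int]] = []
        for sgn in (+1, -1):
            ang = theta + sgn * k * cfg.fan_step
            hits = _in_rectangle(rel, ang, cur_len, width)
            found.extend((nearby[i], sgn * k) for i in np.nonzero(hits)[0])
        if found:
            return found
        k += 1
    return []


def _pick_best(cands: list[tuple[Seed, int]], position: np.ndarray,
               theta: float) -> tuple[Seed, int]:
    """Deterministic choice: nearest; ties by angular deviation, then index."""
    def keyfun(item):
        s, _bin = item
        rel = s.position - position
        dist = float(np.linalg.norm(rel))
        dev = abs((math.atan2(rel[0], rel[1]) - theta + math.pi) % TWO_PI
                  - math.pi)
        return (round(dist, 9), round(dev, 9), s.index)
    return min(cands, key=keyfun)


def _has_backward_continuation(cand: Seed, position: np.ndarray,
                               index: SeedIndex, length: float = 18.0,
                               width: float = 5.0) -> bool:
    """True when alive seeds continue *behind* the candidate's direction.

    Distinguishes an X-crossing from a Y-bifurcation at a junction: a
    crossing neurite passes through, so it has alive seeds on the far side
    of the junction (opposite the candidate), while a true branch only
    extends forward.  Seeds of the current trace are already dead and do
    not trigger this.
    """
    rel_c = cand.position - position
    phi = math.atan2(rel_c[0], rel_c[1])
    back = phi + math.pi
    nearby = index.query_disk(position, length + width)
    for s in nearby:
        if s is cand:
            continue
        rel = s.position - position
        if np.linalg.norm(rel) < 2.0:
            continue
        if _in_rectangle(rel[None, :], back, length, width)[0]:
            return True
    return False


def next_seed_search(position: np.ndarray, theta: float, index: SeedIndex,
                     cfg: TraceConfig, local_radius: float = 1.5,
                     collect_branches: bool = False):
    """Search for the next seed over up to ``max_rounds`` growing rounds.

    Round r uses rectangles of base length ``initial_length + r *
    length_increment`` and width ``max(min_rect_width, 2 * local_radius)``.
    Returns the chosen seed (or ``None``), plus — when ``collect_branches``
    — any other seeds of the successful round lying in angular bins
    separated from the chosen one by more than one fan step (candidate
    bifurcations).
    """
    cfg.validate()
    width = max(cfg.min_rect_width, 2.0 * local_radius)
    for r in range(cfg.max_rounds):
        length = cfg.initial_length + r * cfg.length_increment
        cands = _round_candidates(position, theta, length, width, cfg, index)
        if cands:
            best, best_bin = _pick_best(cands, position, theta)
            if not collect_branches:
                return best
            extras = []
            seen_bins = {best_bin}
            for s, b in sorted(cands, key=lambda t: t[0].index):
                if s is best:
                    continue
                if all(abs(b - sb) > 1 for sb in seen_bins) and \
                        not _has_backward_continuation(s, position, index):
                    extras.append(s)
                    seen_bins.add(b)
            return best, extras
    return (None, []) if collect_branches else None


def trace_neurite(start: NeuriteStart, index: SeedIndex, cfg: TraceConfig,
                  arc_offset: float = 0.0, allow_branches: bool = True):
    """Trace one neurite from its start; returns (Neurite, branch requests).

    Seeds are appended and consumed until no seed is found within the
    search fans; the expected orientation is the direction of the last two
    trace points.  Branch requests are (position, theta, node_index, arc)
    tuples for seeds found in disjoint angular sub-fans.
    """
    nodes = [np.asarray(start.point, dtype=float)]
    radii = [1.0]
    arcs = [arc_offset]
    theta = start.theta0
    branch_requests = []
    while True:
        pos = nodes[-1]
        res = next_seed_search(pos, theta, index, cfg,
                               local_radius=radii[-1],
                               collect_branches=allow_branches)
        seed, extras = res if allow_branches else (res, [])
        if seed is None:
            break
        seed.alive = False
        step = np.linalg.norm(seed.position - pos)
        nodes.append(seed.position.copy())
        radii.append(seed.radius)
        arcs.append(arcs[-1] + step)
        vec = nodes[-1] - nodes[-2]
        theta = math.atan2(vec[0], vec[1]) % TWO_PI
        for s in extras:
            s.alive = False
            bvec = s.position - pos
            btheta = math.atan2(bvec[0], bvec[1]) % TWO_PI
            branch_requests.append(
                (s, pos.copy(), btheta, len(nodes) - 2, arcs[-2]))
    neurite = Neurite(nodes=np.asarray(nodes), arclength=np.asarray(arcs),
                      radii=np.asarray(radii), parent=None)
    return neurite, branch_requests


def _corridor_jump(position: np.ndarray, theta: float, index: SeedIndex,
                   f: BinaryMask, cfg: TraceConfig) -> Seed | None:
    """Bridge a stretch whose seeds were consumed by another front.

    Where neurites run merged for a while, only one seed chain exists and
    the first front through consumes it; the other front would terminate
    even though its neurite continues.  If an alive seed lies in a narrow
    forward cone (half-angle pi/8) within ``jump_length`` and the straight
    path to it stays on foreground, the front reconnects there.  Nearest
    seed first; no branch spawning on jumps.
    """
    nearby = index.query_disk(position, cfg.jump_length)
    best, best_d = None, np.inf
    for s in nearby:
        rel = s.position - position
        dist = float(np.linalg.norm(rel))
        if dist < 1e-9 or dist >= best_d:
            continue
        dev = abs((math.atan2(rel[0], rel[1]) - theta + math.pi) % TWO_PI
                  - math.pi)
        if dev > math.pi / 8:
            continue
        n_samp = max(int(dist), 2)
        t = np.linspace(0.0, 1.0, n_samp)
        pts = position[None, :] + t[:, None] * rel[None, :]
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, f.shape[0] - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, f.shape[1] - 1)
        if f.f[rr, cc].mean() < 0.9:
            continue
        best, best_d = s, dist
    return best


class _ActiveTrace:
    """One growing front during multi-neuron extraction."""

    __slots__ = ("soma_label", "order", "nodes", "radii", "arcs", "theta",
                 "parent_trace", "parent_node", "done", "is_branch")

    def __init__(self, soma_label: int, order: int, point: np.ndarray,
                 theta: float, radius: float = 1.0, arc0: float = 0.0,
                 parent_trace: "_ActiveTrace | None" = None,
                 parent_node: int = -1, is_branch: bool = False):
        self.soma_label = soma_label
        self.order = order
        self.nodes = [np.asarray(point, dtype=float)]
        self.radii = [radius]
        self.arcs = [arc0]
        self.theta = theta
        self.parent_trace = parent_trace
        self.parent_node = parent_node
        self.done = False
        self.is_branch = is_branch

    def step(self, index: SeedIndex, cfg: TraceConfig,
             f: "BinaryMask | None" = None) -> list["_ActiveTrace"]:
        """Advance by one seed; returns spawned branch traces."""
        pos = self.nodes[-1]
        seed, extras = next_seed_search(pos, self.theta, index, cfg,
                                        local_radius=self.radii[-1],
                                        collect_branches=True)
        if f is not None and len(self.nodes) >= 3 and cfg.jump_length > 0:
            if seed is None:
                seed = _corridor_jump(pos, self.theta, index, f, cfg)
                extras = []
            else:
                # orientation continuity: when the found seed deviates
                # strongly (its straight-ahead competitor was likely
                # consumed at a crossing), prefer a clean dead-ahead
                # corridor continuation if one exists
                rel = seed.position - pos
                dev = abs((math.atan2(rel[0], rel[1]) - self.theta + math.pi)
                          % TWO_PI - math.pi)
                if dev > math.pi / 8:
                    alt = _corridor_jump(pos, self.theta, index, f, cfg)
                    if alt is not None and alt is not seed:
                        seed = alt
                        extras = []
        if seed is None:
            self.done = True
            return []
        seed.alive = False
        step_len = float(np.linalg.norm(seed.position - pos))
        self.nodes.append(seed.position.copy())
        self.radii.append(seed.radius)
        self.arcs.append(self.arcs[-1] + step_len)
        vec = self.nodes[-1] - self.nodes[-2]
        self.theta = math.atan2(vec[0], vec[1]) % TWO_PI
        spawned = []
        for s in extras:
            s.alive = False
            bvec = s.position - pos
            btheta = math.atan2(bvec[0], bvec[1]) % TWO_PI
            child = _ActiveTrace(
                self.soma_label, order=-1, point=pos, theta=btheta,
                radius=self.radii[-2], arc0=self.arcs[-2],
                parent_trace=self, parent_node=len(self.nodes) - 2,
                is_branch=True)
            # the reserved seed becomes the branch's first step
            child.nodes.append(s.position.copy())
            child.radii.append(s.radius)
            child.arcs.append(child.arcs[-1]
                              + float(np.linalg.norm(s.position - pos)))
            cvec = child.nodes[-1] - child.nodes[-2]
            child.theta = math.atan2(cvec[0], cvec[1]) % TWO_PI
            spawned.append(child)
        return spawned


def _polyline_samples(neurites: list[Neurite], step: float = 1.0) -> np.ndarray:
    """Densified points of a list of neurites (for overlap tests)."""
    out = []
    for nr in neurites:
        nodes = nr.nodes
        if len(nodes) < 2:
            out.append(nodes)
            continue
        seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(int(math.ceil(arc[-1] / step)) + 1, 2)
        t = np.linspace(0, arc[-1], n)
        out.append(np.column_stack([np.interp(t, arc, nodes[:, 0]),
                                    np.interp(t, arc, nodes[:, 1])]))
    return np.vstack(out) if out else np.empty((0, 2))


def _drop_duplicate_stubs(trees: list[NeuronTree], cfg: TraceConfig,
                          max_len: float = 60.0, tol: float = 2.5,
                          overlap_frac: float = 0.8) -> None:
    """Remove short soma-level traces that duplicate another tree's path.

    When a foreign neurite touches a soma, initialization can start a short
    trace along it before the rightful owner's front claims the rest; the
    stub then runs inside the other tree's traced corridor.  A root-level
    neurite shorter than ``max_len`` px whose densified points lie (at
    fraction >= overlap_frac) within ``tol`` px of another tree's polyline
    is dropped.  Neurites with child branches are kept.
    """
    others = {t.neuron_id: _polyline_samples(t.neurites) for t in trees}
    for tree in trees:
        has_child = {nr.parent[0] for nr in tree.neurites
                     if nr.parent is not None}
        drop = set()
        for j, nr in enumerate(tree.neurites):
            if nr.parent is not None or j in has_child:
                continue
            if nr.length >= max_len or nr.n_nodes < 2:
                continue
            pts = _polyline_samples([nr])
            for other in trees:
                if other is tree or not len(others[other.neuron_id]):
                    continue
                d, _ = cKDTree(others[other.neuron_id]).query(pts)
                if (d <= tol).mean() >= overlap_frac:
                    drop.add(j)
                    break
        if drop:
            keep_idx = [j for j in range(len(tree.neurites)) if j not in drop]
            remap = {old: new for new, old in enumerate(keep_idx)}
            kept = []
            for j in keep_idx:
                nr = tree.neurites[j]
                if nr.parent is not None:
                    nr.parent = (remap[nr.parent[0]], nr.parent[1])
                kept.append(nr)
            tree.neurites = kept
            tree.validate()


@dataclass
class TraceReport:
    """Run metadata: seed usage, conflicts and termination bookkeeping."""

    n_seeds: int = 0
    n_seeds_consumed: int = 0
    neurites_per_neuron: dict[int, int] = field(default_factory=dict)
    conflicts: list[dict] = field(default_factory=list)


def extract_trees(somas: list[SomaRegion], f: BinaryMask,
                  seeds: list[Seed] | None = None,
                  cfg: TraceConfig | None = None,
                  ) -> tuple[list[NeuronTree], TraceReport]:
    """Extract one rooted tree per soma by simultaneous front propagation.

    All somas' neurite fronts advance in round-robin (one seed per front
    per round), so every neuron claims the seeds nearest its own soma
    before a longer-reaching front from another neuron can wander onto
    them; a seed consumed by one front is dead for all others.  Somas are
    ordered by descending area within each round and ties broken
    deterministically, so extraction is fully reproducible.  Seeds inside
    any soma mask are never trace targets.  A conflict log records nodes
    claimed within 2 px of another tree's nodes (ambiguous assignments at
    shallow crossings).
    """
    if not somas:
        raise ValueError("at least one soma is required")
    cfg = cfg or TraceConfig()
    cfg.validate()
    if seeds is None:
        seeds = compute_seeds(f, cfg)
    soma_union = np.zeros(f.shape, dtype=bool)
    for s in somas:
        soma_union |= s.mask
    usable = [s for s in seeds
              if not soma_union[int(round(s.position[0])),
                                int(round(s.position[1]))]]
    index = SeedIndex(usable)
    report = TraceReport(n_seeds=len(usable))

    ordered = sorted(somas, key=lambda s: -s.area)
    active: list[_ActiveTrace] = []
    traces_per_soma: dict[int, list[_ActiveTrace]] = {}
    for soma in ordered:
        starts = initialize_neurites(soma, f, cfg)
        traces_per_soma[soma.label] = []
        for st in starts:
            tr = _ActiveTrace(soma.label, order=len(active), point=st.point,
                              theta=st.theta0)
            active.append(tr)
            traces_per_soma[soma.label].append(tr)

    frontier = list(active)
    while frontier:
        spawned_all: list[_ActiveTrace] = []
        for tr in frontier:
            if tr.done:
                continue
            spawned = tr.step(index, cfg, f)
            for child in spawned:
                traces_per_soma[tr.soma_label].append(child)
                spawned_all.append(child)
        frontier = [t for t in frontier if not t.done] + spawned_all

    trees: list[NeuronTree] = []
    for soma in ordered:
        tree = NeuronTree(neuron_id=soma.label, root=soma.centroid,
                          soma_radius=soma.equivalent_radius)
        kept: dict[int, int] = {}  # id(trace) -> neurite index
        for tr in traces_per_soma[soma.label]:
            if len(tr.nodes) <= 1 and tr.is_branch:
                continue
            # a soma-level trace much shorter than any real neurite is an
            # initialization artifact (e.g. a stub of a passing neurite)
            if not tr.is_branch and tr.arcs[-1] - tr.arcs[0] < cfg.min_root_length:
                continue
            if tr.parent_trace is not None:
                pidx = kept.get(id(tr.parent_trace))
                parent_ref = (pidx, tr.parent_node) if pidx is not None else None
            else:
                parent_ref = None
            neurite = Neurite(nodes=np.asarray(tr.nodes),
                              arclength=np.asarray(tr.arcs),
                              radii=np.asarray(tr.radii),
                              parent=parent_ref)
            tree.neurites.append(neurite)
            kept[id(tr)] = len(tree.neurites) - 1
        tree.validate()
        trees.append(tree)
        report.neurites_per_neuron[soma.label] = tree.n_neurites

    _drop_duplicate_stubs(trees, cfg)
    for t in trees:
        report.neurites_per_neuron[t.neuron_id] = t.n_neurites

    # conflict log: nodes of one tree within 2 px of another tree's nodes
    for i, a in enumerate(trees):
        pts_a = a.all_nodes()
        if not len(pts_a):
            continue
        for b in trees[i + 1:]:
            pts_b = b.all_nodes()
            if not len(pts_b):
                continue
            d, _ = cKDTree(pts_b).query(pts_a)
            for pt in pts_a[d < 2.0]:
                report.conflicts.append({
                    "neurons": [a.neuron_id, b.neuron_id],
                    "position": [float(pt[0]), float(pt[1])],
                })
    report.n_seeds_consumed = sum(not s.alive for s in usable)
    return trees, report


# ---------------------------------------------------------------------------
# tiling for large images
# ---------------------------------------------------------------------------

def tile_large_image(f: BinaryMask, somas: list[SomaRegion],
                     max_tile: int = 1024, overlap: int = 64,
                     cluster_cutoff: float = 150.0,
                     ) -> list[tuple[tuple[int, int, int, int], list[SomaRegion]]]:
    """Partition work into overlapping rectangles by soma proximity.

    Somas are grouped by single-linkage clustering with ``cluster_cutoff``
    (px); each rectangle is the group's soma bounding box plus an
    ``overlap`` margin, clipped to the image.  A soma whose mask would
    overlap its rectangle's boundary is reassigned to its own tile, so
    every soma belongs to exactly one tile.  Raises ``ValueError`` if a
    soma cannot fit in ``max_tile``.
    """
    if not somas:
        return []
    h, w = f.shape
    cents = np.array([s.centroid for s in somas])
    # single linkage via union-find on the distance cutoff
    parent = list(range(len(somas)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(len(somas)):
        for j in range(i + 1, len(somas)):
            if np.linalg.norm(cents[i] - cents[j]) <= cluster_cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(len(somas)):
        groups.setdefault(find(i), []).append(i)

    def soma_bbox(idx: list[int]) -> tuple[int, int, int, int]:
        rows, cols = [], []
        for i in idx:
            rr, cc = np.nonzero(somas[i].mask)
            rows.extend([rr.min(), rr.max()])
            cols.extend([cc.min(), cc.max()])
        return min(rows), max(rows) + 1, min(cols), max(cols) + 1

    tiles = []
    pending = [sorted(g) for g in groups.values()]
    while pending:
        idx = pending.pop(0)
        r0, r1, c0, c1 = soma_bbox(idx)
        r0 = max(r0 - overlap, 0)
        c0 = max(c0 - overlap, 0)
        r1 = min(r1 + overlap, h)
        c1 = min(c1 + overlap, w)
        if (r1 - r0) > max_tile or (c1 - c0) > max_tile:
            if len(idx) == 1:
                raise ValueError(
                    f"soma {somas[idx[0]].label} does not fit in a "
                    f"{max_tile} px tile")
            # split the cluster along its larger extent and retry
            axis = 0 if (r1 - r0) >= (c1 - c0) else 1
            order = sorted(idx, key=lambda i: cents[i][axis])
            half = len(order) // 2
            pending.append(order[:half])
            pending.append(order[half:])
            continue
        tiles.append(((r0, r1, c0, c1), [somas[i] for i in idx]))
    return tiles
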