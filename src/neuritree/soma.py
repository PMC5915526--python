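"""Soma detection from the binary mask via the directional ratio.

At each foreground pixel, oriented line filters of a fixed length are
evaluated over many orientations on the binary mask; the directional ratio
is min response / max response.  Inside a blob much wider than the filter
every orientation fits, so the ratio is near 1; on a thin tube only the
along-tube orientation fits and the ratio is small (about width/length).
Thresholding the ratio therefore isolates somas from neurites; boundaries
are refined by geodesic (morphological) reconstruction, and clustered somas
are split by a marker-controlled watershed on the interior distance
transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import disk, h_maxima, opening
from skimage.segmentation import watershed

from .segmentation import BinaryMask

DEFAULT_FILTER_LENGTH = 15
DEFAULT_N_ORIENT = 16
DEFAULT_DR_THRESHOLD = 0.6
DEFAULT_MIN_SOMA_AREA = 100


@dataclass
class SomaRegion:
    """One detected soma: the root of a neuronal tree."""

    label: int
    mask: np.ndarray            # boolean, one connected component
    centroid: np.ndarray        # (row, col)
    area: int

    @staticmethod
    def from_mask(label: int, mask: np.ndarray) -> "SomaRegion":
        mask = np.asarray(mask).astype(bool)
        if not mask.any():
            raise ValueError("soma mask is empty")
        rows, cols = np.nonzero(mask)
        return SomaRegion(label=label, mask=mask,
                          centroid=np.array([rows.mean(), cols.mean()]),
                          area=int(mask.sum()))

    @property
    def equivalent_radius(self) -> float:
        """Radius of the disk with the same area, px."""
        return math.sqrt(self.area / math.pi)


@dataclass
class DirectionalRatioMap:
    """Per-pixel anisotropy score in [0, 1]; 0 on background."""

    scores: np.ndarray
    filter_length: int
    n_orient: int


def _line_kernel(length: int, theta: float) -> np.ndarray:
    """1-px-wide centred line of ``length`` samples at angle theta."""
    half = (length - 1) / 2.0
    size = int(math.ceil(half)) * 2 + 1
    kern = np.zeros((size, size))
    c = size // 2
    dr, dc = math.sin(theta), math.cos(theta)
    for t in np.linspace(-half, half, length):
        r = int(round(c + t * dr))
        col = int(round(c + t * dc))
        kern[r, col] = 1.0
    return kern / kern.sum()


def directional_ratio(mask: BinaryMask, length: int = DEFAULT_FILTER_LENGTH,
                      n_orient: int = DEFAULT_N_ORIENT) -> DirectionalRatioMap:
    """Min/max ratio of oriented line-filter responses on the mask.

    Each oriented response is the fraction of the line (length ``length``
    px, centred at the pixel, angle k*pi/n_orient) lying on foreground.
    """
    if length < 3:
        raise ValueError("filter length must be >= 3")
    if n_orient < 4:
        raise ValueError("n_orient must be >= 4")
    f = mask.f.astype(float)
    if not mask.f.any():
        return DirectionalRatioMap(np.zeros(mask.shape), length, n_orient)
    responses = np.empty((n_orient,) + mask.shape)
    for k in range(n_orient):
        kern = _line_kernel(length, k * math.pi / n_orient)
        responses[k] = ndi.correlate(f, kern, mode="constant", cval=0.0)
    rmin = responses.min(axis=0)
    rmax = responses.max(axis=0)
    scores = np.zeros(mask.shape)
    fg = mask.f & (rmax > 0)
    scores[fg] = rmin[fg] / rmax[fg]
    return DirectionalRatioMap(np.clip(scores, 0.0, 1.0), length, n_orient)


def detect_somas(mask: BinaryMask, dr: DirectionalRatioMap | None = None,
                 dr_threshold: float = DEFAULT_DR_THRESHOLD,
                 min_area: int = DEFAULT_MIN_SOMA_AREA,
                 filter_length: int = DEFAULT_FILTER_LENGTH,
                 n_orient: int = DEFAULT_N_ORIENT,
                 split_clusters: bool = True,
                 min_dr_max: float = 0.7,
                 max_elongation: float = 1.65) -> list[SomaRegion]:
    """Detect soma regions in a segmented image.

    Pixels with directional ratio >= ``dr_threshold`` are kept, opened to
    drop thin spurs, and connected components above ``min_area`` become
    soma cores.  Each core is refined by geodesic dilation within the
    foreground restricted to pixels scoring >= dr_threshold/2, which grows
    the core back to the soma boundary while excluding neurite stumps.
    Clustered somas are split by :func:`split_clustered_somas`.  Returns
    regions sorted by descending area (empty list if nothing qualifies).
    """
    if dr is None:
        dr = directional_ratio(mask, filter_length, n_orient)
    core = (dr.scores >= dr_threshold) & mask.f
    core = opening(core, disk(2))
    labels, n = ndi.label(core)
    if n == 0:
        return []
    allowed = mask.f & (dr.scores >= dr_threshold / 2.0)
    # The directional-ratio core misses a boundary ring about half a filter
    # length wide; a geodesic front of that many steps recovers it without
    # racing far down a (thick) neurite stump.
    n_iter = dr.filter_length // 2 + 2
    regions: list[SomaRegion] = []
    next_label = 1
    struct = ndi.generate_binary_structure(2, 2)
    for i in range(1, n + 1):
        comp = labels == i
        # the core is the soma eroded by about half a filter length; the
        # min_area test applies to the refined region, with only a loose
        # pre-filter here
        if comp.sum() < max(min_area // 4, 10):
            continue
        grown = comp
        for _ in range(n_iter):
            nxt = ndi.binary_dilation(grown, structure=struct) & allowed
            if np.array_equal(nxt, grown):
                break
            grown = nxt
        # cut the neurite stumps the front crept into: an opening at the
        # neurite scale leaves the compact soma body
        opened = opening(grown, disk(4))
        opened_labels, n_op = ndi.label(opened)
        if n_op > 0:
            ids, counts = np.unique(opened_labels[opened_labels > 0],
                                    return_counts=True)
            keep = ids[np.argmax(counts)]
            grown = opened_labels == keep
        if split_clusters:
            parts = split_clustered_somas(SomaRegion.from_mask(0, grown))
        else:
            parts = [SomaRegion.from_mask(0, grown)]
        for part in parts:
            # a genuine soma contains a near-isotropic interior point; a
            # neurite-tangle blob that sneaks past the threshold does not
            if dr.scores[part.mask].max() < min_dr_max:
                continue
            # and it is at most mildly elliptical: area within
            # max_elongation of its inscribed disk (tangles are star-shaped)
            inscribed = ndi.distance_transform_edt(part.mask).max()
            if part.area > max_elongation * math.pi * inscribed ** 2:
                continue
            if part.area >= min_area:
                regions.append(SomaRegion.from_mask(next_label, part.mask))
                next_label += 1
    # drop duplicates (two cores growing into the same soma)
    unique: list[SomaRegion] = []
    for reg in sorted(regions, key=lambda r: -r.area):
        if all(not np.logical_and(reg.mask, u.mask).any() for u in unique):
            unique.append(reg)
    for new_label, reg in enumerate(unique, start=1):
        reg.label = new_label
    return unique


def split_clustered_somas(region: SomaRegion, h: float = 3.0) -> list[SomaRegion]:
    """Split touching somas by watershed on the interior distance transform.

    Markers are the h-maxima of the (lightly smoothed) distance transform
    (h in px); a single convex soma has one marker and is returned
    unchanged.  Two equal disks overlapping at 1.5 radii separation have a
    saddle about 0.34 r deep, well above h for any detectable soma.  The
    outputs are disjoint connected regions whose union is exactly the input
    mask.
    """
    dist = ndi.distance_transform_edt(region.mask)
    # smoothing suppresses discretization bumps on ragged boundaries that
    # would otherwise seed spurious markers
    dist_s = ndi.gaussian_filter(dist, 1.0)
    maxima = h_maxima(dist_s, h)
    markers, n_markers = ndi.label(maxima)
    if n_markers <= 1:
        return [region]
    ws = watershed(-dist_s, markers, mask=region.mask)
    parts = []
    for i in range(1, n_markers + 1):
        part = ws == i
        # keep each output connected: watershed fragments can split oddly
        # on noisy boundaries; take components individually
        comp_labels, n_comp = ndi.label(part)
        for j in range(1, n_comp + 1):
            parts.append(SomaRegion.from_mask(len(parts) + 1, comp_labels == j))
    return parts


def soma_label_image(regions: list[SomaRegion], shape) -> np.ndarray:
    """Integer label image (0 background) from a list of soma regions."""
    out = np.zeros(shape, dtype=np.int32)
    for reg in regions:
        out[reg.mask] = reg.label
    return out


def regions_from_label_image(labels: np.ndarray) -> list[SomaRegion]:
    """Rebuild SomaRegion objects from a supplied integer label image."""
    labels = np.asarray(labels)
    regions = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        regions.append(SomaRegion.from_mask(int(lab), labels == lab))
    return regions
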