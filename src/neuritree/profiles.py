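"""Fluorescence intensity profiles along traced neurites and AIS statistics.

The traced centerline provides the spatial reference: intensity is sampled
by bilinear interpolation at uniform arclength steps, and the spatially
varying background is estimated at each sample from a pair of 3x3 windows
placed on the perpendicular to the local trace direction, 2 px beyond the
segmented structure on each side (pushed further out if they overlap other
structures).  The background-corrected profile over the proximal axon
quantifies the axonal initial segment (AIS): its area A_AIS, variance
V_AIS, the amplitude H of a least-squares Gaussian fit
g(x) = H exp(-(x - mu)^2 / (2 sigma^2)), and the polarity ratio
R_AD = A_AIS / A_den against dendrites of comparable thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.optimize import curve_fit
from scipy.stats import ttest_ind

from .io import Image2D
from .segmentation import BinaryMask
from .tree import Neurite, NeuronTree

AIS_INTERVAL_PX = 70  # 70 px at 0.28 um/px ~ 19.6 um


@dataclass
class IntensityProfile:
    """Raw, background and corrected intensity versus arclength (px)."""

    neuron_id: int
    neurite_id: int
    arclength_px: np.ndarray
    raw: np.ndarray
    background: np.ndarray
    pixel_size: float = 0.28

    def __post_init__(self) -> None:
        n = len(self.arclength_px)
        if not (len(self.raw) == len(self.background) == n):
            raise ValueError("profile arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.arclength_px) > 0):
            raise ValueError("arclength must be strictly increasing")

    @property
    def arclength_um(self) -> np.ndarray:
        return self.arclength_px * self.pixel_size

    @property
    def corrected(self) -> np.ndarray:
        """Background-corrected intensity; not clamped at zero."""
        return self.raw - self.background

    @property
    def span_px(self) -> float:
        if len(self.arclength_px) == 0:
            return 0.0
        return float(self.arclength_px[-1] - self.arclength_px[0])


def _resample_polyline(nodes: np.ndarray, step: float):
    nodes = np.asarray(nodes, dtype=float)
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(int(math.floor(total / step)) + 1, 1)
    t = np.arange(n) * step
    ys = np.interp(t, arc, nodes[:, 0])
    xs = np.interp(t, arc, nodes[:, 1])
    return t, np.column_stack([ys, xs])


def _local_directions(pts: np.ndarray) -> np.ndarray:
    """Unit tangents by central differences (forward/backward at the ends)."""
    d = np.gradient(pts, axis=0)
    norms = np.linalg.norm(d, axis=1)
    norms[norms == 0] = 1.0
    return d / norms[:, None]


def _window_mean(img: np.ndarray, center: np.ndarray) -> float:
    """Mean over the 3x3 window centred at (rounded) center."""
    r = int(round(center[0]))
    c = int(round(center[1]))
    h, w = img.shape
    r0, r1 = max(r - 1, 0), min(r + 2, h)
    c0, c1 = max(c - 1, 0), min(c + 2, w)
    return float(img[r0:r1, c0:c1].mean())


def _window_clear(f: np.ndarray, center: np.ndarray) -> bool:
    """True when the 3x3 window does not overlap segmented structure."""
    r = int(round(center[0]))
    c = int(round(center[1]))
    h, w = f.shape
    if not (1 <= r < h - 1 and 1 <= c < w - 1):
        return False
    return not f[r - 1:r + 2, c - 1:c + 2].any()


def sample_profile(img: Image2D, f: BinaryMask, neurite: Neurite | np.ndarray,
                   neuron_id: int = 0, neurite_id: int = 0,
                   step: float = 1.0, window_offset: float = 2.0,
                   max_offset: float = 15.0,
                   arc_offset: float | None = None) -> IntensityProfile:
    """Sample intensity and local background along one neurite.

    At each resampled point the raw value is the bilinear interpolation of
    the image; the background is the mean of a pair of 3x3 windows on the
    perpendicular to the local direction, centred ``window_offset`` px
    beyond the local structure edge on each side.  A window overlapping
    foreground is pushed outward (up to ``max_offset`` px beyond the edge);
    if only one side clears, that window alone is used; if neither does,
    the global robust background (median over background pixels) is used.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if isinstance(neurite, Neurite):
        nodes = neurite.nodes
        arc0 = neurite.arclength[0] if arc_offset is None else arc_offset
    else:
        nodes = np.asarray(neurite, dtype=float)
        arc0 = 0.0 if arc_offset is None else arc_offset
    if len(nodes) < 2:
        t = np.zeros(1)
        pts = nodes.reshape(1, 2)
    else:
        t, pts = _resample_polyline(nodes, step)
    pixels = np.asarray(img.pixels, dtype=float)
    raw = ndi.map_coordinates(pixels, [pts[:, 0], pts[:, 1]], order=1,
                              mode="nearest")
    tangents = _local_directions(pts) if len(pts) > 1 else np.array([[0.0, 1.0]])
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])

    bg_pixels = pixels[~f.f]
    global_bg = float(np.median(bg_pixels)) if bg_pixels.size else 0.0

    background = np.empty(len(pts))
    for i, (p, n) in enumerate(zip(pts, normals)):
        means = []
        for sgn in (+1.0, -1.0):
            # march to the structure edge along the normal
            edge = 0.0
            h, w = f.shape
            while edge < max_offset:
                q = p + sgn * (edge + 1.0) * n
                r, c = int(round(q[0])), int(round(q[1]))
                if not (0 <= r < h and 0 <= c < w) or not f.f[r, c]:
                    break
                edge += 1.0
            # window centre starts offset past the edge (+1 for the 3x3
            # half-width) and is pushed outward until clear of structure
            off = edge + window_offset + 1.0
            found = None
            while off <= edge + max_offset:
                center = p + sgn * off * n
                if _window_clear(f.f, center):
                    found = _window_mean(pixels, center)
                    break
                off += 1.0
            if found is not None:
                means.append(found)
        if means:
            background[i] = float(np.mean(means))
        else:
            background[i] = global_bg
    return IntensityProfile(
        neuron_id=neuron_id, neurite_id=neurite_id,
        arclength_px=arc0 + t, raw=np.asarray(raw, dtype=float),
        background=background, pixel_size=img.pixel_size)


# ---------------------------------------------------------------------------
# AIS metrics
# ---------------------------------------------------------------------------

def _gauss(x, H, mu, sigma):
    return H * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))


@dataclass
class AISMetrics:
    """AIS heterogeneity and polarity statistics of one neuron.

    ``A_ais`` is the trapezoidal integral of the corrected axon profile
    over the first ``interval_px`` of arclength (intensity * px); ``V_ais``
    its variance; (H, mu, sigma) the least-squares Gaussian fit; ``A_den``
    the mean dendritic integral over the same interval; ``R_AD`` the
    polarity ratio A_ais / A_den (undefined when A_den <= 0).
    """

    neuron_id: int
    A_ais: float
    V_ais: float
    H: float
    mu: float
    sigma: float
    A_den: float
    R_AD: float | None
    fit_ok: bool
    interval_px: int = AIS_INTERVAL_PX


def _interval_arrays(profile: IntensityProfile, interval_px: int):
    arc = profile.arclength_px - profile.arclength_px[0]
    sel = arc <= interval_px
    return arc[sel], profile.corrected[sel]


def ais_metrics(profile_axon: IntensityProfile,
                profiles_dendrites: list[IntensityProfile],
                interval_px: int = AIS_INTERVAL_PX,
                neuron_id: int | None = None) -> AISMetrics:
    """AIS statistics from an axon profile and two dendrite profiles.

    All profiles must span at least ``interval_px`` of arclength.  The
    Gaussian fit is initialized at (max, argmax, interval/6), with sigma
    bounded in [1, interval]; non-convergence flags ``fit_ok = False``.
    """
    if profile_axon.span_px < interval_px:
        raise ValueError("axon profile shorter than the AIS interval")
    if len(profiles_dendrites) != 2:
        raise ValueError("exactly two dendrite profiles are required")
    for p in profiles_dendrites:
        if p.span_px < interval_px:
            raise ValueError("dendrite profile shorter than the AIS interval")

    x, y = _interval_arrays(profile_axon, interval_px)
    a_ais = float(np.trapezoid(y, x))
    v_ais = float(np.var(y))

    H = mu = sigma = float("nan")
    fit_ok = False
    if np.any(y != 0):
        p0 = (max(float(y.max()), 1e-6), float(x[int(np.argmax(y))]),
              interval_px / 6.0)
        try:
            popt, _ = curve_fit(
                _gauss, x, y, p0=p0,
                bounds=([0.0, 0.0, 1.0],
                        [np.inf, float(interval_px), float(interval_px)]),
                xtol=1e-8, maxfev=10000)
            H, mu, sigma = (float(v) for v in popt)
            fit_ok = True
        except RuntimeError:
            pass

    dens = []
    for p in profiles_dendrites:
        xd, yd = _interval_arrays(p, interval_px)
        dens.append(float(np.trapezoid(yd, xd)))
    a_den = float(np.mean(dens))
    r_ad = a_ais / a_den if a_den > 0 else None
    return AISMetrics(
        neuron_id=profile_axon.neuron_id if neuron_id is None else neuron_id,
        A_ais=a_ais, V_ais=v_ais, H=H, mu=mu, sigma=sigma,
        A_den=a_den, R_AD=r_ad, fit_ok=fit_ok, interval_px=interval_px)


def identify_axon(tree: NeuronTree, profiles: list[IntensityProfile],
                  interval_px: int = AIS_INTERVAL_PX) -> int:
    """Pick the axon: the neurite with the highest mean corrected target-
    channel intensity over its first ``interval_px`` (Nav enrichment at the
    AIS).  Returns the neurite id; raises if no profile spans the interval.
    """
    best_id, best_val = None, -np.inf
    for p in profiles:
        if p.span_px < interval_px:
            continue
        _, y = _interval_arrays(p, interval_px)
        val = float(np.mean(y))
        if val > best_val:
            best_id, best_val = p.neurite_id, val
    if best_id is None:
        raise ValueError("no neurite spans the AIS interval; no axon visible")
    return best_id


def select_dendrites(tree: NeuronTree, profiles: list[IntensityProfile],
                     axon_id: int, interval_px: int = AIS_INTERVAL_PX
                     ) -> list[IntensityProfile]:
    """The two non-axon neurites whose mean radius is closest to the axon's
    (dendrites of comparable thickness), among those spanning the interval."""
    axon_radius = float(np.mean(tree.neurites[axon_id].radii))
    cands = [p for p in profiles
             if p.neurite_id != axon_id and p.span_px >= interval_px]
    if len(cands) < 2:
        raise ValueError("fewer than two dendrites span the AIS interval")
    cands.sort(key=lambda p: (
        abs(float(np.mean(tree.neurites[p.neurite_id].radii)) - axon_radius),
        p.neurite_id))
    return cands[:2]


def neuron_ais_metrics(tree: NeuronTree, target: Image2D, f: BinaryMask,
                       interval_px: int = AIS_INTERVAL_PX,
                       axon_id: int | None = None,
                       step: float = 1.0) -> tuple[AISMetrics, list[IntensityProfile]]:
    """Profile every neurite of a traced neuron and compute its AIS metrics.

    ``axon_id`` overrides the automatic axon identification.
    """
    profiles = [
        sample_profile(target, f, nr, neuron_id=tree.neuron_id,
                       neurite_id=j, step=step)
        for j, nr in enumerate(tree.neurites)
    ]
    if axon_id is None:
        axon_id = identify_axon(tree, profiles, interval_px)
    axon_profile = next(p for p in profiles if p.neurite_id == axon_id)
    dendrites = select_dendrites(tree, profiles, axon_id, interval_px)
    m = ais_metrics(axon_profile, dendrites, interval_px,
                    neuron_id=tree.neuron_id)
    return m, profiles


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

METRIC_COLUMNS = ("A_ais", "V_ais", "H", "R_AD")


def metrics_frame(metrics: list[AISMetrics], group: str | None = None
                  ) -> pd.DataFrame:
    """Tidy DataFrame of per-neuron AIS metrics."""
    rows = []
    for m in metrics:
        rows.append({
            "neuron_id": m.neuron_id, "A_ais": m.A_ais, "V_ais": m.V_ais,
            "H": m.H, "mu": m.mu, "sigma": m.sigma, "A_den": m.A_den,
            "R_AD": np.nan if m.R_AD is None else m.R_AD,
            "fit_ok": m.fit_ok, "group": group,
        })
    return pd.DataFrame(rows)


def compare_groups(metrics_a: list[AISMetrics] | pd.DataFrame,
                   metrics_b: list[AISMetrics] | pd.DataFrame,
                   columns=METRIC_COLUMNS) -> pd.DataFrame:
    """Two-tailed two-sample t-tests per AIS metric between two groups.

    Returns a DataFrame indexed by metric with columns (t, df, p,
    mean_a, mean_b).  Requires at least two neurons per group.
    """
    fa = metrics_a if isinstance(metrics_a, pd.DataFrame) \
        else metrics_frame(metrics_a)
    fb = metrics_b if isinstance(metrics_b, pd.DataFrame) \
        else metrics_frame(metrics_b)
    if len(fa) < 2 or len(fb) < 2:
        raise ValueError("need at least two neurons per group")
    rows = {}
    for col in columns:
        a = fa[col].dropna().to_numpy(dtype=float)
        b = fb[col].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"metric {col}: fewer than two finite values")
        res = ttest_ind(a, b)
        rows[col] = {
            "t": float(res.statistic),
            "df": float(len(a) + len(b) - 2),
            "p": float(res.pvalue),
            "mean_a": float(a.mean()),
            "mean_b": float(b.mean()),
        }
    return pd.DataFrame(rows).T


def gaussian_area(H: float, mu: float, sigma: float,
                  interval_px: float = AIS_INTERVAL_PX) -> float:
    """Closed-form integral of g over [0, interval]: H sigma sqrt(2 pi)
    (Phi((interval - mu)/sigma) - Phi(-mu/sigma))."""
    from scipy.stats import norm
    return H * sigma * math.sqrt(2 * math.pi) * (
        norm.cdf((interval_px - mu) / sigma) - norm.cdf(-mu / sigma))
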