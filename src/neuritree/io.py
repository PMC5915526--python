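"""Image, morphology and profile I/O plus stack-to-2D projection.

Confocal stacks are thin along z (typically 10-30 optical sections), so the
pipeline works on 2D projections: the maximum intensity projection (MIP, the
default for tracing) or the average intensity projection (AIP).  Morphologies
are written as standard 7-column SWC with pixel coordinates scaled to
micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .tree import Neurite, NeuronTree

DEFAULT_PIXEL_SIZE_UM = 0.28

# SWC structure identifiers (standard): 1 soma, 2 axon, 3 dendrite, 0 undefined
_LABEL_TO_SWC = {"axon": 2, "dendrite": 3, "unassigned": 0}
_SWC_TO_LABEL = {v: k for k, v in _LABEL_TO_SWC.items()}


@dataclass
class ImageStack:
    """Single-channel confocal z-stack with acquisition metadata.

    voxels are indexed (z, y, x); intensities must be finite and >= 0.
    """

    voxels: np.ndarray
    channel: str = "0"
    pixel_size_xy: float = DEFAULT_PIXEL_SIZE_UM
    z_step: float = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty (z, y, x) array")
        if not np.all(np.isfinite(self.voxels)) or self.voxels.min() < 0:
            raise ValueError("intensities must be finite and non-negative")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class Image2D:
    """Single-channel 2D raster, the working unit after projection."""

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    channel: str = "0"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D (y, x) array")
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise ValueError("intensities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def project_mip(stack: ImageStack) -> Image2D:
    """Maximum intensity projection: per pixel, the max over all z slices."""
    return Image2D(
        pixels=stack.voxels.max(axis=0),
        pixel_size=stack.pixel_size_xy,
        channel=stack.channel,
    )


def project_aip(stack: ImageStack) -> Image2D:
    """Average intensity projection: per pixel, the mean over all z slices."""
    return Image2D(
        pixels=stack.voxels.mean(axis=0),
        pixel_size=stack.pixel_size_xy,
        channel=stack.channel,
    )


# ---------------------------------------------------------------------------
# TIFF
# ---------------------------------------------------------------------------

def read_tiff(path: str | Path, pixel_size_xy: float = DEFAULT_PIXEL_SIZE_UM,
              z_step: float = 1.0) -> list[ImageStack]:
    """Read a TIFF into one ``ImageStack`` per channel.

    Accepted layouts: 2D (y, x) -> one single-slice stack; 3D (z, y, x) ->
    one stack; 4D (c, z, y, x) -> one stack per channel.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 3:
        return [ImageStack(data, channel="0", pixel_size_xy=pixel_size_xy,
                           z_step=z_step)]
    if data.ndim == 4:
        return [
            ImageStack(data[c], channel=str(c), pixel_size_xy=pixel_size_xy,
                       z_step=z_step)
            for c in range(data.shape[0])
        ]
    raise ValueError(f"unsupported TIFF dimensionality {data.ndim} in {path}")


def write_tiff(stacks: ImageStack | list[ImageStack], path: str | Path) -> None:
    """Write one stack as (z, y, x) pages or several as a (c, z, y, x) TIFF."""
    path = Path(path)
    if isinstance(stacks, ImageStack):
        tifffile.imwrite(path, stacks.voxels)
    else:
        data = np.stack([s.voxels for s in stacks], axis=0)
        tifffile.imwrite(path, data)


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean or integer label mask as PNG (.png) or NPY (.npy)."""
    path = Path(path)
    mask = np.asarray(mask)
    if path.suffix == ".npy":
        np.save(path, mask)
    elif path.suffix == ".png":
        if mask.dtype == bool:
            iio.imwrite(path, (mask.astype(np.uint8)) * 255)
        else:
            if mask.max(initial=0) > np.iinfo(np.uint16).max:
                raise ValueError("label mask exceeds uint16 range for PNG")
            iio.imwrite(path, mask.astype(np.uint16))
    else:
        raise ValueError(f"unsupported mask format {path.suffix!r}")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask written by :func:`write_mask`; PNG binary masks -> bool."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"mask file not found: {path}")
    if path.suffix == ".npy":
        return np.load(path)
    arr = np.asarray(iio.imread(path))
    if arr.dtype == np.uint8:
        return arr > 0
    return arr.astype(np.int64)


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def write_swc(tree: NeuronTree, path: str | Path,
              pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> None:
    """Write a neuron tree as standard 7-column SWC.

    One sample per node; internal (row, col) pixel coordinates are written as
    (x, y, z=0) in micrometres (x = col * pixel_size, y = row * pixel_size).
    The soma centroid is the single root sample (type 1, parent -1); each
    neurite chain attaches either to the root or to its branch-point node.
    """
    tree.validate()
    path = Path(path)
    lines = ["# id type x y z radius parent",
             f"# pixel_size_um {pixel_size:.6g}"]

    def fmt(i: int, t: int, rc: np.ndarray, radius: float, parent: int) -> str:
        x = rc[1] * pixel_size
        y = rc[0] * pixel_size
        return f"{i} {t} {x:.4f} {y:.4f} 0.0000 {radius:.4f} {parent}"

    soma_radius_um = max(tree.soma_radius, 1.0) * pixel_size
    lines.append(fmt(1, 1, tree.root, soma_radius_um, -1))
    next_id = 2
    # swc id of node (neurite_idx, node_idx)
    node_ids: dict[tuple[int, int], int] = {}
    for ni, neurite in enumerate(tree.neurites):
        swc_type = _LABEL_TO_SWC[neurite.label]
        for j in range(neurite.n_nodes):
            if j == 0:
                parent = 1 if neurite.parent is None else node_ids[neurite.parent]
            else:
                parent = node_ids[(ni, j - 1)]
            radius_um = max(neurite.radii[j], 0.5) * pixel_size
            lines.append(fmt(next_id, swc_type, neurite.nodes[j], radius_um, parent))
            node_ids[(ni, j)] = next_id
            next_id += 1
    path.write_text("\n".join(lines) + "\n")


def read_swc(path: str | Path,
             pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> NeuronTree:
    """Read an SWC file written by :func:`write_swc` back into a tree.

    Reconstructs neurites by walking child chains from the root; branch
    points become sub-branch parent pointers, so topology, coordinates,
    radii and labels round-trip exactly (up to the 4-decimal SWC format).
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"SWC file not found: {path}")
    samples: dict[int, tuple[int, float, float, float, int]] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        sid, stype = int(parts[0]), int(parts[1])
        x, y, radius = float(parts[2]), float(parts[3]), float(parts[5])
        parent = int(parts[6])
        samples[sid] = (stype, x, y, radius, parent)

    roots = [sid for sid, s in samples.items() if s[4] == -1]
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root in {path}, got {len(roots)}")
    root_id = roots[0]
    children: dict[int, list[int]] = {sid: [] for sid in samples}
    for sid, s in samples.items():
        if s[4] != -1:
            if s[4] not in samples:
                raise ValueError(f"sample {sid} references missing parent {s[4]}")
            children[s[4]].append(sid)
    for sid in children:
        children[sid].sort()

    def to_rc(s: tuple) -> np.ndarray:
        return np.array([s[2] / pixel_size, s[1] / pixel_size])

    root_s = samples[root_id]
    tree = NeuronTree(
        neuron_id=0,
        root=to_rc(root_s),
        soma_radius=root_s[3] / pixel_size,
    )
    # Walk chains: each child of the root (or of a branch node) starts a neurite.
    # (swc_id, parent_ref) where parent_ref is None (soma) or (neurite, node)
    stack: list[tuple[int, tuple[int, int] | None, float]] = [
        (c, None, 0.0) for c in reversed(children[root_id])
    ]
    while stack:
        sid, parent_ref, arc0 = stack.pop()
        nodes, radii = [], []
        swc_type = samples[sid][0]
        cur = sid
        while True:
            s = samples[cur]
            nodes.append(to_rc(s))
            radii.append(s[3] / pixel_size)
            kids = children[cur]
            if len(kids) == 1:
                cur = kids[0]
            else:
                break
        nodes_arr = np.asarray(nodes)
        steps = np.linalg.norm(np.diff(nodes_arr, axis=0), axis=1)
        arclength = arc0 + np.concatenate([[0.0], np.cumsum(steps)])
        # first node carries a positive offset from its origin
        if parent_ref is None:
            origin = tree.root
        else:
            origin = tree.neurites[parent_ref[0]].nodes[parent_ref[1]]
        arclength = arclength + np.linalg.norm(nodes_arr[0] - origin)
        neurite = Neurite(
            nodes=nodes_arr,
            arclength=arclength,
            radii=np.asarray(radii),
            parent=parent_ref,
            label=_SWC_TO_LABEL.get(swc_type, "unassigned"),
        )
        tree.neurites.append(neurite)
        ni = len(tree.neurites) - 1
        for kid in reversed(children[cur]):
            stack.append((kid, (ni, len(nodes) - 1), float(arclength[-1])))
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

PROFILE_CSV_COLUMNS = [
    "neuron_id", "neurite_id", "arclength_px", "arclength_um",
    "raw", "background", "corrected",
]


def write_profile_csv(profiles, path: str | Path) -> None:
    """Write intensity profiles (one or a list) to a tidy CSV."""
    from .profiles import IntensityProfile  # local import: avoid cycle

    if isinstance(profiles, IntensityProfile):
        profiles = [profiles]
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "neuron_id": p.neuron_id,
            "neurite_id": p.neurite_id,
            "arclength_px": p.arclength_px,
            "arclength_um": p.arclength_um,
            "raw": p.raw,
            "background": p.background,
            "corrected": p.corrected,
        }))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=PROFILE_CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_profile_csv(path: str | Path) -> pd.DataFrame:
    """Read a profile CSV into a DataFrame with the standard columns."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"profile CSV not found: {path}")
    df = pd.read_csv(path)
    missing = set(PROFILE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV {path} missing columns {sorted(missing)}")
    return df
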