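"""Rooted-tree representation of a traced neuron.

A neuron is modelled as a directed rooted tree: the soma is the root and
every neurite node has exactly one path back to it.  Neurites are stored as
ordered node sequences (row, col) with cumulative arclength from the soma;
sub-branches point at their parent (neurite index, node index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NEURITE_LABELS = ("axon", "dendrite", "unassigned")


@dataclass
class Neurite:
    """One ordered trace from its origin (soma boundary or branch point) outward.

    Parameters
    ----------
    nodes : (n, 2) float array
        Ordered (row, col) positions, starting at the neurite origin.
    arclength : (n,) float array
        Cumulative Euclidean polyline length measured from the soma boundary
        start point (branches inherit the arclength at their branch point).
    radii : (n,) float array
        Local half-width estimate at each node (clearance radius), pixels.
    parent : tuple[int, int] or None
        ``(neurite_index, node_index)`` of the branch point for sub-branches;
        ``None`` for neurites emanating directly from the soma.
    label : str
        One of ``axon | dendrite | unassigned``.
    """

    nodes: np.ndarray
    arclength: np.ndarray
    radii: np.ndarray
    parent: tuple[int, int] | None = None
    label: str = "unassigned"

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 2)
        self.arclength = np.asarray(self.arclength, dtype=float).ravel()
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        if len(self.arclength) != len(self.nodes):
            raise ValueError("arclength and nodes must have equal length")
        if len(self.radii) != len(self.nodes):
            raise ValueError("radii and nodes must have equal length")
        if self.label not in NEURITE_LABELS:
            raise ValueError(f"unknown neurite label {self.label!r}")
        if len(self.arclength) > 1 and not np.all(np.diff(self.arclength) > 0):
            raise ValueError("arclength must be strictly increasing")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def length(self) -> float:
        """Arclength span covered by this neurite (px)."""
        if self.n_nodes == 0:
            return 0.0
        return float(self.arclength[-1] - self.arclength[0])


@dataclass
class NeuronTree:
    """Directed rooted tree for one neuron: soma root plus traced neurites."""

    neuron_id: int
    root: np.ndarray  # (row, col) soma centroid
    neurites: list[Neurite] = field(default_factory=list)
    soma_radius: float = 0.0

    def __post_init__(self) -> None:
        self.root = np.asarray(self.root, dtype=float).ravel()
        if self.root.shape != (2,):
            raise ValueError("root must be a (row, col) pair")

    @property
    def n_neurites(self) -> int:
        return len(self.neurites)

    @property
    def n_nodes(self) -> int:
        """Total node count including the root."""
        return 1 + sum(n.n_nodes for n in self.neurites)

    def validate(self) -> None:
        """Check the rooted-tree invariants; raise ``ValueError`` on violation.

        Every sub-branch must point at an earlier neurite (no cycles among
        parent pointers) and arclength must strictly increase along each
        neurite.
        """
        for i, neurite in enumerate(self.neurites):
            if neurite.parent is not None:
                pi, pj = neurite.parent
                if not (0 <= pi < len(self.neurites)) or pi >= i:
                    raise ValueError(
                        f"neurite {i} has parent pointer {neurite.parent} that "
                        "does not reference an earlier neurite"
                    )
                if not (0 <= pj < self.neurites[pi].n_nodes):
                    raise ValueError(f"neurite {i} parent node index out of range")
            if neurite.n_nodes > 1 and not np.all(np.diff(neurite.arclength) > 0):
                raise ValueError(f"neurite {i} arclength not strictly increasing")

    def all_nodes(self) -> np.ndarray:
        """Stack of all neurite node positions, (n, 2); empty if soma-only."""
        if not self.neurites:
            return np.empty((0, 2))
        return np.vstack([n.nodes for n in self.neurites])
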