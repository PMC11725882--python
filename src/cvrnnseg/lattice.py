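"""Topographic lattice geometry and distance-dependent recurrent connectivity.

Nodes live on an ``n_side x n_side`` square grid, one node per image pixel,
indexed row-major.  Coordinates are normalised to the unit square so that the
spatial scale ``sigma`` of the Gaussian connection kernel is dimensionless and
independent of grid size: on a 32-grid adjacent nodes sit 1/31 apart, which is
commensurate with the local kernel scale sigma = 0.0313 used by the
segmentation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "LatticeSpec",
    "KernelParams",
    "ConnectivityMatrix",
    "build_lattice",
    "gaussian_adjacency",
    "mask_background",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the square node lattice.

    Attributes
    ----------
    n_side : int
        Side length; the lattice has ``n_side ** 2`` nodes.
    coords : ndarray, shape (n_nodes, 2)
        (row, col) positions scaled to [0, 1], row-major node order.
    distances : ndarray, shape (n_nodes, n_nodes)
        Pairwise Euclidean distances in normalised units.
    """

    n_side: int
    coords: np.ndarray
    distances: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.n_side**2

    def node_index(self, row: int, col: int) -> int:
        """Row-major (row, col) -> flat node index."""
        return row * self.n_side + col

    def node_coords(self, index: int) -> tuple[int, int]:
        """Flat node index -> (row, col)."""
        return divmod(index, self.n_side)


def build_lattice(n_side: int) -> LatticeSpec:
    """Construct the normalised square lattice and its distance matrix.

    Coordinates are ``(row / (n_side - 1), col / (n_side - 1))`` so the grid
    spans the unit square regardless of resolution.
    """
    if n_side < 2:
        raise ValueError(f"lattice side length must be >= 2, got {n_side}")
    rows, cols = np.divmod(np.arange(n_side**2), n_side)
    coords = np.column_stack([rows, cols]).astype(float) / (n_side - 1)
    distances = cdist(coords, coords)
    return LatticeSpec(n_side=n_side, coords=coords, distances=distances)


@dataclass(frozen=True)
class KernelParams:
    """Parameters of the Gaussian connection kernel.

    ``alpha`` is the peak connection strength (the weight at zero distance),
    ``sigma`` the spatial decay scale in normalised grid units, and
    ``epsilon`` a global coupling gain applied when the recurrent matrix is
    folded into the system matrix.  Larger epsilon shortens the usable
    transient by accelerating synchronisation; the default folds all scaling
    into alpha.
    """

    alpha: float
    sigma: float
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "sigma", "epsilon"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value}")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Real symmetric recurrent weight matrix with an optional node mask.

    ``masked`` flags nodes whose rows and columns have been zeroed and which
    must not be evolved by the dynamics (used to remove the background in the
    second pipeline layer).
    """

    weights: np.ndarray
    params: KernelParams
    masked: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.masked is None:
            object.__setattr__(
                self, "masked", np.zeros(self.weights.shape[0], dtype=bool)
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def active(self) -> np.ndarray:
        """Boolean mask of nodes that participate in the dynamics."""
        return ~self.masked


def gaussian_adjacency(
    lattice: LatticeSpec, params: KernelParams
) -> ConnectivityMatrix:
    """Distance-dependent weights ``a_ij = alpha * exp(-d_ij^2 / (2 sigma^2))``.

    The kernel is applied to every pair including the diagonal (``a_ii =
    alpha``); the self-connection is kept because the recurrence never
    excludes it.
    """
    weights = params.alpha * np.exp(
        -(lattice.distances**2) / (2.0 * params.sigma**2)
    )
    weights = (weights + weights.T) / 2.0  # symmetrise away rounding noise
    return ConnectivityMatrix(weights=weights, params=params)


def mask_background(
    connectivity: ConnectivityMatrix, background: np.ndarray
) -> ConnectivityMatrix:
    """Zero the rows and columns of background nodes.

    Masked nodes are disconnected and flagged so the dynamics modules skip
    them entirely; masking is cumulative with any pre-existing mask.
    """
    background = np.asarray(background, dtype=bool)
    if background.shape != (connectivity.n_nodes,):
        raise ValueError(
            f"mask length {background.shape} does not match "
            f"{connectivity.n_nodes} nodes"
        )
    masked = connectivity.masked | background
    if masked.all():
        raise ValueError("degenerate mask: every node would be removed")
    weights = connectivity.weights.copy()
    weights[masked, :] = 0.0
    weights[:, masked] = 0.0
    return replace(connectivity, weights=weights, masked=masked)
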