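"""The complex-valued linear recurrent network and its exact spectral solution.

The network state is a complex vector x(k) evolved by the linear map

    x(k+1) = B x(k),      B = diag(i * omega) + epsilon * A,

where A is the real, symmetric, distance-dependent recurrent weight matrix
and omega holds per-node intrinsic frequencies driven by image pixels.  All
computation lives in the phases Arg x(k) during the transient; amplitudes
eventually diverge or vanish, so iteration optionally rescales the state by a
positive real scalar each step, which leaves every phase untouched.

Because the map is linear, the trajectory admits the closed form

    x(k) = B^k x(0) = sum_i  lambda_i^k (r_i^T x(0)) v_i,

with (lambda_i, v_i) the eigenpairs of B and r_i^T the rows of the inverse
eigenvector matrix.  ``spectral_solve`` evaluates this sum exactly and
``truncated_solve`` keeps only the leading modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .lattice import ConnectivityMatrix

__all__ = [
    "InputDrive",
    "CvRnnSystem",
    "Trajectory",
    "SpectralDecomposition",
    "NumericRangeError",
    "IllConditionedEigenbasis",
    "encode_input",
    "compose_system",
    "random_init",
    "iterate",
    "spectral_decomposition",
    "spectral_solve",
    "truncated_solve",
]

#: overflow guard for unstabilised iteration
_AMPLITUDE_LIMIT = 1e150

#: eigenbasis condition number above which B is treated as near-defective
_EIG_COND_LIMIT = 1e8


class NumericRangeError(OverflowError):
    """State amplitude left the representable range during iteration."""


class IllConditionedEigenbasis(UserWarning):
    """The eigenvector matrix of B is too ill-conditioned to trust."""


@dataclass(frozen=True)
class InputDrive:
    """Per-node intrinsic frequencies (radians per step), row-major order."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float).ravel()
        if not np.all(np.isfinite(omega)):
            raise ValueError("omega contains non-finite values")
        object.__setattr__(self, "omega", omega)

    @property
    def n_nodes(self) -> int:
        return self.omega.size


def encode_input(image, omega_offset: float, omega_gain: float) -> InputDrive:
    """Map pixel intensities to node frequencies, ``omega = offset + gain * p``.

    Higher pixel intensities yield faster oscillation; the mapping depends
    only on intensity, never on pixel position.  ``image`` may be a ShapeImage
    or a bare 2-D array; pixels are flattened row-major to match the lattice
    node indexing.
    """
    pixels = np.asarray(getattr(image, "pixels", image), dtype=float)
    if not np.all(np.isfinite(pixels)):
        raise ValueError("image pixels must be finite")
    return InputDrive(omega=omega_offset + omega_gain * pixels.ravel())


@dataclass(frozen=True)
class CvRnnSystem:
    """Composite system matrix B = diag(i*omega) + epsilon * A.

    Nodes flagged as masked in the connectivity do not evolve: they are
    excluded from the active index set and their state stays identically zero.
    """

    matrix: np.ndarray  # complex, full n_nodes x n_nodes
    drive: InputDrive
    connectivity: ConnectivityMatrix
    epsilon: float

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def active(self) -> np.ndarray:
        return self.connectivity.active

    @property
    def active_matrix(self) -> np.ndarray:
        """B restricted to the evolving (unmasked) nodes."""
        idx = np.flatnonzero(self.active)
        return self.matrix[np.ix_(idx, idx)]


def compose_system(
    connectivity: ConnectivityMatrix, drive: InputDrive, epsilon: float = 1.0
) -> CvRnnSystem:
    """Assemble B from recurrent weights and the image-driven frequencies."""
    if drive.n_nodes != connectivity.n_nodes:
        raise ValueError(
            f"drive has {drive.n_nodes} nodes but connectivity has "
            f"{connectivity.n_nodes}"
        )
    matrix = epsilon * connectivity.weights.astype(complex)
    idx = np.arange(connectivity.n_nodes)
    matrix[idx, idx] += 1j * drive.omega
    # masked nodes are fully inert: no self-dynamics either
    masked = connectivity.masked
    if masked.any():
        matrix[masked, :] = 0.0
        matrix[:, masked] = 0.0
    return CvRnnSystem(
        matrix=matrix, drive=drive, connectivity=connectivity, epsilon=epsilon
    )


def random_init(n: int, seed: int) -> np.ndarray:
    """Random initial state: |x| ~ U[0, 1], Arg x ~ U[-pi, pi], i.i.d."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    amplitude = rng.uniform(0.0, 1.0, size=n)
    phase = rng.uniform(-np.pi, np.pi, size=n)
    return amplitude * np.exp(1j * phase)


@dataclass(frozen=True)
class Trajectory:
    """Complex states x(k), k = 0..K, with per-step phases and amplitudes.

    When stabilisation is on, ``states[k]`` is the true state divided by a
    positive real scalar whose log is accumulated in ``log_scale[k]``; phases
    are unaffected.  Masked nodes hold zeros throughout and their phases are
    reported as NaN.
    """

    states: np.ndarray  # (K+1, n_nodes) complex
    active: np.ndarray  # (n_nodes,) bool
    log_scale: np.ndarray  # (K+1,) cumulative log of stabilising divisors

    @cached_property
    def phases(self) -> np.ndarray:
        phases = np.angle(self.states)
        phases[:, ~self.active] = np.nan
        return phases

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.states)

    @property
    def n_steps(self) -> int:
        return self.states.shape[0] - 1

    def final_phases(self) -> np.ndarray:
        return self.phases[-1]

    def phase_window(self, k_start: int, k_end: int) -> np.ndarray:
        """Active-node phases over steps k_start..k_end inclusive, (F, T)."""
        if not 0 <= k_start <= k_end <= self.n_steps:
            raise ValueError(
                f"window [{k_start}, {k_end}] outside trajectory 0..{self.n_steps}"
            )
        return self.phases[k_start : k_end + 1, self.active].T


def iterate(
    system: CvRnnSystem,
    x0: np.ndarray,
    steps: int,
    stabilize: bool = True,
) -> Trajectory:
    """Evolve x(k+1) = B x(k) for ``steps`` steps.

    With ``stabilize`` each step divides the state by its maximum amplitude —
    a positive real scalar, so every phase is exactly preserved — and records
    the accumulated log scale.  Without it, amplitudes beyond float range
    raise :class:`NumericRangeError`.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x0 = np.asarray(x0, dtype=complex).ravel()
    if x0.size != system.n_nodes:
        raise ValueError(
            f"x0 has {x0.size} entries for a {system.n_nodes}-node system"
        )
    active = system.active
    sub = system.active_matrix
    x = x0[active].copy()

    states = np.zeros((steps + 1, system.n_nodes), dtype=complex)
    log_scale = np.zeros(steps + 1)
    states[0, active] = x
    for k in range(1, steps + 1):
        x = sub @ x
        log_scale[k] = log_scale[k - 1]
        if stabilize:
            peak = np.abs(x).max()
            if peak > 0:
                x = x / peak
                log_scale[k] += np.log(peak)
        elif not np.all(np.abs(x) < _AMPLITUDE_LIMIT):
            raise NumericRangeError(
                f"amplitude overflow at step {k}; rerun with stabilize=True "
                "(rescaling preserves all phases)"
            )
        states[k, active] = x
    return Trajectory(states=states, active=active, log_scale=log_scale)


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigenpairs of B, sorted by decreasing |lambda|.

    ``modes`` holds the right eigenvectors as columns, ``left`` the rows r_i^T
    of the inverse eigenvector matrix, so that
    ``x(k) = sum_i lambda_i**k * (left[i] @ x0) * modes[:, i]``.
    """

    lambdas: np.ndarray  # (m,) complex
    modes: np.ndarray  # (n, m) columns v_i
    left: np.ndarray  # (m, n) rows r_i^T
    active: np.ndarray  # (n_nodes,) bool; n = active.sum()
    condition: float = field(default=np.nan)

    @property
    def n_modes(self) -> int:
        return self.lambdas.size

    def coefficients(self, x0: np.ndarray, k: int) -> np.ndarray:
        """Mode coefficients mu_i(k) = lambda_i^k (r_i^T x(0))."""
        x0 = np.asarray(x0, dtype=complex).ravel()
        if x0.size == self.active.size:
            x0 = x0[self.active]
        return self.lambdas**k * (self.left @ x0)


def spectral_decomposition(system: CvRnnSystem) -> SpectralDecomposition:
    """Eigendecompose the active part of B, modes ordered by decreasing |lambda|.

    Warns (:class:`IllConditionedEigenbasis`) when the eigenvector matrix has
    condition number above 1e8, i.e. B is numerically near-defective.
    """
    sub = system.active_matrix
    lambdas, modes = np.linalg.eig(sub)
    order = np.argsort(-np.abs(lambdas), kind="stable")
    lambdas, modes = lambdas[order], modes[:, order]
    condition = np.linalg.cond(modes)
    if condition > _EIG_COND_LIMIT:
        warnings.warn(
            f"eigenbasis condition number {condition:.3g} exceeds "
            f"{_EIG_COND_LIMIT:.0e}; spectral reconstruction may be inaccurate",
            IllConditionedEigenbasis,
            stacklevel=2,
        )
    left = np.linalg.inv(modes)
    return SpectralDecomposition(
        lambdas=lambdas,
        modes=modes,
        left=left,
        active=system.active.copy(),
        condition=condition,
    )


def _embed_full(values: np.ndarray, active: np.ndarray) -> np.ndarray:
    full = np.zeros(active.size, dtype=complex)
    full[active] = values
    return full


def spectral_solve(
    system: CvRnnSystem,
    x0: np.ndarray,
    k: int,
    decomposition: SpectralDecomposition | None = None,
) -> np.ndarray:
    """Closed-form state x(k) = sum_i lambda_i^k (r_i^T x0) v_i.

    Falls back to direct iteration (with stabilisation, then undoing the
    recorded scale) when the eigenbasis is near-defective.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    x0 = np.asarray(x0, dtype=complex).ravel()
    if decomposition is None:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", IllConditionedEigenbasis)
            decomposition = spectral_decomposition(system)
        if any(issubclass(w.category, IllConditionedEigenbasis) for w in caught):
            warnings.warn(
                "falling back to direct iteration for near-defective B",
                IllConditionedEigenbasis,
                stacklevel=2,
            )
            if k == 0:
                out = x0.copy()
                out[~system.active] = 0.0
                return out
            traj = iterate(system, x0, k, stabilize=True)
            return traj.states[-1] * np.exp(traj.log_scale[-1])
    mu = decomposition.coefficients(x0, k)
    return _embed_full(decomposition.modes @ mu, decomposition.active)


def truncated_solve(
    system: CvRnnSystem,
    x0: np.ndarray,
    k: int,
    rank: int,
    decomposition: SpectralDecomposition | None = None,
    order: str = "eigenvalue",
) -> np.ndarray:
    """Low-rank approximation keeping only ``rank`` modes of the exact solution.

    ``order='eigenvalue'`` keeps the modes with largest |lambda| (the default,
    matching the descending-|lambda| mode ordering); ``order='contribution'``
    keeps those with largest |mu_i(k)| at the requested step.  Full rank
    reproduces :func:`spectral_solve` exactly.
    """
    if decomposition is None:
        decomposition = spectral_decomposition(system)
    if not 1 <= rank <= decomposition.n_modes:
        raise ValueError(
            f"rank must be in [1, {decomposition.n_modes}], got {rank}"
        )
    mu = decomposition.coefficients(x0, k)
    if order == "eigenvalue":
        keep = np.arange(rank)  # modes already sorted by |lambda|
    elif order == "contribution":
        keep = np.argsort(-np.abs(mu), kind="stable")[:rank]
    else:
        raise ValueError(f"unknown mode ordering {order!r}")
    partial = decomposition.modes[:, keep] @ mu[keep]
    return _embed_full(partial, decomposition.active)
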