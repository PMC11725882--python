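"""Interpretability tools: eigenmode phase maps, mode contributions, truncation.

Because the dynamics are linear, every traveling wave the network produces is
a superposition of eigenmodes of the system matrix B.  The argument of each
eigenvector, reshaped to the pixel grid, is the wave pattern that mode
imprints; the coefficient mu_i(k) = lambda_i^k (r_i^T x(0)) sets how strongly
it contributes at step k.  These maps make the segmentation computation
inspectable mode by mode, and quantify how well a low-rank truncation of the
exact solution reproduces the full phase field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CvRnnSystem,
    SpectralDecomposition,
    spectral_decomposition,
    spectral_solve,
    truncated_solve,
)

__all__ = [
    "EigenmodeMaps",
    "eigenmode_maps",
    "mode_contributions",
    "truncation_report",
    "phase_gradient_energy",
    "phase_coherence",
]


@dataclass(frozen=True)
class EigenmodeMaps:
    """Phase maps Arg(v_i) of the leading eigenvectors on the pixel grid.

    ``maps[i]`` is the n_side x n_side phase field of mode i (NaN on masked
    nodes); ``lambdas`` the matching eigenvalues, decreasing in |lambda|.
    """

    maps: np.ndarray  # (n_modes, n_side, n_side)
    lambdas: np.ndarray


def eigenmode_maps(
    system: CvRnnSystem,
    n_modes: int,
    decomposition: SpectralDecomposition | None = None,
) -> EigenmodeMaps:
    """Arguments of the top-``n_modes`` eigenvectors of B as pixel-grid maps."""
    if decomposition is None:
        decomposition = spectral_decomposition(system)
    if not 1 <= n_modes <= decomposition.n_modes:
        raise ValueError(
            f"n_modes must be in [1, {decomposition.n_modes}], got {n_modes}"
        )
    n_side = int(round(np.sqrt(system.n_nodes)))
    maps = np.full((n_modes, system.n_nodes), np.nan)
    active = decomposition.active
    for i in range(n_modes):
        maps[i, active] = np.angle(decomposition.modes[:, i])
    return EigenmodeMaps(
        maps=maps.reshape(n_modes, n_side, n_side),
        lambdas=decomposition.lambdas[:n_modes].copy(),
    )


def mode_contributions(
    decomposition: SpectralDecomposition, x0: np.ndarray, k_max: int
) -> np.ndarray:
    """|mu_i(k)| = |lambda_i|^k |r_i^T x(0)| for k = 0..k_max, shape (m, k_max+1).

    Each row is a geometric progression with ratio |lambda_i|; at large k the
    contribution ranking converges to the eigenvalue-magnitude ranking.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    mu0 = np.abs(decomposition.coefficients(x0, 0))
    growth = np.abs(decomposition.lambdas)[:, None] ** np.arange(k_max + 1)[None, :]
    return mu0[:, None] * growth


def _circular_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.abs(np.angle(np.exp(1j * (a - b))))


def phase_coherence(a: np.ndarray, b: np.ndarray) -> float:
    """Global circular correlation of two phase fields, in [0, 1].

    The mean resultant length of the pointwise phase difference: 1 when the
    fields agree up to a single global rotation, near 0 when unrelated.
    """
    return float(np.abs(np.mean(np.exp(1j * (np.asarray(a) - np.asarray(b))))))


def truncation_report(
    system: CvRnnSystem,
    x0: np.ndarray,
    k: int,
    ranks,
    order: str = "eigenvalue",
) -> dict[int, dict]:
    """Phase-field error of rank-m truncations against the exact solution.

    For each rank, reports the mean and max circular distance between the
    phases of the truncated and exact states over active nodes, plus their
    global phase coherence.
    """
    decomposition = spectral_decomposition(system)
    exact = spectral_solve(system, x0, k, decomposition=decomposition)
    active = decomposition.active
    exact_phase = np.angle(exact[active])
    report: dict[int, dict] = {}
    for rank in ranks:
        approx = truncated_solve(
            system, x0, k, rank, decomposition=decomposition, order=order
        )
        approx_phase = np.angle(approx[active])
        err = _circular_distance(approx_phase, exact_phase)
        report[int(rank)] = {
            "mean_error": float(err.mean()),
            "max_error": float(err.max()),
            "coherence": phase_coherence(approx_phase, exact_phase),
        }
    return report


def phase_gradient_energy(phase_map: np.ndarray, mask: np.ndarray) -> float:
    """Mean circular phase-gradient magnitude over pixels inside ``mask``.

    Gradients are taken between lattice neighbours with both endpoints in the
    mask, wrapping differences to (-pi, pi]; used to quantify how strongly a
    mode's wave pattern is localised to an object versus the background.
    """
    phase_map = np.asarray(phase_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if phase_map.shape != mask.shape:
        raise ValueError("phase map and mask must have identical shape")
    grads = []
    for axis in (0, 1):
        diff = np.angle(
            np.exp(1j * (np.diff(phase_map, axis=axis)))
        )
        pair_mask = (
            mask[1:, :] & mask[:-1, :] if axis == 0 else mask[:, 1:] & mask[:, :-1]
        )
        valid = pair_mask & np.isfinite(diff)
        grads.append(np.abs(diff[valid]))
    grads = np.concatenate(grads) if grads else np.array([])
    return float(grads.mean()) if grads.size else np.nan
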