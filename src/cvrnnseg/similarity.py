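"""Phase-similarity embedding and clustering of node trajectories.

Nodes riding the same traveling wave keep a fixed phase relation over time.
The pairwise similarity

    s_jk = (1/T) * sum_t exp(i * (phi_j(t) - phi_k(t)))

is the complex inner product of the unit-modulus signals exp(i*phi): its
modulus is near 1 for a locked phase relation and near 0 for independent
dynamics, while its argument encodes the mean phase lag.  S is Hermitian with
unit diagonal, so its eigenvalues are real; projecting the real part of S onto
the real parts of its three leading eigenvectors gives each node a point in a
3-D similarity space where waves form separable clusters, labelled by K-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = [
    "SimilarityEmbedding",
    "similarity_matrix",
    "embed",
    "cluster",
    "pixel_accuracy",
]


@dataclass(frozen=True)
class SimilarityEmbedding:
    """Hermitian phase-similarity matrix with its spectral projection.

    ``matrix`` is F x F over the F participating nodes and ``window_length``
    the number of time points averaged.  After :func:`embed`, ``eigvals``
    holds the (real) eigenvalues sorted by decreasing absolute value and
    ``projection`` the F x 3 coordinates Re(S) @ [Re(z1) Re(z2) Re(z3)].
    """

    matrix: np.ndarray
    window_length: int
    eigvals: np.ndarray | None = None
    eigvecs: np.ndarray | None = None
    projection: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def similarity_matrix(phases: np.ndarray) -> SimilarityEmbedding:
    """Time-averaged complex inner product of unit-modulus phase signals.

    ``phases`` is F x T (radians).  The inner product is taken between the
    signals exp(i*phi(t)), not the raw phase values, which makes S Hermitian
    with unit diagonal and |s_jk| <= 1.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 2 or phases.shape[1] < 2:
        raise ValueError("phases must be F x T with T >= 2")
    if not np.all(np.isfinite(phases)):
        raise ValueError("phases contain non-finite values")
    signals = np.exp(1j * phases)
    T = phases.shape[1]
    S = (signals @ signals.conj().T) / T
    np.fill_diagonal(S, 1.0)  # |exp(i phi)| == 1 exactly, up to rounding
    return SimilarityEmbedding(matrix=S, window_length=T)


def embed(similarity: SimilarityEmbedding, n_vectors: int = 3) -> SimilarityEmbedding:
    """Project Re(S) onto the real parts of the leading eigenvectors of S.

    Eigenvalues of the Hermitian S are real; they are ordered by decreasing
    absolute value and the projection uses the first ``n_vectors`` (three,
    spanning the similarity space used for clustering).
    """
    S = similarity.matrix
    if S.shape[0] < n_vectors:
        raise ValueError(
            f"need at least {n_vectors} nodes to embed, got {S.shape[0]}"
        )
    eigvals, eigvecs = np.linalg.eigh(S)
    order = np.argsort(-np.abs(eigvals), kind="stable")
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    projection = S.real @ eigvecs[:, :n_vectors].real
    return SimilarityEmbedding(
        matrix=S,
        window_length=similarity.window_length,
        eigvals=eigvals,
        eigvecs=eigvecs,
        projection=projection,
    )


def cluster(
    projection: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    restarts: int = 20,
) -> np.ndarray:
    """K-means labels (0..K-1, arbitrary up to permutation) on the projection.

    Runs ``restarts`` initialisations and keeps the lowest within-cluster sum
    of squares; fully deterministic for a fixed seed.
    """
    projection = np.asarray(projection, dtype=float)
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if projection.shape[0] < n_clusters:
        raise ValueError(
            f"cannot form {n_clusters} clusters from {projection.shape[0]} points"
        )
    km = KMeans(
        n_clusters=n_clusters,
        n_init=restarts,
        random_state=seed,
    ).fit(projection)
    return km.labels_.astype(int)


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of pixels correct under the best bijection between label sets.

    All pixels count, background included.  The optimal one-to-one mapping
    between predicted and true ids is found by solving the assignment problem
    on the label confusion matrix (equivalent to exhaustive search over
    permutations).
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    pred_ids, pred_inv = np.unique(pred, return_inverse=True)
    true_ids, true_inv = np.unique(truth, return_inverse=True)
    confusion = np.zeros((pred_ids.size, true_ids.size), dtype=int)
    np.add.at(confusion, (pred_inv.ravel(), true_inv.ravel()), 1)
    rows, cols = linear_sum_assignment(confusion, maximize=True)
    return float(confusion[rows, cols].sum()) / pred.size
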