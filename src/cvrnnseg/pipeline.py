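"""Two-layer segmentation pipeline.

Layer 1 runs the network with a broad connection kernel: under broad coupling
the phases collapse onto two synchronised groups, one for background pixels
and one for object pixels, and thresholding the final phases at their circular
mean separates them.  Layer 2 disconnects the background nodes and reruns the
dynamics from a fresh random state with a local kernel, so each object carries
its own traveling wave; the phase-similarity embedding of a late time window
then clusters nodes into objects with K-means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import core, lattice, similarity
from .config import PipelineConfig, default_config
from .shapes import ShapeImage

__all__ = [
    "BackgroundSplit",
    "SegmentationResult",
    "Pipeline",
    "layer1_split",
    "layer2_waves",
    "segment",
]


@dataclass(frozen=True)
class BackgroundSplit:
    """Layer-1 partition of the node set.

    ``background`` and ``foreground`` are complementary boolean masks over the
    flattened grid; ``no_foreground`` flags the degenerate fully-synchronised
    case (e.g. a uniform image), in which everything counts as background.
    """

    background: np.ndarray
    layer1_final_phase: np.ndarray
    no_foreground: bool = False

    @property
    def foreground(self) -> np.ndarray:
        return ~self.background

    def background_grid(self, n_side: int) -> np.ndarray:
        return self.background.reshape(n_side, n_side)


@dataclass
class SegmentationResult:
    """Per-pixel labels (0 = background, 1..K = objects) with diagnostics."""

    labels: np.ndarray
    split: BackgroundSplit
    embedding: similarity.SimilarityEmbedding | None
    diagnostics: dict = field(default_factory=dict)

    def accuracy(self, truth: np.ndarray) -> float:
        """Permutation-matched pixel accuracy against a ground-truth grid."""
        return similarity.pixel_accuracy(self.labels, truth)


def _wrap(angles: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * angles))


class Pipeline:
    """Reusable two-layer segmenter; caches connectivity per image size.

    A single master seed per run is split deterministically into the layer-1
    initial state, the fresh layer-2 initial state and the K-means seed, so a
    (image, seed, config) triple fully determines the result.
    """

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or default_config()
        self._cache: dict[int, dict] = {}

    # -- connectivity caching -------------------------------------------------

    def _entry(self, n_side: int) -> dict:
        entry = self._cache.get(n_side)
        if entry is None:
            spec = lattice.build_lattice(n_side)
            entry = {
                "lattice": spec,
                "conn1": lattice.gaussian_adjacency(
                    spec, self.config.layer1.params
                ),
                "conn2": lattice.gaussian_adjacency(
                    spec, self.config.layer2.params
                ),
            }
            if not self.config.keep_diagonal:
                for key in ("conn1", "conn2"):
                    weights = entry[key].weights.copy()
                    np.fill_diagonal(weights, 0.0)
                    entry[key] = lattice.ConnectivityMatrix(
                        weights=weights, params=entry[key].params
                    )
            self._cache[n_side] = entry
        return entry

    def _seeds(self, seed: int) -> tuple[int, int, int]:
        children = np.random.SeedSequence(seed).spawn(3)
        return tuple(int(c.generate_state(1)[0] % 2**31) for c in children)

    def _drive(self, image: ShapeImage) -> core.InputDrive:
        enc = self.config.encoding
        return core.encode_input(image, enc.omega_offset, enc.omega_gain)

    # -- stages ---------------------------------------------------------------

    def layer1_split(self, image: ShapeImage, seed: int = 0) -> BackgroundSplit:
        """Broad-kernel run; threshold final phases at their circular mean.

        The group on each side of the mean is one synchronised set; the larger
        group is taken to be the background.  If the whole network has
        synchronised (peak angular deviation below ``min_phase_spread``) the
        image has no detectable foreground.
        """
        cfg = self.config.layer1
        entry = self._entry(image.n_side)
        system = core.compose_system(
            entry["conn1"], self._drive(image), cfg.params.epsilon
        )
        seed1 = cfg.init_seed if cfg.init_seed is not None else self._seeds(seed)[0]
        x0 = core.random_init(system.n_nodes, seed1)
        traj = core.iterate(system, x0, cfg.steps)
        phases = traj.final_phases()

        mean_angle = np.angle(np.mean(np.exp(1j * phases)))
        deviation = _wrap(phases - mean_angle)
        if np.abs(deviation).max() < self.config.min_phase_spread:
            return BackgroundSplit(
                background=np.ones(system.n_nodes, dtype=bool),
                layer1_final_phase=phases,
                no_foreground=True,
            )
        if self.config.background_rule == "two-means":
            points = np.column_stack([np.cos(phases), np.sin(phases)])
            groups = similarity.cluster(points, 2, seed=0, restarts=5) == 1
        elif self.config.background_rule == "mean-threshold":
            groups = deviation >= 0
        else:
            raise ValueError(
                f"unknown background rule {self.config.background_rule!r}"
            )
        if groups.all() or not groups.any():
            return BackgroundSplit(
                background=np.ones(system.n_nodes, dtype=bool),
                layer1_final_phase=phases,
                no_foreground=True,
            )
        background = groups if groups.sum() >= (~groups).sum() else ~groups
        return BackgroundSplit(background=background, layer1_final_phase=phases)

    def layer2_waves(
        self, image: ShapeImage, split: BackgroundSplit, seed: int = 0
    ) -> core.Trajectory:
        """Masked local-kernel run from a fresh random state.

        Background nodes are disconnected and not evolved; their states stay
        zero and their phases are excluded from all records.
        """
        if split.no_foreground or not split.foreground.any():
            raise ValueError("layer 2 requires a nonempty foreground")
        cfg = self.config.layer2
        entry = self._entry(image.n_side)
        masked = lattice.mask_background(entry["conn2"], split.background)
        system = core.compose_system(masked, self._drive(image), cfg.params.epsilon)
        seed2 = cfg.init_seed if cfg.init_seed is not None else self._seeds(seed)[1]
        x0 = core.random_init(system.n_nodes, seed2)
        return core.iterate(system, x0, cfg.steps)

    def segment(
        self, image: ShapeImage, k_objects: int, seed: int = 0
    ) -> SegmentationResult:
        """Full pipeline: split, masked waves, similarity embedding, K-means."""
        if k_objects < 1:
            raise ValueError("k_objects must be >= 1")
        split = self.layer1_split(image, seed=seed)
        n = image.n_side
        diagnostics: dict = {
            "seed": seed,
            "config": self.config.to_dict(),
            "n_foreground": int(split.foreground.sum()),
        }
        if split.no_foreground:
            diagnostics["status"] = "no foreground detected"
            return SegmentationResult(
                labels=np.zeros((n, n), dtype=int),
                split=split,
                embedding=None,
                diagnostics=diagnostics,
            )
        n_fg = int(split.foreground.sum())
        if n_fg < max(3, k_objects):
            diagnostics["status"] = (
                f"foreground too small to cluster ({n_fg} nodes)"
            )
            labels = np.zeros((n, n), dtype=int)
            labels.ravel()[split.foreground] = 1
            return SegmentationResult(
                labels=labels, split=split, embedding=None, diagnostics=diagnostics
            )

        traj = self.layer2_waves(image, split, seed=seed)
        phases = traj.phase_window(*self.config.layer2.phase_window)
        emb = similarity.embed(similarity.similarity_matrix(phases))
        kmeans_seed = self._seeds(seed)[2]
        fg_labels = similarity.cluster(
            emb.projection,
            k_objects,
            seed=kmeans_seed,
            restarts=self.config.kmeans_restarts,
        )
        labels = np.zeros((n, n), dtype=int)
        labels.ravel()[split.foreground] = fg_labels + 1
        inertia = sum(
            float(((emb.projection[fg_labels == c]
                    - emb.projection[fg_labels == c].mean(axis=0)) ** 2).sum())
            for c in range(k_objects)
        )
        diagnostics.update(
            status="ok",
            kmeans_seed=kmeans_seed,
            similarity_eigvals=emb.eigvals[: max(5, k_objects)].tolist(),
            kmeans_inertia=inertia,
            # per-step growth of the stabilisation ledger ~ spectral radius
            layer2_spectral_radius_est=float(
                np.exp(traj.log_scale[-1] - traj.log_scale[-2])
            ),
        )
        return SegmentationResult(
            labels=labels, split=split, embedding=emb, diagnostics=diagnostics
        )


# -- module-level convenience wrappers (one shared default pipeline) ----------

_default_pipeline: Pipeline | None = None


def _pipeline(config: PipelineConfig | None) -> Pipeline:
    global _default_pipeline
    if config is not None:
        return Pipeline(config)
    if _default_pipeline is None:
        _default_pipeline = Pipeline()
    return _default_pipeline


def layer1_split(
    image: ShapeImage, seed: int = 0, config: PipelineConfig | None = None
) -> BackgroundSplit:
    return _pipeline(config).layer1_split(image, seed=seed)


def layer2_waves(
    image: ShapeImage,
    split: BackgroundSplit,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> core.Trajectory:
    return _pipeline(config).layer2_waves(image, split, seed=seed)


def segment(
    image: ShapeImage,
    k_objects: int,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> SegmentationResult:
    return _pipeline(config).segment(image, k_objects, seed=seed)
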