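"""Generalized Procrustes analysis (GPA) and Procrustes distances/variances.

Superimposition removes translation (centroid to origin), size (centroid size
scaled to 1) and orientation (least-squares proper rotation, reflections
disallowed), leaving pure shape variation.  Full-Procrustes coordinates are
used directly downstream; no tangent-space projection is applied — at the
curvature magnitudes this package targets the two are numerically
indistinguishable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateConfigurationError, StructuralError
from .tps_io import Dataset, LandmarkConfiguration

logger = logging.getLogger(__name__)

__all__ = [
    "ShapeDataset",
    "centroid_size",
    "align_pair",
    "gpa",
    "procrustes_distance",
    "procrustes_variance",
]

#: consensus RMS change below which GPA iteration stops
GPA_TOL = 1e-10
GPA_MAX_ITER = 100


@dataclass
class ShapeDataset:
    """Procrustes shape coordinates for ``n`` specimens.

    Attributes
    ----------
    coords : (n, p, 2) array
        Aligned configurations, each with centroid at the origin and unit
        centroid size.
    centroid_sizes : (n,) array
        Centroid sizes of the original configurations, before scaling.
    ids, species : lists of per-specimen metadata.
    """

    coords: np.ndarray
    centroid_sizes: np.ndarray
    ids: list[str]
    species: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.centroid_sizes = np.asarray(self.centroid_sizes, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise StructuralError(f"coords must be (n, p, 2), got {self.coords.shape}")
        if not self.species:
            self.species = [None] * self.n_specimens

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def consensus(self) -> np.ndarray:
        """Mean shape, (p, 2)."""
        return self.coords.mean(axis=0)

    def flattened(self) -> np.ndarray:
        """(n, 2p) view of the aligned coordinates (x1, y1, x2, y2, ...)."""
        return self.coords.reshape(self.n_specimens, -1)

    def to_dataset(self) -> Dataset:
        """Repackage aligned coordinates as a plain :class:`Dataset`."""
        return Dataset(
            [
                LandmarkConfiguration(
                    specimen_id=i, coords=c, species=s
                )
                for i, c, s in zip(self.ids, self.coords, self.species)
            ]
        )


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    The standard geometric-morphometric size measure; scales linearly with the
    configuration (CS(k·X) = k·CS(X)).
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide; centroid size is 0")
    return cs


def _standardize(coords: np.ndarray) -> np.ndarray:
    """Center at the origin and scale to unit centroid size."""
    centered = coords - coords.mean(axis=0)
    cs = np.sqrt((centered**2).sum())
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide")
    return centered / cs


def _optimal_rotation(reference: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper (det = +1) rotation matrix R minimizing ||target @ R - reference||."""
    u, _, vt = np.linalg.svd(target.T @ reference)
    d = np.sign(np.linalg.det(u @ vt))
    # force a rotation, never a reflection
    correction = np.diag([1.0, d])
    return u @ correction @ vt


def align_pair(
    reference: LandmarkConfiguration | np.ndarray,
    target: LandmarkConfiguration | np.ndarray,
) -> np.ndarray:
    """Superimpose ``target`` on ``reference`` (translation, scale, rotation).

    Both are centered and scaled to unit centroid size; ``target`` is then
    rotated (proper rotation only) to minimize the summed squared distance to
    the standardized reference.  Returns the aligned (p, 2) target.
    """
    ref = reference.coords if isinstance(reference, LandmarkConfiguration) else np.asarray(reference, float)
    tgt = target.coords if isinstance(target, LandmarkConfiguration) else np.asarray(target, float)
    if ref.shape != tgt.shape:
        raise StructuralError(f"landmark mismatch: {ref.shape} vs {tgt.shape}")
    ref_s = _standardize(ref)
    tgt_s = _standardize(tgt)
    return tgt_s @ _optimal_rotation(ref_s, tgt_s)


def gpa(dataset: Dataset) -> ShapeDataset:
    """Generalized Procrustes analysis of a dataset.

    Iterative superimposition: standardize every configuration, rotate each to
    the current consensus, recompute the consensus, repeat until the consensus
    RMS change drops below 1e-10 (at most 100 iterations, with a warning on
    non-convergence).  Original centroid sizes are stored before scaling.
    """
    if dataset.n_specimens < 2:
        raise StructuralError("GPA needs at least 2 configurations")
    sizes = np.array([centroid_size(c) for c in dataset])
    shapes = np.stack([_standardize(c.coords) for c in dataset])
    consensus = shapes[0]
    for _ in range(GPA_MAX_ITER):
        shapes = np.stack([s @ _optimal_rotation(consensus, s) for s in shapes])
        new_consensus = _standardize(shapes.mean(axis=0))
        delta = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if delta < GPA_TOL:
            break
    else:
        warnings.warn("GPA did not converge within 100 iterations", stacklevel=2)
    # final rotation pass against the converged consensus
    shapes = np.stack([s @ _optimal_rotation(consensus, s) for s in shapes])
    return ShapeDataset(
        coords=shapes,
        centroid_sizes=sizes,
        ids=dataset.ids(),
        species=dataset.species(),
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two aligned shapes viewed as 2p-vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise StructuralError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm((a - b).ravel()))


def procrustes_variance(sds: ShapeDataset, per_landmark: bool = False):
    """Procrustes variance: mean squared distance to the consensus (divisor n−1).

    With ``per_landmark=True`` returns the p-vector of each landmark's
    contribution; the per-landmark values sum to the total exactly.
    """
    n = sds.n_specimens
    if n < 2:
        raise StructuralError("Procrustes variance needs n >= 2")
    dev = sds.coords - sds.consensus
    if per_landmark:
        return (dev**2).sum(axis=(0, 2)) / (n - 1)
    return float((dev**2).sum() / (n - 1))
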