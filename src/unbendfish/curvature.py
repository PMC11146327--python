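"""Index of curvature (IC) of an ordered body-axis landmark chain.

The body axis of a fish is traced by an ordered chain of landmarks from the
tip of the snout, along the vertebral column, to the posterior end of the
hypurals.  Postmortem arching makes the chain's arc length exceed its chord
(the straight snout-to-hypural distance); the index of curvature quantifies
the relative length reduction::

    IC = 1 - chord / arc = (arc - chord) / arc

IC is dimensionless and similarity-invariant, 0 for a straight monotone chain
and approaching 1 at the theoretical maximum of arching.  IC = 0.0137 reads
as a 1.37% reduction in standard length.  For comparison with literature that
reports the raw arc/chord ratio (>= 1), pass ``convention="ratio"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateConfigurationError, StructuralError
from .procrustes import ShapeDataset
from .tps_io import Dataset, LandmarkConfiguration

__all__ = [
    "AxisSpec",
    "CurvatureRecord",
    "arc_length",
    "chord_length",
    "curvature_index",
    "curvature_table",
]

#: default body-axis chain, 1-based landmark numbers:
#: snout tip (12) -> postcranial column start (15) -> vertebral
#: semilandmarks (16-19) -> posterior hypural margin (4)
DEFAULT_CHAIN = (12, 15, 16, 17, 18, 19, 4)


@dataclass(frozen=True)
class AxisSpec:
    """Ordered 1-based landmark indices tracing the body axis snout -> caudal end."""

    chain: tuple[int, ...] = DEFAULT_CHAIN

    def __post_init__(self) -> None:
        if len(self.chain) < 3:
            raise StructuralError("axis chain needs at least 3 landmarks")
        if len(set(self.chain)) != len(self.chain):
            raise StructuralError("axis chain indices must be distinct")
        if min(self.chain) < 1:
            raise StructuralError("axis chain indices are 1-based (>= 1)")
        object.__setattr__(self, "chain", tuple(int(i) for i in self.chain))

    def indices(self, p_total: int) -> np.ndarray:
        """0-based chain indices, validated against the configuration size."""
        if max(self.chain) > p_total:
            raise StructuralError(
                f"axis index {max(self.chain)} exceeds landmark count {p_total}"
            )
        return np.asarray(self.chain, dtype=int) - 1

    @classmethod
    def parse(cls, text: str) -> "AxisSpec":
        """Parse a comma-separated chain such as ``"12,15,16,17,18,19,4"``."""
        return cls(tuple(int(tok) for tok in text.split(",") if tok.strip()))


@dataclass(frozen=True)
class CurvatureRecord:
    """Arc, chord and index of curvature of one specimen's axis chain."""

    specimen_id: str
    arc: float
    chord: float
    ic: float


def _chain_coords(config: LandmarkConfiguration | np.ndarray, axis: AxisSpec) -> np.ndarray:
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    return coords[axis.indices(coords.shape[0])]


def arc_length(config: LandmarkConfiguration | np.ndarray, axis: AxisSpec) -> float:
    """Sum of Euclidean distances between consecutive chain landmarks."""
    pts = _chain_coords(config, axis)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        warnings.warn("coincident consecutive chain landmarks (zero-length segment)",
                      stacklevel=2)
    return float(seg.sum())


def chord_length(config: LandmarkConfiguration | np.ndarray, axis: AxisSpec) -> float:
    """Straight-line distance between the first and last chain landmarks."""
    pts = _chain_coords(config, axis)
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord == 0.0:
        raise DegenerateConfigurationError("chain endpoints coincide; chord is 0")
    return chord


def curvature_index(
    config: LandmarkConfiguration | np.ndarray,
    axis: AxisSpec,
    convention: str = "reduction",
) -> CurvatureRecord:
    """Index of curvature of one configuration.

    ``convention="reduction"`` (default) returns IC = 1 − chord/arc in [0, 1);
    ``convention="ratio"`` returns the raw arc/chord ratio (>= 1).
    """
    arc = arc_length(config, axis)
    chord = chord_length(config, axis)
    if arc == 0.0:
        raise DegenerateConfigurationError("axis chain has zero arc length")
    if convention == "reduction":
        ic = 1.0 - chord / arc
        # polyline chord can exceed arc only by roundoff
        ic = max(ic, 0.0)
    elif convention == "ratio":
        ic = arc / chord
    else:
        raise ValueError(f"unknown IC convention {convention!r}")
    sid = config.specimen_id if isinstance(config, LandmarkConfiguration) else ""
    return CurvatureRecord(specimen_id=sid, arc=arc, chord=chord, ic=ic)


def curvature_table(
    data: Dataset | ShapeDataset,
    axis: AxisSpec,
    convention: str = "reduction",
) -> list[CurvatureRecord]:
    """Per-specimen curvature records for a raw or Procrustes-aligned dataset.

    IC is a ratio of lengths, so the values are identical (to roundoff)
    whether computed on raw or aligned coordinates.
    """
    if isinstance(data, ShapeDataset):
        return [
            curvature_index(
                LandmarkConfiguration(specimen_id=i, coords=c), axis, convention
            )
            for i, c in zip(data.ids, data.coords)
        ]
    return [curvature_index(c, axis, convention) for c in data]
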