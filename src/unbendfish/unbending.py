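"""The two corrections for postmortem body arching.

**Regression unbending** regresses every Procrustes coordinate on the index of
curvature and keeps the residuals (added back to the consensus shape): the
corrected data are, by construction, linearly uncorrelated with the index.

**Curve-fit (Tps-style) unbending** straightens each specimen geometrically: a
quadratic or cubic polynomial is fitted through the body-axis landmarks in the
specimen's chord-aligned frame, and every landmark is remapped to
``(s, d)`` coordinates — arc length ``s`` along the fitted curve and signed
perpendicular offset ``d`` from it.  The axis lands on a straight horizontal
line while every other landmark keeps its position relative to the body axis.
Axis semilandmarks that only served to trace the curvature can then be
dropped before the final re-superimposition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .curvature import AxisSpec, curvature_index
from .errors import (
    DegenerateConfigurationError,
    StructuralError,
    UnfittableAxisError,
)
from .procrustes import ShapeDataset, gpa
from .tps_io import Dataset, LandmarkConfiguration

logger = logging.getLogger(__name__)

__all__ = [
    "AxisCurve",
    "UnbendResult",
    "fit_axis_curve",
    "tps_unbend_specimen",
    "tps_unbend_dataset",
    "regression_unbend",
]

#: number of samples used to bracket the global foot-point minimum
_FOOT_SAMPLES = 2048
#: fraction by which the curve's support is extended beyond the chord
_SUPPORT_MARGIN = 0.10


@dataclass
class AxisCurve:
    """Fitted polynomial body midline of one specimen.

    The curve lives in the specimen's chord-aligned frame: the chord from the
    first to the last axis landmark lies on the positive x'-axis starting at
    the origin, and the polynomial gives y' = f(x').

    Attributes
    ----------
    degree : int
        2 (quadratic) or 3 (cubic).
    coefficients : array
        Polynomial coefficients in ascending order (c0 + c1 x + ...).
    angle : float
        Rotation (radians) from the chord-aligned frame back to specimen
        coordinates.
    origin : (2,) array
        Specimen-frame position of the chord start (first axis landmark).
    chord : float
        Chord length (x' of the last axis landmark).
    fit_rmse : float
        RMS residual of the axis landmarks about the fitted curve.
    """

    degree: int
    coefficients: np.ndarray
    angle: float
    origin: np.ndarray
    chord: float
    fit_rmse: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.degree not in (2, 3):
            raise StructuralError(f"degree must be 2 or 3, got {self.degree}")
        if self.coefficients.shape != (self.degree + 1,):
            raise StructuralError("coefficient count must equal degree + 1")

    def f(self, x):
        return np.polynomial.polynomial.polyval(x, self.coefficients)

    def fprime(self, x):
        return np.polynomial.polynomial.polyval(
            x, np.polynomial.polynomial.polyder(self.coefficients)
        )

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """Map specimen coordinates into the chord-aligned frame."""
        c, s = math.cos(self.angle), math.sin(self.angle)
        rot = np.array([[c, s], [-s, c]])
        return (np.atleast_2d(points) - self.origin) @ rot.T

    def arc_length(self, x0: float, x1: float) -> float:
        """Signed arc length along the curve between abscissae x0 and x1."""
        val, _ = quad(
            lambda t: math.hypot(1.0, float(self.fprime(t))),
            x0,
            x1,
            epsabs=1e-10,
            limit=200,
        )
        return val


@dataclass
class UnbendResult:
    """Outcome of an unbending run.

    ``corrected`` is the re-superimposed shape data (semilandmarks already
    removed for the curve-fit method); ``residual_ic`` is the per-specimen
    index of curvature measured after correction; ``diagnostics`` carries the
    per-specimen curve-fit RMSE for the tps method.
    """

    corrected: ShapeDataset
    method: str
    residual_ic: np.ndarray
    diagnostics: pd.DataFrame | None = None


def fit_axis_curve(
    config: LandmarkConfiguration, axis: AxisSpec, degree: int = 3
) -> AxisCurve:
    """Fit a polynomial midline through a specimen's axis landmarks.

    The configuration is rotated/translated so that the chord (first to last
    chain landmark) lies on the positive x'-axis starting at the origin, and a
    least-squares polynomial y' = f(x') of the requested degree is fitted
    through the chain points in that frame.
    """
    chain_idx = axis.indices(config.n_landmarks)
    pts = config.coords[chain_idx]
    if len(pts) < degree + 1:
        raise UnfittableAxisError(
            f"{config.specimen_id!r}: {len(pts)} chain points cannot support "
            f"a degree-{degree} fit"
        )
    chord_vec = pts[-1] - pts[0]
    chord = float(np.linalg.norm(chord_vec))
    if chord == 0.0:
        raise DegenerateConfigurationError(
            f"{config.specimen_id!r}: chord endpoints coincide"
        )
    angle = math.atan2(chord_vec[1], chord_vec[0])
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, s], [-s, c]])
    local = (pts - pts[0]) @ rot.T
    x, y = local[:, 0], local[:, 1]
    dx = np.diff(x)
    backtrack = float(-dx[dx < 0].sum())
    if backtrack > 0.01 * chord:
        raise UnfittableAxisError(
            f"{config.specimen_id!r}: chain doubles back along the chord by "
            f"{backtrack / chord:.1%} (vertical folding); y' = f(x') is "
            "ill-defined"
        )
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    resid = np.polynomial.polynomial.polyval(x, coeffs) - y
    return AxisCurve(
        degree=degree,
        coefficients=coeffs,
        angle=angle,
        origin=pts[0].copy(),
        chord=chord,
        fit_rmse=float(np.sqrt(np.mean(resid**2))),
    )


def _foot_point(curve: AxisCurve, point: np.ndarray, label: str) -> float:
    """Abscissa of the globally nearest curve point (sampled bracket + refine)."""
    lo = -_SUPPORT_MARGIN * curve.chord
    hi = (1.0 + _SUPPORT_MARGIN) * curve.chord
    xs = np.linspace(lo, hi, _FOOT_SAMPLES)
    d2 = (xs - point[0]) ** 2 + (curve.f(xs) - point[1]) ** 2
    k = int(np.argmin(d2))
    if k in (0, _FOOT_SAMPLES - 1):
        raise UnfittableAxisError(
            f"landmark {label}: nearest curve point falls outside the "
            "extended axis support"
        )
    res = minimize_scalar(
        lambda t: (t - point[0]) ** 2 + (float(curve.f(t)) - point[1]) ** 2,
        bounds=(xs[k - 1], xs[k + 1]),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def tps_unbend_specimen(
    config: LandmarkConfiguration,
    axis: AxisSpec,
    degree: int = 3,
    curve: AxisCurve | None = None,
) -> LandmarkConfiguration:
    """Straighten one specimen along its fitted polynomial midline.

    Every landmark (axis and non-axis) is mapped to ``(s, d)``: ``s`` the arc
    length along the fitted curve from its point at x' = 0 to the landmark's
    foot (globally nearest curve point), ``d`` the signed perpendicular offset
    (positive on the left of the direction of increasing arc).  Axis landmarks
    land on the horizontal line d ≈ 0, and distances along the axis are
    preserved: the output chain's extent equals the input curve's arc length
    within fit error.
    """
    if curve is None:
        curve = fit_axis_curve(config, axis, degree)
    local = curve.to_frame(config.coords)
    out = np.empty_like(local)
    for i, pt in enumerate(local):
        x_foot = _foot_point(curve, pt, str(i + 1))
        s = curve.arc_length(0.0, x_foot)
        slope = float(curve.fprime(x_foot))
        norm = math.hypot(1.0, slope)
        # left normal of the tangent direction (1, slope)
        n_left = np.array([-slope, 1.0]) / norm
        foot = np.array([x_foot, float(curve.f(x_foot))])
        d = float(np.dot(pt - foot, n_left))
        out[i] = (s, d)
    return config.with_coords(out)


def _renumber_axis(axis: AxisSpec, drop: tuple[int, ...], p: int) -> AxisSpec:
    """Axis chain restricted to surviving landmarks, in the post-drop numbering."""
    dropped = set(drop)
    keep = [i for i in range(1, p + 1) if i not in dropped]
    new_number = {old: new for new, old in enumerate(keep, start=1)}
    surviving = [new_number[i] for i in axis.chain if i not in dropped]
    return AxisSpec(tuple(surviving))


def tps_unbend_dataset(
    dataset: Dataset | ShapeDataset,
    axis: AxisSpec,
    degree: int | None = 3,
    drop: tuple[int, ...] = (16, 17, 18, 19),
    groups: int | None = None,
    skip_bad: bool = False,
) -> UnbendResult:
    """Curve-fit unbending of a whole dataset.

    Each specimen gets its own polynomial fit in its own chord-aligned frame.
    ``groups`` (optional) partitions the sample into equal-frequency bins of
    the index of curvature; within each group the polynomial degree is chosen
    (from {2, 3}, when ``degree`` is None) by the smaller mean axis-fit RMSE —
    grouping never pools specimens into one fit.  After straightening, the
    ``drop`` landmarks (the axis semilandmarks, by default 16–19) are removed
    and the data re-superimposed by GPA.  ``residual_ic`` is computed on the
    surviving chain landmarks.
    """
    if isinstance(dataset, ShapeDataset):
        dataset = dataset.to_dataset()
    p = dataset.n_landmarks
    chain = set(axis.chain)
    interior = chain - {axis.chain[0], axis.chain[-1]}
    bad_drop = set(drop) - interior
    if bad_drop:
        raise StructuralError(
            f"drop indices {sorted(bad_drop)} are not interior axis-chain landmarks"
        )
    n = dataset.n_specimens
    ics = np.array([curvature_index(c, axis).ic for c in dataset])

    # group assignment: equal-frequency bins of ic (one group when groups is None)
    order = np.argsort(ics, kind="stable")
    group_of = np.zeros(n, dtype=int)
    n_groups = groups if groups else 1
    for g, chunk in enumerate(np.array_split(order, n_groups)):
        group_of[chunk] = g

    def _group_degree(members: np.ndarray) -> int:
        if degree is not None:
            return degree
        rmse = {}
        for d in (2, 3):
            rmse[d] = float(
                np.mean(
                    [fit_axis_curve(dataset[i], axis, d).fit_rmse for i in members]
                )
            )
        return min(rmse, key=rmse.get)

    degrees = {}
    for g in range(n_groups):
        members = np.flatnonzero(group_of == g)
        degrees[g] = _group_degree(members)

    straightened: list[LandmarkConfiguration] = []
    rows = []
    for i, config in enumerate(dataset):
        d_g = degrees[group_of[i]]
        try:
            curve = fit_axis_curve(config, axis, d_g)
            flat = tps_unbend_specimen(config, axis, d_g, curve=curve)
        except (UnfittableAxisError, DegenerateConfigurationError) as exc:
            if skip_bad:
                logger.warning("skipping %r: %s", config.specimen_id, exc)
                continue
            raise UnfittableAxisError(
                f"specimen {config.specimen_id!r}: {exc}"
            ) from exc
        straightened.append(flat)
        rows.append(
            {
                "id": config.specimen_id,
                "group": group_of[i],
                "degree": d_g,
                "ic_before": ics[i],
                "fit_rmse": curve.fit_rmse,
            }
        )

    keep0 = np.array([i for i in range(p) if (i + 1) not in set(drop)], dtype=int)
    surviving_axis = _renumber_axis(axis, tuple(drop), p)
    pruned = Dataset([c.with_coords(c.coords[keep0]) for c in straightened])
    residual_ic = np.array(
        [curvature_index(c, surviving_axis).ic for c in pruned]
    )
    corrected = gpa(pruned)
    diag = pd.DataFrame(rows)
    diag["ic_after"] = residual_ic
    return UnbendResult(
        corrected=corrected, method="tps", residual_ic=residual_ic, diagnostics=diag
    )


def regression_unbend(
    sds: ShapeDataset, ic: np.ndarray, axis: AxisSpec | None = None
) -> UnbendResult:
    """Remove arching by multivariate regression of shape on the index of curvature.

    Each of the 2p Procrustes coordinates is regressed on ic (intercept +
    slope, ordinary least squares); the corrected shapes are the consensus
    plus the residuals, re-superimposed by GPA.  The corrected coordinates
    have exactly zero sample covariance with ic.  When ``axis`` is given (or
    the default chain fits the landmark scheme), ``residual_ic`` reports the
    index of curvature re-measured on the corrected shapes.
    """
    ic = np.asarray(ic, dtype=float)
    n = sds.n_specimens
    if ic.shape != (n,):
        raise StructuralError(f"ic length {ic.shape} does not match n = {n}")
    if n < 3:
        raise StructuralError("regression unbending needs n >= 3")
    if np.ptp(ic) == 0.0 or np.var(ic) == 0.0:
        raise DegenerateConfigurationError(
            "index of curvature is constant; regression design is degenerate"
        )
    Y = sds.flattened()
    X = np.column_stack([np.ones(n), ic])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    corrected_flat = sds.consensus.ravel() + resid
    coords = corrected_flat.reshape(n, sds.n_landmarks, 2)
    corrected_ds = Dataset(
        [
            LandmarkConfiguration(specimen_id=i, coords=c, species=s)
            for i, c, s in zip(sds.ids, coords, sds.species)
        ]
    )
    corrected = gpa(corrected_ds)
    if axis is None and max(AxisSpec().chain) <= sds.n_landmarks:
        axis = AxisSpec()
    if axis is not None:
        residual_ic = np.array(
            [curvature_index(c, axis).ic for c in corrected.coords]
        )
    else:
        residual_ic = np.full(n, np.nan)
    return UnbendResult(
        corrected=corrected, method="regression", residual_ic=residual_ic
    )
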