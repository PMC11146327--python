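"""Evaluation statistics for shape data: PCA, regressions, Welch's test, disparity.

The battery mirrors how arching corrections are judged in practice:

- a shape PCA, to see whether curvature concentrates in one dimension or
  spreads across several;
- a permutation (Goodall-style) regression of the full Procrustes coordinates
  on a covariate such as the index of curvature;
- classical per-PC and scalar ordinary-least-squares regressions with
  parametric F tests;
- Welch's unequal-variance t test for group differences in a scalar;
- a permutation contrast of total Procrustes variance (disparity) between two
  datasets, which need not share a landmark scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateConfigurationError, StructuralError
from .procrustes import ShapeDataset, procrustes_variance

__all__ = [
    "PCAResult",
    "RegressionFit",
    "DisparityResult",
    "shape_pca",
    "regress_shape_on_covariate",
    "regress_scalar",
    "pc_vs_covariate",
    "welch_test",
    "disparity_contrast",
]


@dataclass
class PCAResult:
    """Principal components of the flattened Procrustes coordinates.

    ``eigenvalues`` are sample variances along the axes (divisor n−1),
    descending, and sum to the total Procrustes variance.  Each axis's
    largest-magnitude loading is made positive so signs are deterministic.
    """

    eigenvalues: np.ndarray
    axes: np.ndarray  # (k, 2p), orthonormal rows
    scores: np.ndarray  # (n, k)
    proportion_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class RegressionFit:
    """A univariate-design regression summary (scalar or multivariate response)."""

    F: float
    df_model: int
    df_residual: int
    r_squared: float
    p: float
    coefficients: np.ndarray
    permutation: bool = False


@dataclass
class DisparityResult:
    """Total Procrustes variances of two datasets and their permutation contrast."""

    variance_a: float
    variance_b: float
    abs_difference: float
    p_perm: float


def shape_pca(sds: ShapeDataset) -> PCAResult:
    """PCA of the flattened Procrustes coordinates (covariance, divisor n−1)."""
    n = sds.n_specimens
    if n < 3:
        raise StructuralError("shape PCA needs n >= 3")
    X = sds.flattened()
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    # deterministic sign: largest-|loading| entry of each axis positive
    for j in range(vt.shape[0]):
        k = int(np.argmax(np.abs(vt[j])))
        if vt[j, k] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    total = eigenvalues.sum()
    prop = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return PCAResult(
        eigenvalues=eigenvalues, axes=vt, scores=scores, proportion_variance=prop
    )


def _goodall_f(Y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Goodall-style F for a multivariate response on one covariate.

    Sums of squares pool over all response columns; F uses (1, n−2) df.
    Returns (F, r_squared, ss_total).
    """
    n = len(x)
    Yc = Y - Y.mean(axis=0)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    beta = (xc @ Yc) / sxx  # (2p,) slopes
    ss_model = sxx * float(beta @ beta)
    ss_total = float((Yc**2).sum())
    ss_resid = max(ss_total - ss_model, 0.0)
    if ss_resid == 0.0:
        return np.inf, 1.0, ss_total
    F = (ss_model / 1.0) / (ss_resid / (n - 2))
    return F, ss_model / ss_total, ss_total


def regress_shape_on_covariate(
    sds: ShapeDataset,
    covariate: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> RegressionFit:
    """Permutation regression of the full shape data on one covariate.

    The statistic is Goodall-style: sums of squares pooled over all 2p
    Procrustes coordinates, F = (SS_model/1) / (SS_residual/(n−2)).  The
    p-value counts permutations of the covariate whose F reaches the observed
    one: p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).
    """
    x = np.asarray(covariate, dtype=float)
    n = sds.n_specimens
    if x.shape != (n,):
        raise StructuralError(f"covariate length {x.shape} does not match n = {n}")
    if n < 4:
        raise StructuralError("shape regression needs n >= 4")
    if np.var(x) == 0.0:
        raise DegenerateConfigurationError("covariate is constant")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = sds.flattened()
    F_obs, r2, _ = _goodall_f(Y, x)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        F_perm, _, _ = _goodall_f(Y, rng.permutation(x))
        if F_perm >= F_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    xc = x - x.mean()
    slopes = (xc @ (Y - Y.mean(axis=0))) / float(xc @ xc)
    return RegressionFit(
        F=F_obs,
        df_model=1,
        df_residual=n - 2,
        r_squared=r2,
        p=p,
        coefficients=slopes,
        permutation=True,
    )


def regress_scalar(y: np.ndarray, x: np.ndarray) -> RegressionFit:
    """Ordinary least squares of scalar y on scalar x, classical F test (1, n−2)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise StructuralError("y and x must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise StructuralError("scalar regression needs n >= 3")
    if np.var(x) == 0.0:
        raise DegenerateConfigurationError("predictor is constant")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    intercept = float(y.mean() - slope * x.mean())
    ss_model = sxx * slope**2
    ss_total = float(yc @ yc)
    ss_resid = ss_total - ss_model
    df_resid = n - 2
    if ss_resid <= 0:
        F = np.inf
        p = 0.0
        r2 = 1.0
    else:
        F = (ss_model / 1.0) / (ss_resid / df_resid)
        p = float(stats.f.sf(F, 1, df_resid))
        r2 = ss_model / ss_total
    return RegressionFit(
        F=float(F),
        df_model=1,
        df_residual=df_resid,
        r_squared=float(r2),
        p=p,
        coefficients=np.array([intercept, slope]),
    )


def pc_vs_covariate(
    pca: PCAResult, covariate: np.ndarray, k: int = 6
) -> list[RegressionFit]:
    """Classical regression of each of the first k PC scores on the covariate.

    No multiple-testing correction is applied (each PC is judged at the bare
    nominal level); callers wanting Holm-adjusted p-values can adjust the
    returned p's themselves.
    """
    if k > pca.n_components:
        raise StructuralError(
            f"requested {k} PCs but only {pca.n_components} available"
        )
    return [regress_scalar(pca.scores[:, j], covariate) for j in range(k)]


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: returns (t, Welch–Satterthwaite df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StructuralError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        raise DegenerateConfigurationError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def disparity_contrast(
    sds_a: ShapeDataset,
    sds_b: ShapeDataset,
    n_perm: int = 999,
    seed: int | None = None,
) -> DisparityResult:
    """Permutation contrast of total Procrustes variance between two datasets.

    Each specimen contributes its squared Procrustes distance to its own
    dataset's consensus; the observed statistic is the absolute difference of
    the two variances (divisor n−1).  Group labels are then shuffled over the
    pooled per-specimen squared deviations.  The datasets need not share a
    landmark scheme (e.g., original 19-landmark vs corrected 15-landmark
    data).
    """
    if sds_a.n_specimens < 3 or sds_b.n_specimens < 3:
        raise StructuralError("disparity contrast needs n >= 3 per dataset")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    var_a = procrustes_variance(sds_a)
    var_b = procrustes_variance(sds_b)
    obs = abs(var_a - var_b)
    d2_a = ((sds_a.coords - sds_a.consensus) ** 2).sum(axis=(1, 2))
    d2_b = ((sds_b.coords - sds_b.consensus) ** 2).sum(axis=(1, 2))
    pooled = np.concatenate([d2_a, d2_b])
    na, nb = len(d2_a), len(d2_b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = abs(perm[:na].sum() / (na - 1) - perm[na:].sum() / (nb - 1))
        if stat >= obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return DisparityResult(
        variance_a=var_a, variance_b=var_b, abs_difference=obs, p_perm=p
    )
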