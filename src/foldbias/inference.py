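"""Association and group statistics.

Map-to-map associations use an area-weighted Pearson correlation, and
their significance is assessed with a spatial permutation test that
preserves the maps' autocorrelation.  On toroidal synthetic sheets the
exact autocorrelation-preserving symmetry group is the set of cyclic 2D
grid translations (the analogue of spinning a sphere); a naive random
vertex permutation is available only as an explicitly flagged fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mesh import TriangleMesh, as_values


def weighted_pearson(x, y, w=None) -> float:
    """Pearson correlation with per-vertex weights (e.g. surface areas).

    Vertices where either map is NaN are dropped pairwise.  Uniform
    weights reduce to the ordinary Pearson correlation; the result is
    invariant to rescaling of the weights.
    """
    x = as_values(x)
    y = as_values(y)
    if x.size != y.size:
        raise ValueError("maps have different lengths")
    w = np.ones(x.size) if w is None else as_values(w)
    if w.size != x.size:
        raise ValueError("weights have wrong length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y, w = x[keep], y[keep], w[keep]
    sw = w.sum()
    if sw <= 0:
        raise ValueError("total weight must be positive")
    mx = np.average(x, weights=w)
    my = np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    if vx == 0 or vy == 0:
        raise ValueError("zero weighted variance")
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


@dataclass
class PermutationResult:
    """Observed statistic, permutation null sample and two-sided p-value."""

    observed: float
    null: np.ndarray
    p: float
    n_perm: int
    scheme: str


def shift_permutation_test(
    x,
    y,
    mesh: TriangleMesh,
    w=None,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
    allow_fallback: bool = False,
) -> PermutationResult:
    """Spatial permutation test by cyclic grid translation of ``y``.

    The mesh must be a periodic sheet with a known grid layout; each
    permutation translates ``y`` by a random 2D offset and recomputes the
    weighted Pearson correlation with ``x``.  ``exhaustive=True``
    enumerates all translations instead (including the identity).  Two
    sided p with add-one correction:
    ``p = (1 + #{|null| >= |observed|}) / (1 + n_perm)``.

    For non-periodic meshes, ``allow_fallback=True`` switches to a random
    vertex permutation (flagged; this null ignores autocorrelation).
    """
    x = as_values(x)
    y = as_values(y)
    observed = weighted_pearson(x, y, w)
    periodic = mesh.periodic_domain is not None and mesh.grid_shape is not None
    if not periodic and not allow_fallback:
        raise ValueError(
            "mesh is not a periodic grid; pass allow_fallback=True for a "
            "(autocorrelation-naive) random vertex permutation"
        )
    rng = np.random.default_rng(seed)
    null = []
    if periodic:
        nx, ny = mesh.grid_shape
        grid = y.reshape(nx, ny)
        if exhaustive:
            shifts = [(di, dj) for di in range(nx) for dj in range(ny)]
        else:
            shifts = list(
                zip(rng.integers(0, nx, n_perm), rng.integers(0, ny, n_perm))
            )
        for di, dj in shifts:
            ys = np.roll(grid, (int(di), int(dj)), axis=(0, 1)).ravel()
            null.append(weighted_pearson(x, ys, w))
        scheme = "torus_shift_exhaustive" if exhaustive else "torus_shift"
    else:
        warnings.warn(
            "falling back to random vertex permutation; this null does not "
            "preserve spatial autocorrelation",
            stacklevel=2,
        )
        for _ in range(n_perm):
            null.append(weighted_pearson(x, y[rng.permutation(y.size)], w))
        scheme = "vertex_permutation"
    null = np.asarray(null)
    n = null.size
    p = (1 + int(np.sum(np.abs(null) >= abs(observed)))) / (1 + n)
    return PermutationResult(
        observed=observed, null=null, p=float(p), n_perm=n, scheme=scheme
    )


@dataclass
class TestResult:
    """Classical t-test result with Cohen's d effect size."""

    t: float
    df: int
    p: float
    cohens_d: float


def _finish(t: float, df: int, d: float) -> TestResult:
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(t=float(t), df=int(df), p=float(p), cohens_d=float(d))


def one_sample_t(x, popmean: float = 0.0) -> TestResult:
    """One-sample t-test; Cohen's d = mean deviation / SD."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    d = (x.mean() - popmean) / sd
    t = d * np.sqrt(x.size)
    return _finish(t, x.size - 1, d)


def paired_t(x, y) -> TestResult:
    """Paired t-test on x - y; Cohen's d = mean difference / SD(differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal shape")
    return one_sample_t(x - y, popmean=0.0)


def two_sample_t(x, y) -> TestResult:
    """Two-sample unpaired t-test with pooled variance; Cohen's d uses the
    pooled SD (the classical denominator)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per sample")
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    if pooled == 0:
        raise ValueError("zero variance")
    sp = np.sqrt(pooled)
    t = (x.mean() - y.mean()) / (sp * np.sqrt(1.0 / nx + 1.0 / ny))
    d = (x.mean() - y.mean()) / sp
    return _finish(t, nx + ny - 2, d)
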