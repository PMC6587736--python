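"""Morphospace occupation per color category.

Disparity is measured three ways on ordination scores: convex hull volume
on the first three axes, alpha-shape volume (which erodes empty space and
is less outlier-sensitive; alpha is the eraser-sphere radius), and the sum
of variances (robust to sample size). Significance of the iridescent
category's excess volume comes from a label-randomization test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .errors import DegenerateGeometryError

DEFAULT_ALPHAS = (1.3, 2.0, 5.0)


def hull_volume(points: np.ndarray, strict: bool = True) -> float:
    """Volume of the 3-D convex hull of ``points`` (n x 3).

    With ``strict`` False (pipeline mode), degenerate clouds (fewer than 4
    points, or coplanar) report volume 0.0 with a warning instead of
    raising.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    try:
        if pts.shape[0] < 4:
            raise DegenerateGeometryError(
                f"need >= 4 points for a 3-D hull, got {pts.shape[0]}"
            )
        return float(ConvexHull(pts).volume)
    except (QhullError, DegenerateGeometryError) as exc:
        if strict:
            if isinstance(exc, DegenerateGeometryError):
                raise
            raise DegenerateGeometryError(str(exc)) from exc
        warnings.warn(f"degenerate point cloud, reporting volume 0: {exc}")
        return 0.0


def _tetra_volumes(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a, b, c, d = (pts[simplices[:, i]] for i in range(4))
    return np.abs(np.einsum("ij,ij->i", a - d, np.cross(b - d, c - d))) / 6.0


def _circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumsphere radius of each Delaunay tetrahedron."""
    radii = np.empty(len(simplices))
    for k, simp in enumerate(simplices):
        p = pts[simp]
        A = 2.0 * (p[1:] - p[0])
        b = np.sum(p[1:] ** 2 - p[0] ** 2, axis=1)
        try:
            center = np.linalg.solve(A, b)
            radii[k] = np.linalg.norm(center - p[0])
        except np.linalg.LinAlgError:
            radii[k] = np.inf  # flat tetrahedron: infinite circumsphere
    return radii


def alpha_volume(points: np.ndarray, alpha: float, strict: bool = True) -> float:
    """Volume of the 3-D alpha shape: the union of Delaunay tetrahedra whose
    circumsphere radius is at most ``alpha``.

    Approaches the convex hull volume for large alpha and 0 as alpha -> 0;
    monotone nondecreasing in alpha.
    """
    if alpha <= 0:
        return 0.0
    pts = np.asarray(points, dtype=float)
    try:
        if pts.shape[0] < 4:
            raise DegenerateGeometryError(
                f"need >= 4 points for an alpha shape, got {pts.shape[0]}"
            )
        tri = Delaunay(pts)
    except (QhullError, DegenerateGeometryError) as exc:
        if strict:
            if isinstance(exc, DegenerateGeometryError):
                raise
            raise DegenerateGeometryError(str(exc)) from exc
        warnings.warn(f"degenerate point cloud, reporting volume 0: {exc}")
        return 0.0
    vols = _tetra_volumes(pts, tri.simplices)
    radii = _circumradii(pts, tri.simplices)
    return float(vols[radii <= alpha].sum())


@dataclass
class RandomizationResult:
    observed_ratio: float
    null_ratios: np.ndarray = field(repr=False)
    p_value: float
    n_iter: int
    n_degenerate: int
    exact_binomial_p: float


def randomization_test(
    scores: np.ndarray,
    labels,
    n_iter: int = 5000,
    seed: int = 0,
    focal: str = "iridescent",
    volume: str = "hull",
    alpha: float = 2.0,
) -> RandomizationResult:
    """Label-randomization test of excess morphospace volume.

    The observed statistic is volume(focal) / volume(pooled other points);
    the null shuffles category labels (category sizes preserved) ``n_iter``
    times. p = (1 + #{null >= observed}) / (1 + n_iter). Permutations where
    a category is too small for a hull contribute volume 0 and are counted
    in ``n_degenerate``. An exact one-sided binomial test of the count of
    null >= observed against expectation 1/2 is reported alongside.
    """
    from scipy.stats import binomtest

    scores = np.asarray(scores, dtype=float)[:, :3]
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)

    def vol(pts: np.ndarray) -> float:
        if volume == "hull":
            return hull_volume(pts, strict=False)
        return alpha_volume(pts, alpha, strict=False)

    def ratio(lab: np.ndarray) -> tuple[float, bool]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v_focal = vol(scores[lab == focal])
            v_rest = vol(scores[lab != focal])
        if v_rest == 0.0:
            return np.inf if v_focal > 0 else 0.0, True
        return v_focal / v_rest, v_focal == 0.0

    observed, _ = ratio(labels)
    nulls = np.empty(n_iter)
    n_degen = 0
    for i in range(n_iter):
        r, degen = ratio(rng.permutation(labels))
        nulls[i] = r
        n_degen += int(degen)
    n_ge = int(np.sum(nulls >= observed))
    p = (1 + n_ge) / (1 + n_iter)
    exact = binomtest(n_ge, n_iter, 0.5, alternative="less").pvalue
    return RandomizationResult(
        observed_ratio=float(observed),
        null_ratios=nulls,
        p_value=float(p),
        n_iter=n_iter,
        n_degenerate=n_degen,
        exact_binomial_p=float(exact),
    )


def sum_of_variances(
    scores: np.ndarray,
    labels,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-category sum of within-category variances across all axes, with
    95% percentile-bootstrap confidence intervals (resampling samples within
    category)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    rows = []
    for cat in pd.unique(labels):
        pts = scores[labels == cat]
        if len(pts) < 2:
            raise ValueError(f"category {cat!r} has fewer than 2 samples")
        sov = float(pts.var(axis=0, ddof=1).sum())
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, len(pts), size=len(pts))
            boots[b] = pts[idx].var(axis=0, ddof=1).sum()
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(dict(category=cat, sov=sov, ci_low=float(lo), ci_high=float(hi)))
    return pd.DataFrame.from_records(rows)


def category_volumes(
    scores: np.ndarray,
    labels,
    alphas=DEFAULT_ALPHAS,
) -> pd.DataFrame:
    """Convex hull and alpha-shape volumes per category on 3 axes."""
    scores = np.asarray(scores, dtype=float)[:, :3]
    labels = np.asarray(labels)
    rows = []
    for cat in pd.unique(labels):
        pts = scores[labels == cat]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = dict(category=cat, hull_volume=hull_volume(pts, strict=False))
            for a in alphas:
                rec[f"alpha_{a}"] = alpha_volume(pts, a, strict=False)
        rows.append(rec)
    return pd.DataFrame.from_records(rows)
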