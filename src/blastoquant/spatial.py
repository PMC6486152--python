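"""Ellipsoid fitting and inner/outer cell classification.

Each embryo's nuclear centroids are fit with a general quadric constrained to
an ellipsoid; a cell's normalized radial position r_norm is the norm of its
centroid after translating to the ellipsoid center, rotating into the axis
frame and dividing by the semi-axes (r_norm = 1 exactly on the surface).
Cells at or above a configurable r_norm threshold are called outer, the rest
inner — the automated counterpart of assigning inner/outer positions from a
3-D embryo reconstruction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EllipsoidModel",
    "EllipsoidFitError",
    "fit_ellipsoid",
    "fit_embryo_surface",
    "radial_position",
    "classify_inner_outer",
    "classify_nucleus_table",
    "DEFAULT_THRESHOLD",
]

#: default r_norm cut between inner and outer cells (ties go outward)
DEFAULT_THRESHOLD = 0.7


class EllipsoidFitError(ValueError):
    """Raised when an embryo/frame has too few points to fit an ellipsoid."""


@dataclass(frozen=True)
class EllipsoidModel:
    """Fitted ellipsoid: center, semi-axes (descending) and orientation.

    ``orientation`` columns are the unit axis directions matching
    ``semi_axes``; ``fit_residual`` is the RMS of ``|r_norm - 1|`` over the
    fitting points; ``degenerate`` marks the bounding-box fallback used for
    coplanar or non-ellipsoidal point sets.
    """

    center: np.ndarray
    semi_axes: np.ndarray
    orientation: np.ndarray
    fit_residual: float = float("nan")
    degenerate: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        a = np.asarray(self.semi_axes, dtype=float).reshape(3)
        q = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if np.any(a <= 0):
            raise ValueError("semi-axes must be positive")
        if np.any(np.diff(a) > 1e-9):
            raise ValueError("semi-axes must be sorted descending")
        if np.max(np.abs(q.T @ q - np.eye(3))) > 1e-9:
            raise ValueError("orientation must be orthonormal")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "semi_axes", a)
        object.__setattr__(self, "orientation", q)


def _bounding_fallback(pts: np.ndarray) -> EllipsoidModel:
    center = 0.5 * (pts.min(axis=0) + pts.max(axis=0))
    half = 0.5 * (pts.max(axis=0) - pts.min(axis=0))
    # sqrt(3)*half-extent guarantees every point lies inside the ellipsoid
    axes = np.maximum(np.sqrt(3.0) * half, 1e-6)
    order = np.argsort(axes)[::-1]
    model = EllipsoidModel(
        center=center,
        semi_axes=axes[order],
        orientation=np.eye(3)[:, order],
        degenerate=True,
    )
    res = float(np.sqrt(np.mean((radial_position(pts, model) - 1.0) ** 2)))
    object.__setattr__(model, "fit_residual", res)
    return model


def fit_ellipsoid(points, embryo=None, frame=None) -> EllipsoidModel:
    """Least-squares ellipsoid through a 3-D point cloud.

    Solves the quadric x'Qx + l'x = 1 in the nine quadric coefficients by
    ordinary least squares, then extracts center, semi-axes and orientation
    from the eigendecomposition of Q.  Requires >= 9 points (raises
    :class:`EllipsoidFitError` naming the embryo/frame otherwise).  Coplanar
    point sets or an indefinite fitted quadric fall back to the axis-aligned
    bounding ellipsoid, flagged ``degenerate``.

    The parametrization assumes the surface does not pass through the
    coordinate origin, which holds for centroids in positive µm coordinates.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    where = ""
    if embryo is not None or frame is not None:
        where = f" (embryo={embryo!r}, frame={frame!r})"
    if len(pts) < 9:
        raise EllipsoidFitError(
            f"need >= 9 points to fit an ellipsoid, got {len(pts)}{where}"
        )
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        warnings.warn(
            f"coplanar points{where}; using bounding-ellipsoid fallback",
            stacklevel=2,
        )
        return _bounding_fallback(pts)

    # normalize for conditioning (rigid shift + uniform scale)
    mu = pts.mean(axis=0)
    scale = float(np.mean(np.linalg.norm(pts - mu, axis=1)))
    P = (pts - mu) / scale
    x, y, z = P.T
    # direct ellipsoid-constrained least squares (k=4 quadratic constraint,
    # which guarantees the fitted quadric is an ellipsoid)
    D = np.column_stack(
        [x * x, y * y, z * z, 2 * y * z, 2 * x * z, 2 * x * y,
         2 * x, 2 * y, 2 * z, np.ones(len(P))]
    )
    S = D.T @ D
    S11, S12, S22 = S[:6, :6], S[:6, 6:], S[6:, 6:]
    kcon = 4.0
    C = np.zeros((6, 6))
    C[:3, :3] = kcon / 2 - 1
    np.fill_diagonal(C[:3, :3], -1.0)
    C[3:, 3:] = -kcon * np.eye(3)
    try:
        T = -np.linalg.solve(S22, S12.T)
        M = np.linalg.solve(C, S11 + S12 @ T)
    except np.linalg.LinAlgError:
        warnings.warn(
            f"singular design{where}; using bounding-ellipsoid fallback",
            stacklevel=2,
        )
        return _bounding_fallback(pts)
    eigval_m, eigvec_m = np.linalg.eig(M)
    cand = []
    for i in range(6):
        if abs(eigval_m[i].imag) > 1e-8:
            continue
        u1 = eigvec_m[:, i].real
        if u1 @ C @ u1 > 0:
            cand.append((eigval_m[i].real, u1))
    if not cand:
        warnings.warn(
            f"no ellipsoidal solution{where}; using bounding-ellipsoid "
            "fallback",
            stacklevel=2,
        )
        return _bounding_fallback(pts)
    _, u1 = max(cand, key=lambda c: c[0])
    u2 = T @ u1
    a, b, c_, f, g, h = u1
    p, q, r_, d = u2
    Q = np.array([[a, h, g], [h, b, f], [g, f, c_]])
    lin = np.array([p, q, r_])
    try:
        center = np.linalg.solve(-Q, lin)
    except np.linalg.LinAlgError:
        warnings.warn(
            f"singular quadric{where}; using bounding-ellipsoid fallback",
            stacklevel=2,
        )
        return _bounding_fallback(pts)
    # surface: (v-c)'Q(v-c) = c'Qc - d; only Q/k must be positive definite
    k = center @ Q @ center - d
    if k == 0:
        warnings.warn(
            f"degenerate quadric{where}; using bounding-ellipsoid fallback",
            stacklevel=2,
        )
        return _bounding_fallback(pts)
    eigval, eigvec = np.linalg.eigh(Q / k)
    if np.any(eigval <= 0):
        warnings.warn(
            f"fitted quadric is not an ellipsoid{where}; "
            "using bounding-ellipsoid fallback",
            stacklevel=2,
        )
        return _bounding_fallback(pts)
    center = center * scale + mu
    axes = scale / np.sqrt(eigval)
    order = np.argsort(axes)[::-1]
    axes = axes[order]
    rot = eigvec[:, order]
    if np.linalg.det(rot) < 0:
        rot = rot.copy()
        rot[:, -1] *= -1
    model = EllipsoidModel(center=center, semi_axes=axes, orientation=rot)
    res = float(np.sqrt(np.mean((radial_position(pts, model) - 1.0) ** 2)))
    object.__setattr__(model, "fit_residual", res)
    return model


def fit_embryo_surface(
    points,
    embryo=None,
    frame=None,
    refine_iters: int = 4,
    shell_fraction: float = 0.75,
    inflate: bool = True,
) -> EllipsoidModel:
    """Estimate the embryo's surface ellipsoid from all nuclear centroids.

    A raw quadric fit through a solid cloud of nuclei is dragged inward by
    the deep (inner) cells, so the surface is reconstructed in three steps:

    1. fit :func:`fit_ellipsoid` to the convex-hull vertices of the cloud
       (the outermost nuclei; identical to a plain fit when the points are
       surface samples);
    2. iteratively refit to the points in the outer shell of the current
       model (normalized radius >= ``shell_fraction`` of the maximum), which
       brings all surface-monolayer cells, not only hull vertices, into the
       fit;
    3. optionally inflate the semi-axes by half the radial spread of the
       shell points: the fit passes through the *centroids* of the outer
       cell monolayer, while the embryo envelope lies about half a monolayer
       further out.

    The inflation is estimated from the data (10th-90th percentile spread of
    the shell radii), so no assumption about absolute cell size enters.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 9:
        # delegate for the uniform error message
        return fit_ellipsoid(pts, embryo=embryo, frame=frame)
    try:
        from scipy.spatial import ConvexHull, QhullError

        hv = ConvexHull(pts).vertices
        seed_pts = pts[hv] if len(hv) >= 9 else pts
    except QhullError:
        seed_pts = pts
    model = fit_ellipsoid(seed_pts, embryo=embryo, frame=frame)
    shell = seed_pts
    for _ in range(refine_iters):
        r = radial_position(pts, model)
        sel = pts[r >= shell_fraction * r.max()]
        if len(sel) < 9 or len(sel) == len(pts):
            break
        refit = fit_ellipsoid(sel, embryo=embryo, frame=frame)
        if refit.degenerate:
            break
        model, shell = refit, sel
    if inflate and len(shell) >= 9 and not model.degenerate:
        rs = radial_position(shell, model)
        factor = 1.0 + 0.5 * float(np.quantile(rs, 0.9) - np.quantile(rs, 0.1))
        inflated = EllipsoidModel(
            center=model.center,
            semi_axes=model.semi_axes * factor,
            orientation=model.orientation,
        )
        res = float(
            np.sqrt(np.mean((radial_position(shell, inflated) - 1.0) ** 2))
        )
        object.__setattr__(inflated, "fit_residual", res)
        model = inflated
    return model


def radial_position(points, model: EllipsoidModel) -> np.ndarray:
    """Normalized radius of points w.r.t. an ellipsoid (1 on the surface)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u = (pts - model.center) @ model.orientation
    return np.sqrt(np.sum((u / model.semi_axes) ** 2, axis=1))


def classify_inner_outer(
    points,
    model: EllipsoidModel,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """(r_norm, label) for each point; outer iff r_norm >= threshold."""
    if model is None:
        raise ValueError("missing ellipsoid model")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    r = radial_position(points, model)
    labels = np.where(r >= threshold, "outer", "inner")
    return r, labels


def classify_nucleus_table(
    nuclei: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    per_frame: bool = True,
) -> pd.DataFrame:
    """Fit ellipsoids per embryo (per frame by default) and label every cell.

    Returns a copy of the nucleus table with ``r_norm`` and ``in_out``
    columns.  Excluded nuclei (an optional boolean ``excluded`` column) do
    not contribute to the fit but are still assigned a position.
    """
    df = nuclei.copy()
    df["r_norm"] = np.nan
    df["in_out"] = pd.NA
    keys = ["embryo_id", "frame"] if per_frame else ["embryo_id"]
    excluded = (
        df["excluded"].fillna(False).astype(bool)
        if "excluded" in df
        else pd.Series(False, index=df.index)
    )
    for key, idx in df.groupby(keys, sort=False).groups.items():
        sub = df.loc[idx]
        fit_pts = sub.loc[~excluded.loc[idx], ["x_um", "y_um", "z_um"]].values
        embryo = key[0] if isinstance(key, tuple) else key
        frame = key[1] if (per_frame and isinstance(key, tuple)) else None
        model = fit_embryo_surface(fit_pts, embryo=embryo, frame=frame)
        r, lab = classify_inner_outer(
            sub[["x_um", "y_um", "z_um"]].values, model, threshold
        )
        df.loc[idx, "r_norm"] = r
        df.loc[idx, "in_out"] = lab
    df["in_out"] = df["in_out"].astype("string")
    return df
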