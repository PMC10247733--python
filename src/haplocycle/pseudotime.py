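"""Elliptical cell-cycle pseudo-time.

Cells in the (G1S, G2M) metagene-score plane lie on an approximately
elliptical loop tracing cell-cycle progression.  An ellipse is fitted by
stable direct least squares on the conic representation; each cell gets an
angular position (parametric angle of its nearest ellipse point); gene
expression is smoothed along the loop by a rolling circle: at each anchor
point on the ellipse, the mean and SEM of expression over all cells within
a fixed radius, with 95% CI bands at mean +- 1.96 x SEM.

Pseudo-time orientation is fixed so that it increases through the phase
order G1S -> S -> G2 -> G2M -> MG1 (majority vote of assigned phases along
the anchor grid), with the origin at the anchor of maximal smoothed G1S
score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .config import PHASES
from .errors import DegenerateDataError, ParameterError

__all__ = [
    "EllipseModel",
    "CellCycleEllipse",
    "fit_ellipse",
    "project_angle",
    "rolling_profile",
    "compare_trajectories",
    "TrajectoryProfile",
]

Z95 = 1.96  # normal 95% CI multiplier applied to the SEM


@dataclass(frozen=True)
class EllipseModel:
    """Geometric ellipse: center, semi-axes (a >= b > 0), rotation in [0, pi)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation_phi: float

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (np.isfinite(a) and np.isfinite(b) and a >= b > 0):
            raise DegenerateDataError(f"invalid semi-axes {self.semi_axes}")
        if not np.all(np.isfinite(self.center)) or not np.isfinite(self.rotation_phi):
            raise DegenerateDataError("non-finite ellipse parameters")

    def point(self, theta) -> np.ndarray:
        """Point(s) on the ellipse at parametric angle(s) theta, shape (..., 2)."""
        theta = np.asarray(theta, dtype=float)
        a, b = self.semi_axes
        c, s = np.cos(self.rotation_phi), np.sin(self.rotation_phi)
        x = a * np.cos(theta)
        y = b * np.sin(theta)
        return np.stack(
            [self.center[0] + c * x - s * y, self.center[1] + s * x + c * y], axis=-1
        )


def fit_ellipse(points: np.ndarray) -> EllipseModel:
    """Direct least-squares conic fit with the ellipse constraint
    (numerically stable partitioned formulation), converted to geometric
    parameters.

    Requires at least 6 points with non-degenerate (non-collinear) scatter.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("points must be an (n, 2) array")
    if pts.shape[0] < 6:
        raise DegenerateDataError(f"need >= 6 points, got {pts.shape[0]}")
    # center/scale for conditioning; parameters are mapped back afterwards
    mu = pts.mean(axis=0)
    scale = pts.std(axis=0).mean()
    if scale <= 0:
        raise DegenerateDataError("all points identical")
    x, y = ((pts - mu) / scale).T

    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError("rank-deficient scatter (collinear points)") from exc
    m = s1 + s2 @ t
    # inverse of the constraint matrix C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    valid = np.where(np.isreal(eigval) & (cond > 0))[0]
    if len(valid) == 0:
        raise DegenerateDataError("no elliptical solution (degenerate scatter)")
    a1 = np.real(eigvec[:, valid[0]])
    coeffs = np.concatenate([a1, t @ a1])  # A, B, C, D, E, F (scaled frame)
    return _conic_to_geometric(coeffs, mu, scale)


def _conic_to_geometric(coeffs: np.ndarray, mu: np.ndarray, scale: float) -> EllipseModel:
    a_, b_, c_, d_, e_, f_ = coeffs
    q = np.array([[a_, b_ / 2.0], [b_ / 2.0, c_]])
    det = np.linalg.det(q)
    if det <= 0:
        raise DegenerateDataError("conic is not an ellipse")
    center = np.linalg.solve(2.0 * q, [-d_, -e_])
    f_c = center @ q @ center + np.array([d_, e_]) @ center + f_
    lam, vec = np.linalg.eigh(q)  # ascending; both same sign since det > 0
    if lam[0] < 0:
        # normalize the conic's overall sign so q is positive definite
        lam, vec, f_c = -lam[::-1], vec[:, ::-1], -f_c
    if f_c >= 0 or lam[0] <= 0:
        raise DegenerateDataError("conic is not a real ellipse")
    axes2 = -f_c / lam  # descending: axes2[0] pairs with the smaller eigenvalue
    axes = np.sqrt(axes2)  # descending: axes[0] (major) pairs with lam[0]
    major_vec = vec[:, 0]
    phi = float(np.arctan2(major_vec[1], major_vec[0])) % np.pi
    return EllipseModel(
        center=(float(center[0] * scale + mu[0]), float(center[1] * scale + mu[1])),
        semi_axes=(float(axes[0] * scale), float(axes[1] * scale)),
        rotation_phi=phi,
    )


class CellCycleEllipse(BaseEstimator):
    """Sklearn-style estimator for the elliptical cell-cycle manifold.

    ``fit(X)`` on (n, 2) score points stores the geometric model;
    ``predict(X)`` returns each point's parametric angle on the fitted
    ellipse.  Fitted attributes: ``model_``, ``center_``, ``semi_axes_``,
    ``rotation_phi_``.
    """

    def fit(self, X, y=None):
        self.model_ = fit_ellipse(X)
        self.center_ = self.model_.center
        self.semi_axes_ = self.model_.semi_axes
        self.rotation_phi_ = self.model_.rotation_phi
        return self

    def predict(self, X) -> np.ndarray:
        pts = np.asarray(X, dtype=float)
        return np.array([project_angle(p, self.model_) for p in pts])


def project_angle(point, ellipse: EllipseModel, n_coarse: int = 256) -> float:
    """Parametric angle of the ellipse point nearest to ``point`` (Euclidean),
    by coarse grid search refined with bounded 1-D minimization.

    A point at the ellipse center has no nearest angle and raises."""
    p = np.asarray(point, dtype=float)
    if np.hypot(*(p - np.asarray(ellipse.center))) < 1e-12:
        raise DegenerateDataError("point at the ellipse center: angle is ambiguous")

    def dist2(theta):
        return float(((ellipse.point(theta) - p) ** 2).sum())

    grid = np.linspace(0.0, 2.0 * np.pi, n_coarse, endpoint=False)
    d = ((ellipse.point(grid) - p) ** 2).sum(axis=1)
    k = int(np.argmin(d))
    step = 2.0 * np.pi / n_coarse
    res = minimize_scalar(
        dist2, bounds=(grid[k] - step, grid[k] + step), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x) % (2.0 * np.pi)


@dataclass
class TrajectoryProfile:
    """Pseudo-time-ordered smoothed expression.

    ``pseudotime`` is a strictly increasing grid over [0, 2*pi) starting at
    the G1S-score maximum and advancing through the canonical phase order;
    ``theta`` holds the corresponding raw parametric angles on the ellipse.
    ``mean``/``sem`` are (n_anchors, n_genes); windows with no cells are
    NaN, SEM additionally requires >= 2 cells.
    """

    pseudotime: np.ndarray
    theta: np.ndarray
    genes: list[str]
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    majority_phase: np.ndarray
    ellipse: EllipseModel | None = None
    meta: dict = field(default_factory=dict)

    @property
    def ci_low(self) -> np.ndarray:
        return self.mean - Z95 * self.sem

    @property
    def ci_high(self) -> np.ndarray:
        return self.mean + Z95 * self.sem

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gene, anchor_angle (pseudotime), mean, sem,
        ci_low, ci_high, n."""
        k, g = self.mean.shape
        return pd.DataFrame({
            "gene": np.repeat(self.genes, k),
            "anchor_angle": np.tile(self.pseudotime, g),
            "theta": np.tile(self.theta, g),
            "majority_phase": np.tile(self.majority_phase, g),
            "mean": self.mean.T.ravel(),
            "sem": self.sem.T.ravel(),
            "ci_low": self.ci_low.T.ravel(),
            "ci_high": self.ci_high.T.ravel(),
            "n": np.tile(self.n, g),
        })

    def peak_angle(self, gene: str) -> float:
        """Pseudo-time of the gene's smoothed-expression maximum."""
        j = self.genes.index(gene)
        col = self.mean[:, j]
        if np.all(np.isnan(col)):
            raise DegenerateDataError(f"gene {gene!r} has no non-missing anchors")
        return float(self.pseudotime[np.nanargmax(col)])


_ORDER = {p: i for i, p in enumerate(PHASES)}


def _choose_direction(majority: np.ndarray) -> int:
    """+1 if increasing anchor index advances through the canonical phase
    order, else -1 (majority vote over adjacent anchor transitions)."""
    idx = np.array([_ORDER.get(p, -1) for p in majority])
    votes = 0
    k = len(idx)
    for i in range(k):
        a, b = idx[i], idx[(i + 1) % k]
        if a < 0 or b < 0 or a == b:
            continue
        if (b - a) % len(PHASES) == 1:
            votes += 1
        elif (a - b) % len(PHASES) == 1:
            votes -= 1
    return 1 if votes >= 0 else -1


def rolling_profile(
    scores2d: np.ndarray,
    expression: np.ndarray,
    ellipse: EllipseModel,
    phase_labels: np.ndarray | pd.Series,
    genes: list[str] | None = None,
    radius: float = 0.5,
    n_anchors: int = 360,
) -> TrajectoryProfile:
    """Rolling-circle smoothing of expression along the ellipse.

    For each anchor (ellipse point at a uniform parametric-angle grid), the
    window is the set of cells whose (G1S, G2M) score point lies within
    ``radius`` of the anchor; smoothed mean and SEM are computed per gene
    over the window.  The radius is in score-plane units (z-scored metagene
    scores under the default scoring mode).
    """
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    pts = np.asarray(scores2d, dtype=float)
    expr = np.asarray(expression, dtype=float)
    if expr.ndim == 1:
        expr = expr[:, None]
    if pts.shape[0] != expr.shape[0]:
        raise ParameterError("scores2d and expression must have equal cell counts")
    genes = list(genes) if genes is not None else [f"gene{j}" for j in range(expr.shape[1])]
    phase_labels = np.asarray(phase_labels, dtype=object)

    theta_grid = np.linspace(0.0, 2.0 * np.pi, n_anchors, endpoint=False)
    anchors = ellipse.point(theta_grid)
    tree = cKDTree(pts)
    windows = tree.query_ball_point(anchors, r=radius)

    k, g = n_anchors, expr.shape[1]
    mean = np.full((k, g), np.nan)
    sem = np.full((k, g), np.nan)
    n = np.zeros(k, dtype=int)
    g1s_smooth = np.full(k, np.nan)
    majority = np.full(k, "", dtype=object)
    for i, idx in enumerate(windows):
        n[i] = len(idx)
        if not idx:
            continue
        sub = expr[idx]
        mean[i] = sub.mean(axis=0)
        if len(idx) >= 2:
            sem[i] = sub.std(axis=0, ddof=1) / np.sqrt(len(idx))
        g1s_smooth[i] = pts[idx, 0].mean()
        labels, counts = np.unique(
            [p for p in phase_labels[idx] if p in _ORDER], return_counts=True
        )
        if len(labels):
            majority[i] = labels[np.argmax(counts)]
    if n.sum() == 0:
        raise DegenerateDataError(
            f"every rolling window is empty at radius {radius}; increase the radius"
        )

    direction = _choose_direction(majority)
    origin = int(np.nanargmax(g1s_smooth))
    order = (origin + direction * np.arange(k)) % k
    return TrajectoryProfile(
        pseudotime=theta_grid.copy(),
        theta=theta_grid[order],
        genes=genes,
        mean=mean[order],
        sem=sem[order],
        n=n[order],
        majority_phase=majority[order],
        ellipse=ellipse,
        meta={"radius": radius, "direction": direction, "origin_theta": float(theta_grid[origin])},
    )


def compare_trajectories(profile_a: TrajectoryProfile, profile_b: TrajectoryProfile) -> pd.DataFrame:
    """Per-anchor difference of two profiles with pooled 95% CI.

    Profiles must share the anchor grid and gene list; the difference is
    mean_a - mean_b and its CI half-width 1.96 * sqrt(sem_a^2 + sem_b^2).
    Anchors missing in either profile are missing in the output.
    """
    if profile_a.genes != profile_b.genes:
        raise ParameterError("profiles cover different gene lists")
    if not np.allclose(profile_a.pseudotime, profile_b.pseudotime):
        raise ParameterError("profiles use different anchor grids")
    diff = profile_a.mean - profile_b.mean
    half = Z95 * np.sqrt(profile_a.sem ** 2 + profile_b.sem ** 2)
    k, g = diff.shape
    return pd.DataFrame({
        "gene": np.repeat(profile_a.genes, k),
        "anchor_angle": np.tile(profile_a.pseudotime, g),
        "diff": diff.T.ravel(),
        "ci_low": (diff - half).T.ravel(),
        "ci_high": (diff + half).T.ravel(),
    })
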