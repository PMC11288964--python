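"""Row scaling, PCA with SVD imputation, and group prediction ellipses.

The sample-level ordination used throughout the stoichiometry pipeline:
each RP ratio row is centered and scaled to unit variance so every RP
contributes equally, missing entries are filled by iterative rank-k SVD
reconstruction, and principal-component scores are taken for the samples.
Per-group 95% prediction ellipses summarize the score cloud: a new
observation from the same group falls inside its ellipse with the stated
probability.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ratios import RatioMatrix

__all__ = [
    "ScaledMatrix",
    "PCAResult",
    "Ellipse",
    "scale_rows",
    "pca_svd_impute",
    "prediction_ellipse",
]

logger = logging.getLogger(__name__)


@dataclass
class ScaledMatrix:
    """Rows x samples matrix after per-row centering/unit-variance scaling.

    ``scaling_record`` notes which transforms were applied and which rows
    were dropped (zero variance or fewer than two observations).
    """

    values: pd.DataFrame
    scaling_record: dict = field(default_factory=dict)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, RatioMatrix):
        return matrix.ratios
    if isinstance(matrix, ScaledMatrix):
        return matrix.values
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise TypeError(f"unsupported matrix type {type(matrix).__name__}")


def scale_rows(
    matrix,
    center: bool = True,
    unit_variance: bool = True,
) -> ScaledMatrix:
    """Center rows and/or scale them to unit variance (sd with n-1).

    Per-row statistics use that row's non-missing values.  Rows that cannot
    be scaled — constant rows when ``unit_variance`` is on, or rows with
    fewer than two observations — are dropped and listed in
    ``scaling_record["dropped"]``.

    Raises
    ------
    ValueError
        If the input is empty or every row is dropped.
    """
    frame = _as_frame(matrix)
    if frame.size == 0:
        raise ValueError("empty matrix")
    out = frame.astype(float).copy()
    dropped: list[str] = []
    if unit_variance or center:
        n_obs = out.notna().sum(axis=1)
        too_few = n_obs < (2 if unit_variance else 1)
        sd = out.std(axis=1, ddof=1, skipna=True)
        constant = unit_variance & (sd == 0)
        bad = too_few | constant if unit_variance else too_few
        if bad.any():
            dropped = list(out.index[bad])
            logger.warning("dropping %d unscalable row(s): %s",
                           len(dropped), dropped[:10])
            out = out.loc[~bad]
            sd = sd.loc[~bad]
        if out.shape[0] == 0:
            raise ValueError("no rows left after removing constant rows")
        if center:
            out = out.sub(out.mean(axis=1, skipna=True), axis=0)
        if unit_variance:
            out = out.div(sd, axis=0)
    return ScaledMatrix(
        out,
        {"centered": center, "unit_variance": unit_variance,
         "dropped": dropped},
    )


@dataclass
class PCAResult:
    """Principal components of a rows x samples matrix.

    ``scores`` are sample coordinates (samples x components), ``loadings``
    the row weights (rows x components), ``explained_var`` the proportion of
    total variance captured by each component.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_var: np.ndarray
    converged: bool
    n_iter: int
    imputed: pd.DataFrame | None = None


def _svd_rank_k(x: np.ndarray, k: int):
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    return u[:, :k], s[:k], vt[:k]


def pca_svd_impute(
    scaled: ScaledMatrix,
    n_components: int = 2,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> PCAResult:
    """PCA of a rows x samples matrix, imputing missing entries by SVD.

    Missing entries are initialized with their row means (zero for a
    centered row) and then refined iteratively: a rank-``n_components`` SVD
    reconstruction of the current matrix replaces *only* the missing
    entries, until the relative change of the imputed values falls below
    ``tol`` or ``max_iter`` is reached.  The final SVD of the completed
    matrix yields loadings (left singular vectors), sample scores
    (right singular vectors times singular values) and per-component
    explained-variance proportions.

    Column signs are fixed so the largest-magnitude loading of each
    component is positive, making results reproducible across SVD backends.

    Raises
    ------
    ValueError
        If a row or column is entirely missing, or fewer rows than
        components remain.
    """
    frame = _as_frame(scaled)
    x = frame.to_numpy(dtype=float)
    n_rows, n_cols = x.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(n_rows, n_cols):
        raise ValueError(
            f"n_components={n_components} exceeds matrix rank bound "
            f"{min(n_rows, n_cols)}"
        )
    mask = np.isnan(x)
    if mask.all(axis=1).any():
        rows = list(frame.index[mask.all(axis=1)])
        raise ValueError(f"rows entirely missing: {rows}")
    if mask.all(axis=0).any():
        cols = list(frame.columns[mask.all(axis=0)])
        raise ValueError(f"columns entirely missing: {cols}")

    filled = x.copy()
    if mask.any():
        row_means = np.nanmean(x, axis=1)
        filled[mask] = np.broadcast_to(row_means[:, None], x.shape)[mask]

    converged = True
    n_iter = 0
    if mask.any():
        converged = False
        prev = filled[mask]
        for n_iter in range(1, max_iter + 1):
            u, s, vt = _svd_rank_k(filled, n_components)
            recon = (u * s) @ vt
            filled[mask] = recon[mask]
            cur = filled[mask]
            denom = max(float(np.linalg.norm(cur)), np.finfo(float).tiny)
            delta = float(np.linalg.norm(cur - prev)) / denom
            prev = cur.copy()
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"SVD imputation did not converge in {max_iter} iterations "
                f"(last relative change {delta:.3g})",
                RuntimeWarning,
                stacklevel=2,
            )

    u, s, vt = np.linalg.svd(filled, full_matrices=False)
    k = n_components
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(u[np.argmax(np.abs(u[:, :k]), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = u[:, :k] * flip
    scores = (vt[:k].T * s[:k]) * flip
    total = float(np.sum(s**2))
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)

    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=frame.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=frame.index, columns=comp_names),
        explained_var=explained,
        converged=converged,
        n_iter=n_iter,
        imputed=pd.DataFrame(filled, index=frame.index, columns=frame.columns),
    )


@dataclass
class Ellipse:
    """A group's bivariate-normal prediction ellipse in score space.

    ``semi_axes`` are the half-lengths along the principal directions,
    ``angle`` the orientation of the major axis in radians.  A fresh
    observation from the group's distribution falls inside with probability
    ``coverage_prob``.
    """

    group: str
    center: np.ndarray
    semi_axes: np.ndarray
    angle: float
    coverage_prob: float
    n: int
    cov: np.ndarray
    radius_sq: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of which (m x 2) points fall inside the ellipse."""
        pts = np.atleast_2d(points) - self.center
        inv = np.linalg.inv(self.cov)
        maha = np.einsum("ij,jk,ik->i", pts, inv, pts)
        return maha <= self.radius_sq

    def boundary(self, n_points: int = 200) -> np.ndarray:
        """Points tracing the ellipse outline (for plotting)."""
        t = np.linspace(0.0, 2.0 * math.pi, n_points)
        circle = np.stack([np.cos(t) * self.semi_axes[0],
                           np.sin(t) * self.semi_axes[1]], axis=1)
        c, s = math.cos(self.angle), math.sin(self.angle)
        rot = np.array([[c, -s], [s, c]])
        return circle @ rot.T + self.center

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "center": [float(v) for v in self.center],
            "semi_axes": [float(v) for v in self.semi_axes],
            "angle": float(self.angle),
            "coverage_prob": float(self.coverage_prob),
            "n": int(self.n),
        }


def _prediction_radius_sq(n: int, prob: float, method: str) -> float:
    if method == "f":
        # Hotelling-type prediction region for one future observation:
        # (x - xbar)' S^{-1} (x - xbar) <= 2 (n-1)(n+1) / (n (n-2)) * F(2, n-2)
        if n < 3:
            raise ValueError("F-based prediction ellipse needs n >= 3")
        quant = stats.f.ppf(prob, 2, n - 2)
        return 2.0 * (n - 1) * (n + 1) / (n * (n - 2)) * quant
    if method == "chi2":
        return float(stats.chi2.ppf(prob, 2))
    raise ValueError(f"unknown ellipse method {method!r}")


def prediction_ellipse(
    scores: pd.DataFrame,
    groups: pd.Series | dict[str, str],
    prob: float = 0.95,
    method: str = "f",
) -> list[Ellipse]:
    """Per-group prediction ellipses on the first two score columns.

    The default ``method="f"`` uses the small-sample F-distribution
    prediction quantile (appropriate for the n=3 group sizes common in
    these designs); ``method="chi2"`` is the large-sample limit.

    Raises
    ------
    ValueError
        If a group has fewer than 3 samples or a singular covariance
        (e.g. collinear points).
    """
    if not 0.0 < prob < 1.0:
        raise ValueError("coverage probability must be in (0, 1)")
    if scores.shape[1] < 2:
        raise ValueError("need at least two score columns")
    labels = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    labels = labels.reindex(scores.index)
    if labels.isna().any():
        missing = list(scores.index[labels.isna()])
        raise ValueError(f"samples without group label: {missing}")

    ellipses: list[Ellipse] = []
    xy = scores.iloc[:, :2].to_numpy(dtype=float)
    for group in pd.unique(labels):
        pts = xy[(labels == group).to_numpy()]
        n = pts.shape[0]
        if n < 3:
            raise ValueError(
                f"group {group!r} has {n} samples; >=3 required for an ellipse"
            )
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False, ddof=1)
        det = float(np.linalg.det(cov))
        if not np.isfinite(det) or det <= np.finfo(float).tiny:
            raise ValueError(
                f"group {group!r} has a singular covariance (collinear or "
                "duplicated points); no ellipse is defined"
            )
        r2 = _prediction_radius_sq(n, prob, method)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        semi_axes = np.sqrt(eigvals * r2)
        angle = math.atan2(eigvecs[1, 0], eigvecs[0, 0])
        ellipses.append(
            Ellipse(
                group=str(group), center=center, semi_axes=semi_axes,
                angle=angle, coverage_prob=prob, n=n, cov=cov, radius_sq=r2,
            )
        )
    return ellipses
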