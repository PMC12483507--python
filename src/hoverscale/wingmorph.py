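"""Wing morphology: outline metrics, semi-landmarks, Procrustes, phylogenetic PCA.

The central quantity is the wing's second-moment-of-area

.. math:: S_2 = \\int_0^R c(r)\\, r^2 \\, dr,

the only morphological parameter entering the quasi-steady hovering force
model.  ``S2`` mixes wing size and shape; the dimensionless
``S2* = S2 / (R^3 c̄)`` isolates the spanwise distribution of area (larger
values mean area concentrated towards the tip), and ``R`` and the mean chord
``c̄ = S / R`` carry the size.

Outlines are closed 2-D polygons in mm with a marked hinge (wing base)
vertex.  The span axis is the line from the hinge to the outline point
farthest from it; the local chord ``c(r)`` is the total length of the
intersection of the outline with the perpendicular to the span axis at
radial position ``r`` (multi-segment intersections are summed, so outlines
need not be single-valued around the span axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    GeometryError,
    InvalidParameterError,
    LabelMismatchError,
)
from .trees import cholesky_or_raise, vcv_matrix

__all__ = [
    "WingOutline",
    "MorphologySummary",
    "LandmarkConfiguration",
    "morphology_from_outline",
    "resample_semilandmarks",
    "GeneralizedProcrustes",
    "procrustes_align",
    "PhylogeneticPCA",
    "phylo_pca",
    "flatten_configurations",
]


@dataclass
class WingOutline:
    """Closed simple polygon (mm) with a hinge landmark.

    ``points`` need not repeat the first vertex; the polygon is implicitly
    closed.  Validation rejects self-intersecting or zero-area outlines.
    """

    points: np.ndarray
    hinge_index: int = 0
    specimen_id: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidParameterError("points must be an (N, 2) array")
        # drop an explicit closing vertex
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 50:
            raise GeometryError("outline needs at least 50 points")
        if not (0 <= self.hinge_index < len(pts)):
            raise GeometryError("hinge_index out of range")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("outline has non-finite coordinates")
        self.points = pts
        poly = Polygon(pts)
        if not poly.is_valid:
            raise GeometryError("outline is self-intersecting or otherwise invalid")
        if poly.area <= 0:
            raise GeometryError("outline encloses zero area")

    @property
    def hinge(self) -> np.ndarray:
        return self.points[self.hinge_index]

    def polygon(self) -> Polygon:
        return Polygon(self.points)


@dataclass
class MorphologySummary:
    """Per-wing size and shape metrics (mm / mg units at the interface)."""

    S: float            # single-wing area, mm^2
    R: float            # wingspan (hinge to tip), mm
    c_bar: float        # mean chord S / R, mm
    S2: float           # second-moment-of-area, mm^4
    S2_star: float      # S2 / (R^3 c_bar), dimensionless
    R_star: float | None = None   # R / m^(1/3), mm mg^(-1/3)
    mass: float | None = None     # body mass, mg
    specimen_id: str = ""

    def as_dict(self) -> dict[str, float]:
        d = {"S_mm2": self.S, "R_mm": self.R, "cbar_mm": self.c_bar,
             "S2_mm4": self.S2, "S2star": self.S2_star}
        if self.mass is not None:
            d["mass_mg"] = self.mass
            d["Rstar"] = self.R_star
        return d


@dataclass
class LandmarkConfiguration:
    """One fixed base landmark (index 0) plus equidistant semi-landmarks."""

    points: np.ndarray
    specimen_id: str = ""
    n_semilandmarks: int = field(init=False)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidParameterError("landmarks must be an (N, 2) array")
        self.points = pts
        self.n_semilandmarks = len(pts) - 1


def _span_frame(outline: WingOutline) -> tuple[np.ndarray, float]:
    """Outline coordinates in the span frame: hinge at origin, span on +x.

    The span axis is the ray from the hinge through the area centroid of the
    outline; ``R`` is the maximum projection of the outline onto that axis.
    For wing shapes (hinge at the base, area spread spanwise) this coincides
    with the hinge-to-tip line, and it stays well defined for blunt-tipped
    outlines where the vertex farthest from the hinge is a corner.
    """
    pts = outline.points - outline.hinge
    cen = Polygon(pts).centroid
    u = np.array([cen.x, cen.y])
    norm = np.hypot(*u)
    if norm <= 0:
        raise GeometryError("degenerate outline: centroid coincides with hinge")
    u /= norm
    proj = pts @ u
    R = float(proj.max())
    if R <= 0:
        raise GeometryError("degenerate outline: no extent along the span axis")
    rot = np.array([[u[0], u[1]], [-u[1], u[0]]])
    return pts @ rot.T, R


def chord_profile(outline: WingOutline, r: np.ndarray) -> np.ndarray:
    """Local chord (total intersection length) at radial stations ``r``."""
    pts, _R = _span_frame(outline)
    poly = Polygon(pts)
    ylo = pts[:, 1].min() - 1.0
    yhi = pts[:, 1].max() + 1.0
    lines = shapely.linestrings(
        [[[float(x), ylo], [float(x), yhi]] for x in np.asarray(r, dtype=float)]
    )
    inter = shapely.intersection(lines, poly)
    return shapely.length(inter)


def morphology_from_outline(
    outline: WingOutline,
    mass: float | None = None,
    n_strips: int = 1000,
) -> MorphologySummary:
    """Measure S, R, c̄, S2, S2* (and R* when mass is given) from an outline.

    Area comes from the polygon (shoelace) and is cross-checked against
    midpoint-rule strip integration of the chord profile, which must agree
    within 0.5%; ``S2`` is the strip sum of ``c(r) r^2 Δr``.
    """
    if n_strips < 100:
        raise InvalidParameterError("n_strips must be >= 100")
    if mass is not None and mass <= 0:
        raise InvalidParameterError("mass must be > 0")
    pts, R = _span_frame(outline)
    poly = Polygon(pts)
    S = float(poly.area)
    if S <= 0:
        raise GeometryError("outline encloses zero area")
    dr = R / n_strips
    r_mid = (np.arange(n_strips) + 0.5) * dr
    c = chord_profile(outline, r_mid)
    S_strips = float(np.sum(c) * dr)
    if abs(S_strips - S) > 0.005 * S:
        raise GeometryError(
            f"strip-integrated area {S_strips:.6g} deviates from polygon area "
            f"{S:.6g} by more than 0.5%; outline may be degenerate"
        )
    S2 = float(np.sum(c * r_mid**2) * dr)
    c_bar = S / R
    S2_star = S2 / (R**3 * c_bar)
    R_star = None if mass is None else R / mass ** (1.0 / 3.0)
    return MorphologySummary(
        S=S, R=R, c_bar=c_bar, S2=S2, S2_star=S2_star,
        R_star=R_star, mass=mass, specimen_id=outline.specimen_id,
    )


def resample_semilandmarks(outline: WingOutline, n: int = 300) -> LandmarkConfiguration:
    """Equidistant arc-length resampling into 1 base landmark + ``n`` semi-landmarks.

    All ``n + 1`` points are uniformly spaced along the closed outline
    (spacing ``L / (n + 1)``) starting from the hinge, after normalising the
    traversal orientation to counter-clockwise.
    """
    if n < 3:
        raise InvalidParameterError("need at least 3 semi-landmarks")
    pts = outline.points
    # rotate vertex order so hinge is first
    pts = np.roll(pts, -outline.hinge_index, axis=0)
    # orientation: counter-clockwise (positive signed area)
    x, y = pts[:, 0], pts[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed < 0:
        pts = np.concatenate([pts[:1], pts[1:][::-1]], axis=0)
    ring = np.vstack([pts, pts[:1]])
    seg = np.hypot(np.diff(ring[:, 0]), np.diff(ring[:, 1]))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    L = s[-1]
    if L <= 0:
        raise GeometryError("outline has zero perimeter")
    targets = np.arange(n + 1) * L / (n + 1)
    xs = np.interp(targets, s, ring[:, 0])
    ys = np.interp(targets, s, ring[:, 1])
    return LandmarkConfiguration(
        points=np.column_stack([xs, ys]), specimen_id=outline.specimen_id
    )


# ---------------------------------------------------------------------------
# Generalised Procrustes analysis
# ---------------------------------------------------------------------------

def _center_scale(config: np.ndarray) -> np.ndarray:
    c = config - config.mean(axis=0)
    size = np.sqrt(np.sum(c**2))
    if size <= 0:
        raise GeometryError("degenerate landmark configuration (all points identical)")
    return c / size

def _rotate_to(config: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation (no reflection) of ``config`` onto ``target``."""
    M = config.T @ target
    U, _s, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    Rm = U @ D @ Vt
    return config @ Rm


class GeneralizedProcrustes(BaseEstimator, TransformerMixin):
    """Generalised Procrustes superimposition of 2-D landmark configurations.

    Removes position (centroid translation), size (unit centroid size), and
    orientation (least-squares rotation to an iteratively re-estimated mean
    shape), leaving pure shape variation.  Left wings should be mirrored to
    the right-wing convention *before* alignment; reflections are not fitted.

    Parameters
    ----------
    tol : float
        Convergence threshold on the root-mean-square change of the mean
        shape between iterations.
    max_iter : int
        Iteration cap for the mean-shape update loop.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        configs = self._as_array(X)
        aligned = np.stack([_center_scale(c) for c in configs])
        mean = aligned[0].copy()
        for it in range(self.max_iter):
            aligned = np.stack([_rotate_to(c, mean) for c in aligned])
            new_mean = _center_scale(aligned.mean(axis=0))
            new_mean = _rotate_to(new_mean, mean)
            delta = np.sqrt(np.mean((new_mean - mean) ** 2))
            mean = new_mean
            if delta < self.tol:
                break
        self.mean_shape_ = self._canonical_orientation(mean)
        self.n_iter_ = it + 1
        self.n_landmarks_ = mean.shape[0]
        return self

    def transform(self, X):
        configs = self._as_array(X)
        if configs.shape[1] != self.mean_shape_.shape[0]:
            raise AlignmentErrorLike()
        return np.stack(
            [_rotate_to(_center_scale(c), self.mean_shape_) for c in configs]
        )

    @staticmethod
    def _canonical_orientation(mean: np.ndarray) -> np.ndarray:
        """Rotate the mean shape to a deterministic orientation.

        The GPA optimum is only defined up to a global rotation; fixing the
        mean's principal axis to +x (sign set by the landmark with the
        largest axial coordinate) makes alignment idempotent and
        reproducible.
        """
        _evals, evecs = np.linalg.eigh(mean.T @ mean)
        u = evecs[:, -1]
        proj = mean @ u
        if proj[np.argmax(np.abs(proj))] < 0:
            u = -u
        rot = np.column_stack([u, [-u[1], u[0]]])
        return mean @ rot

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, (list, tuple)):
            arrs = [c.points if isinstance(c, LandmarkConfiguration) else np.asarray(c, float)
                    for c in X]
            shapes = {a.shape for a in arrs}
            if len(shapes) != 1:
                raise InvalidParameterError("configurations must share landmark count")
            X = np.stack(arrs)
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 2 or X.shape[0] < 2:
            raise InvalidParameterError("need >= 2 configurations of shape (k, 2)")
        return X


class AlignmentErrorLike(GeometryError):
    """Landmark counts do not match the fitted mean shape."""


def procrustes_align(configs) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper: returns (aligned configurations, mean shape)."""
    gpa = GeneralizedProcrustes().fit(configs)
    return gpa.transform(configs), gpa.mean_shape_


def flatten_configurations(configs, labels) -> pd.DataFrame:
    """Stack (k, 2) configurations into an (n, 2k) species-indexed matrix."""
    arr = GeneralizedProcrustes._as_array(configs)
    flat = arr.reshape(arr.shape[0], -1)
    return pd.DataFrame(flat, index=list(labels))


# ---------------------------------------------------------------------------
# Phylogenetic PCA
# ---------------------------------------------------------------------------

class PhylogeneticPCA(BaseEstimator, TransformerMixin):
    """PCA of the phylogenetically corrected covariance (Brownian motion).

    The trait matrix is centred on the GLS (phylogenetic) mean and the
    covariance is weighted by the inverse of the Brownian-motion tip
    covariance ``C`` from the tree; eigenvectors of that matrix are the
    components.  On a star phylogeny with equal branch lengths this reduces
    to ordinary PCA.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree with branch lengths; tip labels must match the row index
        of the trait matrix passed to :meth:`fit`.
    n_components : int or None
        Number of components to keep (default: all with positive variance).
    """

    def __init__(self, tree: dendropy.Tree = None, n_components: int | None = None):
        self.tree = tree
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        if self.tree is None:
            raise InvalidParameterError("PhylogeneticPCA requires a tree")
        X = self._as_frame(X)
        if len(X) < 3:
            raise InvalidParameterError("need >= 3 species")
        C = vcv_matrix(self.tree)
        missing = set(X.index) - set(C.index)
        if missing:
            raise LabelMismatchError(f"species not in tree: {sorted(missing)}")
        C = C.loc[X.index, X.index].to_numpy()
        L = cholesky_or_raise(C)
        n = len(X)
        ones = np.ones(n)
        Xv = X.to_numpy()
        Ci_one = np.linalg.solve(C, ones)
        w = Ci_one / (ones @ Ci_one)
        a = w @ Xv                      # phylogenetic (GLS) mean, shape (p,)
        Xc = Xv - a
        Z = np.linalg.solve(L, Xc)      # whitened residuals
        R = (Z.T @ Z) / (n - 1)
        evals, evecs = np.linalg.eigh(R)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        k = self.n_components or int(np.sum(evals > max(evals[0], 1e-300) * 1e-12))
        k = max(k, 1)
        self.mean_ = a
        self.components_ = evecs[:, :k].T
        self.explained_variance_ = evals[:k]
        total = evals.sum()
        self.explained_variance_ratio_ = (
            evals[:k] / total if total > 0 else np.zeros(k)
        )
        self.percent_variance_ = 100.0 * self.explained_variance_ratio_
        self.species_ = list(X.index)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._as_frame(X)
        scores = (X.to_numpy() - self.mean_) @ self.components_.T
        cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
        return pd.DataFrame(scores, index=X.index, columns=cols)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise InvalidParameterError("X must be a species-indexed DataFrame")
        return X.astype(float)


def phylo_pca(X: pd.DataFrame, tree: dendropy.Tree) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Functional wrapper: (scores, component loadings, percent variance)."""
    est = PhylogeneticPCA(tree=tree).fit(X)
    return est.transform(X), est.components_, est.percent_variance_
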