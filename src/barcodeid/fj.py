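"""FJ-Curve encoding: tetrahedral chaos-game representation of DNA.

The four bases sit at the corners of a regular tetrahedron,
A = (-1, 1, -1), G = (1, 1, 1), C = (1, -1, -1), T = (-1, -1, 1).
Starting from the origin, each successive base moves the current point
halfway toward its vertex (Jeffrey's chaos-game rule), producing a zigzag
3-D polyline of N + 1 points that stays inside the tetrahedron and is
sensitive to base order, not just composition.

A curve is summarised by five descriptors: the centroid of its points
(three coordinates) and the leading eigenvalues of two pairwise ratio
matrices over the curve's points — L/L (Euclidean distance over along-curve
path length) and M/M (Euclidean distance over edge-count graph distance).
Because L/L and M/M carry overlapping information, descriptor sets are
decorrelated by PCA, dropping components that explain less than a threshold
(default 1%) of total variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .errors import (
    DegenerateDescriptorError,
    DegenerateVarianceError,
    EncodingError,
    MalformedCurveError,
)

#: vertex coordinates of the base tetrahedron, row order A, C, G, T
VERTICES: dict[str, np.ndarray] = {
    "A": np.array([-1.0, 1.0, -1.0]),
    "G": np.array([1.0, 1.0, 1.0]),
    "C": np.array([1.0, -1.0, -1.0]),
    "T": np.array([-1.0, -1.0, 1.0]),
}

_VERTEX_TABLE = np.array([VERTICES[b] for b in "ACGT"])
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

#: matrices above this size use power iteration instead of a dense solve
DENSE_EIG_LIMIT = 2048
_POWER_TOL = 1e-10
_POWER_MAX_ITER = 10_000


def fj_curve(sequence: str) -> np.ndarray:
    """Build the FJ-Curve: (N + 1) x 3 array of points, P_0 = origin.

    P_i = (P_{i-1} + V(s_i)) / 2 where V(s_i) is the vertex of base s_i.
    """
    if not sequence:
        raise EncodingError("cannot encode an empty sequence")
    try:
        idx = np.array([_BASE_INDEX[b] for b in sequence], dtype=np.intp)
    except KeyError as exc:
        raise EncodingError(f"sequence contains non-ACGT symbol {exc.args[0]!r}") from None
    vertices = _VERTEX_TABLE[idx]
    points = np.zeros((idx.size + 1, 3))
    p = points[0]
    for i in range(idx.size):
        p = (p + vertices[i]) / 2.0
        points[i + 1] = p
    return points


def centroid_descriptors(curve: np.ndarray) -> np.ndarray:
    """Arithmetic mean of P_1..P_N (the origin carries no sequence signal)."""
    curve = np.asarray(curve, dtype=float)
    if curve.shape[0] < 2:
        raise DegenerateDescriptorError("centroid undefined for an empty curve")
    return curve[1:].mean(axis=0)


def _check_curve(curve: np.ndarray) -> np.ndarray:
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[0] < 2:
        raise MalformedCurveError("curve must hold at least two points")
    return curve


def ll_matrix(curve: np.ndarray) -> np.ndarray:
    """L/L ratio matrix: Euclidean distance over along-curve path length.

    Entry (i, j) divides the straight-line distance between points i and j
    by the summed segment lengths between them along the polyline; adjacent
    points give exactly 1, and no entry can exceed 1.
    """
    curve = _check_curve(curve)
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    if np.any(seg == 0):
        raise MalformedCurveError("coincident consecutive points give zero path length")
    euclid = squareform(pdist(curve))
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    path = np.abs(cum[:, None] - cum[None, :])
    with np.errstate(invalid="ignore"):
        out = np.where(path > 0, euclid / np.where(path > 0, path, 1.0), 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def mm_matrix(curve: np.ndarray) -> np.ndarray:
    """M/M ratio matrix: Euclidean distance over graph distance |i - j|."""
    curve = _check_curve(curve)
    n = curve.shape[0]
    euclid = squareform(pdist(curve))
    graph = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    np.fill_diagonal(graph, 1.0)  # avoid 0/0; diagonal reset below
    out = euclid / graph
    np.fill_diagonal(out, 0.0)
    return out


def leading_eigenvalue(m: np.ndarray) -> float:
    """Largest eigenvalue of a symmetric matrix.

    Dense symmetric solve up to :data:`DENSE_EIG_LIMIT`; shifted power
    iteration (tolerance 1e-10) beyond it.  For the non-negative ratio
    matrices used here the largest eigenvalue equals the spectral radius.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    n = m.shape[0]
    if n <= DENSE_EIG_LIMIT:
        return float(eigh(m, eigvals_only=True, subset_by_index=[n - 1, n - 1])[0])
    # shift by a Gershgorin bound so all eigenvalues are non-negative and the
    # power method converges to the algebraically largest
    shift = float(np.abs(m).sum(axis=1).max())
    a = m + shift * np.eye(n)
    rng = np.random.default_rng(0)
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(_POWER_MAX_ITER):
        w = a @ v
        lam = float(v @ w)
        residual = np.linalg.norm(w - lam * v)
        v = w / np.linalg.norm(w)
        if residual < _POWER_TOL * max(1.0, abs(lam)):
            break
    return lam - shift


def fj_feature_vector(sequence: str) -> np.ndarray:
    """Five-component FJ characterization.

    Order: (centroid_x, centroid_y, centroid_z, leading eigenvalue of L/L,
    leading eigenvalue of M/M).
    """
    curve = fj_curve(sequence)
    cx, cy, cz = centroid_descriptors(curve)
    lam_ll = leading_eigenvalue(ll_matrix(curve))
    lam_mm = leading_eigenvalue(mm_matrix(curve))
    return np.array([cx, cy, cz, lam_ll, lam_mm])


def fj_feature_matrix(sequences: list[str]) -> np.ndarray:
    return np.array([fj_feature_vector(s) for s in sequences])


@dataclass
class PcaTransform:
    """A fitted standardize-then-project transform.

    Columns are centered and scaled to unit variance with statistics from the
    fit set, then projected onto the principal components whose explained
    variance ratio reaches ``threshold``.  Fitting on the reference library
    only (never on queries) keeps evaluation splits leak-free.
    """

    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (n_retained, n_features)
    explained_variance_ratio: np.ndarray
    threshold: float

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.center.size:
            raise ValueError(
                f"expected {self.center.size} features, got {x.shape[1]}"
            )
        z = (x - self.center) / self.scale
        return z @ self.loadings.T

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PcaTransform":
        return cls(
            center=np.array(d["center"]),
            scale=np.array(d["scale"]),
            loadings=np.array(d["loadings"]),
            explained_variance_ratio=np.array(d["explained_variance_ratio"]),
            threshold=float(d["threshold"]),
        )


def fit_pca(features: np.ndarray, threshold: float = 0.01) -> PcaTransform:
    """Fit a :class:`PcaTransform` on a feature matrix (rows = records).

    Components contributing less than ``threshold`` of total variance are
    dropped; at least one component is always retained.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two feature rows to fit PCA")
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    if np.all(scale == 0):
        raise DegenerateVarianceError("all feature columns are constant")
    scale = np.where(scale == 0, 1.0, scale)
    z = (x - center) / scale
    pca = PCA(n_components=min(x.shape))
    pca.fit(z)
    ratios = pca.explained_variance_ratio_
    keep = ratios >= threshold
    if not keep.any():
        keep[0] = True
    return PcaTransform(
        center=center,
        scale=scale,
        loadings=pca.components_[keep],
        explained_variance_ratio=ratios[keep],
        threshold=threshold,
    )


def apply_pca(t: PcaTransform, v: np.ndarray) -> np.ndarray:
    """Project feature vector(s) with a fitted transform."""
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    out = t.transform(v)
    return out[0] if single else out
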