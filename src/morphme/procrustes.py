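"""Generalized Procrustes analysis and shape-space summaries.

Configurations are centred, scaled to unit centroid size (CS), and
rotated — rotation only, reflections are never allowed — to minimize
the summed squared distance to an iteratively updated consensus.  The
resulting Procrustes shape coordinates live on the unit sphere in
``R^{2L}``; statistics are computed in the flat tangent plane obtained
by projecting orthogonally to the consensus direction.  The shape space
has ``2L - 4`` informative dimensions (four degrees of freedom are lost
to translation, scale and rotation).

"Procrustes shape distance" defaults to the Euclidean distance between
aligned coordinate vectors, the standard tangent-plane proxy; the
geodesic ``rho = arccos`` form backs the tangent-space diagnostic,
which checks that the two are interchangeable for the data at hand
(``r`` close to 1 and slope close to 1 in an origin-centred
regression, as expected for the low shape dispersion typical of
within-species data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from skbio import TreeNode

from .landmark_io import DigitizationDataset, LandmarkConfiguration, SpecimenMeta

__all__ = [
    "ShapeData",
    "DistanceMatrix",
    "PcaResult",
    "TangentDiagnostic",
    "centroid_size",
    "gpa",
    "gpa_arrays",
    "procrustes_distance_matrix",
    "tangent_diagnostic",
    "pca",
    "flag_outliers",
    "cluster_phenogram",
    "project_to_tangent",
]


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 1:
        raise ValueError("expected an L x 2 coordinate matrix with L >= 1")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centred**2)))


@dataclass
class ShapeData:
    """Procrustes-aligned shapes with consensus, sizes and tangent coordinates."""

    aligned: np.ndarray            # (n, L, 2), unit CS, centred, rotated
    consensus: np.ndarray          # (L, 2), unit CS
    cs: np.ndarray                 # (n,) centroid sizes, mm
    tangent: np.ndarray            # (n, 2L) tangent-plane coordinates
    meta: list[SpecimenMeta]
    landmark_labels: list[str]
    n_iterations: int = 0

    @property
    def n_records(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def flat(self) -> np.ndarray:
        """Aligned coordinates flattened to (n, 2L)."""
        return self.aligned.reshape(self.n_records, -1)

    def record_keys(self) -> list[str]:
        return [f"{m.individual_id}:{m.rep_label}" for m in self.meta]

    def select(self, mask: np.ndarray) -> "ShapeData":
        """Row subset (no re-superimposition)."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ShapeData(
            aligned=self.aligned[idx],
            consensus=self.consensus,
            cs=self.cs[idx],
            tangent=self.tangent[idx],
            meta=[self.meta[i] for i in idx],
            landmark_labels=self.landmark_labels,
            n_iterations=self.n_iterations,
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise shape-distance matrix with record labels."""

    d: np.ndarray
    labels: list[str]

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class PcaResult:
    """Principal components of a set of row vectors (covariance PCA)."""

    scores: np.ndarray            # (n, k)
    eigenvalues: np.ndarray       # (k,), non-increasing
    vectors: np.ndarray           # (k, p), rows are unit eigenvectors
    variance_fraction: np.ndarray # (k,), sums to 1 over non-null dimensions
    mean: np.ndarray              # (p,)


@dataclass
class TangentDiagnostic:
    """Agreement between tangent-plane and geodesic Procrustes distances."""

    r: float
    slope: float


def _optimal_rotations(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate each centred configuration in X (n,L,2) onto target (L,2).

    The optimal 2D rotation angle maximizing the inner product with the
    target has ``tan(theta) = sum(x ^ t) / sum(x . t)``; using a proper
    rotation matrix excludes reflections by construction.
    """
    dots = np.einsum("nlk,lk->n", X, target)
    crosses = np.einsum("nl,l->n", X[:, :, 0], target[:, 1]) \
        - np.einsum("nl,l->n", X[:, :, 1], target[:, 0])
    theta = np.arctan2(crosses, dots)
    c, s = np.cos(theta), np.sin(theta)
    # per-record rotation: [x', y'] = [c x - s y, s x + c y]
    out = np.empty_like(X)
    out[:, :, 0] = c[:, None] * X[:, :, 0] - s[:, None] * X[:, :, 1]
    out[:, :, 1] = s[:, None] * X[:, :, 0] + c[:, None] * X[:, :, 1]
    return out


def gpa_arrays(
    coords: np.ndarray,
    meta: list[SpecimenMeta],
    landmark_labels: list[str],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ShapeData:
    """Generalized Procrustes superimposition of raw (n, L, 2) coordinates.

    Each configuration is centred and pre-scaled to unit CS, then
    iteratively rotated to the consensus (initialized from the first
    record); the consensus is re-estimated, re-centred and re-scaled to
    unit CS each round until its Frobenius change falls below *tol*.
    Tangent coordinates are the aligned coordinates projected
    orthogonally to the consensus direction.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 1:
        raise ValueError("need at least one configuration")
    centred = coords - coords.mean(axis=1, keepdims=True)
    cs = np.sqrt(np.sum(centred**2, axis=(1, 2)))
    if np.any(cs == 0):
        bad = int(np.argmax(cs == 0))
        key = f"{meta[bad].individual_id}:{meta[bad].rep_label}" if meta else str(bad)
        raise ValueError(f"degenerate configuration with CS=0: record {key}")
    X = centred / cs[:, None, None]
    consensus = X[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        X = _optimal_rotations(X, consensus)
        new = X.mean(axis=0)
        new -= new.mean(axis=0)
        norm = np.sqrt(np.sum(new**2))
        if norm == 0:
            raise ValueError("degenerate consensus (all shapes cancel)")
        new /= norm
        change = np.sqrt(np.sum((new - consensus) ** 2))
        consensus = new
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3e})"
        )
    X = _optimal_rotations(X, consensus)
    flat = X.reshape(n, -1)
    c = consensus.ravel()
    tangent = flat - np.outer(flat @ c, c)
    return ShapeData(
        aligned=X,
        consensus=consensus,
        cs=cs,
        tangent=tangent,
        meta=list(meta),
        landmark_labels=list(landmark_labels),
        n_iterations=n_iter,
    )


def gpa(dataset: DigitizationDataset, tol: float = 1e-10, max_iter: int = 100) -> ShapeData:
    """Generalized Procrustes superimposition of a digitization dataset."""
    return gpa_arrays(
        dataset.coords_array(), dataset.metas, dataset.landmark_labels,
        tol=tol, max_iter=max_iter,
    )


def procrustes_distance_matrix(shape: ShapeData) -> DistanceMatrix:
    """Pairwise Euclidean distances between aligned coordinate vectors."""
    d = squareform(pdist(shape.flat()))
    return DistanceMatrix(d=d, labels=shape.record_keys())


def geodesic_distance_matrix(shape: ShapeData) -> DistanceMatrix:
    """Pairwise Procrustes geodesic distances rho = arccos(<x_i, x_j>)."""
    flat = shape.flat()
    gram = np.clip(flat @ flat.T, -1.0, 1.0)
    d = np.arccos(gram)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(d=d, labels=shape.record_keys())


def tangent_diagnostic(shape: ShapeData) -> TangentDiagnostic:
    """Correlation and origin-centred slope of tangent vs geodesic distances.

    With low shape dispersion the Euclidean tangent approximation of the
    curved shape space is excellent (r and slope both ~1); widely
    dispersed shapes give slope < 1 because chordal/tangent distances
    shrink relative to the arc.
    """
    if shape.n_records < 2:
        raise ValueError("need at least 2 records")
    t = pdist(shape.tangent)
    g = squareform(geodesic_distance_matrix(shape).d, checks=False)
    if np.allclose(g, 0):
        raise ValueError("no shape variation: all shapes identical")
    slope = float(np.sum(t * g) / np.sum(g * g))
    if len(t) < 2 or np.std(t) == 0 or np.std(g) == 0:
        r = 1.0  # a single distance pair (or constant distances) fits perfectly
    else:
        r = float(pearsonr(t, g)[0])
    return TangentDiagnostic(r=r, slope=slope)


def pca(vectors: np.ndarray, tol: float = 1e-12) -> PcaResult:
    """Covariance-matrix PCA with a deterministic sign convention.

    Eigenvectors are ordered by non-increasing eigenvalue; each
    eigenvector's largest-magnitude loading is forced positive (PC signs
    are arbitrary, a fixed convention keeps results reproducible).
    Variance fractions are computed over the positive eigenvalues only.
    """
    vectors = np.asarray(vectors, dtype=float)
    n, p = vectors.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    mean = vectors.mean(axis=0)
    centred = vectors - mean
    cov = centred.T @ centred / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evals = np.where(evals < tol * max(evals.max(), 1.0), 0.0, evals)
    k = int(np.count_nonzero(evals > 0))
    k = max(k, 1)
    evals = evals[:k]
    evecs = evecs[:, :k]
    # sign convention: largest-|loading| positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    scores = centred @ evecs
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    return PcaResult(
        scores=scores,
        eigenvalues=evals,
        vectors=evecs.T,
        variance_fraction=frac,
        mean=mean,
    )


def flag_outliers(shape: ShapeData) -> list[tuple[str, float]]:
    """Records ranked by decreasing Procrustes distance to the consensus.

    Ranking only — nothing is excluded automatically: a large distance
    may itself be a digitization error worth keeping in an error study.
    """
    d = np.linalg.norm(shape.flat() - shape.consensus.ravel(), axis=1)
    order = np.argsort(-d, kind="stable")
    keys = shape.record_keys()
    return [(keys[i], float(d[i])) for i in order]


def cluster_phenogram(dm: DistanceMatrix, method: str = "UPGMA") -> TreeNode:
    """Agglomerative phenogram (UPGMA = average linkage, NN = single linkage).

    Returns a tree with branch lengths; leaf names are the distance
    matrix labels.  UPGMA merge heights are non-decreasing.
    """
    methods = {"UPGMA": "average", "NN": "single"}
    if method not in methods:
        raise ValueError(f"method must be one of {sorted(methods)}, got {method!r}")
    if dm.d.shape[0] < 2:
        raise ValueError("need at least 2 records to cluster")
    Z = linkage(dm.condensed(), method=methods[method])
    return TreeNode.from_linkage_matrix(Z, dm.labels)


def project_to_tangent(vector: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Project a flat (2L,) displacement into the tangent space at the consensus.

    Removes the components along the similarity-transformation
    directions — x/y translation, scaling (the consensus direction
    itself) and infinitesimal rotation (the 90-degree-rotated
    consensus) — and normalizes to unit length.  Useful for comparing
    an injected raw-coordinate bias with directions recovered in shape
    space.
    """
    v = np.asarray(vector, dtype=float).ravel().copy()
    L = v.size // 2
    cons = np.asarray(consensus, dtype=float).reshape(L, 2)
    basis = []
    tx = np.zeros((L, 2)); tx[:, 0] = 1.0
    ty = np.zeros((L, 2)); ty[:, 1] = 1.0
    rot = np.stack([-cons[:, 1], cons[:, 0]], axis=1)
    for b in (tx.ravel(), ty.ravel(), cons.ravel(), rot.ravel()):
        b = b / np.linalg.norm(b)
        for prev in basis:
            b = b - (b @ prev) * prev
        b /= np.linalg.norm(b)
        basis.append(b)
    for b in basis:
        v -= (v @ b) * b
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("vector lies entirely in the similarity subspace")
    return v / norm
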