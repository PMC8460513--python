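"""Per-vertex principal curvatures, curvedness, and shape index.

The estimator fits an osculating quadric over an n-ring vertex neighborhood
in the local tangent frame (robust on irregular marching-cubes triangles) and
takes the eigenvalues of the resulting shape operator. Sign convention: with
outward normals, a convex-outward sphere of radius R has k1 = k2 = +1/R, so
gyri carry positive shape index and sulci negative.

Curvedness C = sqrt((k1^2 + k2^2)/2)   (mm^-1, bending magnitude)
Shape index SI = (2/pi) atan((k1 + k2)/(k1 - k2)),  k1 >= k2, SI in [-1, 1];
at umbilic points (k1 == k2) SI is defined by continuity as sign(k1) * 1, and
it is masked invalid where C falls below a flatness tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix

from .errors import ParameterError
from .io import SurfaceMesh

__all__ = ["CurvatureField", "principal_curvatures", "curvedness",
           "shape_index", "curvature_field"]

FLAT_TOL = 1e-4  # mm^-1; below this curvedness SI is undefined (planar point)


@dataclass
class CurvatureField:
    k1: np.ndarray
    k2: np.ndarray
    curvedness: np.ndarray
    shape_index: np.ndarray
    valid: np.ndarray

    def summary(self, mesh: SurfaceMesh) -> dict:
        """Area-weighted summary statistics over valid vertices."""
        w = mesh.vertex_areas()
        ok = self.valid
        wv = w[ok]
        if wv.sum() == 0:
            return {k: float("nan") for k in
                    ("mean_curvedness", "median_curvedness", "mean_shape_index",
                     "median_shape_index", "gyral_area_fraction", "valid_fraction")}
        def wmean(x):
            return float(np.sum(wv * x[ok]) / wv.sum())
        def wmedian(x):
            order = np.argsort(x[ok])
            cw = np.cumsum(wv[order])
            return float(x[ok][order][np.searchsorted(cw, 0.5 * cw[-1])])
        return {
            "mean_curvedness": wmean(self.curvedness),
            "median_curvedness": wmedian(self.curvedness),
            "mean_shape_index": wmean(self.shape_index),
            "median_shape_index": wmedian(self.shape_index),
            "gyral_area_fraction": float(np.sum(wv * (self.shape_index[ok] > 0)) / wv.sum()),
            "valid_fraction": float(ok.mean()),
        }


def _vertex_adjacency(mesh: SurfaceMesh):
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
    n = mesh.n_vertices
    adj = coo_matrix((np.ones(len(rows), bool), (rows, cols)), shape=(n, n)).tocsr()
    adj.data[:] = True
    return adj


def _vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    v, f = mesh.vertices, mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # area-weighted
    vn = np.zeros_like(v)
    for k in range(3):
        np.add.at(vn, f[:, k], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vn / norms


def principal_curvatures(mesh: SurfaceMesh, neighborhood_rings: int = 2):
    """Per-vertex (k1, k2, valid) with k1 >= k2, via local quadric fits.

    Vertices with fewer than 5 neighbors in the n-ring are marked invalid.
    """
    if neighborhood_rings < 1:
        raise ParameterError("neighborhood_rings must be >= 1")
    n = mesh.n_vertices
    adj = _vertex_adjacency(mesh)
    reach = adj.copy()
    for _ in range(neighborhood_rings - 1):
        reach = ((reach @ adj) + reach).astype(bool)
    reach = reach.tocsr()
    normals = _vertex_normals(mesh)
    v = mesh.vertices
    k1 = np.zeros(n)
    k2 = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    indptr, indices = reach.indptr, reach.indices
    for i in range(n):
        nb = indices[indptr[i]:indptr[i + 1]]
        nb = nb[nb != i]
        if len(nb) < 5:
            continue
        nrm = normals[i]
        # local tangent frame (e1, e2, nrm)
        ref = np.array([1.0, 0.0, 0.0]) if abs(nrm[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(nrm, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(nrm, e1)
        d = v[nb] - v[i]
        x = d @ e1
        y = d @ e2
        h = d @ nrm
        # h(x,y) = a x^2 + b xy + c y^2 + d x + e y
        A = np.column_stack([x * x, x * y, y * y, x, y])
        coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        a, b, c, dx, ey = coef
        # first/second fundamental forms of the Monge patch, normal = +nrm
        denom = np.sqrt(1.0 + dx * dx + ey * ey)
        E = 1.0 + dx * dx
        F = dx * ey
        G = 1.0 + ey * ey
        L = 2.0 * a / denom
        M = b / denom
        N = 2.0 * c / denom
        # shape operator = I^-1 II; negate so outward-convex is positive
        det = E * G - F * F
        S = -np.array([[G * L - F * M, G * M - F * N],
                       [E * M - F * L, E * N - F * M]]) / det
        ev = np.linalg.eigvals(0.5 * (S + S.T)).real
        k1[i], k2[i] = max(ev), min(ev)
        valid[i] = True
    return k1, k2, valid


def curvedness(k1: np.ndarray, k2: np.ndarray) -> np.ndarray:
    """sqrt((k1^2 + k2^2)/2), the bending magnitude in mm^-1."""
    k1 = np.asarray(k1, float)
    k2 = np.asarray(k2, float)
    if np.any(k1 < k2):
        raise ParameterError("principal curvatures must satisfy k1 >= k2")
    return np.sqrt((k1 * k1 + k2 * k2) / 2.0)


def shape_index(k1, k2, tol: float = FLAT_TOL):
    """(SI, valid): SI = (2/pi) atan((k1+k2)/(k1-k2)) in [-1, 1].

    Umbilic points (k1 == k2) take the continuity limit sign(k1); points with
    curvedness below ``tol`` are flagged invalid (SI undefined on planes).
    """
    k1 = np.atleast_1d(np.asarray(k1, float))
    k2 = np.atleast_1d(np.asarray(k2, float))
    if np.any(k1 < k2):
        raise ParameterError("principal curvatures must satisfy k1 >= k2")
    c = curvedness(k1, k2)
    si = np.zeros_like(k1)
    umbilic = np.isclose(k1, k2, rtol=0.0, atol=1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        si[~umbilic] = (2.0 / np.pi) * np.arctan(
            (k1[~umbilic] + k2[~umbilic]) / (k1[~umbilic] - k2[~umbilic]))
    si[umbilic] = np.sign(k1[umbilic])
    si = np.clip(si, -1.0, 1.0)
    return si, c >= tol


def curvature_field(mesh: SurfaceMesh, neighborhood_rings: int = 2,
                    tol: float = FLAT_TOL) -> CurvatureField:
    """Full per-vertex curvature field with validity mask."""
    k1, k2, ok = principal_curvatures(mesh, neighborhood_rings)
    c = curvedness(k1, k2)
    si, flat_ok = shape_index(k1, k2, tol=tol)
    valid = ok & flat_ok
    return CurvatureField(k1=k1, k2=k2, curvedness=c, shape_index=si, valid=valid)
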