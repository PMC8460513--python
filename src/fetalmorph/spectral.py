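"""Spectral mesh correspondence for longitudinal surface pairs.

Pipeline: a rigid coherent-point-drift (CPD) alignment gives initial
inter-surface links; the two cotangent Laplacians are assembled into one
dual-layer graph whose layers are tied by those links; the shared low
eigenmodes of the joint operator embed both surfaces in a common spectral
space (sign and order consistent by construction); each post-surface vertex
is then matched to its nearest pre-surface vertex in that space, optionally
augmented with normalized 3D coordinates. Scalar fields measured on the post
surface (curvedness, shape index) are pulled back to the pre surface through
the correspondence and differenced vertex-wise (post minus pre).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .errors import ConnectivityError, NumericError, RegistrationError
from .io import SurfaceMesh

__all__ = ["SpectralEmbedding", "Correspondence", "RigidTransform",
           "mesh_laplacian", "lumped_mass", "spectral_embedding", "cpd_rigid",
           "joint_spectral_match", "transfer_field", "delta_field"]


# ---------------------------------------------------------------------------
# Laplacians
# ---------------------------------------------------------------------------

def mesh_laplacian(mesh: SurfaceMesh, kind: str = "cotangent",
                   require_connected: bool = True) -> sp.csr_matrix:
    """Symmetric PSD mesh Laplacian (row sums zero).

    ``cotangent`` uses the standard half-cotangent edge weights (geometry
    aware); ``combinatorial`` uses unit weights. Non-finite or negative
    cotangent weights from degenerate triangles are clamped to a small
    positive floor, preserving positive semi-definiteness.
    """
    n = mesh.n_vertices
    f = mesh.faces
    v = mesh.vertices
    if kind not in ("cotangent", "combinatorial"):
        raise ValueError(f"unknown laplacian kind {kind!r}")
    ii, jj, ww = [], [], []
    for (a, b, c) in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        # cotangent at corner c, opposite edge (a, b)
        if kind == "cotangent":
            u = v[f[:, a]] - v[f[:, c]]
            w = v[f[:, b]] - v[f[:, c]]
            cross = np.linalg.norm(np.cross(u, w), axis=1)
            cot = np.einsum("ij,ij->i", u, w) / np.maximum(cross, 1e-12)
            wt = 0.5 * cot
            wt = np.where(np.isfinite(wt), wt, 0.0)
        else:
            wt = np.full(len(f), 0.5)  # each undirected edge visited twice
        ii.append(f[:, a]); jj.append(f[:, b]); ww.append(wt)
        ii.append(f[:, b]); jj.append(f[:, a]); ww.append(wt)
    W = sp.coo_matrix((np.concatenate(ww), (np.concatenate(ii), np.concatenate(jj))),
                      shape=(n, n)).tocsr()
    if kind == "cotangent":
        W.data = np.maximum(W.data, 1e-8)  # clamp degenerate negative weights
    deg = np.asarray(W.sum(axis=1)).ravel()
    L = sp.diags(deg) - W
    n_comp, _ = sp.csgraph.connected_components(W, directed=False)
    if n_comp > 1 and require_connected:
        raise ConnectivityError(f"mesh has {n_comp} connected components")
    return L.tocsr()


def lumped_mass(mesh: SurfaceMesh) -> sp.dia_matrix:
    """Diagonal (barycentric) vertex-area mass matrix."""
    return sp.diags(np.maximum(mesh.vertex_areas(), 1e-12))


@dataclass
class SpectralEmbedding:
    eigenvalues: np.ndarray   # ascending, length k
    eigenvectors: np.ndarray  # (N, k)
    laplacian_kind: str
    k: int


def _eigsh_smallest(L, M, k):
    n = L.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the vertex count")
    v0 = np.full(n, 1.0 / np.sqrt(n))
    try:
        vals, vecs = spla.eigsh(L, k=k, M=M, sigma=-1e-3, which="LM", v0=v0)
    except Exception as exc:  # pragma: no cover - solver-dependent
        raise NumericError(f"sparse eigensolver failed: {exc}") from exc
    order = np.argsort(vals)
    return np.maximum(vals[order], 0.0), vecs[:, order]


def spectral_embedding(mesh: SurfaceMesh, k: int = 30,
                       kind: str = "cotangent") -> SpectralEmbedding:
    """k smallest generalized eigenpairs of (L, mass); mode 0 is constant."""
    L = mesh_laplacian(mesh, kind=kind)
    M = lumped_mass(mesh)
    vals, vecs = _eigsh_smallest(L, M, k)
    # unit M-norm, deterministic sign: largest-magnitude entry positive
    for j in range(vecs.shape[1]):
        nrm = np.sqrt(vecs[:, j] @ (M @ vecs[:, j]))
        vecs[:, j] /= max(nrm, 1e-300)
        i_max = np.argmax(np.abs(vecs[:, j]))
        if vecs[i_max, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return SpectralEmbedding(np.maximum(vals, 0.0), vecs, kind, k)


# ---------------------------------------------------------------------------
# Rigid coherent point drift
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    rotation: np.ndarray   # (3, 3)
    translation: np.ndarray
    scale: float = 1.0

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return self.scale * pts @ self.rotation.T + self.translation


def _cpd_em(Xn: np.ndarray, Yn: np.ndarray, w: float, tol: float,
            max_iters: int, with_scaling: bool, R0: np.ndarray,
            anneal_rate: float = 0.9):
    """EM core on normalized clouds; returns (R, t, s, sigma2).

    A deterministic-annealing floor ``sigma2_0 * anneal_rate**iter`` keeps
    the kernel wide during early iterations, which broadens the convergence
    basin for rotational misalignments (and prevents the premature
    scale-collapse attractor of the free-scale model).
    """
    D = 3
    N, M = len(Xn), len(Yn)
    R = R0.copy()
    t = np.zeros(D)
    s = 1.0
    sigma2_0 = float(((Xn[:, None, :] - (Yn @ R.T)[None, :, :]) ** 2).sum(-1).mean()) / D
    sigma2 = sigma2_0
    for it in range(max_iters):
        floor = sigma2_0 * anneal_rate ** it if anneal_rate else 0.0
        sig = max(sigma2, floor)
        TY = s * Yn @ R.T + t
        d2 = ((Xn[:, None, :] - TY[None, :, :]) ** 2).sum(-1)
        c = (2 * np.pi * sig) ** (D / 2) * (w / (1 - w)) * (M / N)
        P = np.exp(-d2 / (2 * sig))
        P = P / np.maximum(P.sum(axis=1, keepdims=True) + c, 1e-300)
        Np = P.sum()
        if Np < 1e-10:
            break  # everything explained as outliers; keep last estimate
        Pt1 = P.sum(axis=1)
        P1 = P.sum(axis=0)
        mu_x = (Pt1 @ Xn) / Np
        mu_y = (P1 @ Yn) / Np
        Xh = Xn - mu_x
        Yh = Yn - mu_y
        A = Xh.T @ P @ Yh
        U, _, Vt = np.linalg.svd(A)
        C = np.eye(D)
        C[-1, -1] = np.sign(np.linalg.det(U @ Vt))
        R = U @ C @ Vt
        trAR = np.trace(A.T @ R)
        yPy = float((P1 * np.einsum("ij,ij->i", Yh, Yh)).sum())
        s = trAR / yPy if with_scaling else 1.0
        t = mu_x - s * R @ mu_y
        xPx = float((Pt1 * np.einsum("ij,ij->i", Xh, Xh)).sum())
        sigma2_new = (xPx - s * trAR) / (Np * D)
        if not np.isfinite(sigma2_new) or sigma2_new < 1e-10:
            sigma2 = 1e-10
            if floor < 1e-8:
                break
            continue
        if abs(sigma2 - sigma2_new) < tol * sigma2 and floor < sigma2_new:
            sigma2 = sigma2_new
            break
        sigma2 = sigma2_new
    return R, t, s, sigma2


def _pca_rotation_candidates(Xn: np.ndarray, Yn: np.ndarray):
    """Proper rotations aligning the principal axes of Y to those of X
    (4 sign combinations with det +1)."""
    _, Vy = np.linalg.eigh(np.cov(Yn.T))
    _, Vx = np.linalg.eigh(np.cov(Xn.T))
    out = []
    for sgn in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        R0 = Vx @ np.diag(sgn) @ Vy.T
        if np.linalg.det(R0) > 0:
            out.append(R0)
    return out or [np.eye(3)]


def cpd_rigid(source: np.ndarray, target: np.ndarray, w: float = 0.1,
              tol: float = 1e-6, max_iters: int = 200, with_scaling: bool = True,
              subsample: int | None = 1500, seed: int = 0,
              init: str = "identity", anneal_rate: float = 0.9) -> RigidTransform:
    """Rigid coherent point drift: EM fit of a GMM centered on the
    transformed source points to the target points, uniform outlier weight
    ``w``. Returns the similarity transform mapping source onto target.

    Clouds are internally centered and RMS-normalized (the returned
    transform is in world units); large clouds are subsampled for this
    initialization stage only. ``init="pca"`` additionally tries the four
    principal-axes alignments and keeps the candidate with the lowest final
    GMM variance — useful when the initial misalignment is large.
    """
    X = np.asarray(target, float)
    Y = np.asarray(source, float)
    if len(X) < 4 or len(Y) < 4:
        raise RegistrationError("need at least 4 points on each side")
    if np.linalg.matrix_rank(X - X.mean(0)) < 3 or np.linalg.matrix_rank(Y - Y.mean(0)) < 3:
        raise RegistrationError("degenerate (coplanar) point geometry")
    rng = np.random.default_rng(seed)
    if subsample is not None:
        if len(X) > subsample:
            X = X[rng.choice(len(X), subsample, replace=False)]
        if len(Y) > subsample:
            Y = Y[rng.choice(len(Y), subsample, replace=False)]
    mx, my = X.mean(0), Y.mean(0)
    sx = float(np.sqrt(((X - mx) ** 2).sum(1).mean()))
    sy = float(np.sqrt(((Y - my) ** 2).sum(1).mean()))
    Xn = (X - mx) / sx
    Yn = (Y - my) / sy
    if init == "identity":
        starts = [np.eye(3)]
    elif init == "pca":
        starts = [np.eye(3)] + _pca_rotation_candidates(Xn, Yn)
    else:
        raise ValueError(f"unknown init {init!r}")
    best = None
    for R0 in starts:
        R, t, s, sigma2 = _cpd_em(Xn, Yn, w, tol, max_iters, with_scaling, R0,
                                  anneal_rate=anneal_rate)
        if best is None or sigma2 < best[3]:
            best = (R, t, s, sigma2)
    R, t, s, _ = best
    s_world = s * sx / sy
    t_world = mx + sx * t - s_world * R @ my
    return RigidTransform(rotation=R, translation=t_world, scale=s_world)


# ---------------------------------------------------------------------------
# Joint spectral matching
# ---------------------------------------------------------------------------

@dataclass
class Correspondence:
    """post -> pre vertex correspondence.

    ``target_vertex[i]`` is the pre-surface vertex matched to post vertex i;
    ``n_target`` the pre vertex count; ``target_vertices`` (optional) the pre
    coordinates, used to fill pre vertices that no post vertex selected when
    a field is pulled back.
    """
    target_vertex: np.ndarray
    match_cost: np.ndarray
    n_target: int
    direction: str = "post->pre"
    transform: RigidTransform | None = None
    target_vertices: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def _mutual_nearest_links(a: np.ndarray, b: np.ndarray,
                          cap: int | None) -> np.ndarray:
    ta, tb = cKDTree(a), cKDTree(b)
    _, ab = tb.query(a)  # for each a, nearest b
    d_ba, ba = ta.query(b)  # for each b, nearest a
    mutual = np.flatnonzero(ba[ab] == np.arange(len(a)))
    links = np.column_stack([mutual, ab[mutual]])
    if cap is not None and len(links) > cap:
        d = np.linalg.norm(a[links[:, 0]] - b[links[:, 1]], axis=1)
        links = links[np.argsort(d)[:cap]]
    if len(links) == 0:
        raise RegistrationError("no mutual-nearest-neighbor links found")
    return links


def joint_spectral_match(pre: SurfaceMesh, post: SurfaceMesh, k: int = 30,
                         gamma: float = 1.0, link_cap_fraction: float = 1.0,
                         xyz_weight: float = 1.0, kind: str = "cotangent",
                         cpd_kwargs: dict | None = None) -> Correspondence:
    """Vertex correspondence post -> pre via dual-layer shared eigenmodes.

    CPD rigidly aligns the post surface to the pre surface; mutual nearest
    neighbors provide the inter-layer links (capped at ``link_cap_fraction``
    of the vertex count); links of weight ``gamma`` (relative to the mean
    intra-layer edge weight) tie the two Laplacians into one joint operator
    whose k smallest non-trivial modes embed both layers consistently; each
    post vertex matches its nearest pre vertex in the combined
    spectral + normalized-xyz feature space.
    """
    n_pre, n_post = pre.n_vertices, post.n_vertices
    tf = cpd_rigid(post.vertices, pre.vertices, **(cpd_kwargs or {}))
    post_aligned = tf.apply(post.vertices)
    cap = max(1, int(link_cap_fraction * min(n_pre, n_post))) \
        if link_cap_fraction else None
    links = _mutual_nearest_links(pre.vertices, post_aligned, cap)

    L1 = mesh_laplacian(pre, kind=kind)
    L2 = mesh_laplacian(post, kind=kind)
    M1 = lumped_mass(pre)
    M2 = lumped_mass(post)
    # link weight relative to the mean intra-layer (off-diagonal) edge weight
    off = L1.copy()
    off.setdiag(0.0)
    off.eliminate_zeros()
    mean_w = float(np.abs(off.data).mean()) if off.nnz else 1.0
    link_w = max(gamma * mean_w, 1e-8)
    rows = np.concatenate([links[:, 0], links[:, 1] + n_pre])
    cols = np.concatenate([links[:, 1] + n_pre, links[:, 0]])
    vals = np.full(2 * len(links), link_w)
    Wl = sp.coo_matrix((vals, (rows, cols)), shape=(n_pre + n_post,) * 2).tocsr()
    degl = sp.diags(np.asarray(Wl.sum(axis=1)).ravel())
    Lj = sp.block_diag([L1, L2]).tocsr() + (degl - Wl)
    Mj = sp.block_diag([M1, M2]).tocsr()
    vals_j, vecs_j = _eigsh_smallest(Lj, Mj, k + 1)
    modes = vecs_j[:, 1:]  # drop the constant mode
    lam = np.maximum(vals_j[1:], 1e-12)
    coords = modes / np.sqrt(lam)  # diffusion-style scaling

    feat_pre = coords[:n_pre]
    feat_post = coords[n_pre:]
    if xyz_weight > 0:
        bbox = pre.vertices.max(0) - pre.vertices.min(0)
        scale = np.linalg.norm(bbox)
        spec_scale = np.linalg.norm(feat_pre.std(axis=0))
        xyz_pre = pre.vertices / scale * spec_scale * xyz_weight / 0.3
        xyz_post = post_aligned / scale * spec_scale * xyz_weight / 0.3
        feat_pre = np.hstack([feat_pre, xyz_pre])
        feat_post = np.hstack([feat_post, xyz_post])
    tree = cKDTree(feat_pre)
    cost, idx = tree.query(feat_post)
    return Correspondence(target_vertex=idx.astype(np.int64),
                          match_cost=cost, n_target=n_pre, transform=tf,
                          target_vertices=pre.vertices.copy(),
                          meta={"k": k, "gamma": gamma, "links": len(links),
                                "eigenvalues": vals_j})


def transfer_field(corr: Correspondence, field_on_post: np.ndarray) -> np.ndarray:
    """Pull a post-surface per-vertex field back to the pre surface.

    Nearest-neighbor pull-back: each pre vertex receives the value of the
    post vertex matched to it (lowest match cost wins if several); pre
    vertices selected by no post vertex take the value of the spatially
    nearest matched pre vertex. The transferred range is therefore a subset
    of the source range (no extrapolation).
    """
    f = np.asarray(field_on_post, float)
    if len(f) != len(corr.target_vertex):
        raise ValueError("field length does not match post vertex count")
    out = np.full(corr.n_target, np.nan)
    order = np.argsort(corr.match_cost)[::-1]  # low-cost assignments last -> win
    out[corr.target_vertex[order]] = f[order]
    missing = np.flatnonzero(np.isnan(out))
    if len(missing):
        filled = np.flatnonzero(~np.isnan(out))
        if corr.target_vertices is not None:
            tree = cKDTree(corr.target_vertices[filled])
            _, j = tree.query(corr.target_vertices[missing])
        else:
            tree = cKDTree(filled[:, None].astype(float))
            _, j = tree.query(missing[:, None].astype(float))
        out[missing] = out[filled[j]]
    return out


def delta_field(pre_field: np.ndarray, transferred_post_field: np.ndarray) -> np.ndarray:
    """Post-minus-pre per-vertex change (B - A)."""
    a = np.asarray(pre_field, float)
    b = np.asarray(transferred_post_field, float)
    if a.shape != b.shape:
        raise ValueError("field lengths differ")
    return b - a
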