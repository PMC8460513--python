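"""Gyrified brain phantoms with known ground truth.

The phantom stands in for segmented fetal-brain MRI: an ellipsoidal
"unmyelinated white matter" compartment whose outer surface is modulated by a
band-limited spherical-harmonic fold pattern, an enclosed ellipsoidal
ventricular compartment, and a separate posterior-inferior cerebellar
ellipsoid. Because the folded surface is radially parameterized over the unit
sphere, ground-truth volumes, surface correspondence and landmarks are all
available in closed or quadrature form.

The fold pattern for a given seed is *fixed in shape* and grows only in
amplitude, so the pre and post surfaces of a longitudinal pair share one
angular parameterization and the ground-truth vertex correspondence is the
identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import trimesh
from scipy.optimize import brentq
from scipy.special import sph_harm_y

from .errors import ParameterError
from .io import DEFAULT_LABEL_MAP, LabelVolume, SurfaceMesh

__all__ = [
    "PhantomSpec", "PhantomTruth", "FoldField", "generate_phantom",
    "phantom_surface", "generate_longitudinal_pair", "phantom_landmarks",
    "reference_parcellation_labels",
]


# ---------------------------------------------------------------------------
# Fold pattern
# ---------------------------------------------------------------------------

class FoldField:
    """Band-limited real spherical-harmonic pattern on the unit sphere.

    A seeded random combination of the ``2l+1`` real harmonics of a single
    degree ``l``, normalized so that max |Y| ~= 1 over the sphere. Smooth,
    self-intersection-free for amplitudes below half the smallest semi-axis,
    and reproducible from the seed alone.
    """

    def __init__(self, degree: int, seed: int):
        self.degree = int(degree)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.coeffs = rng.standard_normal(2 * self.degree + 1)
        # normalize on a deterministic Fibonacci sampling of the sphere
        u = _fibonacci_sphere(8192)
        self._scale = 1.0
        raw = self(u)
        self._scale = 1.0 / max(np.abs(raw).max(), 1e-12)

    def __call__(self, u: np.ndarray) -> np.ndarray:
        """Evaluate at unit vectors ``u`` of shape (..., 3)."""
        u = np.asarray(u, dtype=float)
        theta = np.arccos(np.clip(u[..., 2], -1.0, 1.0))
        phi = np.arctan2(u[..., 1], u[..., 0])
        l = self.degree
        out = np.zeros(u.shape[:-1])
        for i, m in enumerate(range(-l, l + 1)):
            ylm = sph_harm_y(l, abs(m), theta, phi)
            if m > 0:
                basis = np.sqrt(2.0) * ylm.real
            elif m < 0:
                basis = np.sqrt(2.0) * ylm.imag
            else:
                basis = ylm.real
            out += self.coeffs[i] * basis
        return out * self._scale


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


# ---------------------------------------------------------------------------
# Specs and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic brain.

    ``semi_axes`` are the white-matter base-ellipsoid semi-axes (mm) in
    (x = left-right, y = anterior-posterior, z = superior-inferior) order.
    ``fold_amplitude`` is the world-mm amplitude of the radial perturbation,
    ``fold_frequency`` its spherical-harmonic degree. The ventricle is an
    interior ellipsoid with semi-axes ``ventricle_scale * semi_axes``; the
    cerebellum a separate ellipsoid placed posterior-inferiorly.
    """

    semi_axes: tuple = (30.0, 25.0, 20.0)
    fold_amplitude: float = 2.0
    fold_frequency: int = 6
    ventricle_scale: float = 0.35
    cerebellum_center: tuple = (0.0, -16.0, -28.0)
    cerebellum_semi_axes: tuple = (11.0, 7.0, 6.0)
    spacing: float = 0.8
    seed: int = 0
    cso_angle_deg: float = 80.0
    chl_mm: float = 6.0

    def __post_init__(self):
        a = np.asarray(self.semi_axes, float)
        if np.any(a <= 0) or self.spacing <= 0:
            raise ParameterError("semi-axes and spacing must be positive")
        if self.fold_amplitude < 0:
            raise ParameterError("fold_amplitude must be >= 0")
        if self.fold_amplitude >= a.min() / 2.0:
            raise ParameterError("fold_amplitude must stay below min(semi_axes)/2")
        if not (0.0 <= self.ventricle_scale < 1.0):
            raise ParameterError("ventricle_scale must lie in [0, 1)")
        # ventricle strictly inside the folded WM surface: along the worst
        # direction the surface radius is at least rho_min - amplitude.
        if self.ventricle_scale > 0:
            margin = (1.0 - self.fold_amplitude / a.min()) - self.ventricle_scale
            if margin <= 0.02:
                raise ParameterError("ventricle ellipsoid not strictly inside the WM surface")

    @property
    def fold_field(self) -> FoldField:
        return FoldField(self.fold_frequency, self.seed)


@dataclass
class PhantomTruth:
    """Analytic / quadrature reference values for one phantom."""

    wm_volume: float
    ventricle_volume: float
    cerebellum_volume: float
    wm_surface_area: float
    landmarks: dict = field(default_factory=dict)
    spec: Optional[PhantomSpec] = None


# ---------------------------------------------------------------------------
# Implicit geometry
# ---------------------------------------------------------------------------

def _wm_implicit(points: np.ndarray, spec: PhantomSpec, fold: FoldField) -> np.ndarray:
    """< 0 inside the folded WM outer surface, > 0 outside."""
    a = np.asarray(spec.semi_axes)
    q = points / a
    m = np.linalg.norm(q, axis=-1)
    out = np.empty_like(m)
    center = m < 1e-9
    out[center] = -1.0
    qn = q[~center] / m[~center, None]
    rho = np.linalg.norm(qn * a, axis=-1)
    bump = spec.fold_amplitude * fold(qn) / rho if spec.fold_amplitude > 0 else 0.0
    out[~center] = m[~center] - 1.0 - bump
    return out


def _surface_radius_factor(spec: PhantomSpec, fold: FoldField, u: np.ndarray) -> np.ndarray:
    """Radial scale 1 + A*Y/rho of the folded surface at unit directions u."""
    a = np.asarray(spec.semi_axes)
    rho = np.linalg.norm(u * a, axis=-1)
    if spec.fold_amplitude == 0:
        return np.ones(u.shape[:-1])
    return 1.0 + spec.fold_amplitude * fold(u) / rho


def _ellipsoid_volume(semi_axes) -> float:
    a, b, c = semi_axes
    return 4.0 / 3.0 * np.pi * a * b * c


def _wm_region_volume(spec: PhantomSpec, fold: FoldField,
                      n_theta: int = 160, n_phi: int = 320) -> float:
    """Volume enclosed by the folded outer surface, by exact radial
    integration with Gauss-Legendre x trapezoid angular quadrature."""
    x, w = np.polynomial.legendre.leggauss(n_theta)  # x = cos(theta)
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    ct = x[:, None]
    st = np.sqrt(1.0 - ct ** 2)
    u = np.stack([st * np.cos(phi)[None, :],
                  st * np.sin(phi)[None, :],
                  np.broadcast_to(ct, (n_theta, n_phi))], axis=-1)
    g = _surface_radius_factor(spec, fold, u)
    a, b, c = spec.semi_axes
    integrand = (g ** 3).sum(axis=1) * (2.0 * np.pi / n_phi)
    return float(a * b * c / 3.0 * (w * integrand).sum())


# ---------------------------------------------------------------------------
# Surfaces and landmarks
# ---------------------------------------------------------------------------

def phantom_surface(spec: PhantomSpec, structure: str = "unmyelinated_wm",
                    subdivisions: int = 4) -> SurfaceMesh:
    """Exact parameterized surface of a phantom structure.

    Built by mapping an icosphere through the radial fold function, so two
    phantoms that share a seed (and hence a fold pattern) have vertex-wise
    identical parameterizations regardless of size or amplitude.
    """
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(ico.vertices, float)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    a = np.asarray(spec.semi_axes)
    if structure == "unmyelinated_wm":
        g = _surface_radius_factor(spec, spec.fold_field, u)
        verts = g[:, None] * (u * a)
    elif structure == "ventricles":
        if spec.ventricle_scale <= 0:
            raise ParameterError("phantom has no ventricle compartment")
        verts = u * (spec.ventricle_scale * a)
    elif structure == "cerebellum":
        verts = u * np.asarray(spec.cerebellum_semi_axes) + np.asarray(spec.cerebellum_center)
    else:
        raise KeyError(f"unknown structure {structure!r}")
    return SurfaceMesh(verts, np.asarray(ico.faces, np.int64))


def phantom_landmarks(spec: PhantomSpec) -> dict:
    """Biometric landmarks placed by construction on the phantom geometry.

    TCD endpoints are the cerebellar lateral extremes; VW endpoints span the
    ventricular atrium width along x; the foramen-magnum plane passes through
    the cerebellar center ``chl_mm`` above the lowest cerebellar point; the
    clivus and supraocciput lines meet at ``cso_angle_deg`` in the
    midsagittal plane.
    """
    cc = np.asarray(spec.cerebellum_center)
    cs = np.asarray(spec.cerebellum_semi_axes)
    lm = {
        "tcd_left": cc + np.array([-cs[0], 0.0, 0.0]),
        "tcd_right": cc + np.array([cs[0], 0.0, 0.0]),
    }
    if spec.ventricle_scale > 0:
        va = spec.ventricle_scale * np.asarray(spec.semi_axes)
        lm["vw_medial"] = np.array([0.0, -va[1] * 0.3, 0.0])
        lm["vw_lateral"] = np.array([va[0], -va[1] * 0.3, 0.0])
    z_fm = cc[2] - cs[2] + spec.chl_mm
    lm["fm_plane_a"] = np.array([0.0, cc[1], z_fm])
    lm["fm_plane_b"] = np.array([10.0, cc[1], z_fm])
    lm["fm_plane_c"] = np.array([0.0, cc[1] + 10.0, z_fm])
    lm["cereb_lowest"] = cc + np.array([0.0, 0.0, -cs[2]])
    half = np.deg2rad(spec.cso_angle_deg) / 2.0
    base = np.array([0.0, cc[1], z_fm])
    d_clivus = np.array([0.0, np.sin(half), np.cos(half)])
    d_supra = np.array([0.0, -np.sin(half), np.cos(half)])
    lm["clivus_a"] = base
    lm["clivus_b"] = base + 15.0 * d_clivus
    lm["supraocciput_a"] = base
    lm["supraocciput_b"] = base + 15.0 * d_supra
    return {k: np.asarray(v, float) for k, v in lm.items()}


def reference_parcellation_labels(mesh: SurfaceMesh) -> np.ndarray:
    """Analytic 8-sector lobe labels for a phantom WM surface.

    Hemisphere from the sign of x; lobe from the angle of (y, z) about the
    centroid: frontal = anterior, parietal = superior, occipital = posterior,
    temporal = inferior. Returns per-vertex string codes from
    {LF, RF, LT, RT, LP, RP, LO, RO}.
    """
    v = mesh.vertices - mesh.vertices.mean(axis=0)
    hemi = np.where(v[:, 0] < 0, "L", "R")
    ang = np.degrees(np.arctan2(v[:, 2], v[:, 1]))  # 0 = anterior, 90 = superior
    lobe = np.full(len(v), "F", dtype="U1")
    lobe[(ang >= 45) & (ang < 135)] = "P"
    lobe[(ang >= 135) | (ang < -135)] = "O"
    lobe[(ang >= -135) & (ang < -45)] = "T"
    return np.char.add(hemi, lobe)


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

def _check_cerebellum_disjoint(spec: PhantomSpec, fold: FoldField) -> None:
    u = _fibonacci_sphere(2048)
    pts = u * np.asarray(spec.cerebellum_semi_axes) + np.asarray(spec.cerebellum_center)
    pts = np.vstack([pts, np.asarray(spec.cerebellum_center)[None, :]])
    if np.any(_wm_implicit(pts, spec, fold) <= 0):
        raise ParameterError("cerebellum ellipsoid intersects the WM compartment")


def generate_phantom(spec: PhantomSpec) -> tuple[LabelVolume, PhantomTruth]:
    """Voxelize a phantom and return it with its ground truth.

    Labels: background=0, unmyelinated_wm=1, ventricles=2, cerebellum=3.
    The three foreground labels are disjoint by construction (the ventricle
    carves the WM interior; the cerebellum lies outside the WM surface).
    Truth volumes come from radial quadrature / closed forms, the truth
    surface area from a finely subdivided parameterized mesh.
    """
    fold = spec.fold_field
    _check_cerebellum_disjoint(spec, fold)
    a = np.asarray(spec.semi_axes)
    lo = np.minimum(-(a + spec.fold_amplitude),
                    np.asarray(spec.cerebellum_center) - np.asarray(spec.cerebellum_semi_axes))
    hi = np.maximum(a + spec.fold_amplitude,
                    np.asarray(spec.cerebellum_center) + np.asarray(spec.cerebellum_semi_axes))
    lo -= 2 * spec.spacing
    hi += 2 * spec.spacing
    shape = np.ceil((hi - lo) / spec.spacing).astype(int) + 1
    affine = np.eye(4)
    affine[:3, :3] *= spec.spacing
    affine[:3, 3] = lo
    ii = [lo[k] + spec.spacing * np.arange(shape[k]) for k in range(3)]
    grid = np.stack(np.meshgrid(*ii, indexing="ij"), axis=-1)
    pts = grid.reshape(-1, 3)

    wm_inside = _wm_implicit(pts, spec, fold) <= 0.0
    labels = np.zeros(len(pts), dtype=np.int16)
    labels[wm_inside] = DEFAULT_LABEL_MAP["unmyelinated_wm"]
    if spec.ventricle_scale > 0:
        vent = np.linalg.norm(pts / (spec.ventricle_scale * a), axis=1) <= 1.0
        labels[vent] = DEFAULT_LABEL_MAP["ventricles"]
    cereb = np.linalg.norm((pts - np.asarray(spec.cerebellum_center))
                           / np.asarray(spec.cerebellum_semi_axes), axis=1) <= 1.0
    labels[cereb] = DEFAULT_LABEL_MAP["cerebellum"]
    vol = LabelVolume(labels.reshape(shape), affine, dict(DEFAULT_LABEL_MAP))

    region = _wm_region_volume(spec, fold)
    v_vent = _ellipsoid_volume(spec.ventricle_scale * a) if spec.ventricle_scale > 0 else 0.0
    truth = PhantomTruth(
        wm_volume=region - v_vent,
        ventricle_volume=v_vent,
        cerebellum_volume=_ellipsoid_volume(spec.cerebellum_semi_axes),
        wm_surface_area=float(phantom_surface(spec, subdivisions=5).triangle_areas().sum()),
        landmarks=phantom_landmarks(spec),
        spec=spec,
    )
    return vol, truth


# ---------------------------------------------------------------------------
# Longitudinal pairs
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalPair:
    pre_spec: PhantomSpec
    post_spec: PhantomSpec
    pre_volume: LabelVolume
    post_volume: LabelVolume
    pre_mesh: SurfaceMesh
    post_mesh: SurfaceMesh
    pre_truth: PhantomTruth
    post_truth: PhantomTruth
    correspondence_truth: np.ndarray  # identity on the shared parameterization
    delta_ga: float
    rates: dict


def _solve_post_spec(spec: PhantomSpec, growth: dict, fold_increase: float,
                     delta_ga: float) -> PhantomSpec:
    fold = spec.fold_field
    a = np.asarray(spec.semi_axes)
    amp_post = spec.fold_amplitude + fold_increase * delta_ga
    v_vent_pre = _ellipsoid_volume(spec.ventricle_scale * a) if spec.ventricle_scale > 0 else 0.0
    region_pre = _wm_region_volume(spec, fold)
    wm_target = (region_pre - v_vent_pre) + growth.get("unmyelinated_wm", 0.0) * delta_ga
    vent_target = v_vent_pre + growth.get("ventricles", 0.0) * delta_ga
    cereb_target = _ellipsoid_volume(spec.cerebellum_semi_axes) \
        + growth.get("cerebellum", 0.0) * delta_ga
    if min(wm_target, cereb_target) <= 0 or vent_target < 0:
        raise ParameterError("growth drives a structure volume non-positive")
    region_target = wm_target + vent_target

    def f(s):
        trial = replace(spec, semi_axes=tuple(s * a), fold_amplitude=amp_post)
        return _wm_region_volume(trial, fold) - region_target

    s = brentq(f, 0.5, 2.0, xtol=1e-6)
    axes_post = tuple(s * a)
    if vent_target > 0:
        vscale = (vent_target / (4.0 / 3.0 * np.pi * np.prod(s * a))) ** (1.0 / 3.0)
    else:
        vscale = 0.0
    cs = np.asarray(spec.cerebellum_semi_axes) \
        * (cereb_target / _ellipsoid_volume(spec.cerebellum_semi_axes)) ** (1.0 / 3.0)
    # keep the cerebellum clear of the (possibly grown) WM surface
    cc = np.asarray(spec.cerebellum_center) * s
    return replace(spec, semi_axes=axes_post, fold_amplitude=amp_post,
                   ventricle_scale=float(vscale),
                   cerebellum_center=tuple(cc), cerebellum_semi_axes=tuple(cs))


def generate_longitudinal_pair(spec: PhantomSpec, growth_per_week: dict,
                               fold_increase_per_week: float, delta_ga: float,
                               subdivisions: int = 4,
                               voxelize: bool = True) -> LongitudinalPair:
    """Pre/post phantoms with structure volumes grown linearly over
    ``delta_ga`` weeks and fold amplitude increased by
    ``fold_increase_per_week * delta_ga``.

    Both surfaces share the icosphere parameterization, so the ground-truth
    correspondence is the identity on vertex indices.
    """
    if delta_ga <= 0:
        raise ParameterError("delta_ga must be positive")
    post_spec = _solve_post_spec(spec, growth_per_week, fold_increase_per_week, delta_ga)
    if voxelize:
        pre_vol, pre_truth = generate_phantom(spec)
        post_vol, post_truth = generate_phantom(post_spec)
    else:
        pre_vol = post_vol = None
        pre_truth = _truth_only(spec)
        post_truth = _truth_only(post_spec)
    pre_mesh = phantom_surface(spec, subdivisions=subdivisions)
    post_mesh = phantom_surface(post_spec, subdivisions=subdivisions)
    rates = {name: (getattr(post_truth, attr) - getattr(pre_truth, attr)) / delta_ga
             for name, attr in [("unmyelinated_wm", "wm_volume"),
                                ("ventricles", "ventricle_volume"),
                                ("cerebellum", "cerebellum_volume")]}
    return LongitudinalPair(
        pre_spec=spec, post_spec=post_spec,
        pre_volume=pre_vol, post_volume=post_vol,
        pre_mesh=pre_mesh, post_mesh=post_mesh,
        pre_truth=pre_truth, post_truth=post_truth,
        correspondence_truth=np.arange(pre_mesh.n_vertices),
        delta_ga=delta_ga, rates=rates,
    )


def _truth_only(spec: PhantomSpec) -> PhantomTruth:
    fold = spec.fold_field
    a = np.asarray(spec.semi_axes)
    v_vent = _ellipsoid_volume(spec.ventricle_scale * a) if spec.ventricle_scale > 0 else 0.0
    return PhantomTruth(
        wm_volume=_wm_region_volume(spec, fold) - v_vent,
        ventricle_volume=v_vent,
        cerebellum_volume=_ellipsoid_volume(spec.cerebellum_semi_axes),
        wm_surface_area=float(phantom_surface(spec, subdivisions=5).triangle_areas().sum()),
        landmarks=phantom_landmarks(spec),
        spec=spec,
    )
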