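"""Volume, surface area, global shape parameter, and paired per-week rates.

Structure volume is the count of labeled voxels times the voxel volume
(product of the spacings). Surface area is the sum of triangle areas of the
structure mesh. The global shape parameter is surface area / volume (mm^-1),
a compactness measure that decreases as a structure grows and increases as
its surface folds.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes
import trimesh

from .errors import EmptyStructureError, FetalmorphError, ParameterError
from .io import LabelVolume, SurfaceMesh, validate_closed_oriented

__all__ = [
    "StructureMetrics", "PairedRate", "volume_from_labels", "extract_mesh",
    "surface_area", "shape_parameter", "paired_rate", "parse_ga",
    "structure_metrics",
]


@dataclass
class StructureMetrics:
    structure: str
    volume: float           # mm^3, voxel-count based
    surface_area: float     # mm^2, triangle sum
    shape_parameter: float  # mm^-1
    mesh_source: str = ""   # provenance, e.g. "marching_cubes(taubin=10)"


@dataclass
class PairedRate:
    metric: str
    pre: float
    post: float
    ga_pre: float
    ga_post: float

    @property
    def rate(self) -> float:
        return (self.post - self.pre) / (self.ga_post - self.ga_pre)


def volume_from_labels(vol: LabelVolume, structure: str) -> float:
    """Voxel-count volume of a labeled structure in mm^3."""
    return float(np.count_nonzero(vol.mask(structure))) * vol.voxel_volume


def extract_mesh(vol: LabelVolume, structure: str, smoothing_iters: int = 10,
                 largest_component: bool = True) -> SurfaceMesh:
    """Marching-cubes surface of a labeled structure, in world mm.

    The binary mask is contoured at 0.5, optionally restricted to its largest
    connected component, Taubin-smoothed (non-shrinking, so volumetry stays
    consistent), and re-wound to outward orientation.
    """
    mask = vol.mask(structure)
    if not mask.any():
        raise EmptyStructureError(f"structure {structure!r} has no voxels")
    if largest_component:
        labeled, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
            mask = labeled == (1 + int(np.argmax(sizes)))
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    verts -= 1.0  # undo padding offset, back to voxel-index coordinates
    world = verts @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    tm = trimesh.Trimesh(world, faces, process=False)
    if smoothing_iters > 0:
        trimesh.smoothing.filter_taubin(tm, lamb=0.5, nu=-0.53, iterations=smoothing_iters)
    mesh = SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))
    _, mesh = validate_closed_oriented(mesh, fix=True)
    return mesh


def surface_area(mesh: SurfaceMesh) -> float:
    """Sum of triangle areas (mm^2); degenerate faces contribute 0."""
    areas = mesh.triangle_areas()
    if np.any(areas == 0):
        warnings.warn("mesh contains zero-area faces; they contribute no area")
    return float(areas.sum())


def shape_parameter(area: float, volume: float) -> float:
    """Global shape parameter: surface area / volume (mm^-1)."""
    if volume <= 0:
        raise ParameterError("shape parameter requires volume > 0")
    return float(area) / float(volume)


def structure_metrics(vol: LabelVolume, structure: str,
                      smoothing_iters: int = 10) -> StructureMetrics:
    """Volume, area and shape parameter of one structure in one call."""
    v = volume_from_labels(vol, structure)
    mesh = extract_mesh(vol, structure, smoothing_iters=smoothing_iters)
    a = surface_area(mesh)
    return StructureMetrics(structure, v, a, shape_parameter(a, v),
                            mesh_source=f"marching_cubes(taubin={smoothing_iters})")


_GA_RE = re.compile(r"^\s*(\d+)\s*\+\s*(\d+)\s*$")


def parse_ga(ga) -> float:
    """Gestational age to decimal weeks; accepts numbers or 'W+D' strings
    (e.g. '23+6' -> 23 + 6/7)."""
    if isinstance(ga, str):
        m = _GA_RE.match(ga)
        if not m:
            raise FetalmorphError(f"cannot parse gestational age {ga!r}")
        weeks, days = int(m.group(1)), int(m.group(2))
        if days > 6:
            raise FetalmorphError("days part of GA must be 0-6")
        return weeks + days / 7.0
    return float(ga)


def paired_rate(pre: float, post: float, ga_pre, ga_post, metric: str = "") -> PairedRate:
    """Per-week rate of change under the linear-growth assumption."""
    wp, wq = parse_ga(ga_pre), parse_ga(ga_post)
    if wq <= wp:
        raise ParameterError("ga_post must exceed ga_pre")
    return PairedRate(metric, float(pre), float(post), wp, wq)
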