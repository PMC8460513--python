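"""Landmark-based posterior-fossa and ventricular biometry.

Four clinical measures, each computed from named 3D landmark coordinates
(placed manually in practice, by construction on phantoms):

* TCD — transverse cerebellar diameter: distance between the cerebellar
  lateral extremes.
* VW — ventricular width: distance between the atrial width endpoints.
* CHL — cerebellar herniation level: signed perpendicular distance of the
  lowest cerebellar point from the foramen-magnum plane; positive = below
  the plane (herniated), so successful hindbrain-herniation reversal is a
  decrease.
* CSO — clivus–supraocciput angle: angle between the clivus and
  supraocciput lines, reported in (0, 180] degrees (not folded to <= 90,
  since the anatomical angle can be obtuse).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError, LandmarkError

__all__ = ["LandmarkSet", "tcd", "vw", "chl", "cso", "all_biometrics",
           "read_landmarks_csv", "write_landmarks_csv"]

_NAMES = ("vw_medial", "vw_lateral", "tcd_left", "tcd_right",
          "fm_plane_a", "fm_plane_b", "fm_plane_c", "cereb_lowest",
          "clivus_a", "clivus_b", "supraocciput_a", "supraocciput_b")


class LandmarkSet(dict):
    """Mapping landmark name -> (3,) world-mm point."""

    def __init__(self, points: dict):
        super().__init__({k: np.asarray(v, float).reshape(3) for k, v in points.items()})

    def require(self, *names) -> list:
        missing = [n for n in names if n not in self]
        if missing:
            raise LandmarkError(f"missing landmarks: {missing}")
        return [self[n] for n in names]


def _distance(p, q, what: str) -> float:
    d = float(np.linalg.norm(p - q))
    if d == 0.0:
        warnings.warn(f"{what}: coincident landmarks give zero length")
    return d


def tcd(lm: LandmarkSet) -> float:
    """Transverse cerebellar diameter (mm)."""
    left, right = lm.require("tcd_left", "tcd_right")
    return _distance(left, right, "TCD")


def vw(lm: LandmarkSet) -> float:
    """Ventricular width at the atria (mm)."""
    a, b = lm.require("vw_medial", "vw_lateral")
    return _distance(a, b, "VW")


def chl(lm: LandmarkSet, caudal=(0.0, 0.0, -1.0)) -> float:
    """Cerebellar herniation level (mm, signed; positive = herniated below
    the foramen-magnum plane).

    The plane normal is oriented along the caudal direction (default -z), so
    points below the plane get positive distances.
    """
    a, b, c, p = lm.require("fm_plane_a", "fm_plane_b", "fm_plane_c", "cereb_lowest")
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise GeometryError("foramen-magnum plane points are collinear")
    n = n / nn
    if n @ np.asarray(caudal, float) < 0:
        n = -n
    return float((p - a) @ n)


def cso(lm: LandmarkSet) -> float:
    """Clivus-supraocciput angle in degrees, in (0, 180]."""
    a, b, c, d = lm.require("clivus_a", "clivus_b", "supraocciput_a", "supraocciput_b")
    u = b - a
    v = d - c
    if np.linalg.norm(u) < 1e-12 or np.linalg.norm(v) < 1e-12:
        raise GeometryError("zero-length biometry line")
    cosang = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def all_biometrics(lm: LandmarkSet) -> dict:
    """All four measures; a measure whose landmarks are missing is NaN."""
    out = {}
    for name, fn in (("tcd", tcd), ("vw", vw), ("chl", chl), ("cso", cso)):
        try:
            out[name] = fn(lm)
        except LandmarkError:
            out[name] = float("nan")
    return out


def read_landmarks_csv(path) -> dict:
    """Read a landmarks table (subject_id, name, x, y, z) into
    ``{subject_id: LandmarkSet}``."""
    df = pd.read_csv(path)
    required = {"subject_id", "name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise LandmarkError(f"landmarks CSV must have columns {sorted(required)}")
    out = {}
    for sid, grp in df.groupby("subject_id"):
        out[str(sid)] = LandmarkSet(
            {row["name"]: (row["x"], row["y"], row["z"]) for _, row in grp.iterrows()})
    return out


def write_landmarks_csv(landmarks: dict, path, subject_id: str = "phantom") -> None:
    """Write one subject's named landmarks to CSV."""
    rows = [{"subject_id": subject_id, "name": k,
             "x": v[0], "y": v[1], "z": v[2]} for k, v in landmarks.items()]
    pd.DataFrame(rows).to_csv(Path(path), index=False)
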