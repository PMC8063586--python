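"""Restricting geometries for the Monte Carlo diffusion study.

A substrate is either free space or a periodic square packing of
impermeable obstacles: one sphere per cubic unit cell ("cells"), or one
infinite parallel cylinder per square-prism cell ("neurites"). The unit
cell edge is ``separation_factor × diameter``, so the restricted volume
fraction has the exact closed forms

* spheres:   π / (6 k³)
* cylinders: π / (4 k²)

with k the separation factor. Walkers move in unbounded space; obstacle
membership is evaluated through periodic reduction. Wall collisions are
specular (elastic) reflections, preserving step length; a step requiring
more than ``max_reflect`` bounces is rejected and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import advance_one

__all__ = ["Substrate", "GeometryError", "free", "sphere_pack", "cylinder_pack",
           "separation_for_fraction"]

#: Maximum reflections resolved within one step before the step is rejected.
MAX_REFLECT = 10


class GeometryError(ValueError):
    """Raised for inconsistent substrate geometry."""


_GEOM_CODES = {"free": 0, "sphere_pack": 1, "cylinder_pack": 2}


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping ``axis`` onto +z."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    s = np.linalg.norm(v)
    c = float(a @ z)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


@dataclass(frozen=True)
class Substrate:
    """Impermeable restricting geometry with a periodic square packing."""

    geometry: str  # free | sphere_pack | cylinder_pack
    diameter: float = 0.0  # µm
    separation_factor: float = 1.0  # unit-cell edge = k·diameter
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)  # cylinder axis

    def __post_init__(self):
        if self.geometry not in _GEOM_CODES:
            raise GeometryError(f"unknown geometry {self.geometry!r}")
        if self.geometry != "free":
            if self.diameter <= 0:
                raise GeometryError("diameter must be positive")
            if self.separation_factor < 1.0:
                raise GeometryError(
                    "separation_factor < 1 would overlap neighbouring obstacles")

    @property
    def geom_code(self) -> int:
        return _GEOM_CODES[self.geometry]

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def cell_edge(self) -> float:
        """Unit-cell edge L = k·d, µm (0 for free space)."""
        if self.geometry == "free":
            return 0.0
        return self.separation_factor * self.diameter

    @property
    def boundary_eps(self) -> float:
        """Post-reflection nudge off the membrane, 10⁻⁶ × diameter."""
        return 1e-6 * self.diameter if self.diameter > 0 else 0.0

    @property
    def rotation(self) -> np.ndarray:
        """Rotation from lab frame into the substrate frame (cylinder axis → z)."""
        if self.geometry == "cylinder_pack":
            return _rotation_to_z(np.asarray(self.axis))
        return np.eye(3)

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry,
            "diameter_um": self.diameter,
            "separation_factor": self.separation_factor,
            "axis": list(self.axis),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Substrate":
        return cls(
            geometry=d["geometry"],
            diameter=float(d.get("diameter_um", d.get("diameter", 0.0)) or 0.0),
            separation_factor=float(d.get("separation_factor", 1.0)),
            axis=tuple(d.get("axis", (0.0, 0.0, 1.0))),
        )


def free() -> Substrate:
    """Free (unrestricted) diffusion control."""
    return Substrate("free")


def sphere_pack(diameter: float, separation_factor: float) -> Substrate:
    return Substrate("sphere_pack", diameter, separation_factor)


def cylinder_pack(diameter: float, separation_factor: float,
                  axis=(0.0, 0.0, 1.0)) -> Substrate:
    return Substrate("cylinder_pack", diameter, separation_factor, tuple(axis))


def restricted_fraction(s: Substrate) -> float:
    """Exact intra-obstacle volume fraction of the periodic packing."""
    if s.geometry == "free":
        return 0.0
    k = s.separation_factor
    if k < 1.0:
        raise GeometryError("separation_factor < 1")
    if s.geometry == "sphere_pack":
        return float(np.pi / (6.0 * k**3))
    return float(np.pi / (4.0 * k**2))


def separation_for_fraction(geometry: str, fraction: float) -> float:
    """Invert :func:`restricted_fraction`: the separation factor k giving
    the requested packing fraction."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if geometry == "sphere_pack":
        k = (np.pi / (6.0 * fraction)) ** (1.0 / 3.0)
    elif geometry == "cylinder_pack":
        k = (np.pi / (4.0 * fraction)) ** 0.5
    else:
        raise GeometryError(f"no packing fraction for geometry {geometry!r}")
    if k < 1.0:
        raise GeometryError(f"fraction {fraction} exceeds the square-packing limit")
    return float(k)


def _inside_frame(s: Substrate, pts: np.ndarray) -> np.ndarray:
    """Obstacle membership for (n, 3) points already in the substrate frame."""
    L = s.cell_edge
    rel = np.mod(pts, L) - L / 2.0
    if s.geometry == "sphere_pack":
        d2 = np.sum(rel**2, axis=1)
    else:
        d2 = np.sum(rel[:, :2] ** 2, axis=1)
    return d2 < s.radius**2


def inside(s: Substrate, point) -> bool | np.ndarray:
    """True where ``point`` (µm, lab frame) lies strictly inside an obstacle.

    Accepts a single 3-vector or an (n, 3) array.
    """
    p = np.atleast_2d(np.asarray(point, dtype=float))
    if s.geometry == "free":
        out = np.zeros(len(p), dtype=bool)
    else:
        out = _inside_frame(s, p @ s.rotation.T)
    if np.asarray(point).ndim == 1:
        return bool(out[0])
    return out


def advance_with_reflection(s: Substrate, start, step,
                            max_reflect: int = MAX_REFLECT):
    """Advance one walker by ``step`` with specular wall reflections.

    Returns (new_position, ok); ``ok`` is False when the step was rejected
    (too many reflections) and the walker stayed at ``start``.
    """
    p = np.asarray(start, dtype=float)
    v = np.asarray(step, dtype=float)
    R = s.rotation
    pr = R @ p
    vr = R @ v
    x, y, z, ok = advance_one(
        s.geom_code, pr[0], pr[1], pr[2], vr[0], vr[1], vr[2],
        s.cell_edge, s.radius, s.boundary_eps, max_reflect)
    return R.T @ np.array([x, y, z]), bool(ok)


def sample_positions(s: Substrate, n: int, rng: np.random.Generator,
                     initialization: str = "everywhere") -> np.ndarray:
    """Sample walker start positions (substrate frame) in one unit cell.

    ``initialization`` ∈ {everywhere, intra_only, extra_only}.
    """
    if s.geometry == "free":
        return np.zeros((n, 3))
    L = s.cell_edge
    if initialization == "everywhere":
        return rng.uniform(0.0, L, size=(n, 3))
    want_inside = initialization == "intra_only"
    if initialization not in ("intra_only", "extra_only"):
        raise ValueError(f"unknown initialization {initialization!r}")
    out = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(0.0, L, size=(max(256, n), 3))
        flag = _inside_frame(s, cand)
        keep = cand[flag == want_inside]
        take = min(len(keep), n - got)
        out[got:got + take] = keep[:take]
        got += take
    return out
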