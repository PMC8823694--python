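"""Slab detector geometry and direction bookkeeping.

Coordinates are millimetres in a right-handed frame with the incident beam
along +z.  The detector occupies 0 <= z <= depth_Ld and is unbounded in x and
y, so a scattered photon can only leave through one of the two z faces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectorGeometry",
    "UNBOUNDED_EXIT_MM",
    "unit_vector",
    "scatter_direction",
    "angle_between",
    "BEAM_DIRECTION",
]

#: Sentinel used for rays that never reach a z face (direction in the xy
#: plane).  Large enough that exp(-mu * L) underflows to exactly 0.
UNBOUNDED_EXIT_MM = 1.0e6

BEAM_DIRECTION = np.array([0.0, 0.0, 1.0])


def unit_vector(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n


@dataclass(frozen=True)
class DetectorGeometry:
    """Slab detector: faces at z = 0 and z = depth_Ld, unbounded laterally.

    ``incident_area_mm`` is the (x, y) extent of the rectangle at z = 0 from
    which incident photon positions are sampled.
    """

    depth_Ld: float = 80.0
    incident_area_mm: tuple[float, float] = (10.0, 10.0)

    def __post_init__(self) -> None:
        if self.depth_Ld <= 0:
            raise ValueError("detector depth must be positive")

    def contains_z(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return (z >= 0.0) & (z <= self.depth_Ld)

    def exit_distance(self, position, direction) -> float:
        """Distance from ``position`` to the nearer z face along ``direction``.

        Directions with zero z component never exit (the slab is laterally
        unbounded) and get the ``UNBOUNDED_EXIT_MM`` sentinel, whose
        exponentiated escape probability is numerically zero.
        """
        position = np.asarray(position, dtype=float)
        z = float(position[2])
        if not (0.0 <= z <= self.depth_Ld):
            raise ValueError("position outside detector slab")
        dz = float(np.asarray(direction, dtype=float)[2])
        return self.exit_distance_z(z, dz)

    def exit_distance_z(self, z, dz):
        """Vector-friendly exit distance from depth ``z`` for z-component ``dz``."""
        z = np.asarray(z, dtype=float)
        dz = np.asarray(dz, dtype=float)
        out = np.full(np.broadcast(z, dz).shape, UNBOUNDED_EXIT_MM)
        up = dz > 0
        down = dz < 0
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(up, (self.depth_Ld - z) / np.where(up, dz, 1.0), out)
            out = np.where(down, z / np.where(down, -dz, 1.0), out)
        out = np.minimum(out, UNBOUNDED_EXIT_MM)
        if out.ndim == 0:
            return float(out)
        return out

    def sample_incident_position(self, rng: np.random.Generator, n: int = 1):
        """Uniform incident (x, y) positions over the incident area at z = 0."""
        ax, ay = self.incident_area_mm
        xy = rng.random((n, 2)) * np.array([ax, ay])
        return xy


def _companion_axes(incoming: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal (e1, e2) completing ``incoming`` to a frame.

    For a +z incoming direction the azimuth phi is measured from +x; any other
    direction gets a Gram-Schmidt companion built from the coordinate axis
    least aligned with it, which keeps the convention reproducible.
    """
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(incoming)))] = 1.0
    e1 = ref - np.dot(ref, incoming) * incoming
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(incoming, e1)
    return e1, e2


def scatter_direction(incoming, theta: float, phi: float) -> np.ndarray:
    """Unit direction at polar angle ``theta`` from ``incoming``, azimuth ``phi``."""
    if not 0.0 <= theta <= np.pi:
        raise ValueError("theta must lie in [0, pi]")
    d = unit_vector(incoming)
    e1, e2 = _companion_axes(d)
    out = (
        np.cos(theta) * d
        + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
    )
    return out / np.linalg.norm(out)


def direction_z_components(incoming, theta_grid, phi_grid) -> np.ndarray:
    """z components of scatter_direction(incoming, theta, phi) on a grid.

    Returns an array of shape (len(theta_grid), len(phi_grid)).  Used by the
    escape-probability quadrature, for which only the z component matters.
    """
    d = unit_vector(incoming)
    e1, e2 = _companion_axes(d)
    theta = np.asarray(theta_grid, dtype=float)[:, None]
    phi = np.asarray(phi_grid, dtype=float)[None, :]
    return (
        np.cos(theta) * d[2]
        + np.sin(theta) * (np.cos(phi) * e1[2] + np.sin(phi) * e2[2])
    )


def angle_between(start, end, reference) -> float:
    """Polar angle between the segment start->end and a reference direction."""
    seg = np.asarray(end, dtype=float) - np.asarray(start, dtype=float)
    n = np.linalg.norm(seg)
    if n == 0:
        raise ValueError("segment endpoints coincide")
    ref = unit_vector(reference)
    cosang = np.clip(np.dot(seg / n, ref), -1.0, 1.0)
    return float(np.arccos(cosang))
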