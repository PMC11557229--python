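"""Synthetic voxel phantoms with known ground truth.

Three families of binary volumes emulate the geometry of a layered fibrous
wall as seen in a binarized µCT scan:

* **fibre phantoms** — stacked pseudo-layers of straight chords inflated to
  tubes (default radius 3 voxels, a typical silk-fibre half-width at 2 µm
  voxels), with a controllable azimuthal orientation law and near-horizontal
  polar angles;
* **pore phantoms** — a solid block with spherical cavities, optionally with
  a per-layer radius gradient, as ground truth for pore-size recovery;
* **geometric primitives** — ball, cylinder, solid torus, dumbbell, used as
  oracle fixtures with known topology.

Every generator is deterministic given its seed and returns the ground-truth
geometry (line endpoints and angles, or sphere centres and radii) alongside
the volume, so downstream recovery can be scored exactly.
Rasterization is by voxel-centre inclusion: a voxel belongs to a tube iff its
centre lies within the tube radius of the axis segment (closed), and to a
spherical cavity iff its centre lies strictly inside the sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import BinaryVolume

__all__ = [
    "FibrePhantomSpec",
    "PorePhantomSpec",
    "PhantomSpecError",
    "generate_fibre_phantom",
    "generate_pore_phantom",
    "generate_primitive",
]


class PhantomSpecError(ValueError):
    """A phantom specification violates one of its invariants."""


@dataclass(frozen=True)
class FibrePhantomSpec:
    """Layered network of straight tubes.

    ``azimuth_model`` is either ``"uniform"`` (azimuths uniform on [0°, 180°))
    or ``("peaked", center_deg, spread_deg)`` (wrapped-normal azimuths).
    ``polar_jitter`` bounds |θ| of the generated lines in degrees; 0 keeps
    every line horizontal.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 40)
    voxel_size: float = 2.0
    n_layers: int = 5
    layer_thickness: int = 8
    lines_per_layer: int = 12
    fibre_radius: float = 3.0
    azimuth_model: str | tuple = "uniform"
    polar_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny, nz = self.grid_shape
        if self.n_layers * self.layer_thickness > nz:
            raise PhantomSpecError(
                f"invariant violated: n_layers * layer_thickness = "
                f"{self.n_layers * self.layer_thickness} exceeds z-extent {nz}"
            )
        if self.fibre_radius < 1:
            raise PhantomSpecError(
                f"invariant violated: fibre_radius must be >= 1, got {self.fibre_radius}"
            )
        if self.lines_per_layer < 0:
            raise PhantomSpecError("invariant violated: lines_per_layer must be >= 0")
        model = self.azimuth_model
        if isinstance(model, str):
            if model != "uniform":
                raise PhantomSpecError(
                    f"invariant violated: unknown azimuth model {model!r}"
                )
        else:
            name, _center, spread = model
            if name != "peaked":
                raise PhantomSpecError(
                    f"invariant violated: unknown azimuth model {name!r}"
                )
            if not spread > 0:
                raise PhantomSpecError(
                    "invariant violated: spread_deg must be > 0 for the peaked model"
                )


@dataclass(frozen=True)
class PorePhantomSpec:
    """Solid block with spherical cavities.

    Either an explicit ``spheres`` list of ``(center_xyz, radius_vox)`` or a
    gradient rule: ``layer_radii[i]`` gives the cavity radius in layer ``i``
    (slab of ``layer_thickness`` voxels) and ``spheres_per_layer`` the count,
    with centres sampled uniformly so each sphere fits inside the grid.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 2.0
    spheres: tuple | None = None
    layer_radii: tuple[float, ...] | None = None
    spheres_per_layer: int = 8
    layer_thickness: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.spheres is None) == (self.layer_radii is None):
            raise PhantomSpecError(
                "exactly one of spheres or layer_radii must be given"
            )
        if self.spheres is not None:
            for center, radius in self.spheres:
                if radius < 1:
                    raise PhantomSpecError(
                        f"invariant violated: sphere radius {radius} < 1"
                    )
                for c, n in zip(center, self.grid_shape):
                    if c - radius < 0 or c + radius > n - 1:
                        raise PhantomSpecError(
                            f"invariant violated: sphere at {tuple(center)} with "
                            f"radius {radius} exceeds the grid"
                        )
        else:
            if any(r < 1 for r in self.layer_radii):
                raise PhantomSpecError("invariant violated: radii must be >= 1")
            depth = self.layer_thickness or self.grid_shape[2] // len(self.layer_radii)
            if depth * len(self.layer_radii) > self.grid_shape[2]:
                raise PhantomSpecError(
                    "invariant violated: layers exceed the z-extent"
                )


# ---------------------------------------------------------------------------
# fibre phantom
# ---------------------------------------------------------------------------


def _sample_azimuth(model, rng: np.random.Generator) -> float:
    if model == "uniform":
        return float(rng.uniform(0.0, 180.0))
    _, center, spread = model
    return float(np.mod(rng.normal(center, spread), 180.0))


def _clip_chord(p, u, lo, hi):
    """Intersect the line p + t·u with the box [lo, hi] (slab clipping)."""
    tmin, tmax = -np.inf, np.inf
    for a in range(3):
        if abs(u[a]) < 1e-12:
            if not (lo[a] <= p[a] <= hi[a]):
                return None
            continue
        t0 = (lo[a] - p[a]) / u[a]
        t1 = (hi[a] - p[a]) / u[a]
        tmin = max(tmin, min(t0, t1))
        tmax = min(tmax, max(t0, t1))
    if tmax <= tmin:
        return None
    return p + tmin * u, p + tmax * u


def _paint_tube(grid: np.ndarray, a: np.ndarray, b: np.ndarray, r: float) -> None:
    """Set to 1 every voxel whose centre is within r of segment ab."""
    lo = np.maximum(np.floor(np.minimum(a, b) - r), 0).astype(int)
    hi = np.minimum(np.ceil(np.maximum(a, b) + r), np.array(grid.shape) - 1).astype(int)
    if np.any(hi < lo):
        return
    xs, ys, zs = [np.arange(lo[i], hi[i] + 1) for i in range(3)]
    P = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).astype(float)
    d = b - a
    L2 = float(d @ d)
    if L2 < 1e-12:
        dist2 = ((P - a) ** 2).sum(-1)
    else:
        t = np.clip(((P - a) @ d) / L2, 0.0, 1.0)
        proj = a + t[..., None] * d
        dist2 = ((P - proj) ** 2).sum(-1)
    sub = grid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    sub[dist2 <= r * r + 1e-9] = 1


def generate_fibre_phantom(
    spec: FibrePhantomSpec,
) -> tuple[BinaryVolume, pd.DataFrame]:
    """Rasterize a layered network of straight tubes.

    Per layer, ``lines_per_layer`` chords are drawn through a uniformly
    sampled interior point with azimuth from the spec's orientation law and
    polar angle uniform in ±``polar_jitter``; each chord spans the full XY
    window and is inflated to a tube of ``fibre_radius`` voxels.

    Returns the volume and a ground-truth table with one row per line:
    ``x0..z1`` (voxel coordinates of the chord endpoints), ``azimuth_deg``,
    ``polar_deg`` and ``layer``.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    grid = np.zeros(spec.grid_shape, dtype=np.uint8)
    r = spec.fibre_radius
    rows = []
    for layer in range(spec.n_layers):
        z0 = layer * spec.layer_thickness
        z1 = z0 + spec.layer_thickness - 1
        zlo, zhi = z0 + r, z1 - r
        if zlo > zhi:  # slab too thin for a margin; centre the lines
            zlo = zhi = (z0 + z1) / 2.0
        for _ in range(spec.lines_per_layer):
            phi = _sample_azimuth(spec.azimuth_model, rng)
            theta = (
                float(rng.uniform(-spec.polar_jitter, spec.polar_jitter))
                if spec.polar_jitter > 0
                else 0.0
            )
            p = np.array(
                [
                    rng.uniform(0, nx - 1),
                    rng.uniform(0, ny - 1),
                    rng.uniform(zlo, zhi),
                ]
            )
            cp, sp = math.cos(math.radians(phi)), math.sin(math.radians(phi))
            ct, st = math.cos(math.radians(theta)), math.sin(math.radians(theta))
            u = np.array([ct * cp, ct * sp, st])
            clipped = _clip_chord(
                p, u, np.array([0.0, 0.0, z0]), np.array([nx - 1.0, ny - 1.0, float(z1)])
            )
            if clipped is None:
                continue
            a, b = clipped
            _paint_tube(grid, a, b, r)
            rows.append(
                dict(
                    x0=a[0], y0=a[1], z0=a[2], x1=b[0], y1=b[1], z1=b[2],
                    azimuth_deg=phi, polar_deg=theta, layer=layer,
                )
            )
    truth = pd.DataFrame(
        rows,
        columns=["x0", "y0", "z0", "x1", "y1", "z1", "azimuth_deg", "polar_deg", "layer"],
    )
    return BinaryVolume(grid=grid, voxel_size=spec.voxel_size), truth


# ---------------------------------------------------------------------------
# pore phantom
# ---------------------------------------------------------------------------


def _carve_sphere(grid: np.ndarray, center: np.ndarray, radius: float) -> None:
    lo = np.maximum(np.floor(center - radius), 0).astype(int)
    hi = np.minimum(np.ceil(center + radius), np.array(grid.shape) - 1).astype(int)
    xs, ys, zs = [np.arange(lo[i], hi[i] + 1) for i in range(3)]
    P = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).astype(float)
    dist2 = ((P - center) ** 2).sum(-1)
    sub = grid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    sub[dist2 < radius * radius - 1e-9] = 0  # strictly inside


def generate_pore_phantom(
    spec: PorePhantomSpec,
) -> tuple[BinaryVolume, pd.DataFrame]:
    """Carve spherical cavities out of a solid block.

    Returns the volume and a ground-truth table with columns
    ``cx, cy, cz, radius_vox, layer``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = np.ones(spec.grid_shape, dtype=np.uint8)
    rows = []
    if spec.spheres is not None:
        for center, radius in spec.spheres:
            c = np.asarray(center, dtype=float)
            _carve_sphere(grid, c, float(radius))
            rows.append(
                dict(cx=c[0], cy=c[1], cz=c[2], radius_vox=float(radius), layer=0)
            )
    else:
        nx, ny, nz = spec.grid_shape
        depth = spec.layer_thickness or nz // len(spec.layer_radii)
        for layer, radius in enumerate(spec.layer_radii):
            z0, z1 = layer * depth, (layer + 1) * depth - 1
            for _ in range(spec.spheres_per_layer):
                c = np.array(
                    [
                        rng.uniform(radius, nx - 1 - radius),
                        rng.uniform(radius, ny - 1 - radius),
                        rng.uniform(
                            max(radius, z0), min(nz - 1 - radius, float(z1))
                        ),
                    ]
                )
                _carve_sphere(grid, c, float(radius))
                rows.append(
                    dict(cx=c[0], cy=c[1], cz=c[2], radius_vox=float(radius), layer=layer)
                )
    truth = pd.DataFrame(rows, columns=["cx", "cy", "cz", "radius_vox", "layer"])
    return BinaryVolume(grid=grid, voxel_size=spec.voxel_size), truth


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def generate_primitive(
    name: str,
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    voxel_size: float = 2.0,
    **params,
) -> BinaryVolume:
    """Rasterize a named solid by voxel-centre inclusion.

    Supported primitives and their parameters (all lengths in voxels):

    * ``ball`` — ``radius``, optional ``center``
    * ``cylinder`` — ``radius``, axis along x through the grid centre
    * ``solid_torus`` — ``major_radius``, ``minor_radius``, tube ring in the
      central XY plane
    * ``dumbbell`` — two balls of ``ball_radius`` whose centres are
      ``separation`` apart along x, joined by a ``bridge_radius`` cylinder
    """
    shape = np.asarray(grid_shape)
    center = np.asarray(params.pop("center", (shape - 1) / 2.0), dtype=float)
    P = np.stack(
        np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij"), axis=-1
    ).astype(float)

    if name == "ball":
        r = params["radius"]
        mask = ((P - center) ** 2).sum(-1) <= r * r + 1e-9
    elif name == "cylinder":
        r = params["radius"]
        d2 = (P[..., 1] - center[1]) ** 2 + (P[..., 2] - center[2]) ** 2
        mask = d2 <= r * r + 1e-9
    elif name == "solid_torus":
        R, r = params["major_radius"], params["minor_radius"]
        rho = np.sqrt((P[..., 0] - center[0]) ** 2 + (P[..., 1] - center[1]) ** 2)
        d2 = (rho - R) ** 2 + (P[..., 2] - center[2]) ** 2
        mask = d2 <= r * r + 1e-9
    elif name == "dumbbell":
        r = params["ball_radius"]
        sep = params["separation"]
        rb = params.get("bridge_radius", max(1.0, r / 2.0))
        c1 = center - np.array([sep / 2.0, 0, 0])
        c2 = center + np.array([sep / 2.0, 0, 0])
        mask = ((P - c1) ** 2).sum(-1) <= r * r + 1e-9
        mask |= ((P - c2) ** 2).sum(-1) <= r * r + 1e-9
        inx = (P[..., 0] >= c1[0]) & (P[..., 0] <= c2[0])
        d2 = (P[..., 1] - center[1]) ** 2 + (P[..., 2] - center[2]) ** 2
        mask |= inx & (d2 <= rb * rb + 1e-9)
    else:
        raise ValueError(
            f"unknown primitive {name!r}; expected ball, cylinder, solid_torus or dumbbell"
        )
    if not mask.any():
        raise ValueError(f"primitive {name!r} does not intersect the grid")
    return BinaryVolume(grid=mask.astype(np.uint8), voxel_size=voxel_size)
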