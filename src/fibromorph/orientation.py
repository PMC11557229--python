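"""Edge-angle statistics of a fibre skeleton and the discretization band.

Each skeleton edge is an undirected segment; its **polar angle** θ ∈ [0°, 90°]
is the deviation from the horizontal (XY) plane and its **azimuth** φ ∈
[0°, 180°) the in-plane direction measured from +x.  Azimuth histograms are
normalized to mean density 1 so a perfectly uniform orientation law is the
constant 1; they are binned within thin z pseudo-layers (default 40 µm).

Voxelization and thinning leave residual fluctuations in the azimuth
histogram even for a perfectly uniform fibre network.  The **discretization
band** calibrates this: the full pipeline is run on a uniform-azimuth phantom
and the global min/max of its normalized density envelope any curve that is
statistically indistinguishable from uniform.  A circular XY window is applied
before collating azimuths because in a square window diagonal (45°/135°)
chords are systematically longer than axis-aligned ones, biasing the
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantoms import FibrePhantomSpec, generate_fibre_phantom
from .skeleton import SkeletonGraph, extract_skeleton

__all__ = [
    "EdgeAngles",
    "AngleDistribution",
    "UniformityBand",
    "UniformityVerdict",
    "edge_angles",
    "circular_window",
    "angle_histogram",
    "discretization_band",
    "uniformity_verdict",
    "PSEUDO_LAYER_UM",
]

#: Default pseudo-layer thickness in µm for azimuth binning.
PSEUDO_LAYER_UM = 40.0
#: Width (bins) of the moving-average smoothing applied before verdicts.
SMOOTH_BINS = 5


@dataclass(frozen=True)
class EdgeAngles:
    """Per-edge angles: ``theta_deg``, ``phi_deg`` (NaN when the XY projection
    vanishes), midpoint (µm), ``length_um`` and ``pseudo_layer``."""

    table: pd.DataFrame
    pseudo_layer_um: float

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class AngleDistribution:
    """Histogram normalized to mean density 1 (uniform → constant 1)."""

    bin_edges: np.ndarray
    density: np.ndarray
    sample_count: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class UniformityBand:
    """Min/max fluctuation envelope of a uniform phantom's azimuth density."""

    lower: float
    upper: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.lower <= 1.0 <= self.upper):
            raise ValueError(
                f"band must bracket the mean density 1, got [{self.lower}, {self.upper}]"
            )


@dataclass(frozen=True)
class UniformityVerdict:
    """Outcome of comparing an azimuth distribution with the band."""

    uniform: bool
    offending_bins_deg: np.ndarray

    @property
    def verdict(self) -> str:
        return "indistinguishable_from_uniform" if self.uniform else "deviates"


def edge_angles(
    sg: SkeletonGraph, pseudo_layer_um: float = PSEUDO_LAYER_UM
) -> EdgeAngles:
    """Polar/azimuth angles, midpoints and pseudo-layer ids for every edge.

    θ = |atan2(dz, hypot(dx, dy))|, φ = atan2(dy, dx) mod 180°; φ is NaN for
    exactly vertical edges (zero XY projection).  Zero-length edges are
    excluded with a warning.
    """
    if sg.n_edges == 0:
        raise ValueError("skeleton graph has no edges")
    pos = sg.positions()
    rows = []
    n_zero = 0
    for u, v in sg.graph.edges():
        d = pos[v] - pos[u]
        length = float(np.linalg.norm(d))
        if length <= 0:
            n_zero += 1
            continue
        dxy = float(np.hypot(d[0], d[1]))
        theta = abs(np.degrees(np.arctan2(d[2], dxy)))
        phi = np.degrees(np.arctan2(d[1], d[0])) % 180.0 if dxy > 0 else np.nan
        mid = (pos[u] + pos[v]) / 2.0
        rows.append(
            dict(
                theta_deg=theta,
                phi_deg=phi,
                mx=mid[0], my=mid[1], mz=mid[2],
                length_um=length,
                pseudo_layer=int(mid[2] // pseudo_layer_um),
            )
        )
    if n_zero:
        warnings.warn(f"excluded {n_zero} zero-length edges")
    table = pd.DataFrame(
        rows,
        columns=["theta_deg", "phi_deg", "mx", "my", "mz", "length_um", "pseudo_layer"],
    )
    return EdgeAngles(table=table, pseudo_layer_um=pseudo_layer_um)


def circular_window(e: EdgeAngles, volume_extent_um: tuple[float, float]) -> EdgeAngles:
    """Keep edges whose midpoint lies in the largest XY-inscribed circle.

    ``volume_extent_um`` is the (X, Y) extent of the sample in µm; the circle
    is centred in XY with radius min(X, Y)/2.
    """
    cx, cy = volume_extent_um[0] / 2.0, volume_extent_um[1] / 2.0
    radius = min(volume_extent_um) / 2.0
    t = e.table
    keep = (t["mx"] - cx) ** 2 + (t["my"] - cy) ** 2 <= radius**2
    return EdgeAngles(table=t[keep].reset_index(drop=True), pseudo_layer_um=e.pseudo_layer_um)


def _normalized_histogram(values: np.ndarray, lo: float, hi: float, bin_deg: float):
    edges = np.arange(lo, hi + bin_deg / 2.0, bin_deg)
    counts, _ = np.histogram(values, bins=edges)
    mean = counts.mean()
    density = counts / mean if mean > 0 else counts.astype(float)
    return edges, density


def angle_histogram(
    e: EdgeAngles,
    which: str,
    bin_deg: float = 1.0,
    per_layer: bool | None = None,
) -> AngleDistribution | dict[int, AngleDistribution]:
    """Normalized angle histogram; per pseudo-layer for φ, global for θ.

    φ histograms span [0°, 180°), θ histograms [0°, 90°]; density is
    normalized to mean 1 over the bins.  ``per_layer`` defaults to True for φ
    and False for θ; edges with undefined φ are excluded.
    """
    if which not in ("theta", "phi"):
        raise ValueError("which must be 'theta' or 'phi'")
    if per_layer is None:
        per_layer = which == "phi"
    t = e.table
    col = "theta_deg" if which == "theta" else "phi_deg"
    lo, hi = (0.0, 90.0) if which == "theta" else (0.0, 180.0)

    def _one(values: np.ndarray) -> AngleDistribution:
        values = values[np.isfinite(values)]
        if len(values) == 0:
            raise ValueError("no edges with a defined angle in the selection")
        edges, density = _normalized_histogram(values, lo, hi, bin_deg)
        return AngleDistribution(
            bin_edges=edges, density=density, sample_count=len(values)
        )

    if not per_layer:
        return _one(t[col].to_numpy())
    return {
        int(layer): _one(group[col].to_numpy())
        for layer, group in t.groupby("pseudo_layer")
    }


def smooth_density(density: np.ndarray, window: int = SMOOTH_BINS, circular: bool = True) -> np.ndarray:
    """Moving-average smoothing; circular wrap for periodic azimuth bins."""
    if window <= 1:
        return density
    kernel = np.ones(window) / window
    if circular:
        pad = window // 2
        ext = np.concatenate([density[-pad:], density, density[:pad]])
        return np.convolve(ext, kernel, mode="valid")[: len(density)]
    return np.convolve(density, kernel, mode="same")


def run_orientation_pipeline(
    spec: FibrePhantomSpec,
    pseudo_layer_um: float = PSEUDO_LAYER_UM,
    window: str = "circular",
    bin_deg: float = 1.0,
) -> tuple[EdgeAngles, AngleDistribution]:
    """Phantom → skeleton → angles → (optional circular window) → pooled φ
    histogram.  Shared by calibration and the bias diagnostics."""
    volume, _ = generate_fibre_phantom(spec)
    sg = extract_skeleton(volume)
    angles = edge_angles(sg, pseudo_layer_um=pseudo_layer_um)
    if window == "circular":
        extent = (
            (volume.shape[0] - 1) * volume.voxel_size,
            (volume.shape[1] - 1) * volume.voxel_size,
        )
        angles = circular_window(angles, extent)
    dist = angle_histogram(angles, "phi", bin_deg=bin_deg, per_layer=False)
    return angles, dist


def discretization_band(
    spec: FibrePhantomSpec,
    pseudo_layer_um: float = PSEUDO_LAYER_UM,
    bin_deg: float = 1.0,
) -> UniformityBand:
    """Calibrate the fluctuation envelope on a uniform-azimuth phantom.

    Runs the full skeleton/orientation pipeline on the phantom, smooths the
    pooled normalized azimuth density and takes its global min/max.
    """
    if spec.azimuth_model != "uniform":
        raise ValueError("the discretization band requires a uniform-azimuth phantom")
    _, dist = run_orientation_pipeline(
        spec, pseudo_layer_um=pseudo_layer_um, window="circular", bin_deg=bin_deg
    )
    smoothed = smooth_density(dist.density)
    return UniformityBand(
        lower=float(smoothed.min()),
        upper=float(smoothed.max()),
        provenance={"spec": spec.__dict__ | {"grid_shape": list(spec.grid_shape)},
                    "seed": spec.seed},
    )


def uniformity_verdict(
    dist: AngleDistribution, band: UniformityBand
) -> UniformityVerdict:
    """Compare a normalized azimuth distribution with the calibrated band.

    The band is centred on the distribution's mean density (1 after
    normalization); the smoothed curve deviates iff any bin leaves
    [lower, upper].
    """
    smoothed = smooth_density(dist.density)
    outside = (smoothed < band.lower) | (smoothed > band.upper)
    centers = dist.bin_centers[outside]
    return UniformityVerdict(uniform=not outside.any(), offending_bins_deg=centers)
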