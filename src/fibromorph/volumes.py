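"""Binary volume container, file I/O, layer partitioning and fibre-phase cleanup.

A :class:`BinaryVolume` stores a two-phase voxel grid (0 = pore, 1 = fibre)
on an isotropic lattice.  Array axes are ``(x, y, z)`` where ``z`` is the
wall-thickness direction and the ``z = 0`` plane is the inner wall.

Supported on-disk formats:

* multi-page TIFF (page index = z) with a JSON sidecar carrying the voxel size,
* NRRD (raw encoding; the header carries the spacings),
* raw ``uint8`` with a mandatory JSON sidecar ``{shape, order, voxel_size_um}``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy import ndimage as ndi

__all__ = [
    "BinaryVolume",
    "LayerPartition",
    "read_volume",
    "write_volume",
    "partition_layers",
    "fill_fibre_cavities",
    "remove_small_fibre_clusters",
]

#: 6-connectivity structuring element (face neighbours) for the pore phase.
STRUCT_6 = ndi.generate_binary_structure(3, 1)
#: 26-connectivity structuring element (face/edge/corner) for the fibre phase.
STRUCT_26 = ndi.generate_binary_structure(3, 3)


@dataclass(frozen=True)
class BinaryVolume:
    """Two-phase voxel volume on an isotropic grid.

    Parameters
    ----------
    grid
        ``uint8`` array of shape ``(nx, ny, nz)`` with values in ``{0, 1}``;
        1 = fibre (solid), 0 = pore (void).
    voxel_size
        Edge length of a voxel in µm (isotropic).
    """

    grid: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 3:
            raise ValueError(f"grid must be 3-D, got ndim={g.ndim}")
        vals = np.unique(g)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(
                f"grid must be binary with values in {{0, 1}}; found {vals[:10]}"
            )
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        object.__setattr__(self, "grid", g.astype(np.uint8, copy=False))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def fibre_mask(self) -> np.ndarray:
        return self.grid.astype(bool)

    @property
    def pore_mask(self) -> np.ndarray:
        return ~self.grid.astype(bool)

    @property
    def fibre_fraction(self) -> float:
        return float(self.grid.mean())

    def with_grid(self, grid: np.ndarray) -> "BinaryVolume":
        return replace(self, grid=grid)


@dataclass(frozen=True)
class LayerPartition:
    """Partition of the z-extent into ``n_full`` equal slabs plus a remainder.

    ``boundaries`` are the z indices delimiting layers (exclusive upper edges
    of the full slabs); ``labels`` maps each z slice to its layer id, with the
    remainder slab (if any) labelled ``n_full``.
    """

    boundaries: tuple[int, ...]
    n_full: int
    labels: np.ndarray = field(repr=False)

    @property
    def n_layers(self) -> int:
        return int(self.labels.max()) + 1

    def layer_of_z(self, z: int) -> int:
        return int(self.labels[z])


def partition_layers(
    volume: BinaryVolume, layer_thickness_um: float, n_full: int
) -> LayerPartition:
    """Split the wall thickness into ``n_full`` equal layers plus a remainder.

    The slab depth is ``floor(layer_thickness_um / voxel_size)`` voxels; slabs
    start at the inner wall (z = 0) and the remainder layer, which may be
    thicker or thinner than the others, reaches the outer surface.
    """
    if n_full < 1:
        raise ValueError("n_full must be >= 1")
    depth = int(layer_thickness_um // volume.voxel_size)
    if depth < 1:
        raise ValueError("layer thickness is below one voxel")
    nz = volume.shape[2]
    if n_full * depth > nz:
        feasible = nz // depth
        raise ValueError(
            f"{n_full} layers of {depth} voxels exceed the z-extent of {nz}; "
            f"maximum feasible n_full is {feasible}"
        )
    boundaries = tuple(depth * (i + 1) for i in range(n_full))
    labels = np.minimum(np.arange(nz) // depth, n_full)
    return LayerPartition(boundaries=boundaries, n_full=n_full, labels=labels)


# ---------------------------------------------------------------------------
# cleanup filters
# ---------------------------------------------------------------------------


def fill_fibre_cavities(volume: BinaryVolume) -> BinaryVolume:
    """Relabel enclosed pore cavities as fibre.

    The pore space of a real fibrous wall percolates the sample, so any pore
    component that does not reach the volume boundary is a segmentation cavity
    inside a fibre and is filled.  Pore components use 6-connectivity (the
    complementary pair to 26-connected fibres).
    """
    pore = volume.pore_mask
    labels, n = ndi.label(pore, structure=STRUCT_6)
    if n == 0:
        return volume
    boundary_ids = set()
    for ax in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=ax)
            boundary_ids.update(np.unique(face[face > 0]).tolist())
    enclosed = np.setdiff1d(np.arange(1, n + 1), sorted(boundary_ids))
    if enclosed.size == 0:
        return volume
    fill = np.isin(labels, enclosed)
    return volume.with_grid(volume.grid | fill.astype(np.uint8))


def remove_small_fibre_clusters(
    volume: BinaryVolume, min_voxels: int = 100
) -> BinaryVolume:
    """Drop fibre components that do not exceed ``min_voxels`` voxels.

    Keeps 26-connected fibre clusters of strictly more than ``min_voxels``
    voxels; removed voxels become pore.  Small clusters are typically
    segmentation debris that corrupts the medial axis.
    """
    labels, n = ndi.label(volume.fibre_mask, structure=STRUCT_26)
    if n == 0:
        return volume
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = counts > min_voxels
    keep[0] = False
    return volume.with_grid(keep[labels].astype(np.uint8))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = ("tiff_stack", "nrrd", "raw")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        return "tiff_stack"
    if ext == ".nrrd":
        return "nrrd"
    if ext == ".raw":
        return "raw"
    raise ValueError(f"cannot infer volume format from extension {ext!r}")


def _sidecar_path(path: str) -> str:
    return path + ".json"


def write_volume(volume: BinaryVolume, path: str, format: str | None = None) -> None:
    """Write a volume losslessly; grid and voxel size round-trip exactly."""
    fmt = format or _infer_format(path)
    if fmt == "tiff_stack":
        # pages are z slices; within a page rows are y, columns are x
        tifffile.imwrite(path, volume.grid.transpose(2, 1, 0), photometric="minisblack")
        with open(_sidecar_path(path), "w") as fh:
            json.dump({"voxel_size_um": volume.voxel_size, "axis_order": "xyz"}, fh)
    elif fmt == "nrrd":
        _write_nrrd(volume, path)
    elif fmt == "raw":
        volume.grid.flatten(order="F").tofile(path)
        with open(_sidecar_path(path), "w") as fh:
            json.dump(
                {
                    "shape": list(volume.shape),
                    "order": "F",
                    "dtype": "uint8",
                    "voxel_size_um": volume.voxel_size,
                },
                fh,
            )
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def read_volume(
    path: str, format: str | None = None, threshold: float | None = None
) -> BinaryVolume:
    """Read a volume written by :func:`write_volume`.

    Non-binary voxel data raise unless ``threshold`` is given, in which case
    values strictly above it map to fibre.
    """
    fmt = format or _infer_format(path)
    if fmt == "tiff_stack":
        pages = np.asarray(tifffile.imread(path))
        if pages.ndim == 2:
            pages = pages[None]
        grid = pages.transpose(2, 1, 0)
        sidecar = _sidecar_path(path)
        if not os.path.exists(sidecar):
            raise FileNotFoundError(
                f"missing voxel-size sidecar {sidecar!r} for TIFF stack"
            )
        with open(sidecar) as fh:
            meta = json.load(fh)
        voxel_size = float(meta["voxel_size_um"])
    elif fmt == "nrrd":
        grid, voxel_size = _read_nrrd(path)
    elif fmt == "raw":
        sidecar = _sidecar_path(path)
        if not os.path.exists(sidecar):
            raise FileNotFoundError(
                f"raw volume requires a JSON sidecar at {sidecar!r}"
            )
        with open(sidecar) as fh:
            meta = json.load(fh)
        shape = tuple(meta["shape"])
        grid = np.fromfile(path, dtype=np.dtype(meta.get("dtype", "uint8")))
        grid = grid.reshape(shape, order=meta.get("order", "F"))
        voxel_size = float(meta["voxel_size_um"])
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")

    vals = np.unique(grid)
    if not np.isin(vals, (0, 1)).all():
        if threshold is None:
            raise ValueError(
                "volume data are not binary; pass threshold= to binarize"
            )
        grid = (grid > threshold).astype(np.uint8)
    return BinaryVolume(grid=grid.astype(np.uint8), voxel_size=voxel_size)


# minimal NRRD0004 subset: uint8/float32, raw encoding, isotropic spacings


def _write_nrrd(volume: BinaryVolume, path: str) -> None:
    s = volume.voxel_size
    header = (
        "NRRD0004\n"
        "type: uint8\n"
        "dimension: 3\n"
        f"sizes: {volume.shape[0]} {volume.shape[1]} {volume.shape[2]}\n"
        f"spacings: {s} {s} {s}\n"
        "encoding: raw\n"
        "endian: little\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(volume.grid.flatten(order="F").tobytes())


def _read_nrrd(path: str) -> tuple[np.ndarray, float]:
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path!r} is not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, _, value = text.partition(":")
            fields[key.strip().lower()] = value.strip()
        if fields.get("encoding", "raw") != "raw":
            raise ValueError("only raw-encoded NRRD is supported")
        dtype = np.dtype({"uint8": "u1", "float": "f4", "float32": "f4"}[
            fields["type"]
        ])
        sizes = tuple(int(t) for t in fields["sizes"].split())
        spacings = [float(t) for t in fields.get("spacings", "1 1 1").split()]
        if len(set(spacings)) != 1:
            raise ValueError("anisotropic NRRD spacings are not supported")
        data = np.frombuffer(fh.read(), dtype=dtype)
    grid = data.reshape(sizes, order="F")
    return grid, spacings[0]
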