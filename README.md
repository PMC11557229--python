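# fibromorph

Topological and geometric morphometry of fibrous three-dimensional
microstructures — the kind seen in binarized µCT scans of silkworm
(*Bombyx mori*) cocoon walls and similar non-woven fibre networks.  The
package measures three things from a binary voxel volume (fibre = 1,
pore = 0, isotropic voxels, z = wall thickness):

* **pore-size distributions per wall layer**, via maximal inscribed spheres
  read off zero-dimensional persistent homology;
* **fibre-thickness distributions**, via the same construction on the
  inverted (fibre-foreground) filtration with voxel subdivision;
* **fibre orientation statistics**, via a curve-graph skeleton of the fibre
  phase, with a phantom-calibrated error band that separates genuine
  anisotropy from discretization artefacts.

Because raw tomography volumes are rarely portable, every stage is driven
and validated by **synthetic phantoms** with exported ground truth: layered
networks of inflated lines, solids with planted spherical cavities, and
geometric primitives with known topology.

## Method

For a binary volume the signed Euclidean distance transform (SEDT) assigns
each voxel the exact centre-to-centre distance to the nearest voxel of the
opposite phase, negative inside the phase under analysis.  Sublevel sets of
the SEDT form a filtration of a cubical complex (V-construction: voxels are
vertices, each cell takes the maximum of its vertices).  Persistent homology
of this filtration is computed in dimensions 0 and 1:

* a dimension-0 point with birth *b* < 0 corresponds to a maximal inscribed
  sphere of radius |*b*| (in voxel units, converted to µm) centred at its
  birth voxel — a "pore pocket" (pore foreground) or a fibre-core thickness
  measurement (fibre foreground);
* dimension-0 pairing follows the elder rule (at a merge the older
  component survives); correctness is enforced by an independent in-repo
  oracle that reduces the boundary matrix of the whole complex over GF(2);
* a dimension-1 point with *b* < 0 ≤ *d* is a loop wrapping a fibre; with
  *d* < 0 a loop inside a large pore.

Diagrams are simplified by a persistence threshold: 0.5 voxel units for the
pore analysis, 0 for the fibre analysis.  Radii are pooled per wall layer
(90 µm slabs by default, the last layer taking the remainder) and smoothed
with a Gaussian KDE (Scott's rule); each layer is summarised by its peak
radius, mean, standard deviation and second central moment.

Orientation analysis skeletonizes the fibre phase by overlaying medial axes
of the volume and its three 90° rotations about z, re-thinning the overlay,
converting to a 26-neighbour graph, pruning junctions by incidence angle,
Laplacian smoothing (10 rounds, λ = 0.5), dropping components shorter than
20 edges, and smoothing again.  Each edge yields a polar angle θ ∈ [0°, 90°]
(deviation from the layer plane) and an azimuth φ ∈ [0°, 180°); azimuths are
binned in 40 µm pseudo-layers inside a circular XY window and normalized to
mean density 1.  Running the identical pipeline on a uniform-azimuth phantom
gives the min/max **discretization band**; a sample's azimuth curve is called
anisotropic only where it leaves that band.

## Worked example

Recover a planted pore-size gradient from a phantom:

```python
from fibromorph import (compute_sedt, build_filtration, compute_persistence,
                        partition_layers)
from fibromorph.phantoms import PorePhantomSpec, generate_pore_phantom
from fibromorph.morphometry import extract_spheres, size_distribution

spec = PorePhantomSpec(
    grid_shape=(64, 64, 72),          # voxels, 2 um each
    layer_radii=(2, 3, 4, 5, 6, 7),   # cavity radius per 12-voxel layer
    spheres_per_layer=8,
    layer_thickness=12,
    seed=5,
)
volume, truth = generate_pore_phantom(spec)
layers = partition_layers(volume, layer_thickness_um=24.0, n_full=5)
sedt = compute_sedt(volume, foreground="pore")
diagram = compute_persistence(build_filtration(sedt), max_dim=0)
spheres = extract_spheres(diagram, layers, volume.voxel_size,
                          persistence_threshold=0.5)
print(size_distribution(spheres, layers).summary.round(2).to_string(index=False))
```

```
 layer  peak_radius_um  mean_um  std_um  second_moment_um2  sample_count
     0            3.47     3.38    0.21               0.04             8
     1            5.66     5.47    0.33               0.11             8
     2            7.22     7.14    0.27               0.07             8
     3            9.18     9.24    0.39               0.15             8
     4           11.55    11.38    0.28               0.08             8
     5           13.17    13.13    0.22               0.05             8
```

Planted radii of 2–7 voxels (4–14 µm) are recovered within roughly one
voxel per layer, and the per-layer peaks increase strictly with depth — the
gradient signature.  The same analysis runs from the shell:

```bash
fibromorph phantom --kind pore --seed 5 --out pore.nrrd
fibromorph pores pore.nrrd --layers 5 --layer-thickness-um 24 --out spheres.csv
fibromorph all --input scan.nrrd --seed 1 --outdir results/
```

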