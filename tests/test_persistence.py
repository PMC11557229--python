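"""Persistence pairing: worked examples, the elder rule, oracle equivalence,
stability, and diagram simplification."""

import numpy as np
import pytest

from fibromorph import (
    brute_force_persistence,
    build_filtration,
    compute_persistence,
    simplify,
)
from fibromorph.phantoms import generate_primitive
from fibromorph.sedt import DistanceVolume, compute_sedt

from conftest import random_binary_volume


def _dvol(values):
    return DistanceVolume(
        grid=np.asarray(values, dtype=float), foreground="pore", voxel_size=1.0
    )


def _key(points):
    return sorted(zip(points["dim"], points["birth"], points["death"]))


def test_edge_value_is_vertex_maximum():
    f = build_filtration(_dvol([[[-1.0]], [[3.0]]]))
    flat, vals = f.cells_of_dim(1)
    assert len(vals) == 1 and vals[0] == 3.0


def test_filtration_order_is_monotone_on_faces():
    # every cell's value is >= each of its faces' values (face before coface)
    rng = np.random.default_rng(0)
    for _ in range(10):
        f = build_filtration(_dvol(rng.random((4, 4, 4))))
        D = f.doubled
        for dim in (1, 2, 3):
            flats, vals = f.cells_of_dim(dim)
            for flat, v in zip(flats[:50], vals[:50]):
                c = np.array(np.unravel_index(flat, D.shape))
                for ax in range(3):
                    if c[ax] % 2 == 1:
                        for s in (-1, 1):
                            face = c.copy()
                            face[ax] += s
                            assert D[tuple(face)] <= v + 1e-12


def test_elder_rule_on_two_minimum_profile():
    # minima at -2 and -1.5 merge at 0: the younger (-1.5) bar dies
    diag = compute_persistence(build_filtration(_dvol([[[-2, -1, 0, -1.5, 1]]])))
    d0 = simplify(diag, 0.0).of_dim(0)
    assert _key(d0) == [(0, -2.0, np.inf), (0, -1.5, 0.0)]
    # the finite bar is born at the LARGER (younger) minimum
    finite = d0[np.isfinite(d0["death"])]
    assert float(finite["birth"].iloc[0]) == -1.5
    assert int(finite["bz"].iloc[0]) == 3  # birth location at the -1.5 voxel


def test_constant_volume_single_component():
    diag = compute_persistence(build_filtration(_dvol(np.zeros((3, 3, 3)))))
    kept = simplify(diag, 0.0)
    assert len(kept.points) == 1
    assert kept.n_essential == 1
    assert int(kept.points["dim"].iloc[0]) == 0


def test_max_dim_two_unsupported():
    f = build_filtration(_dvol(np.zeros((2, 2, 2))))
    with pytest.raises(ValueError, match="max_dim"):
        compute_persistence(f, max_dim=2)


def test_oracle_equivalence_on_random_volumes():
    rng = np.random.default_rng(2024)
    for _ in range(30):
        d = DistanceVolume(rng.random((5, 5, 5)), "pore", 1.0)
        fast = compute_persistence(build_filtration(d), max_dim=1).points
        slow = brute_force_persistence(d).points
        slow = slow[slow["dim"] <= 1]
        assert _key(fast) == _key(slow)


def test_essential_count_equals_grid_components():
    rng = np.random.default_rng(3)
    for shape in [(4, 4, 4), (6, 3, 2)]:
        d = DistanceVolume(rng.standard_normal(shape), "pore", 1.0)
        diag = compute_persistence(build_filtration(d), max_dim=1)
        assert diag.n_essential == 1  # a box is connected


def test_torus_pore_loop():
    torus = generate_primitive("solid_torus", (28, 28, 16), major_radius=8, minor_radius=3)
    d = compute_sedt(torus, "pore")
    diag = compute_persistence(build_filtration(d), max_dim=1)
    loops = simplify(diag, 0.5).of_dim(1)
    wrapping = loops[(loops["birth"] < 0) & (loops["death"] > 0)]
    assert len(wrapping) >= 1


def test_torus_loop_via_brute_force_oracle():
    # small enough for the full matrix-reduction oracle (<= 1000 voxels)
    torus = generate_primitive("solid_torus", (12, 12, 6), major_radius=3.5, minor_radius=1.5)
    d = compute_sedt(torus, "fibre")
    diag = brute_force_persistence(d)
    loops = simplify(diag, 0.4).of_dim(1)
    assert len(loops[loops["birth"] < 0]) == 1


def test_dumbbell_two_deep_components():
    # two thick balls joined by a thin bridge: one essential + one finite merge
    db = generate_primitive(
        "dumbbell", (10, 10, 10), ball_radius=2.4, separation=5, bridge_radius=1.0
    )
    d = compute_sedt(db, "fibre")
    diag = brute_force_persistence(d)
    d0 = simplify(diag, 0.0).of_dim(0)
    deep = d0[d0["birth"] < 0]
    assert len(deep) == 2
    assert np.isinf(deep["death"]).sum() == 1


class TestSimplify:
    def test_threshold_zero_strips_diagonal_only(self):
        rng = np.random.default_rng(4)
        d = DistanceVolume(rng.integers(0, 3, (4, 4, 4)).astype(float), "pore", 1.0)
        diag = compute_persistence(build_filtration(d))
        kept = simplify(diag, 0.0).points
        raw = diag.points
        finite = raw[np.isfinite(raw["death"])]
        n_diagonal = int((finite["death"] == finite["birth"]).sum())
        assert n_diagonal > 0  # integer-valued field produces diagonal pairs
        assert len(kept) == len(raw) - n_diagonal

    def test_negative_threshold_errors(self):
        d = DistanceVolume(np.zeros((2, 2, 2)), "pore", 1.0)
        diag = compute_persistence(build_filtration(d))
        with pytest.raises(ValueError, match="threshold"):
            simplify(diag, -0.1)

    def test_large_threshold_keeps_only_essential(self):
        rng = np.random.default_rng(6)
        d = DistanceVolume(rng.random((4, 4, 4)), "pore", 1.0)
        diag = compute_persistence(build_filtration(d))
        kept = simplify(diag, 10.0)
        assert len(kept.points) == kept.n_essential == 1

    def test_count_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        d = DistanceVolume(rng.random((5, 5, 5)), "pore", 1.0)
        diag = compute_persistence(build_filtration(d))
        sizes = [len(simplify(diag, t).points) for t in (0.0, 0.1, 0.3, 0.6)]
        assert sizes == sorted(sizes, reverse=True)


def _one_sided_hausdorff(a, b):
    """Max over points of `a` of the distance to `b` union the diagonal.

    Bottleneck stability implies this is bounded by the perturbation size:
    every feature either moves to a nearby feature or collapses to the
    diagonal (distance (death - birth) / 2 in the sup metric).
    """
    worst = 0.0
    for birth, death in a:
        to_diag = (death - birth) / 2.0
        to_pts = min(
            (max(abs(birth - b2), abs(death - d2)) for b2, d2 in b), default=np.inf
        )
        worst = max(worst, min(to_diag, to_pts))
    return worst


def test_stability_under_small_perturbations():
    rng = np.random.default_rng(12)
    base = rng.random((4, 4, 4))
    eps = 0.01
    d0 = compute_persistence(build_filtration(DistanceVolume(base, "pore", 1.0)))
    noisy = base + rng.uniform(-eps, eps, base.shape)
    d1 = compute_persistence(build_filtration(DistanceVolume(noisy, "pore", 1.0)))
    for dim in (0, 1):
        a = d0.points[np.isfinite(d0.points["death"]) & (d0.points["dim"] == dim)]
        b = d1.points[np.isfinite(d1.points["death"]) & (d1.points["dim"] == dim)]
        pa = a[["birth", "death"]].to_numpy()
        pb = b[["birth", "death"]].to_numpy()
        assert _one_sided_hausdorff(pa, pb) <= eps + 1e-12
        assert _one_sided_hausdorff(pb, pa) <= eps + 1e-12
    # essential births move by at most eps
    ba = d0.points.loc[np.isinf(d0.points["death"]), "birth"].to_numpy()
    bb = d1.points.loc[np.isinf(d1.points["death"]), "birth"].to_numpy()
    assert np.abs(np.sort(ba) - np.sort(bb)).max() <= eps + 1e-12
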