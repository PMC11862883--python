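"""Trajectory observables against constructed scenes and O(n²) oracles."""

import math

import numpy as np
import pytest

from monosurf import synth, traj
from monosurf.errors import InputError, TopologyError
from conftest import make_frameset


def two_bead_frames(directions, box=20.0):
    """One molecule per direction: bead pair along the given unit vector."""
    n = len(directions)
    coords = np.zeros((1, 2 * n, 3))
    coords[0, 0::2] = 10.0
    coords[0, 1::2] = 10.0 + 0.5 * np.asarray(directions)
    return make_frameset(
        coords,
        [[box, box, box]],
        ["X"] * (2 * n),
        ["B1", "B2"] * n,
        np.repeat(np.arange(1, n + 1), 2),
    )


TOPO_X = traj.ChainTopology(chains={"X": {"chain": ("B1", "B2")}})


class TestOrderParameter:
    def test_parallel_bonds_give_exactly_one(self):
        frames = two_bead_frames([[0.0, 0.0, 1.0]] * 10)
        result = traj.order_parameter(frames, TOPO_X)
        assert result.all_p2() == pytest.approx([1.0])

    def test_in_plane_bonds_give_exactly_minus_half(self):
        dirs = [[np.cos(a), np.sin(a), 0.0] for a in np.linspace(0, 3, 10)]
        result = traj.order_parameter(two_bead_frames(dirs), TOPO_X)
        assert result.all_p2() == pytest.approx([-0.5])

    def test_isotropic_bonds_average_to_zero(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=(100_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        result = traj.order_parameter(two_bead_frames(v), TOPO_X)
        assert result.all_p2()[0] == pytest.approx(0.0, abs=0.01)

    def test_magic_angle_tilt(self):
        theta = math.radians(60.0)
        dirs = [[math.sin(theta), 0.0, math.cos(theta)]] * 5
        result = traj.order_parameter(two_bead_frames(dirs), TOPO_X)
        assert result.all_p2() == pytest.approx([-0.125])

    def test_rigid_motion_invariance(self):
        """P2 is unchanged by translation and rotation about the normal."""
        rng = np.random.default_rng(4)
        v = rng.normal(size=(50, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        frames = two_bead_frames(v)
        base = traj.order_parameter(frames, TOPO_X).all_p2()
        a = 0.7
        rot = np.array(
            [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
        )
        center = frames.box[0] / 2
        moved = make_frameset(
            (frames.coords - center) @ rot.T + center + [1.3, -0.8, 0.4],
            frames.box,
            frames.resnames,
            frames.beadnames,
            frames.resids,
        )
        assert traj.order_parameter(moved, TOPO_X).all_p2() == pytest.approx(
            base, rel=1e-9
        )

    def test_default_topology_on_scene(self, small_mixture):
        spec = synth.SceneSpec(
            composition=small_mixture, apl=60.0,
            tilt=synth.TiltSpec("delta", 0.0), seed=0,
        )
        result = traj.order_parameter(synth.gen_scene(spec))
        assert set(result.values) == {"DPPC", "POPC", "POPG"}
        for chains in result.values.values():
            assert set(chains) == {"sn-1", "sn-2"}
            for bonds in chains.values():
                assert len(bonds) == 3  # C1–C2/D2, C2/D2–C3, C3–C4
        assert result.all_p2() == pytest.approx(np.ones(18))

    def test_missing_beads_reported(self):
        frames = two_bead_frames([[0, 0, 1.0]])
        bad = traj.ChainTopology(chains={"X": {"chain": ("B1", "NOPE")}})
        with pytest.raises(TopologyError, match="NOPE"):
            traj.order_parameter(frames, bad)


class TestSurfaceTension:
    def make_series(self, anis, lz=20.0, n=100):
        base = np.full(n, 1.0)
        return traj.PressureSeries(
            t=np.arange(n, dtype=float),
            pxx=base - anis, pyy=base - anis, pzz=base,
            lz=np.full(n, lz),
        )

    def test_isotropic_tensor_gives_zero(self):
        assert traj.surface_tension(self.make_series(0.0)).gamma == 0.0

    def test_unit_conversion_oracle(self):
        # 100 bar anisotropy over Lz=20 nm, 2 interfaces: (10 nm)(1e7 Pa)
        st = traj.surface_tension(self.make_series(100.0, lz=20.0))
        assert st.gamma == pytest.approx(100.0, rel=1e-12)

    def test_antisymmetry(self):
        assert traj.surface_tension(self.make_series(-50.0)).gamma == (
            pytest.approx(-traj.surface_tension(self.make_series(50.0)).gamma)
        )

    def test_linear_in_anisotropy_and_lz(self):
        g1 = traj.surface_tension(self.make_series(30.0, lz=10.0)).gamma
        g2 = traj.surface_tension(self.make_series(60.0, lz=10.0)).gamma
        g3 = traj.surface_tension(self.make_series(30.0, lz=20.0)).gamma
        assert g2 == pytest.approx(2 * g1)
        assert g3 == pytest.approx(2 * g1)

    def test_invalid_interfaces_rejected(self):
        with pytest.raises(InputError):
            traj.surface_tension(self.make_series(10.0), n_interfaces=0)


def brute_force_counts(coords, box, idx_a, idx_b, edges, identical):
    """Independent O(n²) minimum-image pair histogram."""
    counts = np.zeros(len(edges) - 1)
    for ii, i in enumerate(idx_a):
        for j in idx_b[ii + 1:] if identical else idx_b:
            d = coords[i] - coords[j]
            d -= box * np.round(d / box)
            r = math.sqrt(float(d @ d))
            for b in range(len(edges) - 1):
                if edges[b] <= r < edges[b + 1]:
                    counts[b] += 1
                    break
    return counts


class TestRDF:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(42)
        n, n_frames, box = 500, 50, 5.0
        coords = rng.uniform(0, box, size=(n_frames, n, 3))
        frames = make_frameset(
            coords, [[box] * 3] * n_frames, ["G"] * n, ["P"] * n,
            np.arange(1, n + 1),
        )
        res = traj.rdf(frames, "resname G", "resname G", r_max=1.0, n_bins=5)
        assert np.all(np.abs(res.g - 1.0) < 0.05)

    def test_fixed_pair_occupies_single_bin(self):
        coords = np.array([[[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]]])
        frames = make_frameset(
            coords, [[4.0, 4.0, 4.0]], ["A", "B"], ["P", "P"], [1, 2]
        )
        res = traj.rdf(frames, "resname A", "resname B", r_max=1.0, n_bins=10)
        assert res.counts[5] == 1 and res.counts.sum() == 1

    @pytest.mark.parametrize("identical", [True, False])
    def test_counts_match_brute_force(self, identical):
        rng = np.random.default_rng(9)
        n, box = 50, 3.0
        coords = rng.uniform(0, box, size=(3, n, 3))
        resnames = (["A"] * n) if identical else (["A"] * 25 + ["B"] * 25)
        frames = make_frameset(
            coords, [[box] * 3] * 3, resnames, ["P"] * n, np.arange(1, n + 1)
        )
        sel_b = "resname A" if identical else "resname B"
        res = traj.rdf(frames, "resname A", sel_b, r_max=1.0, n_bins=20)
        edges = np.linspace(0, 1.0, 21)
        expected = np.zeros(20)
        idx_a = np.nonzero(np.asarray(resnames) == "A")[0]
        idx_b = idx_a if identical else np.nonzero(np.asarray(resnames) == "B")[0]
        for f in range(3):
            expected += brute_force_counts(
                coords[f], box, idx_a, idx_b, edges, identical
            )
        assert np.array_equal(res.counts, expected)

    def test_lateral_mode_ignores_z(self):
        # two particles far apart in z but laterally close
        coords = np.array([[[1.0, 1.0, 1.0], [1.3, 1.0, 9.0]]])
        frames = make_frameset(
            coords, [[4.0, 4.0, 20.0]], ["A", "B"], ["P", "P"], [1, 2]
        )
        res3 = traj.rdf(frames, "resname A", "resname B", r_max=1.0, n_bins=10)
        res2 = traj.rdf(frames, "resname A", "resname B", r_max=1.0, n_bins=10,
                        mode="2d")
        assert res3.counts.sum() == 0
        assert res2.counts.sum() == 1

    def test_oversized_cutoff_rejected(self):
        frames = make_frameset(
            np.zeros((1, 2, 3)), [[1.5, 1.5, 1.5]], ["A", "B"], ["P", "P"],
            [1, 2],
        )
        with pytest.raises(InputError):
            traj.rdf(frames, "resname A", "resname B", r_max=1.0)


class TestDrugClusters:
    def test_dispersed_drugs_are_singletons(self, small_mixture):
        spec = synth.SceneSpec(
            composition=small_mixture, apl=60.0, drug_count=9,
            drug_placement="dispersed", seed=5,
        )
        res = traj.drug_clusters(synth.gen_scene(spec), "resname MF", cutoff=0.6)
        assert res.sizes[0] == [1] * 9

    def test_prescribed_cluster_sizes_recovered(self, small_mixture):
        spec = synth.SceneSpec(
            composition=small_mixture, apl=60.0, drug_count=10,
            drug_placement="aggregated", drug_cluster_sizes=(5, 3, 2), seed=6,
        )
        res = traj.drug_clusters(synth.gen_scene(spec), "resname MF", cutoff=0.6)
        assert res.sizes[0] == [5, 3, 2]
        assert res.largest_fraction[0] == pytest.approx(0.5)

    def test_chain_is_single_cluster(self):
        # 6 one-bead molecules in a line, spacing 0.4 < cutoff
        n = 6
        coords = np.zeros((1, n, 3))
        coords[0, :, 0] = 1.0 + 0.4 * np.arange(n)
        frames = make_frameset(
            coords, [[10.0] * 3], ["MF"] * n, ["SC1"] * n, np.arange(1, n + 1)
        )
        res = traj.drug_clusters(frames, "resname MF", cutoff=0.5)
        assert res.sizes[0] == [n]

    def test_particle_order_invariance(self):
        rng = np.random.default_rng(8)
        n = 20
        coords = rng.uniform(0, 8.0, size=(1, n, 3))
        frames = make_frameset(
            coords, [[8.0] * 3], ["MF"] * n, ["SC1"] * n, np.arange(1, n + 1)
        )
        base = traj.drug_clusters(frames, "resname MF", cutoff=1.5).sizes[0]
        perm = rng.permutation(n)
        shuffled = make_frameset(
            coords[:, perm], [[8.0] * 3], ["MF"] * n, ["SC1"] * n,
            np.arange(1, n + 1)[perm],
        )
        assert traj.drug_clusters(shuffled, "resname MF", cutoff=1.5).sizes[0] == base

    def test_invalid_cutoff_rejected(self):
        frames = make_frameset(
            np.zeros((1, 1, 3)), [[5.0] * 3], ["MF"], ["SC1"], [1]
        )
        with pytest.raises(InputError):
            traj.drug_clusters(frames, "resname MF", cutoff=0.0)


def fine_lattice_frames(L=12.0, spacing=0.1, holes=()):
    xs = np.arange(0.0, L, spacing) + spacing / 2
    X, Y = np.meshgrid(xs, xs)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    keep = np.ones(len(pts), dtype=bool)
    for cx, cy, r in holes:
        keep &= (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2 > r * r
    pts = pts[keep]
    coords = np.zeros((1, len(pts), 3))
    coords[0, :, :2] = pts
    coords[0, :, 2] = 5.0
    n = len(pts)
    return make_frameset(
        coords, [[L, L, 10.0]], ["LIP"] * n, ["PO4"] * n, np.arange(1, n + 1)
    )


class TestPores:
    def test_defect_free_film_has_no_pores(self):
        frames = fine_lattice_frames()
        res = traj.detect_pores(
            frames, "resname LIP", grid_cell=0.1, bead_radius=0.05
        )
        assert res.count == 0

    def test_excised_disk_area_within_one_cell_ring(self):
        r = 2.0
        frames = fine_lattice_frames(holes=((6.0, 6.0, r),))
        res = traj.detect_pores(
            frames, "resname LIP", grid_cell=0.1, bead_radius=0.05
        )
        assert res.count == 1
        assert abs(res.areas[0] - math.pi * r * r) <= 2 * math.pi * r * 0.1

    def test_two_disks_two_pores(self):
        frames = fine_lattice_frames(holes=((3.0, 3.0, 1.5), (9.0, 9.0, 1.5)))
        res = traj.detect_pores(
            frames, "resname LIP", grid_cell=0.1, bead_radius=0.05
        )
        assert res.count == 2

    def test_area_converges_as_grid_refines(self):
        r = 2.0
        frames = fine_lattice_frames(holes=((6.0, 6.0, r),))
        errs = []
        for cell in (0.4, 0.2, 0.1):
            res = traj.detect_pores(
                frames, "resname LIP", grid_cell=cell, bead_radius=0.05
            )
            assert res.count == 1
            errs.append(abs(res.areas[0] - math.pi * r * r))
        assert errs[-1] <= errs[0]
        assert errs[-1] <= 2 * math.pi * r * 0.1

    def test_periodic_pore_counted_once(self):
        # hole straddling the periodic boundary is one pore, not four
        frames = fine_lattice_frames(holes=((0.0, 0.0, 1.5),))
        res = traj.detect_pores(
            frames, "resname LIP", grid_cell=0.1, bead_radius=0.05
        )
        assert res.count == 1

    def test_scene_pore_recovery(self, small_mixture):
        box = math.sqrt(61.0 * 200) / 10
        r = 2.0
        spec = synth.SceneSpec(
            composition=small_mixture, apl=61.0,
            pores=((box / 2, box / 2, r),), seed=2,
        )
        frames = synth.gen_scene(spec)
        res = traj.detect_pores(frames, grid_cell=0.1)
        assert res.count == 1
        # detected hole is the excised disk eroded by at most the lipid
        # footprint radius plus half a lattice spacing plus one cell
        spacing = box / math.ceil(math.sqrt(200))
        margin = 0.6 + spacing / 2 + 0.1
        assert math.pi * (r - margin) ** 2 <= res.areas[0] <= math.pi * (r + 0.2) ** 2

    def test_invalid_grid_rejected(self):
        frames = fine_lattice_frames()
        with pytest.raises(InputError):
            traj.detect_pores(frames, "resname LIP", grid_cell=0.0)


class TestCollapse3D:
    def test_flat_film_not_collapsed(self, small_mixture):
        frames = synth.gen_scene(
            synth.SceneSpec(composition=small_mixture, apl=60.0, seed=1)
        )
        res = traj.detect_collapse_3d(frames)
        assert not res.collapsed.any()

    def test_displaced_heads_flagged(self, small_mixture):
        frames = synth.gen_scene(
            synth.SceneSpec(
                composition=small_mixture, apl=60.0, n_frames=2,
                collapse_fraction=0.1, collapse_displacement=3.0, seed=2,
            )
        )
        res = traj.detect_collapse_3d(frames)
        assert not res.collapsed[0]  # baseline frame stays flat
        assert res.collapsed[1]

    def test_infinite_threshold_never_collapses(self, small_mixture):
        frames = synth.gen_scene(
            synth.SceneSpec(
                composition=small_mixture, apl=60.0, n_frames=2,
                collapse_fraction=0.3, seed=3,
            )
        )
        res = traj.detect_collapse_3d(frames, spread_threshold=np.inf)
        assert not res.collapsed.any()

    def test_empty_selection_rejected(self, small_mixture):
        frames = synth.gen_scene(
            synth.SceneSpec(composition=small_mixture, apl=60.0, seed=4)
        )
        with pytest.raises(InputError):
            traj.detect_collapse_3d(frames, head_selection="name NOPE")


class TestDensityProfile:
    def test_uniform_particles_flat_profile(self):
        rng = np.random.default_rng(21)
        n = 20000
        coords = rng.uniform(0, 10.0, size=(1, n, 3))
        frames = make_frameset(
            coords, [[10.0] * 3], ["G"] * n, ["P"] * n, np.arange(1, n + 1)
        )
        prof = density = traj.density_profile(
            frames, {"g": "resname G"}, bin_width=1.0
        )["g"][1]
        assert np.all(np.abs(prof / prof.mean() - 1.0) < 0.1)

    def test_plane_occupies_single_bin(self):
        coords = np.zeros((1, 100, 3))
        coords[0, :, 2] = 5.05
        coords[0, :, 0] = np.linspace(0, 9.9, 100)
        frames = make_frameset(
            coords, [[10.0] * 3], ["G"] * 100, ["P"] * 100, np.arange(1, 101)
        )
        centers, dens = traj.density_profile(
            frames, {"g": "resname G"}, bin_width=0.5
        )["g"]
        assert np.count_nonzero(dens) == 1
        assert centers[np.argmax(dens)] == pytest.approx(5.25)

    def test_drug_accumulates_at_head_plane(self, small_mixture):
        spec = synth.SceneSpec(
            composition=small_mixture, apl=60.0, drug_count=16,
            drug_placement="dispersed", seed=7,
        )
        frames = synth.gen_scene(spec)
        profiles = traj.density_profile(
            frames,
            {"drug": "resname MF", "heads": "name PO4 NC3 GL0"},
            bin_width=0.5,
        )
        mode = {k: v[0][np.argmax(v[1])] for k, v in profiles.items()}
        assert abs(mode["drug"] - mode["heads"]) <= 0.5


class TestRoughness:
    def test_constant_profile_is_smooth(self):
        assert traj.roughness_ra(np.full(100, 3.3)) == 0.0

    def test_square_wave(self):
        h = 0.7
        z = np.tile([h, -h], 500)
        assert traj.roughness_ra(z) == pytest.approx(h, rel=1e-12)

    def test_sine_wave_closed_form(self):
        a = 1.3
        t = np.linspace(0, 2 * np.pi, 100001)
        assert traj.roughness_ra(a * np.sin(t)) == pytest.approx(
            2 * a / np.pi, rel=0.01
        )

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            traj.roughness_ra(np.array([1.0]))
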