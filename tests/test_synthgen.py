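"""Synthetic system builders and the Brownian trajectory generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidprint import synthgen as sg
from lipidprint.trajio import min_image_distance


def small_spec(**kw):
    defaults = dict(n_frames=10, seed=0)
    defaults.update(kw)
    return sg.SyntheticSpec(**defaults)


class TestCompositionCounts:
    def test_inner_leaflet_80_15_5(self):
        assert sg.composition_counts({"DMPE": 80, "DMPG": 15, "CL": 5}, 100) == {
            "DMPE": 80, "DMPG": 15, "CL": 5,
        }

    def test_outer_leaflet_1_to_3(self):
        assert sg.composition_counts({"LPS": 1, "DMPE": 3}, 200) == {"LPS": 50, "DMPE": 150}

    @settings(derandomize=True, max_examples=50)
    @given(
        n=st.integers(0, 500),
        ratios=st.lists(st.integers(1, 100), min_size=1, max_size=5),
    )
    def test_counts_sum_and_stay_near_quota(self, n, ratios):
        comp = {f"S{i}": r for i, r in enumerate(ratios)}
        counts = sg.composition_counts(comp, n)
        assert sum(counts.values()) == n
        total = sum(ratios)
        for s, r in comp.items():
            assert abs(counts[s] - n * r / total) < 1.0


class TestBuildBarrel:
    def test_counts_and_strand_map(self):
        spec = small_spec()
        topo, frame = sg.build_barrel(spec)
        n_res = spec.n_strands * spec.residues_per_strand
        assert len(topo.protein_residues()) == n_res
        assert len(topo.strand_map) == n_res
        assert topo.n_beads == 2 * n_res  # backbone + sidechain

    def test_backbone_on_cylinder(self):
        spec = small_spec()
        topo, frame = sg.build_barrel(spec)
        center = np.array([spec.box[0] / 2, spec.box[1] / 2])
        r = np.linalg.norm(frame.positions[topo.backbone_mask, :2] - center, axis=1)
        np.testing.assert_allclose(r, spec.barrel_radius, atol=1e-6)

    def test_deterministic_from_seed(self):
        a_topo, a_frame = sg.build_barrel(small_spec(seed=5))
        b_topo, b_frame = sg.build_barrel(small_spec(seed=5))
        assert [b.residue_name for b in a_topo.beads] == [b.residue_name for b in b_topo.beads]
        np.testing.assert_array_equal(a_frame.positions, b_frame.positions)

    def test_radius_too_small_is_geometry_error(self):
        with pytest.raises(sg.GeometryError):
            sg.build_barrel(small_spec(barrel_radius=0.5, ring_radius=0.8))

    def test_positive_patch(self):
        spec = small_spec(positive_patch_strands=(4, 5))
        topo, _ = sg.build_barrel(spec)
        names = topo.residue_names()
        patch = [
            names[r]
            for r, s in topo.strand_map.items()
            if s in (4, 5) and (r - 1) % spec.residues_per_strand >= 2 * spec.residues_per_strand // 3
        ]
        assert set(patch) <= {"ARG", "LYS"}


class TestBuildMembrane:
    def test_leaflet_compositions_exact(self):
        spec = small_spec()
        topo, _ = sg.build_membrane(spec)
        for leaflet, comp in (("outer", spec.outer_composition), ("inner", spec.inner_composition)):
            mols = {}
            for b in topo.beads:
                if b.leaflet == leaflet:
                    mols[b.molecule_id] = b.species
            n = len(mols)
            expected = sg.composition_counts(comp, n)
            got = {s: list(mols.values()).count(s) for s in comp}
            assert got == expected

    def test_no_lipid_inside_protein_footprint(self):
        spec = small_spec()
        topo, frame = sg.build_membrane(spec)
        center = np.array([spec.box[0] / 2, spec.box[1] / 2])
        heads = [i for i, b in enumerate(topo.beads) if b.category == "head"]
        r = np.linalg.norm(frame.positions[heads, :2] - center, axis=1)
        assert (r > spec.excl).all()

    def test_impossible_packing_is_an_error(self):
        with pytest.raises(sg.PackingError):
            sg.build_membrane(small_spec(box=(0.5, 0.5, 10.0), ring_radius=3.0, barrel_radius=0.1,
                                         exclusion_radius=0.2))


class TestLpsRing:
    def test_three_phospholipids_swapped_per_lps(self):
        spec = small_spec()
        topo, frame = sg.build_system(spec)

        def count(t, species, leaflet="outer"):
            return len({b.molecule_id for b in t.beads if b.species == species and b.leaflet == leaflet})

        # rebuild the pre-ring membrane for comparison
        pre_topo, _ = sg.build_membrane(
            spec, outer_composition={"DMPE": 1},
            start_mol_id=1, start_res_idx=spec.n_strands * spec.residues_per_strand + 1,
        )
        n_before = count(pre_topo, "DMPE")
        assert count(topo, "LPS") == spec.n_lps_ring == 10
        assert n_before - count(topo, "DMPE") == 3 * spec.n_lps_ring

    def test_zero_lps_identity(self):
        spec = small_spec()
        topo, frame = sg.build_membrane(spec)
        t2, f2 = sg.place_lps_ring(topo, frame, 0, spec.ring_radius, spec)
        assert t2 is topo and f2 is frame

    def test_lps_near_ring_radius(self):
        spec = small_spec()
        topo, frame = sg.build_system(spec)
        center = np.array([spec.box[0] / 2, spec.box[1] / 2])
        idx = [i for i, b in enumerate(topo.beads) if b.species == "LPS" and b.bead_name == "GM1"]
        assert len(idx) == 10
        r = np.linalg.norm(frame.positions[idx, :2] - center, axis=1)
        assert np.all(np.abs(r - spec.ring_radius) < 1.2)  # grid jitter + 3-lipid centroid

    def test_insufficient_phospholipids_error(self):
        spec = small_spec()
        topo, frame = sg.build_membrane(spec)
        with pytest.raises(sg.PlacementError):
            sg.place_lps_ring(topo, frame, 60, spec.ring_radius, spec)


class TestAddIons:
    def _neutral_topology(self):
        spec = small_spec(inner_composition={"DMPE": 1}, outer_composition={"DMPE": 1})
        topo, _ = sg.build_membrane(spec)
        return topo

    def test_salt_counts_from_concentration(self):
        # box of 1000 nm^3: 0.1 M NaCl -> round(0.1 * 0.602214 * 1000) = 60 pairs
        counts = sg.add_ions(self._neutral_topology(), (10.0, 10.0, 10.0))
        assert counts.na == 60
        assert counts.ca == 15
        assert counts.cl == 60 + 2 * 15
        assert counts.total_charge == 0

    def test_counter_ions_only(self):
        spec = small_spec(inner_composition={"DMPG": 1}, outer_composition={"DMPG": 1})
        topo, _ = sg.build_membrane(spec)
        q = sg.system_charge(topo)
        assert q < 0
        counts = sg.add_ions(topo, (10, 10, 10), nacl_molar=0.0, cacl2_molar=0.0)
        assert counts.na == -q and counts.cl == 0 and counts.ca == 0

    def test_neutrality_for_random_charge_fixtures(self):
        rng = np.random.default_rng(4)
        topo = self._neutral_topology()
        for _ in range(10):
            charges = {"DMPE": int(rng.integers(-3, 4))}
            counts = sg.add_ions(topo, (8, 9, 11), charges=charges)
            assert counts.total_charge == 0


class TestElasticNetwork:
    def _two_beads(self, d):
        from lipidprint.trajio import BeadRecord, Frame, Topology

        beads = [
            BeadRecord(1, "BB", 1, "ALA", 0, "protein", "backbone"),
            BeadRecord(2, "BB", 3, "GLY", 0, "protein", "backbone"),
        ]
        topo = Topology(beads)
        frame = Frame(np.array([[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]]), (10, 10, 10), 0.0)
        return topo, frame

    def test_bond_within_cutoff(self):
        topo, frame = self._two_beads(0.5)
        bonds = sg.elastic_network(topo, frame)
        assert len(bonds) == 1
        assert bonds.force_constant == 1000.0
        assert bonds.lengths[0] == pytest.approx(0.5)

    def test_no_bond_beyond_cutoff(self):
        topo, frame = self._two_beads(0.8)
        assert len(sg.elastic_network(topo, frame)) == 0

    def test_matches_brute_force_on_random_cloud(self):
        from lipidprint.trajio import BeadRecord, Frame, Topology

        rng = np.random.default_rng(9)
        n = 50
        beads = [BeadRecord(i + 1, "BB", i + 1, "ALA", 0, "protein", "backbone") for i in range(n)]
        topo = Topology(beads)
        pos = rng.uniform(0, 3.0, (n, 3))
        frame = Frame(pos, (3.5, 3.5, 3.5), 0.0)
        bonds = sg.elastic_network(topo, frame, cutoff=0.7)
        expected = set()
        for i in range(n):
            for j in range(i + 1, n):
                if abs((i + 1) - (j + 1)) == 1:
                    continue
                if min_image_distance(pos[i], pos[j], (3.5, 3.5, 3.5)) < 0.7:
                    expected.add((i + 1, j + 1))
        assert {tuple(p) for p in bonds.pairs} == expected
        assert (bonds.lengths <= 0.7).all()


class TestSimulate:
    def test_bit_identical_from_same_seed(self):
        spec = small_spec(n_frames=20)
        topo, frame = sg.build_system(spec)
        a = sg.simulate(topo, frame, spec)
        b = sg.simulate(topo, frame, spec)
        np.testing.assert_array_equal(a.positions(), b.positions())

    def test_counts_conserved_and_times_regular(self):
        spec = small_spec(n_frames=15)
        topo, frame = sg.build_system(spec)
        traj = sg.simulate(topo, frame, spec)
        assert traj.n_frames == 15
        assert traj.topology is topo
        np.testing.assert_allclose(np.diff(traj.times()), spec.frame_interval)
        for f in traj.frames:
            assert f.positions.shape == (topo.n_beads, 3)

    def test_protein_static(self):
        spec = small_spec(n_frames=8)
        topo, frame = sg.build_system(spec)
        traj = sg.simulate(topo, frame, spec)
        prot = topo.protein_mask
        for f in traj.frames:
            np.testing.assert_array_equal(f.positions[prot], frame.positions[prot])

    def test_unstable_step_raises(self):
        spec = small_spec(n_frames=5, wells=[sg.PlantedWell((1,), 5000.0, 1.0)])
        topo, frame = sg.build_system(spec)
        with pytest.raises(sg.StabilityError):
            sg.simulate(topo, frame, spec)

    def test_well_centers_offset_from_surface(self):
        spec = small_spec(wells=[sg.PlantedWell((4, 5, 6), 4.0, 1.0)])
        topo, frame = sg.build_system(spec)
        c = sg.well_centers(spec, topo, frame)
        center = np.array([spec.box[0] / 2, spec.box[1] / 2])
        assert np.linalg.norm(c[0] - center) == pytest.approx(
            spec.barrel_radius + spec.well_offset, abs=1e-9
        )

    def test_stronger_wells_monotonically_increase_occupancy(self):
        from lipidprint import contacts as ct

        occs = []
        for eps in (0.0, 2.0, 4.0, 8.0):
            spec = sg.SyntheticSpec(
                wells=[sg.PlantedWell((1, 2, 3), eps, 1.0)], n_frames=700, seed=7
            )
            topo, frame = sg.build_system(spec)
            traj = sg.simulate(topo, frame, spec)
            iv = ct.contact_intervals(traj, species="LPS")
            occ = ct.residue_occupancy(iv, traj.n_frames)
            anchor = [r for r, s in topo.strand_map.items() if s in (1, 2, 3)]
            occs.append(max(occ[r] for r in anchor))
        assert all(a <= b + 1e-12 for a, b in zip(occs, occs[1:]))


class TestSpecConfig:
    def test_yaml_round_trip(self, tmp_path):
        (tmp_path / "spec.yaml").write_text(
            "box: [12, 12, 9]\n"
            "n_frames: 50\n"
            "seed: 3\n"
            "wells:\n"
            "  - anchor_strands: [2, 3]\n"
            "    depth: 4.0\n"
            "    width: 0.8\n"
        )
        spec = sg.load_spec(tmp_path / "spec.yaml")
        assert spec.box == (12.0, 12.0, 9.0)
        assert spec.wells[0].anchor_strands == (2, 3)
        assert spec.wells[0].species == "LPS"

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            sg.SyntheticSpec(ring_radius=1.0)  # inside the barrel
        with pytest.raises(ValueError):
            sg.SyntheticSpec(n_frames=1)
        with pytest.raises(ValueError):
            sg.PlantedWell((1,), -1.0, 1.0)
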