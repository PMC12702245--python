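"""Contact counting, dual-cutoff intervals, occupancy and residence times."""

import numpy as np
import pytest

from conftest import make_distance_trajectory, make_random_system
from lipidprint import contacts as ct
from lipidprint.contacts import (
    ContactParams,
    NoIntervalsError,
    SelectionError,
    contact_intervals,
    merge_replicas,
    residence_time,
    residue_lipid_contacts,
    residue_occupancy,
)
from lipidprint.trajio import Trajectory, min_image_distance


def brute_force_counts(traj, cutoff, categories=None):
    """Triple loop over frames × residues × lipid molecules (the oracle)."""
    topo = traj.topology
    residues = topo.protein_residues()
    mols = sorted({b.molecule_id for b in topo.beads if b.species is not None})
    counts = {int(r): 0 for r in residues}
    for frame in traj.frames:
        for r in residues:
            p_idx = [
                i for i, b in enumerate(topo.beads)
                if b.is_protein and b.residue_index == r
            ]
            for m in mols:
                l_idx = [
                    i for i, b in enumerate(topo.beads)
                    if b.molecule_id == m and b.species is not None
                    and (categories is None or b.category in categories)
                ]
                dmin = min(
                    min_image_distance(frame.positions[i], frame.positions[j], frame.box)
                    for i in p_idx for j in l_idx
                )
                if dmin < cutoff:
                    counts[int(r)] += 1
    return counts


class TestContactProfile:
    def test_pinned_lipid_gives_unit_normalized_value(self):
        traj = make_distance_trajectory([0.3] * 100)
        prof = residue_lipid_contacts(traj, ContactParams())
        assert prof.values("DMPE")[0] == pytest.approx(1.0)

    def test_duplicating_identical_lipids_leaves_values_unchanged(self):
        from lipidprint.trajio import BeadRecord, Frame, Topology

        beads = [
            BeadRecord(1, "BB", 1, "ALA", 0, "protein", "backbone"),
            BeadRecord(2, "PO4", 2, "DMPE", 1, "lipid:DMPE", "phosphate", "outer"),
            BeadRecord(3, "PO4", 3, "DMPE", 2, "lipid:DMPE", "phosphate", "outer"),
        ]
        topo = Topology(beads, strand_map={1: 1})
        frames = [
            Frame(np.array([[5.0, 5, 5], [5.3, 5, 5], [5.3, 5, 5]]), (20, 20, 20), t * 200.0)
            for t in range(50)
        ]
        prof = residue_lipid_contacts(Trajectory(topo, frames))
        single = residue_lipid_contacts(make_distance_trajectory([0.3] * 50))
        assert prof.values("DMPE")[0] == pytest.approx(single.values("DMPE")[0])

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(21)
        for trial in range(3):
            traj = make_random_system(rng, n_res=4, n_mol=3, n_frames=10)
            prof = residue_lipid_contacts(traj, ContactParams(contact_cutoff=0.9))
            oracle = brute_force_counts(traj, 0.9)
            got = dict(zip((int(r) for r in prof.residues), prof.raw["DMPE"]))
            assert got == oracle

    def test_phosphate_only_mode_matches_brute_force(self):
        rng = np.random.default_rng(22)
        traj = make_random_system(rng, n_res=3, n_mol=2, n_frames=8)
        params = ContactParams(contact_cutoff=0.9, lipid_selection=("phosphate",))
        prof = residue_lipid_contacts(traj, params)
        oracle = brute_force_counts(traj, 0.9, categories=("phosphate",))
        got = dict(zip((int(r) for r in prof.residues), prof.raw["DMPE"]))
        assert got == oracle

    def test_missing_species_is_selection_error(self):
        traj = make_distance_trajectory([0.3])
        with pytest.raises(SelectionError):
            residue_lipid_contacts(traj, species=["LPS"])

    def test_frame_duplication_invariance(self):
        rng = np.random.default_rng(23)
        traj = make_random_system(rng, n_frames=6)
        doubled = Trajectory(traj.topology, traj.frames + [
            type(f)(f.positions, f.box, f.time + 1e6) for f in traj.frames
        ])
        a = residue_lipid_contacts(traj).values("DMPE")
        b = residue_lipid_contacts(doubled).values("DMPE")
        np.testing.assert_allclose(a, b)


class TestMergeReplicas:
    def test_self_merge_is_idempotent_on_values(self):
        traj = make_distance_trajectory([0.3, 0.6, 0.4] * 5)
        p = residue_lipid_contacts(traj)
        merged = merge_replicas([p, p])
        np.testing.assert_allclose(merged.values("DMPE"), p.values("DMPE"))

    def test_unequal_frame_counts_match_concatenation_oracle(self):
        rng = np.random.default_rng(31)
        t1 = make_random_system(rng, n_frames=6)
        t2 = Trajectory(
            t1.topology,
            [
                type(f)(rng.uniform(0, 3, f.positions.shape), f.box, i * 200.0)
                for i, f in enumerate(t1.frames * 3)
            ],
        )
        merged = merge_replicas(
            [residue_lipid_contacts(t1), residue_lipid_contacts(t2)]
        )
        concat = Trajectory(
            t1.topology,
            t1.frames
            + [type(f)(f.positions, f.box, 1e6 + i * 200.0) for i, f in enumerate(t2.frames)],
        )
        np.testing.assert_allclose(
            merged.values("DMPE"), residue_lipid_contacts(concat).values("DMPE")
        )


def intervals_oracle(distances, lower, upper):
    """Independent state machine: contact starts below lower, ends at >= upper."""
    out, start, bound = [], None, False
    for i, d in enumerate(distances):
        if not bound and d < lower:
            bound, start = True, i
        elif bound and d >= upper:
            out.append((start, i))
            bound = False
    if bound:
        out.append((start, len(distances)))
    return out


class TestContactIntervals:
    def test_rule_trace(self):
        # the second dip (0.5) never crosses the 0.475 start cutoff, so only
        # the first event exists under the dual-cutoff scheme
        traj = make_distance_trajectory([0.4, 0.6, 0.9, 0.5, 0.7])
        iv = contact_intervals(traj, ContactParams())
        assert [tuple(x) for x in iv.intervals[(1, 1)]] == [(0, 2)]

    def test_reopening_requires_lower_cutoff(self):
        traj = make_distance_trajectory([0.4, 0.9, 0.3, 0.5, 0.9])
        iv = contact_intervals(traj, ContactParams())
        assert [tuple(x) for x in iv.intervals[(1, 1)]] == [(0, 1), (2, 4)]

    def test_never_below_upper_is_empty(self):
        traj = make_distance_trajectory([0.9, 1.2, 0.85])
        iv = contact_intervals(traj, ContactParams())
        assert iv.intervals == {}

    def test_matches_state_machine_oracle_on_random_series(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            d = rng.uniform(0.2, 1.2, size=20)
            traj = make_distance_trajectory(d)
            iv = contact_intervals(traj, ContactParams())
            got = [tuple(x) for x in iv.intervals.get((1, 1), [])]
            assert got == intervals_oracle(d, 0.475, 0.8)

    def test_dual_cutoff_bounded_by_single_cutoffs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            d = rng.uniform(0.2, 1.2, size=30)
            traj = make_distance_trajectory(d)
            iv = contact_intervals(traj, ContactParams())
            dual = sum(b - a for a, b in iv.intervals.get((1, 1), []))
            assert (d < 0.475).sum() <= dual <= (d < 0.8).sum()

    def test_bad_cutoff_order_rejected(self):
        with pytest.raises(ValueError):
            ContactParams(lower_cutoff=0.8, upper_cutoff=0.475)


class TestOccupancy:
    def test_always_bound_is_one(self):
        traj = make_distance_trajectory([0.3] * 40)
        iv = contact_intervals(traj)
        assert residue_occupancy(iv, 40)[1] == 1.0

    def test_union_of_disjoint_lipids_is_one(self):
        from lipidprint.trajio import BeadRecord, Frame, Topology

        beads = [
            BeadRecord(1, "BB", 1, "ALA", 0, "protein", "backbone"),
            BeadRecord(2, "PO4", 2, "DMPE", 1, "lipid:DMPE", "phosphate", "outer"),
            BeadRecord(3, "PO4", 3, "DMPE", 2, "lipid:DMPE", "phosphate", "outer"),
        ]
        topo = Topology(beads, strand_map={1: 1})
        frames = []
        for t in range(100):
            a = 0.3 if t < 50 else 5.0
            b = 5.0 if t < 50 else 0.3
            frames.append(
                Frame(np.array([[10.0, 10, 10], [10 + a, 10, 10], [10 - b, 10, 10]]),
                      (50, 50, 50), t * 200.0)
            )
        iv = contact_intervals(Trajectory(topo, frames))
        assert residue_occupancy(iv, 100)[1] == 1.0

    def test_constructed_thirty_percent(self):
        d = [0.3] * 30 + [2.0] * 70
        iv = contact_intervals(make_distance_trajectory(d))
        assert residue_occupancy(iv, 100)[1] == pytest.approx(0.30)

    def test_bad_frame_count_rejected(self):
        iv = contact_intervals(make_distance_trajectory([0.3]))
        with pytest.raises(ValueError):
            residue_occupancy(iv, 0)


class TestResidenceTime:
    def test_constant_durations_mean(self):
        stats = residence_time([4.0] * 20)
        assert stats.mean_ns == pytest.approx(4.0)

    def test_exponential_fit_recovers_rate(self):
        rng = np.random.default_rng(51)
        durations = rng.exponential(scale=2.0, size=2000)  # k = 0.5 /ns
        stats = residence_time(durations)
        assert stats.fit_used
        assert stats.tau_ns == pytest.approx(2.0, rel=0.15)

    def test_single_interval_degenerates_to_mean(self):
        stats = residence_time([3.5])
        assert not stats.fit_used
        assert stats.tau_ns == stats.mean_ns == pytest.approx(3.5)

    def test_no_intervals_is_distinct_error(self):
        with pytest.raises(NoIntervalsError):
            residence_time([])

    def test_durations_from_intervals_in_ns(self):
        d = [0.3] * 10 + [2.0] * 10 + [0.3] * 5 + [2.0] * 5
        iv = contact_intervals(make_distance_trajectory(d))
        durs = iv.durations_ns()
        # frame interval 200 ps -> 0.2 ns per frame
        assert sorted(durs.tolist()) == [pytest.approx(1.0), pytest.approx(2.0)]
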