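"""Shared fixtures: tiny hand-built systems and small seeded simulations."""

from __future__ import annotations

import numpy as np
import pytest

from lipidprint.trajio import BeadRecord, Frame, Topology, Trajectory
from lipidprint import synthgen as sg


def make_distance_trajectory(distances, box=(50.0, 50.0, 50.0)):
    """One protein residue and one lipid bead separated by the given
    per-frame distances along x (far from any periodic image)."""
    beads = [
        BeadRecord(1, "BB", 1, "ALA", 0, "protein", "backbone"),
        BeadRecord(2, "PO4", 2, "DMPE", 1, "lipid:DMPE", "phosphate", "outer"),
    ]
    topo = Topology(beads, strand_map={1: 1}, n_strands=22)
    frames = [
        Frame(np.array([[25.0, 25.0, 25.0], [25.0 + d, 25.0, 25.0]]), box, i * 200.0)
        for i, d in enumerate(distances)
    ]
    return Trajectory(topo, frames)


def make_random_system(rng, n_res=4, n_mol=3, n_frames=10, box=(3.0, 3.0, 3.0)):
    """Small random protein+lipid system with periodic wrapping in play."""
    beads = []
    bid = 1
    for r in range(1, n_res + 1):
        beads.append(BeadRecord(bid, "BB", r, "ALA", 0, "protein", "backbone"))
        bid += 1
        beads.append(BeadRecord(bid, "SC1", r, "ALA", 0, "protein", "sidechain"))
        bid += 1
    for m in range(1, n_mol + 1):
        res = n_res + m
        beads.append(BeadRecord(bid, "PO4", res, "DMPE", m, "lipid:DMPE", "phosphate", "outer"))
        bid += 1
        beads.append(BeadRecord(bid, "C1A", res, "DMPE", m, "lipid:DMPE", "acyl", "outer"))
        bid += 1
    topo = Topology(beads, strand_map={r: 1 + (r - 1) % 22 for r in range(1, n_res + 1)})
    frames = [
        Frame(rng.uniform(0, box[0], size=(len(beads), 3)), box, i * 200.0)
        for i in range(n_frames)
    ]
    return Trajectory(topo, frames)


@pytest.fixture(scope="session")
def ring_well_sim():
    """Sparse-ring system (10 LPS) with one deep planted well; 800 frames."""
    spec = sg.SyntheticSpec(
        wells=[sg.PlantedWell((1, 2, 3), 8.0, 1.0)], n_frames=800, seed=1
    )
    topo, frame0 = sg.build_system(spec)
    traj = sg.simulate(topo, frame0, spec)
    return spec, topo, traj


@pytest.fixture(scope="session")
def free_membrane_sim():
    """Well-free membrane with a negligible protein footprint; 1500 frames."""
    spec = sg.SyntheticSpec(
        wells=[],
        n_frames=1500,
        seed=3,
        n_lps_ring=0,
        exclusion_radius=0.05,
        outer_composition={"DMPE": 1},
        inner_composition={"DMPE": 1},
        lps_sugars=False,
    )
    topo, frame0 = sg.build_membrane(spec)
    traj = sg.simulate(topo, frame0, spec)
    return spec, topo, traj
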