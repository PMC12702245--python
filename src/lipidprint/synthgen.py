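"""Synthetic coarse-grained membrane systems with planted binding sites.

Builds a β-barrel scaffold in an asymmetric bilayer (LPS-containing outer
leaflet, phospholipid inner leaflet), places a sparse ring of LPS molecules
around the protein, and generates seeded overdamped-Langevin (Brownian)
trajectories in which lipid binding sites are *planted* as Gaussian wells
anchored to chosen β-strands.  Because the ground truth (well locations,
depths, diffusion coefficients, polysaccharide collapse schedule) is known,
every downstream analysis can be tested as a parameter-recovery problem.

The generator reproduces the statistical structure the analyses assume —
slow 2D lateral diffusion, localized reversible binding, leaflet asymmetry,
a collapsing sugar chain — not the underlying force-field physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .trajio import (
    AMINO_ACIDS,
    BeadRecord,
    Frame,
    Topology,
    Trajectory,
    min_image_displacement,
)

__all__ = [
    "PlantedWell",
    "CollapseModel",
    "SyntheticSpec",
    "BondList",
    "IonCounts",
    "GeometryError",
    "PackingError",
    "PlacementError",
    "ChargeBalanceError",
    "StabilityError",
    "composition_counts",
    "build_barrel",
    "build_membrane",
    "build_system",
    "place_lps_ring",
    "add_ions",
    "elastic_network",
    "simulate",
    "well_centers",
    "predicted_region_occupancy",
    "measured_region_occupancy",
    "load_spec",
]

#: ions per nm^3 at 1 M (Avogadro's number / 1e24 nm^3 per litre)
IONS_PER_NM3_PER_MOLAR = 0.602214076

#: nominal net charge per lipid molecule (elementary charges)
SPECIES_CHARGE = {"DMPE": 0, "DMPG": -1, "CL": -2, "LPS": -6}

RESIDUE_CHARGE = {"ARG": 1, "LYS": 1, "ASP": -1, "GLU": -1}


class GeometryError(ValueError):
    pass


class PackingError(ValueError):
    pass


class PlacementError(ValueError):
    pass


class ChargeBalanceError(ValueError):
    pass


class StabilityError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlantedWell:
    """A Gaussian binding well anchored to a set of adjacent β-strands.

    ``depth`` is the well depth ε in kT, ``width`` the Gaussian σ in nm.
    The well acts only on lipids of ``species`` in ``leaflet`` — it stands
    in for a lipid-specific binding site on the barrel wall.
    """

    anchor_strands: tuple[int, ...]
    depth: float
    width: float
    leaflet: str = "outer"
    species: str = "LPS"

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("well depth must be >= 0 (kT)")
        if self.width <= 0:
            raise ValueError("well width must be > 0 (nm)")
        if self.leaflet not in ("outer", "inner"):
            raise ValueError("leaflet must be outer or inner")
        object.__setattr__(self, "anchor_strands", tuple(sorted(self.anchor_strands)))


@dataclass(frozen=True)
class CollapseModel:
    """Per-frame end-to-end length of the LPS polysaccharide.

    The mean holds at ``start_mean`` for the first ``hold_fraction`` of the
    run, decays linearly, and holds at ``end_mean`` for the last
    ``hold_fraction``; lengths are drawn from a normal with that mean and
    ``sd``, clipped below at ``min_length``.
    """

    start_mean: float = 2.6
    end_mean: float = 1.5
    sd: float = 0.1
    hold_fraction: float = 0.1
    min_length: float = 0.1

    def mean_at(self, t_frac: float | np.ndarray) -> np.ndarray:
        t = np.clip(
            (np.asarray(t_frac, dtype=float) - self.hold_fraction)
            / max(1e-12, 1.0 - 2.0 * self.hold_fraction),
            0.0,
            1.0,
        )
        return self.start_mean + (self.end_mean - self.start_mean) * t


@dataclass
class SyntheticSpec:
    """Complete description of a synthetic system and its dynamics.

    Compositions are ratio dictionaries realized exactly by largest-remainder
    rounding.  Diffusion coefficients are in nm²/ns; they are deliberately
    faster than real LPS lateral diffusion so that binding equilibrates
    within desk-scale trajectories.
    """

    box: tuple[float, float, float] = (14.0, 14.0, 10.0)
    n_strands: int = 22
    barrel_radius: float = 2.4
    residues_per_strand: int = 8
    outer_composition: dict[str, float] = field(default_factory=lambda: {"LPS": 1, "DMPE": 3})
    inner_composition: dict[str, float] = field(
        default_factory=lambda: {"DMPE": 80, "DMPG": 15, "CL": 5}
    )
    n_lps_ring: int = 10
    ring_radius: float = 5.0
    wells: list[PlantedWell] = field(default_factory=list)
    diffusion: dict[str, float] = field(
        default_factory=lambda: {"LPS": 1.0, "DMPE": 1.0, "DMPG": 1.0, "CL": 0.8}
    )
    frame_interval: float = 200.0  # ps
    n_frames: int = 1000
    seed: int = 0
    # geometry / numerics (desk-scale defaults, see docs/methods.md)
    area_per_lipid: float = 0.6  # nm^2
    strand_rise: float = 0.35  # nm per residue along z
    interface_offset: float = 1.0  # phosphate |z - midplane|, nm
    well_offset: float = 0.3  # well centre beyond barrel surface, nm
    exclusion_radius: float | None = None  # lipid keep-out; default barrel_radius + 0.5
    repulsion_k: float = 10.0  # kT/nm^2 half-harmonic wall (k*D*dt <= 0.5)
    dt_ps: float = 50.0  # internal Brownian step
    lps_sugars: bool = True
    positive_patch_strands: tuple[int, ...] = ()
    collapse: CollapseModel = field(default_factory=CollapseModel)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.box):
            raise ValueError("box components must be positive")
        if self.n_strands < 2:
            raise ValueError("n_strands must be >= 2")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.ring_radius <= self.barrel_radius:
            raise ValueError("ring_radius must exceed barrel_radius")
        for comp in (self.outer_composition, self.inner_composition):
            if any(v <= 0 for v in comp.values()):
                raise ValueError("composition ratios must be positive")
        if any(v <= 0 for v in self.diffusion.values()):
            raise ValueError("diffusion coefficients must be positive")
        for w in self.wells:
            bad = [s for s in w.anchor_strands if not 1 <= s <= self.n_strands]
            if bad:
                raise ValueError(f"well anchors outside 1..{self.n_strands}: {bad}")
        if self.frame_interval / self.dt_ps < 1 or (
            abs(self.frame_interval / self.dt_ps - round(self.frame_interval / self.dt_ps)) > 1e-9
        ):
            raise ValueError("frame_interval must be an integer multiple of dt_ps")

    @property
    def excl(self) -> float:
        return (
            self.exclusion_radius
            if self.exclusion_radius is not None
            else self.barrel_radius + 0.5
        )

    def rng(self, *key: int) -> np.random.Generator:
        """Sub-stream generator derived from the spec seed by stable spawn key."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=tuple(key)))


@dataclass
class BondList:
    """Elastic-network bonds between backbone beads."""

    pairs: np.ndarray  # (n_bonds, 2) bead ids
    lengths: np.ndarray  # equilibrium lengths, nm
    force_constant: float  # kJ/mol/nm^2

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class IonCounts:
    na: int
    ca: int
    cl: int
    system_charge: int  # net charge before ions

    @property
    def total_charge(self) -> int:
        return self.system_charge + self.na + 2 * self.ca - self.cl


# ---------------------------------------------------------------------------
# builders


def composition_counts(composition: dict[str, float], n: int) -> dict[str, int]:
    """Split ``n`` molecules among species by largest-remainder rounding.

    Exact for round counts: ``{"DMPE":80,"DMPG":15,"CL":5}`` at n=100 gives
    80/15/5.  Remainder ties break by dict order.
    """
    total = sum(composition.values())
    quotas = {s: n * r / total for s, r in composition.items()}
    counts = {s: int(math.floor(q)) for s, q in quotas.items()}
    short = n - sum(counts.values())
    order = sorted(
        composition,
        key=lambda s: (-(quotas[s] - counts[s]), list(composition).index(s)),
    )
    for s in order[:short]:
        counts[s] += 1
    return counts


# weighted amino-acid composition typical of a transmembrane β-barrel
_BARREL_AA = (
    ["LEU"] * 9 + ["VAL"] * 7 + ["ILE"] * 5 + ["ALA"] * 6 + ["GLY"] * 7
    + ["PHE"] * 5 + ["TYR"] * 6 + ["TRP"] * 3
    + ["SER"] * 6 + ["THR"] * 6 + ["ASN"] * 4 + ["GLN"] * 4
    + ["ARG"] * 5 + ["LYS"] * 5 + ["HIS"] * 2
    + ["ASP"] * 5 + ["GLU"] * 5 + ["MET"] * 2 + ["PRO"] * 2 + ["CYS"] * 1
)


def build_barrel(spec: SyntheticSpec) -> tuple[Topology, Frame]:
    """Place a closed β-barrel scaffold: one backbone and one outward
    sidechain bead per residue, strands on a cylinder at ``barrel_radius``.

    A seeded random sequence assigns residue identities; strands listed in
    ``positive_patch_strands`` get an Arg/Lys-rich patch at their
    outer-leaflet interface (the top third of the strand), so planted wells
    can be anchored at positively charged patches.
    """
    n, rps = spec.n_strands, spec.residues_per_strand
    if rps < 3:
        raise ValueError("residues_per_strand must be >= 3")
    spacing = 2.0 * math.pi * spec.barrel_radius / n
    if spacing < 0.25:
        raise GeometryError(
            f"barrel_radius {spec.barrel_radius} too small: strand spacing {spacing:.2f} nm"
        )
    rng = spec.rng(0)
    cx, cy = spec.box[0] / 2.0, spec.box[1] / 2.0
    z0 = spec.box[2] / 2.0
    beads: list[BeadRecord] = []
    pos: list[tuple[float, float, float]] = []
    strand_map: dict[int, int] = {}
    patch = set(spec.positive_patch_strands)
    bead_id = 1
    res_idx = 0
    for s in range(1, n + 1):
        ang = 2.0 * math.pi * (s - 1) / n
        ux, uy = math.cos(ang), math.sin(ang)
        for j in range(rps):
            res_idx += 1
            z = z0 + (j - (rps - 1) / 2.0) * spec.strand_rise
            if s in patch and j >= (2 * rps) // 3:
                resname = str(rng.choice(["ARG", "LYS"]))
            else:
                resname = str(rng.choice(_BARREL_AA))
            strand_map[res_idx] = s
            beads.append(
                BeadRecord(bead_id, "BB", res_idx, resname, 0, "protein", "backbone")
            )
            pos.append((cx + spec.barrel_radius * ux, cy + spec.barrel_radius * uy, z))
            bead_id += 1
            beads.append(
                BeadRecord(bead_id, "SC1", res_idx, resname, 0, "protein", "sidechain")
            )
            r_sc = spec.barrel_radius + 0.3
            pos.append((cx + r_sc * ux, cy + r_sc * uy, z))
            bead_id += 1
    topo = Topology(beads, strand_map=strand_map, n_strands=n)
    return topo, Frame(np.array(pos), spec.box, 0.0)


def _lipid_stack(species: str, leaflet: str, spec: SyntheticSpec) -> list[tuple[str, str, float, float, float]]:
    """(bead_name, category, dx, dy, dz-from-midplane) for one lipid."""
    s = 1.0 if leaflet == "outer" else -1.0
    h = spec.interface_offset
    if species in ("DMPE", "DMPG"):
        head = "NH3" if species == "DMPE" else "GL0"
        return [
            (head, "head", 0.0, 0.0, s * (h + 0.3)),
            ("PO4", "phosphate", 0.0, 0.0, s * h),
            ("C1A", "acyl", 0.0, 0.0, s * (h - 0.4)),
            ("C2A", "acyl", 0.0, 0.0, s * (h - 0.75)),
        ]
    if species == "CL":  # cardiolipin: two phosphates, four tails
        return [
            ("GL0", "head", 0.0, 0.0, s * (h + 0.25)),
            ("PO1", "phosphate", 0.15, 0.0, s * h),
            ("PO2", "phosphate", -0.15, 0.0, s * h),
            ("C1A", "acyl", 0.15, 0.0, s * (h - 0.4)),
            ("C1B", "acyl", 0.15, 0.0, s * (h - 0.75)),
            ("C2A", "acyl", -0.15, 0.0, s * (h - 0.4)),
            ("C2B", "acyl", -0.15, 0.0, s * (h - 0.75)),
        ]
    if species == "LPS":
        stack = [
            ("GM1", "head", 0.0, 0.0, s * (h + 0.3)),
            ("PO1", "phosphate", 0.15, 0.0, s * h),
            ("PO2", "phosphate", -0.15, 0.0, s * h),
            ("C1A", "acyl", 0.15, 0.0, s * (h - 0.4)),
            ("C1B", "acyl", 0.15, 0.0, s * (h - 0.75)),
            ("C2A", "acyl", -0.15, 0.0, s * (h - 0.4)),
            ("C2B", "acyl", -0.15, 0.0, s * (h - 0.75)),
        ]
        if spec.lps_sugars:
            # ends of the core polysaccharide; S39 height follows the
            # collapse model during simulation
            stack.append(("S01", "sugar", 0.0, 0.0, s * (h + 0.6)))
            stack.append(("S39", "sugar", 0.0, 0.0, s * (h + 0.6 + spec.collapse.start_mean)))
        return stack
    raise ValueError(f"unknown lipid species {species!r}")


def _append_lipid(
    beads: list[BeadRecord],
    pos: list[tuple[float, float, float]],
    species: str,
    leaflet: str,
    xy: tuple[float, float],
    mol_id: int,
    res_idx: int,
    spec: SyntheticSpec,
) -> None:
    z0 = spec.box[2] / 2.0
    for name, cat, dx, dy, dz in _lipid_stack(species, leaflet, spec):
        beads.append(
            BeadRecord(
                len(beads) + 1, name, res_idx, species, mol_id,
                f"lipid:{species}", cat, leaflet,
            )
        )
        pos.append((xy[0] + dx, xy[1] + dy, z0 + dz))


def _grid_sites(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered square grid over the box, excluding the protein footprint."""
    s = math.sqrt(spec.area_per_lipid)
    nx = int(spec.box[0] // s)
    ny = int(spec.box[1] // s)
    if nx < 1 or ny < 1:
        raise PackingError("box too small for one lipid at the given area per lipid")
    xs = (np.arange(nx) + 0.5) * (spec.box[0] / nx)
    ys = (np.arange(ny) + 0.5) * (spec.box[1] / ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts = pts + rng.uniform(-0.15 * s, 0.15 * s, size=pts.shape)
    center = np.array([spec.box[0] / 2.0, spec.box[1] / 2.0])
    keep = np.linalg.norm(pts - center, axis=1) > spec.excl
    return pts[keep]


def build_membrane(
    spec: SyntheticSpec,
    outer_composition: dict[str, float] | None = None,
    start_mol_id: int = 1,
    start_res_idx: int = 1,
) -> tuple[Topology, Frame]:
    """Build both leaflets on jittered grids excluding the protein footprint.

    Leaflet lipid counts realize the composition ratios exactly after
    largest-remainder rounding; species are assigned to grid sites in a
    seeded random order (random placement).
    """
    outer_comp = outer_composition if outer_composition is not None else spec.outer_composition
    rng = spec.rng(1)
    beads: list[BeadRecord] = []
    pos: list[tuple[float, float, float]] = []
    mol_id = start_mol_id
    res_idx = start_res_idx
    for leaflet, comp in (("outer", outer_comp), ("inner", spec.inner_composition)):
        sites = _grid_sites(spec, rng)
        n = len(sites)
        if n == 0:
            raise PackingError(f"no room for lipids in the {leaflet} leaflet")
        counts = composition_counts(comp, n)
        labels = [s for s, c in counts.items() for _ in range(c)]
        rng.shuffle(labels)
        for xy, species in zip(sites, labels):
            _append_lipid(beads, pos, species, leaflet, tuple(xy), mol_id, res_idx, spec)
            mol_id += 1
            res_idx += 1
    topo = Topology(beads, n_strands=spec.n_strands)
    return topo, Frame(np.array(pos), spec.box, 0.0)


def _merge(
    a: tuple[Topology, Frame], b: tuple[Topology, Frame], spec: SyntheticSpec
) -> tuple[Topology, Frame]:
    ta, fa = a
    tb, fb = b
    beads = list(ta.beads)
    off = len(beads)
    for rec in tb.beads:
        beads.append(
            BeadRecord(
                rec.bead_id + off, rec.bead_name, rec.residue_index, rec.residue_name,
                rec.molecule_id, rec.molecule_type, rec.category, rec.leaflet,
            )
        )
    topo = Topology(beads, strand_map=ta.strand_map, n_strands=spec.n_strands)
    frame = Frame(np.vstack([fa.positions, fb.positions]), spec.box, 0.0)
    return topo, frame


def build_system(spec: SyntheticSpec) -> tuple[Topology, Frame]:
    """Barrel + membrane (+ sparse LPS ring when ``n_lps_ring > 0``).

    With a sparse ring the outer leaflet is built LPS-free and
    :func:`place_lps_ring` then swaps 3 phospholipids for each LPS, mirroring
    how the study seeds LPS around the protein; with ``n_lps_ring == 0`` the
    outer leaflet is built directly at ``outer_composition`` (the
    lipid-only-system mode).
    """
    barrel = build_barrel(spec)
    n_res_protein = spec.n_strands * spec.residues_per_strand
    if spec.n_lps_ring > 0:
        outer = {s: r for s, r in spec.outer_composition.items() if s != "LPS"} or {"DMPE": 1}
        membrane = build_membrane(
            spec, outer_composition=outer,
            start_mol_id=1, start_res_idx=n_res_protein + 1,
        )
        topo, frame = _merge(barrel, membrane, spec)
        return place_lps_ring(topo, frame, spec.n_lps_ring, spec.ring_radius, spec)
    membrane = build_membrane(spec, start_mol_id=1, start_res_idx=n_res_protein + 1)
    return _merge(barrel, membrane, spec)


def _molecule_anchors(topology: Topology, frame: Frame) -> dict[int, np.ndarray]:
    """Reference xy per lipid molecule: position of its first bead."""
    anchors: dict[int, np.ndarray] = {}
    for i, b in enumerate(topology.beads):
        if b.species is not None and b.molecule_id not in anchors:
            anchors[b.molecule_id] = frame.positions[i, :2].copy()
    return anchors


def place_lps_ring(
    topology: Topology,
    frame: Frame,
    n_lps: int,
    ring_radius: float,
    spec: SyntheticSpec,
    max_search: float = 3.0,
) -> tuple[Topology, Frame]:
    """Replace outer-leaflet phospholipids with LPS on a sparse ring.

    For each of ``n_lps`` equally spaced ring angles, the 3 nearest
    outer-leaflet phospholipids are deleted and one LPS inserted at their
    centroid.  ``n_lps == 0`` returns the system unchanged.
    """
    if n_lps == 0:
        return topology, frame
    center = np.array([spec.box[0] / 2.0, spec.box[1] / 2.0])
    phos_mols: list[int] = []
    anchors = _molecule_anchors(topology, frame)
    leaflet_of: dict[int, str] = {}
    species_of: dict[int, str] = {}
    for b in topology.beads:
        if b.species is not None:
            leaflet_of[b.molecule_id] = b.leaflet
            species_of[b.molecule_id] = b.species
    for mol, sp in species_of.items():
        if sp != "LPS" and leaflet_of[mol] == "outer":
            phos_mols.append(mol)
    if len(phos_mols) < 3 * n_lps:
        raise PlacementError(
            f"need {3 * n_lps} outer-leaflet phospholipids, have {len(phos_mols)}"
        )
    removed: set[int] = set()
    new_lps_xy: list[np.ndarray] = []
    box2 = np.array(spec.box[:2])
    for k in range(n_lps):
        ang = 2.0 * math.pi * k / n_lps
        target = center + ring_radius * np.array([math.cos(ang), math.sin(ang)])
        avail = [m for m in phos_mols if m not in removed]
        d = np.array(
            [
                np.linalg.norm(min_image_displacement(anchors[m] - target, box2))
                for m in avail
            ]
        )
        order = np.argsort(d, kind="stable")
        if d[order[2]] > max_search:
            raise PlacementError(
                f"insufficient phospholipids within {max_search} nm of ring angle "
                f"{math.degrees(ang):.0f} deg"
            )
        chosen = [avail[i] for i in order[:3]]
        removed.update(chosen)
        pts = np.array([anchors[m] for m in chosen])
        # centroid under minimum image relative to the target point
        centroid = target + min_image_displacement(pts - target, box2).mean(axis=0)
        new_lps_xy.append(np.mod(centroid, box2))
    # rebuild bead list: drop removed molecules, append LPS
    beads: list[BeadRecord] = []
    pos: list[tuple[float, float, float]] = []
    for i, b in enumerate(topology.beads):
        if b.species is not None and b.molecule_id in removed:
            continue
        beads.append(
            BeadRecord(
                len(beads) + 1, b.bead_name, b.residue_index, b.residue_name,
                b.molecule_id, b.molecule_type, b.category, b.leaflet,
            )
        )
        pos.append(tuple(frame.positions[i]))
    next_mol = max((b.molecule_id for b in beads if b.species is not None), default=0) + 1
    next_res = max(b.residue_index for b in beads) + 1
    for xy in new_lps_xy:
        _append_lipid(beads, pos, "LPS", "outer", (float(xy[0]), float(xy[1])), next_mol, next_res, spec)
        next_mol += 1
        next_res += 1
    topo = Topology(beads, strand_map=topology.strand_map, n_strands=topology.n_strands)
    return topo, Frame(np.array(pos), frame.box, frame.time)


def system_charge(topology: Topology, charges: dict[str, int] | None = None) -> int:
    """Net charge: per-residue protein charges plus per-molecule lipid charges."""
    charges = charges or SPECIES_CHARGE
    q = 0
    seen_res: set[int] = set()
    seen_mol: set[int] = set()
    for b in topology.beads:
        if b.is_protein and b.residue_index not in seen_res:
            seen_res.add(b.residue_index)
            q += RESIDUE_CHARGE.get(b.residue_name, 0)
        elif b.species is not None and b.molecule_id not in seen_mol:
            seen_mol.add(b.molecule_id)
            if b.species not in charges:
                raise ChargeBalanceError(f"no charge defined for species {b.species!r}")
            q += charges[b.species]
    return q


def add_ions(
    topology: Topology,
    box: tuple[float, float, float],
    nacl_molar: float = 0.1,
    cacl2_molar: float = 0.025,
    charges: dict[str, int] | None = None,
) -> IonCounts:
    """Salt counts at the requested concentrations plus neutralizing counter-ions.

    Counts = concentration × N_A × box volume, rounded to nearest integer;
    the system's net charge is then cancelled exactly with extra Na+ or Cl−.
    """
    vol = box[0] * box[1] * box[2]
    na = round(nacl_molar * IONS_PER_NM3_PER_MOLAR * vol)
    ca = round(cacl2_molar * IONS_PER_NM3_PER_MOLAR * vol)
    cl = na + 2 * ca
    q = system_charge(topology, charges)
    if q < 0:
        na += -q
    else:
        cl += q
    counts = IonCounts(na=na, ca=ca, cl=cl, system_charge=q)
    if min(counts.na, counts.ca, counts.cl) < 0:
        raise ChargeBalanceError("negative ion count")
    assert counts.total_charge == 0
    return counts


def elastic_network(
    topology: Topology,
    frame: Frame,
    k: float = 1000.0,
    cutoff: float = 0.7,
) -> BondList:
    """Elastic-network bonds between backbone beads closer than the cutoff.

    Sequence-adjacent backbone pairs (already covalently bonded) are
    excluded; each bond's equilibrium length is the observed distance and
    the force constant is ``k`` (kJ/mol/nm²).
    """
    idx = np.flatnonzero(topology.backbone_mask)
    if len(idx) < 2:
        raise ValueError("need at least two backbone beads")
    pts = frame.positions[idx]
    res = topology.residue_indices[idx]
    box = np.array(frame.box)
    diff = min_image_displacement(pts[:, None, :] - pts[None, :, :], box)
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    ii, jj = np.triu_indices(len(idx), k=1)
    keep = (dist[ii, jj] < cutoff) & (np.abs(res[ii] - res[jj]) != 1)
    bead_ids = np.array([topology.beads[i].bead_id for i in idx])
    pairs = np.column_stack([bead_ids[ii[keep]], bead_ids[jj[keep]]])
    return BondList(pairs=pairs, lengths=dist[ii, jj][keep], force_constant=float(k))


# ---------------------------------------------------------------------------
# dynamics


def well_centers(spec: SyntheticSpec, topology: Topology, frame: Frame) -> np.ndarray:
    """xy centre of each planted well: the anchor-strand backbone centroid
    pushed ``well_offset`` nm beyond the barrel surface."""
    center = np.array([spec.box[0] / 2.0, spec.box[1] / 2.0])
    strands = topology.strand_map
    out = []
    for w in spec.wells:
        mask = np.array(
            [
                topology.backbone_mask[i]
                and strands.get(topology.beads[i].residue_index) in w.anchor_strands
                for i in range(topology.n_beads)
            ]
        )
        if not mask.any():
            raise ValueError(f"well anchors {w.anchor_strands} match no backbone beads")
        centroid = frame.positions[mask, :2].mean(axis=0)
        v = centroid - center
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise ValueError("anchor centroid coincides with the barrel axis")
        out.append(center + v / norm * (spec.barrel_radius + spec.well_offset))
    return np.array(out).reshape(len(spec.wells), 2)


def _forces(
    xy: np.ndarray,
    centers: np.ndarray,
    wells: Sequence[PlantedWell],
    active: np.ndarray,
    center: np.ndarray,
    box2: np.ndarray,
    spec: SyntheticSpec,
) -> np.ndarray:
    """−∇U in kT/nm for every molecule (n_mol, 2)."""
    f = np.zeros_like(xy)
    for wi, w in enumerate(wells):
        sel = active[:, wi]
        if not sel.any():
            continue
        d = min_image_displacement(xy[sel] - centers[wi], box2)
        r2 = (d ** 2).sum(axis=1, keepdims=True)
        g = np.exp(-r2 / (2.0 * w.width ** 2))
        f[sel] += -w.depth * g * d / (w.width ** 2)
    # soft half-harmonic wall at the protein footprint
    dc = min_image_displacement(xy - center, box2)
    r = np.sqrt((dc ** 2).sum(axis=1))
    inside = r < spec.excl
    if inside.any():
        rr = np.maximum(r[inside], 1e-9)
        f[inside] += (spec.repulsion_k * (spec.excl - rr) / rr)[:, None] * dc[inside]
    return f


def simulate(topology: Topology, frame: Frame, spec: SyntheticSpec) -> Trajectory:
    """Overdamped 2D Langevin dynamics of the lipids around the fixed barrel.

    Per substep and lipid: Δr = F·D·Δt + √(2 D Δt)·η with F = −∇U in kT/nm
    and η standard normal per axis; the potential is the sum of the planted
    Gaussian wells (species/leaflet selective) and a soft radial wall at the
    protein footprint.  Lipid bead stacks translate rigidly; the LPS S39
    sugar height is redrawn each frame from the collapse model.  Fully
    reproducible from the spec seed via per-molecule substreams.
    """
    topo = topology
    box2 = np.array(spec.box[:2])
    center = np.array([spec.box[0] / 2.0, spec.box[1] / 2.0])
    anchors = _molecule_anchors(topo, frame)
    mol_ids = sorted(anchors)
    n_mol = len(mol_ids)
    if n_mol == 0:
        raise ValueError("no lipid molecules to simulate")
    mol_index = {m: i for i, m in enumerate(mol_ids)}
    # per-molecule metadata and per-bead offsets from the anchor
    species = np.empty(n_mol, dtype=object)
    leaflet = np.empty(n_mol, dtype=object)
    bead_mol = np.full(topo.n_beads, -1, dtype=np.int64)
    offsets = np.zeros((topo.n_beads, 3))
    first_bead: dict[int, int] = {}
    s01_bead: dict[int, int] = {}
    s39_bead: dict[int, int] = {}
    for i, b in enumerate(topo.beads):
        if b.species is None:
            continue
        mi = mol_index[b.molecule_id]
        bead_mol[i] = mi
        species[mi] = b.species
        leaflet[mi] = b.leaflet
        if b.molecule_id not in first_bead:
            first_bead[b.molecule_id] = i
        fb = first_bead[b.molecule_id]
        offsets[i, :2] = min_image_displacement(
            frame.positions[i, :2] - frame.positions[fb, :2], box2
        )
        offsets[i, 2] = frame.positions[i, 2]
        if b.species == "LPS":
            if b.bead_name == "S01":
                s01_bead[b.molecule_id] = i
            elif b.bead_name == "S39":
                s39_bead[b.molecule_id] = i
    for m in mol_ids:
        if species[mol_index[m]] not in spec.diffusion:
            raise ValueError(f"no diffusion coefficient for species {species[mol_index[m]]!r}")
    d_coef = np.array([spec.diffusion[species[i]] for i in range(n_mol)])
    dt_ns = spec.dt_ps / 1000.0
    sigma = np.sqrt(2.0 * d_coef * dt_ns)[:, None]
    mobility = (d_coef * dt_ns)[:, None]
    substeps = int(round(spec.frame_interval / spec.dt_ps))
    centers = well_centers(spec, topo, frame) if spec.wells else np.zeros((0, 2))
    active = np.zeros((n_mol, len(spec.wells)), dtype=bool)
    for wi, w in enumerate(spec.wells):
        active[:, wi] = (species == w.species) & (leaflet == w.leaflet)

    lipid_mask = bead_mol >= 0
    xy = np.array([anchors[m] for m in mol_ids])
    n_sub_total = (spec.n_frames - 1) * substeps
    max_disp_limit = min(spec.box[:2]) / 2.0

    # per-molecule noise substreams (stable spawn keys), drawn in blocks
    noise_rngs = [spec.rng(3, i) for i in range(n_mol)]
    collapse_rng = [spec.rng(4, i) for i in range(n_mol)] if s39_bead else []
    lps_rows = sorted(s39_bead)  # molecule ids with sugar ends

    frames: list[Frame] = []

    def emit(frame_idx: int, xy_now: np.ndarray) -> None:
        pos = np.empty((topo.n_beads, 3))
        pos[~lipid_mask] = frame.positions[~lipid_mask]
        li = np.flatnonzero(lipid_mask)
        base = xy_now[bead_mol[li]]
        pos[li, 0] = np.mod(base[:, 0] + offsets[li, 0], box2[0])
        pos[li, 1] = np.mod(base[:, 1] + offsets[li, 1], box2[1])
        pos[li, 2] = offsets[li, 2]
        if lps_rows:
            t_frac = frame_idx / max(1, spec.n_frames - 1)
            mean = float(spec.collapse.mean_at(t_frac))
            for m in lps_rows:
                mi = mol_index[m]
                ln = max(
                    spec.collapse.min_length,
                    float(mean + spec.collapse.sd * collapse_rng[mi].standard_normal()),
                )
                sgn = 1.0 if leaflet[mi] == "outer" else -1.0
                pos[s39_bead[m], 2] = pos[s01_bead[m], 2] + sgn * ln
        frames.append(Frame(pos, spec.box, frame_idx * spec.frame_interval))

    emit(0, xy)
    block = 500  # substeps of pre-drawn noise per molecule
    step = 0
    while step < n_sub_total:
        nsteps = min(block, n_sub_total - step)
        noise = np.stack(
            [noise_rngs[i].standard_normal((nsteps, 2)) for i in range(n_mol)], axis=1
        )  # (nsteps, n_mol, 2)
        for k in range(nsteps):
            f = _forces(xy, centers, spec.wells, active, center, box2, spec)
            disp = mobility * f + sigma * noise[k]
            md = np.abs(disp).max() if disp.size else 0.0
            if md > max_disp_limit:
                raise StabilityError(
                    f"substep displacement {md:.2f} nm exceeds box/2; reduce dt_ps"
                )
            xy = np.mod(xy + disp, box2)
            step += 1
            if step % substeps == 0:
                emit(step // substeps, xy)
    return Trajectory(topo, frames, frame_interval=spec.frame_interval)


# ---------------------------------------------------------------------------
# equilibrium predictions (generator ground truth)


def predicted_region_occupancy(
    spec: SyntheticSpec,
    topology: Topology,
    frame: Frame,
    well_index: int,
    r_region: float | None = None,
    grid_step: float = 0.05,
) -> float:
    """Boltzmann-predicted probability that ≥1 lipid of the well's species
    sits within ``r_region`` of the well centre at equilibrium.

    Integrates exp(−U) over the leaflet plane on a grid; lipids are
    independent in the model so the site occupancy is 1 − (1 − p)^n.
    """
    w = spec.wells[well_index]
    centers = well_centers(spec, topology, frame)
    r_region = r_region if r_region is not None else 1.5 * w.width
    xs = np.arange(grid_step / 2, spec.box[0], grid_step)
    ys = np.arange(grid_step / 2, spec.box[1], grid_step)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    box2 = np.array(spec.box[:2])
    center = np.array([spec.box[0] / 2.0, spec.box[1] / 2.0])
    u = np.zeros(len(pts))
    for wi, ww in enumerate(spec.wells):
        if ww.species != w.species or ww.leaflet != w.leaflet:
            continue
        d = min_image_displacement(pts - centers[wi], box2)
        u += -ww.depth * np.exp(-(d ** 2).sum(axis=1) / (2.0 * ww.width ** 2))
    dc = min_image_displacement(pts - center, box2)
    r = np.sqrt((dc ** 2).sum(axis=1))
    inside = r < spec.excl
    u[inside] += 0.5 * spec.repulsion_k * (spec.excl - r[inside]) ** 2
    wgt = np.exp(-u)
    din = min_image_displacement(pts - centers[well_index], box2)
    region = np.sqrt((din ** 2).sum(axis=1)) < r_region
    p_single = wgt[region].sum() / wgt.sum()
    n = sum(
        1
        for b in topology.beads
        if b.species == w.species and b.leaflet == w.leaflet and b.category == "head"
    )
    return 1.0 - (1.0 - p_single) ** n


def measured_region_occupancy(
    traj: Trajectory,
    spec: SyntheticSpec,
    well_index: int,
    r_region: float | None = None,
    species: str | None = None,
) -> float:
    """Fraction of frames with ≥1 lipid of the species within the well region."""
    w = spec.wells[well_index]
    species = species or w.species
    r_region = r_region if r_region is not None else 1.5 * w.width
    centers = well_centers(spec, traj.topology, traj.frames[0])
    c = centers[well_index]
    box2 = np.array(spec.box[:2])
    mask = traj.topology.species_mask(species, categories=("head",))
    pos = traj.positions()[:, mask, :2]
    d = min_image_displacement(pos - c, box2)
    r = np.sqrt((d ** 2).sum(axis=-1))
    return float((r < r_region).any(axis=1).mean())


# ---------------------------------------------------------------------------
# config


def load_spec(path: str | Path) -> SyntheticSpec:
    """Read a SyntheticSpec from a YAML mapping (documented schema: the
    dataclass field names; wells as a list of mappings)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return spec_from_dict(data)


def spec_from_dict(data: dict) -> SyntheticSpec:
    data = dict(data)
    if "wells" in data:
        data["wells"] = [
            w if isinstance(w, PlantedWell) else PlantedWell(**w) for w in data["wells"]
        ]
    if "collapse" in data and not isinstance(data["collapse"], CollapseModel):
        data["collapse"] = CollapseModel(**data["collapse"])
    for key in ("box", "positive_patch_strands"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return SyntheticSpec(**data)
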