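"""Coarse-grained system and trajectory I/O.

Holds the bead/residue/strand data model used by every analysis stage and
provides the periodic-distance and rigid-body alignment primitives.

Units follow the GRO convention: coordinates in nm, times in ps.  Boxes are
orthorhombic only; triclinic box lines are rejected rather than silently
mis-measured.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeadRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "GroParseError",
    "GroStructureError",
    "DegenerateAlignmentError",
    "CHEMISTRY_CLASSES",
    "read_gro",
    "write_gro",
    "read_xtc",
    "read_topology_sidecar",
    "write_topology_sidecar",
    "read_strand_map",
    "write_strand_map",
    "min_image_distance",
    "min_image_displacement",
    "align_frames",
]

MOLECULE_TYPES = ("protein", "ion", "water")  # plus "lipid:<species>"
CATEGORIES = ("backbone", "sidechain", "phosphate", "sugar", "acyl", "head", "ion")
LEAFLETS = ("outer", "inner", "none")

AMINO_ACIDS = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

#: Residue chemistry classes covering the 20 standard amino acids.
CHEMISTRY_CLASSES: dict[str, str] = {
    "ARG": "positive", "LYS": "positive", "HIS": "positive",
    "ASP": "negative", "GLU": "negative",
    "PHE": "aromatic", "TYR": "aromatic", "TRP": "aromatic",
    "SER": "polar", "THR": "polar", "ASN": "polar", "GLN": "polar", "CYS": "polar",
    "ALA": "hydrophobic", "VAL": "hydrophobic", "LEU": "hydrophobic",
    "ILE": "hydrophobic", "MET": "hydrophobic", "PRO": "hydrophobic",
    "GLY": "hydrophobic",
}


class GroParseError(ValueError):
    """A malformed fixed-width GRO record, reported with its line number."""


class GroStructureError(ValueError):
    """Structurally inconsistent multi-frame GRO (e.g. varying atom counts)."""


class DegenerateAlignmentError(ValueError):
    """Fewer than three non-collinear beads selected for rigid alignment."""


@dataclass(frozen=True)
class BeadRecord:
    """One coarse-grained bead with its residue/molecule/leaflet metadata."""

    bead_id: int
    bead_name: str
    residue_index: int
    residue_name: str
    molecule_id: int
    molecule_type: str  # protein | lipid:<species> | ion | water
    category: str
    leaflet: str = "none"

    def __post_init__(self) -> None:
        if self.bead_id < 1 or self.residue_index < 1:
            raise ValueError("bead_id and residue_index are 1-based (>=1)")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown bead category {self.category!r}")
        if self.leaflet not in LEAFLETS:
            raise ValueError(f"unknown leaflet {self.leaflet!r}")
        ok = self.molecule_type in MOLECULE_TYPES or self.molecule_type.startswith("lipid:")
        if not ok:
            raise ValueError(f"unknown molecule_type {self.molecule_type!r}")
        if self.molecule_type.startswith("lipid:"):
            if self.leaflet == "none":
                raise ValueError("lipid beads must carry a leaflet")
        elif self.leaflet != "none":
            raise ValueError("leaflet applies to lipids only")

    @property
    def is_protein(self) -> bool:
        return self.molecule_type == "protein"

    @property
    def species(self) -> str | None:
        """Lipid species name, or None for non-lipid beads."""
        if self.molecule_type.startswith("lipid:"):
            return self.molecule_type.split(":", 1)[1]
        return None


class Topology:
    """Ordered bead records plus the residue→strand map and chemistry classes.

    Parameters
    ----------
    beads:
        Bead records in file order; bead_ids must be 1..n contiguous.
    strand_map:
        residue_index → β-strand number (1..n_strands); residues absent from
        the map are unassigned (extracellular loops, turns, plug).
    n_strands:
        Number of β-strands in the barrel (22 for a TonB-dependent
        transporter).
    chemistry:
        residue_name → class; defaults to :data:`CHEMISTRY_CLASSES`.
    """

    def __init__(
        self,
        beads: Sequence[BeadRecord],
        strand_map: dict[int, int] | None = None,
        n_strands: int = 22,
        chemistry: dict[str, str] | None = None,
    ) -> None:
        beads = list(beads)
        if not beads:
            raise ValueError("topology needs at least one bead")
        ids = [b.bead_id for b in beads]
        if ids != list(range(1, len(beads) + 1)):
            raise ValueError("bead_ids must be unique and contiguous from 1")
        if n_strands < 2:
            raise ValueError("n_strands must be >= 2")
        self.beads: list[BeadRecord] = beads
        self.n_strands = int(n_strands)
        self.strand_map: dict[int, int] = dict(strand_map or {})
        protein_res = {b.residue_index for b in beads if b.is_protein}
        bad = set(self.strand_map) - protein_res
        if bad:
            raise ValueError(f"strand_map keys are not protein residues: {sorted(bad)[:5]}")
        for s in self.strand_map.values():
            if not 1 <= s <= self.n_strands:
                raise ValueError(f"strand number {s} outside 1..{self.n_strands}")
        self.chemistry: dict[str, str] = dict(chemistry or CHEMISTRY_CLASSES)
        # cached per-bead arrays
        self.residue_indices = np.array([b.residue_index for b in beads], dtype=np.int64)
        self.molecule_ids = np.array([b.molecule_id for b in beads], dtype=np.int64)
        self.protein_mask = np.array([b.is_protein for b in beads], dtype=bool)
        self.backbone_mask = self.protein_mask & np.array(
            [b.category == "backbone" for b in beads], dtype=bool
        )

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def lipid_species(self) -> list[str]:
        """Lipid species present, in first-appearance order."""
        seen: list[str] = []
        for b in self.beads:
            s = b.species
            if s is not None and s not in seen:
                seen.append(s)
        return seen

    def species_mask(self, species: str, categories: Iterable[str] | None = None) -> np.ndarray:
        """Boolean per-bead mask for one lipid species, optionally restricted
        to bead categories (e.g. phosphate-only analyses)."""
        cats = set(categories) if categories is not None else None
        return np.array(
            [
                b.species == species and (cats is None or b.category in cats)
                for b in self.beads
            ],
            dtype=bool,
        )

    def protein_residues(self) -> np.ndarray:
        """Sorted protein residue indices."""
        return np.unique(self.residue_indices[self.protein_mask])

    def residue_names(self) -> dict[int, str]:
        """residue_index → residue_name for protein residues."""
        out: dict[int, str] = {}
        for b in self.beads:
            if b.is_protein:
                out.setdefault(b.residue_index, b.residue_name)
        return out

    def validate(self) -> None:
        """Check the structural invariants that cheap construction skips."""
        bb = {b.residue_index for b in self.beads if b.is_protein and b.category == "backbone"}
        missing = set(self.protein_residues().tolist()) - bb
        if missing:
            raise ValueError(f"protein residues without backbone bead: {sorted(missing)[:5]}")
        mol_species: dict[int, str] = {}
        for b in self.beads:
            if b.species is None:
                continue
            prev = mol_species.setdefault(b.molecule_id, b.species)
            if prev != b.species:
                raise ValueError(f"molecule {b.molecule_id} mixes lipid species")


@dataclass
class Frame:
    """Bead coordinates (nm) in an orthorhombic periodic box at one time (ps)."""

    positions: np.ndarray  # (n_beads, 3) nm
    box: tuple[float, float, float]
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_beads, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        self.box = tuple(float(v) for v in self.box)
        if len(self.box) != 3 or any(v <= 0 for v in self.box):
            raise ValueError("box components must be positive")


class Trajectory:
    """A topology plus an ordered sequence of frames."""

    def __init__(
        self,
        topology: Topology,
        frames: Sequence[Frame],
        frame_interval: float = 200.0,
    ) -> None:
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        n = topology.n_beads
        for i, f in enumerate(frames):
            if f.positions.shape[0] != n:
                raise ValueError(f"frame {i} has {f.positions.shape[0]} beads, topology has {n}")
        times = [f.time for f in frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        self.topology = topology
        self.frames = frames
        self.frame_interval = float(frame_interval)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def positions(self) -> np.ndarray:
        """All coordinates stacked as (n_frames, n_beads, 3)."""
        return np.stack([f.positions for f in self.frames])

    def boxes(self) -> np.ndarray:
        return np.array([f.box for f in self.frames])

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


# ---------------------------------------------------------------------------
# GRO format


_TIME_RE = re.compile(r"\bt\s*=\s*([-+0-9.eE]+)")


def _parse_gro_atom_line(line: str, lineno: int) -> tuple[int, str, str, int, float, float, float]:
    if len(line.rstrip("\n")) < 44:
        raise GroParseError(f"line {lineno}: GRO atom record shorter than 44 columns")
    try:
        resid = int(line[0:5])
        resname = line[5:10].strip()
        name = line[10:15].strip()
        atomid = int(line[15:20])
        x = float(line[20:28])
        y = float(line[28:36])
        z = float(line[36:44])
    except ValueError as exc:
        raise GroParseError(f"line {lineno}: malformed fixed-width GRO record ({exc})") from exc
    return resid, resname, name, atomid, x, y, z


_ION_NAMES = {"NA", "CL", "CA", "NA+", "CL-", "CA2+", "ION"}


def _fallback_bead(
    bead_id: int, name: str, resid: int, resname: str
) -> BeadRecord:
    """Heuristic typing when no sidecar is supplied (documented fallback):
    BB→backbone, PO*→phosphate, S<digits>→sugar, C?A/C?B/GL*→acyl,
    amino-acid resname→protein."""
    if resname in AMINO_ACIDS:
        cat = "backbone" if name == "BB" else "sidechain"
        return BeadRecord(bead_id, name, resid, resname, 0, "protein", cat)
    if resname in ("W", "WN") or name == "W":
        return BeadRecord(bead_id, name, resid, resname, resid, "water", "head")
    if resname.upper() in _ION_NAMES or name.upper() in _ION_NAMES:
        return BeadRecord(bead_id, name, resid, resname, resid, "ion", "ion")
    if re.fullmatch(r"PO\d", name):
        cat = "phosphate"
    elif re.fullmatch(r"S\d+", name):
        cat = "sugar"
    elif re.fullmatch(r"[CD]\d[AB]", name) or name.startswith("GL"):
        cat = "acyl"
    else:
        cat = "head"
    return BeadRecord(bead_id, name, resid, resname, resid, f"lipid:{resname}", cat, "outer")


def read_gro(
    path: str | Path,
    sidecar: str | Path | None = None,
    strand_map: str | Path | dict[int, int] | None = None,
    frame_interval: float = 200.0,
    n_strands: int = 22,
) -> Trajectory:
    """Read a (possibly multi-frame, concatenated) GRO file.

    Bead metadata is taken from the sidecar TSV when given; otherwise a
    name-based heuristic assigns categories.  Frame times come from a
    ``t=`` token on the title line when present, else ``i * frame_interval``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    names: list[tuple[int, str, str]] = []
    i = 0
    lineno = 0
    first_count: int | None = None
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        title = lines[i]
        m = _TIME_RE.search(title)
        try:
            count = int(lines[i + 1].strip())
        except (IndexError, ValueError) as exc:
            raise GroParseError(f"line {i + 2}: expected atom count") from exc
        if first_count is None:
            first_count = count
        elif count != first_count:
            raise GroStructureError(
                f"frame {frame_idx} has {count} atoms, first frame has {first_count}"
            )
        atom_lines = lines[i + 2 : i + 2 + count]
        if len(atom_lines) < count:
            raise GroStructureError(f"truncated frame {frame_idx}: expected {count} atom lines")
        pos = np.empty((count, 3))
        this_names: list[tuple[int, str, str]] = []
        for j, line in enumerate(atom_lines):
            lineno = i + 3 + j
            resid, resname, name, _atomid, x, y, z = _parse_gro_atom_line(line, lineno)
            pos[j] = (x, y, z)
            this_names.append((resid, resname, name))
        if frame_idx == 0:
            names = this_names
        box_line = lines[i + 2 + count].split()
        try:
            box_vals = [float(v) for v in box_line]
        except ValueError as exc:
            raise GroParseError(f"line {i + 3 + count}: malformed box line") from exc
        if len(box_vals) < 3:
            raise GroParseError(f"line {i + 3 + count}: box line needs 3 values")
        if len(box_vals) > 3 and any(abs(v) > 0 for v in box_vals[3:]):
            raise GroStructureError("triclinic box not supported (orthorhombic only)")
        time = float(m.group(1)) if m else frame_idx * frame_interval
        frames.append(Frame(pos, tuple(box_vals[:3]), time))
        i += 3 + count
        frame_idx += 1
    if not frames:
        raise GroStructureError(f"{path}: no frames found")

    if sidecar is not None:
        beads = read_topology_sidecar(sidecar)
        if len(beads) != first_count:
            raise GroStructureError(
                f"sidecar has {len(beads)} beads, GRO has {first_count}"
            )
    else:
        beads = [
            _fallback_bead(k + 1, nm, resid, resname)
            for k, (resid, resname, nm) in enumerate(names)
        ]
    smap: dict[int, int] | None
    if isinstance(strand_map, (str, Path)):
        smap = read_strand_map(strand_map)
    else:
        smap = strand_map
    topo = Topology(beads, strand_map=smap, n_strands=n_strands)
    return Trajectory(topo, frames, frame_interval=frame_interval)


def write_gro(traj: Trajectory, path: str | Path, title: str = "lipidprint system") -> Path:
    """Write a trajectory as concatenated fixed-width GRO frames (nm, 3 dp)."""
    path = Path(path)
    if not traj.frames:
        raise ValueError("refusing to write an empty trajectory")
    out: list[str] = []
    for frame in traj.frames:
        if np.any(np.abs(frame.positions) >= 10000):
            raise OverflowError("coordinate magnitude exceeds GRO %8.3f field width")
        out.append(f"{title}, t= {frame.time:.3f}")
        out.append(f"{traj.topology.n_beads:5d}")
        for b, (x, y, z) in zip(traj.topology.beads, frame.positions):
            out.append(
                f"{b.residue_index % 100000:5d}{b.residue_name:<5.5s}"
                f"{b.bead_name:>5.5s}{b.bead_id % 100000:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}"
            )
        out.append("{:10.5f}{:10.5f}{:10.5f}".format(*frame.box))
    path.write_text("\n".join(out) + "\n")
    return path


def read_xtc(
    xtc_path: str | Path,
    top_path: str | Path,
    sidecar: str | Path | None = None,
    strand_map: str | Path | dict[int, int] | None = None,
    frame_interval: float = 200.0,
) -> Trajectory:
    """Read a compressed XTC trajectory via an installed mdtraj reader.

    XTC is lossy-compressed binary; GRO remains the bit-exact interchange
    format.  ``top_path`` is a GRO (or PDB) file defining the bead order.
    """
    try:
        import mdtraj as md
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError("XTC reading requires the optional mdtraj package") from exc
    t = md.load(str(xtc_path), top=str(top_path))
    base = read_gro(top_path, sidecar=sidecar, strand_map=strand_map)
    frames = []
    for i in range(t.n_frames):
        lengths = t.unitcell_lengths[i] if t.unitcell_lengths is not None else base.frames[0].box
        time = float(t.time[i]) if t.time is not None else i * frame_interval
        frames.append(Frame(np.asarray(t.xyz[i], dtype=float), tuple(lengths), time))
    return Trajectory(base.topology, frames, frame_interval=frame_interval)


SIDECAR_COLUMNS = [
    "bead_id", "bead_name", "residue_index", "residue_name",
    "molecule_id", "molecule_type", "category", "leaflet",
]


def read_topology_sidecar(path: str | Path) -> list[BeadRecord]:
    """Read the bead-metadata sidecar TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SIDECAR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sidecar missing columns: {sorted(missing)}")
    return [
        BeadRecord(
            int(r.bead_id), str(r.bead_name), int(r.residue_index), str(r.residue_name),
            int(r.molecule_id), str(r.molecule_type), str(r.category), str(r.leaflet),
        )
        for r in df.itertuples(index=False)
    ]


def write_topology_sidecar(topology: Topology, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            (b.bead_id, b.bead_name, b.residue_index, b.residue_name,
             b.molecule_id, b.molecule_type, b.category, b.leaflet)
            for b in topology.beads
        ],
        columns=SIDECAR_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_strand_map(path: str | Path) -> dict[int, int]:
    """Read the residue→strand TSV (columns residue_index, strand)."""
    df = pd.read_csv(path, sep="\t")
    if not {"residue_index", "strand"} <= set(df.columns):
        raise ValueError("strand map needs columns residue_index, strand")
    return {int(r.residue_index): int(r.strand) for r in df.itertuples(index=False)}


def write_strand_map(strand_map: dict[int, int], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(sorted(strand_map.items()), columns=["residue_index", "strand"])
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Geometry primitives


def min_image_displacement(delta: np.ndarray, box: np.ndarray | tuple) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def min_image_distance(a, b, box) -> float | np.ndarray:
    """Minimum-image Euclidean distance in an orthorhombic periodic box.

    Accepts single positions or broadcastable arrays of positions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite positions")
    box_arr = np.asarray(box, dtype=float)
    if np.any(box_arr <= 0):
        raise ValueError("box components must be positive")
    d = min_image_displacement(a - b, box_arr)
    out = np.sqrt(np.sum(d * d, axis=-1))
    return float(out) if out.ndim == 0 else out


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping mobile → ref (least-squares)."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    a = mobile - mc
    b = ref - rc
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = rc - rot @ mc
    return rot, t


def align_frames(
    traj: Trajectory,
    reference: Frame | None = None,
    selection: np.ndarray | Callable[[BeadRecord], bool] | None = None,
) -> Trajectory:
    """Rigid-body align every frame onto the reference using the selected beads.

    Default selection is the protein backbone beads; the whole frame is
    transformed with the rotation/translation fitted on the selection.
    """
    topo = traj.topology
    if selection is None:
        mask = topo.backbone_mask
    elif callable(selection):
        mask = np.array([bool(selection(b)) for b in topo.beads], dtype=bool)
    else:
        mask = np.asarray(selection, dtype=bool)
    if mask.sum() == 0:
        raise DegenerateAlignmentError("empty alignment selection")
    ref = reference if reference is not None else traj.frames[0]
    if ref.positions.shape[0] != topo.n_beads:
        raise ValueError("reference frame bead count differs from topology")
    ref_sel = ref.positions[mask]
    centered = ref_sel - ref_sel.mean(axis=0)
    if mask.sum() < 3 or np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise DegenerateAlignmentError("need >=3 non-collinear beads to align")
    new_frames: list[Frame] = []
    for f in traj.frames:
        rot, t = _kabsch(f.positions[mask], ref_sel)
        new_frames.append(Frame(f.positions @ rot.T + t, f.box, f.time))
    return Trajectory(topo, new_frames, frame_interval=traj.frame_interval)
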