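"""Binding-site detection and characterization.

Pipeline: align the trajectory on the protein backbone → 2D leaflet density
maps → flag residues whose contact value stands ≥ 2σ above the non-zero
background → cluster flagged residues that sit on the same or adjacent
β-strands (adjacency is circular, so the β-seam pair β22/β1 clusters) →
score each site's occupancy with all poses combined, pick a representative
pose, and match sites against externally labelled strand ranges.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .contacts import ContactIntervals, ContactProfile, SelectionError
from .trajio import BeadRecord, Trajectory

__all__ = [
    "DensityMap",
    "BindingSite",
    "SiteMatchReport",
    "InsufficientBackgroundError",
    "density_map",
    "detect_peaks",
    "cluster_sites",
    "site_occupancy",
    "representative_pose",
    "site_concordance",
    "parse_strand_range",
]


class InsufficientBackgroundError(ValueError):
    """Fewer than three residues with non-zero contacts: no background."""


@dataclass
class DensityMap:
    """2D xy histogram of selected bead positions over a frame window."""

    counts: np.ndarray  # (nx, ny)
    x_edges: np.ndarray
    y_edges: np.ndarray
    frame_range: tuple[int, int]  # half-open
    selection: str = ""

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(0.5 * (self.x_edges[:-1] + self.x_edges[1:]), name="x_nm"),
            columns=0.5 * (self.y_edges[:-1] + self.y_edges[1:]),
        )


def density_map(
    traj: Trajectory,
    selection: np.ndarray | Callable[[BeadRecord], bool] | None = None,
    grid_step: float = 0.1,
    window: tuple[float, float] = (0.5, 1.0),
) -> DensityMap:
    """Histogram selected bead xy positions over the window (fractions of the
    run; the default covers the second half of the simulation time).

    The trajectory should already be aligned on the protein backbone.
    Conservation holds exactly: counts sum to selected beads × frames used.
    """
    topo = traj.topology
    if selection is None:
        mask = topo.species_mask("LPS", categories=("phosphate",))
    elif callable(selection):
        mask = np.array([bool(selection(b)) for b in topo.beads], dtype=bool)
    else:
        mask = np.asarray(selection, dtype=bool)
    if mask.sum() == 0:
        raise SelectionError("empty density selection")
    lo, hi = window
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("window must satisfy 0 <= lo < hi <= 1")
    f0 = int(np.floor(lo * traj.n_frames))
    f1 = int(np.ceil(hi * traj.n_frames))
    if f1 <= f0:
        raise SelectionError("empty frame window")
    box = traj.frames[0].box
    x_edges = np.arange(0.0, box[0] + grid_step, grid_step)
    y_edges = np.arange(0.0, box[1] + grid_step, grid_step)
    counts = np.zeros((len(x_edges) - 1, len(y_edges) - 1))
    for frame in traj.frames[f0:f1]:
        xy = frame.positions[mask, :2]
        # clip so beads straddling the box edge after alignment still count
        x = np.clip(xy[:, 0], x_edges[0], np.nextafter(x_edges[-1], 0))
        y = np.clip(xy[:, 1], y_edges[0], np.nextafter(y_edges[-1], 0))
        h, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
        counts += h
    return DensityMap(counts, x_edges, y_edges, (f0, f1), selection=f"{int(mask.sum())} beads")


@dataclass
class BindingSite:
    """A cluster of peak residues on the same or adjacent β-strands."""

    site_id: int
    residues: frozenset[int]
    strands: frozenset[int]
    peak_value: float = 0.0
    occupancy: float = 0.0
    representative: tuple[int, int] | None = None  # (frame, lipid molecule)
    unassigned: bool = False  # loop residue outside the strand map

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("a binding site needs at least one residue")


def detect_peaks(
    profile: ContactProfile,
    species: str,
    z: float = 2.0,
) -> set[int]:
    """Residues whose contact value is at least ``z`` standard deviations
    above the mean of the non-zero background.

    Background statistics are computed in a single pass over *all* non-zero
    values, prospective peaks included.  A uniform non-zero profile (σ = 0)
    yields no peaks; fewer than 3 non-zero values is an error.
    """
    values = profile.values(species)
    nz = values[values > 0]
    if nz.size < 3:
        raise InsufficientBackgroundError(
            f"only {nz.size} residues with non-zero contacts"
        )
    mu = float(nz.mean())
    sigma = float(nz.std(ddof=0))
    if sigma == 0.0:
        return set()
    thr = mu + z * sigma
    return {int(r) for r, v in zip(profile.residues, values) if v >= thr}


def cluster_sites(
    peaks: set[int],
    strand_map: dict[int, int],
    n_strands: int = 22,
    profile: ContactProfile | None = None,
    species: str | None = None,
) -> list[BindingSite]:
    """Group peak residues into sites by connected components of the
    "same or circularly adjacent β-strand" relation.

    Peaks on residues without a strand assignment (extracellular loops)
    become flagged singleton sites rather than being dropped.  When a
    profile is supplied, each site records its peak contact value.
    Sites are ordered by their lowest strand, then lowest residue.
    """

    def adjacent(a: int, b: int) -> bool:
        d = abs(a - b) % n_strands
        return d <= 1 or d == n_strands - 1

    assigned = sorted(p for p in peaks if p in strand_map)
    loose = sorted(p for p in peaks if p not in strand_map)
    g = nx.Graph()
    g.add_nodes_from(assigned)
    for i, a in enumerate(assigned):
        for b in assigned[i + 1 :]:
            if adjacent(strand_map[a], strand_map[b]):
                g.add_edge(a, b)
    values: dict[int, float] = {}
    if profile is not None and species is not None:
        values = {
            int(r): float(v)
            for r, v in zip(profile.residues, profile.values(species))
        }
    groups: list[tuple[frozenset[int], frozenset[int], bool]] = []
    for comp in nx.connected_components(g):
        residues = frozenset(int(r) for r in comp)
        strands = frozenset(strand_map[r] for r in comp)
        groups.append((residues, strands, False))
    for p in loose:
        groups.append((frozenset([int(p)]), frozenset(), True))
    groups.sort(key=lambda t: (min(t[1]) if t[1] else n_strands + 1, min(t[0])))
    return [
        BindingSite(
            site_id=i + 1,
            residues=res,
            strands=strands,
            peak_value=max((values.get(r, 0.0) for r in res), default=0.0),
            unassigned=flag,
        )
        for i, (res, strands, flag) in enumerate(groups)
    ]


def site_occupancy(
    site: BindingSite,
    intervals: ContactIntervals,
    n_frames: int,
) -> float:
    """Fraction of frames with ≥1 lipid bound to ≥1 residue of the site —
    the union over residues and lipid molecules, so distinct poses at the
    same site are combined."""
    if not site.residues:
        raise ValueError("empty site")
    acc = np.zeros(n_frames, dtype=bool)
    for (r, _m), iv in intervals.intervals.items():
        if r in site.residues:
            for a, b in iv:
                acc[a:b] = True
    return float(acc.mean())


def representative_pose(
    site: BindingSite,
    intervals: ContactIntervals,
) -> tuple[int, int]:
    """The (frame, lipid molecule) maximizing the number of site residues
    simultaneously in contact; ties break to the earliest frame, then the
    lowest molecule id."""
    mols = sorted({m for (r, m) in intervals.intervals if r in site.residues})
    if not mols:
        raise NoPoseError("site has zero occupancy")
    best: tuple[int, int, int] | None = None  # (-count, frame, mol)
    for m in mols:
        counts = np.zeros(intervals.n_frames, dtype=np.int32)
        for (r, mm), iv in intervals.intervals.items():
            if mm == m and r in site.residues:
                for a, b in iv:
                    counts[a:b] += 1
        if counts.max() == 0:
            continue
        fr = int(np.argmax(counts))  # argmax returns the earliest maximum
        cand = (-int(counts[fr]), fr, int(m))
        if best is None or cand < best:
            best = cand
    if best is None:
        raise NoPoseError("site has zero occupancy")
    return best[1], best[2]


class NoPoseError(ValueError):
    pass


_RANGE_RE = re.compile(r"^(?:β|beta|b)?(\d+)(?:\s*-\s*(?:β|beta|b)?(\d+))?$")


def parse_strand_range(label: str, n_strands: int = 22) -> frozenset[int]:
    """Parse labels like ``β11-13`` or the wraparound ``β21-β1``."""
    m = _RANGE_RE.match(label.strip())
    if not m:
        raise ValueError(f"malformed strand range {label!r}")
    a = int(m.group(1))
    b = int(m.group(2)) if m.group(2) else a
    if not (1 <= a <= n_strands and 1 <= b <= n_strands):
        raise ValueError(f"strand out of range in {label!r}")
    if a <= b:
        return frozenset(range(a, b + 1))
    return frozenset(list(range(a, n_strands + 1)) + list(range(1, b + 1)))


@dataclass
class SiteMatchReport:
    """One-to-one matching of detected sites against labelled strand ranges."""

    matched: list[tuple[int, str]]  # (site_id, reference label)
    unmatched_md: list[int]
    unmatched_reference: list[str]

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def site_concordance(
    md_sites: Sequence[BindingSite],
    reference: Sequence[str] | dict[str, str],
    n_strands: int = 22,
) -> SiteMatchReport:
    """Greedily match detected sites to reference strand ranges.

    A site matches a range if their strand sets intersect; candidate pairs
    are taken in order of largest intersection, then lowest reference label,
    and each side is used at most once.
    """
    if isinstance(reference, dict):
        ranges = {lab: parse_strand_range(rng, n_strands) for lab, rng in reference.items()}
    else:
        ranges = {lab: parse_strand_range(lab, n_strands) for lab in reference}
    cands = []
    for site in md_sites:
        for lab, strands in ranges.items():
            inter = len(site.strands & strands)
            if inter > 0:
                cands.append((-inter, lab, site.site_id))
    cands.sort()
    used_sites: set[int] = set()
    used_refs: set[str] = set()
    matched: list[tuple[int, str]] = []
    for neg, lab, sid in cands:
        if sid in used_sites or lab in used_refs:
            continue
        matched.append((sid, lab))
        used_sites.add(sid)
        used_refs.add(lab)
    matched.sort()
    return SiteMatchReport(
        matched=matched,
        unmatched_md=[s.site_id for s in md_sites if s.site_id not in used_sites],
        unmatched_reference=[lab for lab in ranges if lab not in used_refs],
    )
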