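"""Per-residue lipid contacts, dual-cutoff intervals, occupancy, residence times.

Two contact framings coexist, as in protein–lipid fingerprinting practice:

* a single 0.55 nm cutoff for the normalized contact profile (counts per
  lipid per frame), and
* a dual-cutoff scheme (0.475 nm to start a contact, 0.8 nm to end it) for
  continuous binding events, from which occupancies and residence times
  derive.

A contact event is counted once per (frame, residue, lipid molecule)
regardless of how many bead pairs lie within the cutoff — group-wise
minimum-distance semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trajio import Topology, Trajectory, min_image_displacement

__all__ = [
    "ContactParams",
    "ContactProfile",
    "ContactIntervals",
    "ResidenceStats",
    "SelectionError",
    "NoIntervalsError",
    "min_distance_series",
    "residue_lipid_contacts",
    "merge_replicas",
    "contact_intervals",
    "residue_occupancy",
    "residence_time",
    "residue_residence_times",
]


class SelectionError(ValueError):
    pass


class NoIntervalsError(ValueError):
    """No binding events: distinct from a residence time of zero."""


@dataclass(frozen=True)
class ContactParams:
    """Distance cutoffs (nm) and the lipid bead selection.

    ``lipid_selection`` restricts which lipid bead categories count (e.g.
    ``("phosphate",)`` for the phosphate-centric analysis); None means all
    beads of the lipid.
    """

    contact_cutoff: float = 0.55
    lower_cutoff: float = 0.475
    upper_cutoff: float = 0.8
    lipid_selection: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if not 0 < self.lower_cutoff < self.upper_cutoff:
            raise ValueError("need 0 < lower_cutoff < upper_cutoff")


def _residue_segments(topology: Topology) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Protein bead indices ordered by residue, segment starts, residue ids."""
    idx = np.flatnonzero(topology.protein_mask)
    res = topology.residue_indices[idx]
    order = np.argsort(res, kind="stable")
    idx = idx[order]
    res = res[order]
    residues, starts = np.unique(res, return_index=True)
    return idx, starts, residues


def _lipid_segments(
    topology: Topology, species: str, categories: Iterable[str] | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mask = topology.species_mask(species, categories)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise SelectionError(
            f"no beads for species {species!r}"
            + (f" with categories {tuple(categories)}" if categories else "")
        )
    mols = topology.molecule_ids[idx]
    order = np.argsort(mols, kind="stable")
    idx = idx[order]
    mols = mols[order]
    mol_ids, starts = np.unique(mols, return_index=True)
    return idx, starts, mol_ids


def min_distance_series(
    traj: Trajectory,
    species: str,
    lipid_selection: Iterable[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum bead-pair distance per (frame, protein residue, lipid molecule).

    Returns ``(dist, residues, mol_ids)`` with ``dist`` of shape
    (n_frames, n_residues, n_molecules), minimum-image in each frame's box.
    """
    topo = traj.topology
    p_idx, p_starts, residues = _residue_segments(topo)
    l_idx, l_starts, mol_ids = _lipid_segments(topo, species, lipid_selection)
    if len(p_idx) == 0:
        raise SelectionError("topology has no protein beads")
    out = np.empty((traj.n_frames, len(residues), len(mol_ids)))
    for fi, frame in enumerate(traj.frames):
        box = np.asarray(frame.box)
        diff = frame.positions[l_idx, None, :] - frame.positions[None, p_idx, :]
        diff -= box * np.round(diff / box)
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        # min over residue bead segments, then over lipid bead segments
        per_res = np.minimum.reduceat(d2, p_starts, axis=1)
        per_pair = np.minimum.reduceat(per_res, l_starts, axis=0)
        out[fi] = per_pair.T
    return np.sqrt(out), residues, mol_ids


@dataclass
class ContactProfile:
    """Normalized per-residue contact rates per lipid species.

    ``value = raw contact events / (n_lipids × n_frames)`` summed over the
    merged replicas; the normalization denominator is recorded so replica
    merging is a denominator-weighted mean.
    """

    residues: np.ndarray
    raw: dict[str, np.ndarray]
    denom: dict[str, float]
    n_lipids: dict[str, int]
    n_frames: int

    @property
    def species(self) -> list[str]:
        return list(self.raw)

    def values(self, species: str) -> np.ndarray:
        if species not in self.raw:
            raise SelectionError(f"species {species!r} not in profile")
        return self.raw[species] / self.denom[species]

    def to_frame(self, topology: Topology | None = None) -> pd.DataFrame:
        rows = []
        names = topology.residue_names() if topology is not None else {}
        smap = topology.strand_map if topology is not None else {}
        for sp in self.raw:
            vals = self.values(sp)
            for r, raw, v in zip(self.residues, self.raw[sp], vals):
                rows.append(
                    (int(r), names.get(int(r), ""), smap.get(int(r), 0), sp, int(raw), v)
                )
        return pd.DataFrame(
            rows,
            columns=["residue_index", "residue_name", "strand", "species", "raw", "value"],
        )


def residue_lipid_contacts(
    traj: Trajectory,
    params: ContactParams = ContactParams(),
    species: Sequence[str] | None = None,
) -> ContactProfile:
    """Count contact events (min bead-pair distance < cutoff) per residue and
    lipid species, normalized to lipid number and frame count."""
    topo = traj.topology
    all_species = topo.lipid_species
    if not all_species:
        raise SelectionError("topology labels no lipid species")
    wanted = list(species) if species is not None else all_species
    missing = set(wanted) - set(all_species)
    if missing:
        raise SelectionError(f"species absent from topology: {sorted(missing)}")
    raw: dict[str, np.ndarray] = {}
    denom: dict[str, float] = {}
    n_lip: dict[str, int] = {}
    residues = None
    for sp in wanted:
        dist, res, mols = min_distance_series(traj, sp, params.lipid_selection)
        residues = res
        raw[sp] = (dist < params.contact_cutoff).sum(axis=(0, 2)).astype(np.int64)
        n_lip[sp] = len(mols)
        denom[sp] = float(len(mols) * traj.n_frames)
    assert residues is not None
    return ContactProfile(residues, raw, denom, n_lip, traj.n_frames)


def merge_replicas(profiles: Sequence[ContactProfile]) -> ContactProfile:
    """Merge replica profiles: raw counts summed, denominators summed
    (denominator-weighted mean of the normalized values)."""
    if not profiles:
        raise ValueError("nothing to merge")
    first = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.residues, first.residues) or set(p.raw) != set(first.raw):
            raise ValueError("replica topology/species mismatch")
    raw = {sp: sum(p.raw[sp] for p in profiles) for sp in first.raw}
    denom = {sp: sum(p.denom[sp] for p in profiles) for sp in first.raw}
    n_lip = dict(first.n_lipids)
    n_frames = sum(p.n_frames for p in profiles)
    return ContactProfile(first.residues.copy(), raw, denom, n_lip, n_frames)


@dataclass
class ContactIntervals:
    """Sorted disjoint half-open frame intervals per (residue, lipid molecule).

    Produced by the dual-cutoff scheme: a contact starts when the minimum
    distance drops below the lower cutoff and ends at the first frame at or
    above the upper cutoff.
    """

    intervals: dict[tuple[int, int], np.ndarray]  # (res, mol) -> (k, 2)
    residues: np.ndarray
    mol_ids: np.ndarray
    n_frames: int
    frame_interval: float  # ps
    species: str

    def pair_bool(self, residue: int, mol: int) -> np.ndarray:
        out = np.zeros(self.n_frames, dtype=bool)
        for a, b in self.intervals.get((residue, mol), ()):
            out[a:b] = True
        return out

    def residue_bool(self, residue: int) -> np.ndarray:
        """Union over lipid molecules of in-contact frames for one residue."""
        out = np.zeros(self.n_frames, dtype=bool)
        for (r, _m), iv in self.intervals.items():
            if r == residue:
                for a, b in iv:
                    out[a:b] = True
        return out

    def durations_ns(self, residues: Iterable[int] | None = None) -> np.ndarray:
        keep = set(residues) if residues is not None else None
        durs = [
            (iv[:, 1] - iv[:, 0]) * self.frame_interval / 1000.0
            for (r, _m), iv in self.intervals.items()
            if keep is None or r in keep
        ]
        return np.concatenate(durs) if durs else np.empty(0)


def _runs(mask: np.ndarray) -> np.ndarray:
    """Maximal True runs of a boolean series as (k, 2) half-open intervals."""
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return np.column_stack([starts, ends])


def contact_intervals(
    traj: Trajectory,
    params: ContactParams = ContactParams(),
    species: str | None = None,
) -> ContactIntervals:
    """Dual-cutoff binding intervals for one lipid species (the only one
    present when ``species`` is omitted)."""
    topo = traj.topology
    if species is None:
        sps = topo.lipid_species
        if len(sps) != 1:
            raise SelectionError(f"specify species; topology has {sps}")
        species = sps[0]
    dist, residues, mol_ids = min_distance_series(traj, species, params.lipid_selection)
    below_lo = dist < params.lower_cutoff
    below_hi = dist < params.upper_cutoff
    state = np.zeros(dist.shape[1:], dtype=bool)
    bound = np.empty_like(below_lo)
    for fi in range(dist.shape[0]):
        state = below_lo[fi] | (state & below_hi[fi])
        bound[fi] = state
    ivs: dict[tuple[int, int], np.ndarray] = {}
    for ri, r in enumerate(residues):
        for mi, m in enumerate(mol_ids):
            runs = _runs(bound[:, ri, mi])
            if len(runs):
                ivs[(int(r), int(m))] = runs
    return ContactIntervals(
        ivs, residues, mol_ids, traj.n_frames, traj.frame_interval, species
    )


def strand_binding_events(
    traj: Trajectory,
    params: ContactParams = ContactParams(),
    species: str | None = None,
    min_gap_frames: int = 25,
    n_strands: int | None = None,
) -> np.ndarray:
    """Count independent binding events per β-strand.

    A strand-level event is a dual-cutoff (hysteresis) contact run of one
    lipid molecule with any residue of the strand; runs separated by less
    than ``min_gap_frames`` are merged, so brief excursions do not split one
    visit into several.  Event counts are near-independent across events,
    which makes them suitable for count statistics (e.g. uniformity tests),
    unlike raw per-frame contact counts, which are strongly autocorrelated.
    """
    topo = traj.topology
    if species is None:
        sps = topo.lipid_species
        if len(sps) != 1:
            raise SelectionError(f"specify species; topology has {sps}")
        species = sps[0]
    n_strands = n_strands if n_strands is not None else topo.n_strands
    dist, residues, _mols = min_distance_series(traj, species, params.lipid_selection)
    strand_of = np.array([topo.strand_map.get(int(r), 0) for r in residues])
    events = np.zeros(n_strands)
    for s in range(1, n_strands + 1):
        sel = strand_of == s
        if not sel.any():
            continue
        d = dist[:, sel, :].min(axis=1)  # (frames, mol)
        lo, hi = d < params.lower_cutoff, d < params.upper_cutoff
        state = np.zeros(d.shape[1], dtype=bool)
        bound = np.empty_like(lo)
        for fi in range(d.shape[0]):
            state = lo[fi] | (state & hi[fi])
            bound[fi] = state
        for mi in range(d.shape[1]):
            runs = _runs(bound[:, mi])
            if len(runs) == 0:
                continue
            n_ev = 1
            for k in range(1, len(runs)):
                if runs[k, 0] - runs[k - 1, 1] >= min_gap_frames:
                    n_ev += 1
            events[s - 1] += n_ev
    return events


def residue_occupancy(intervals: ContactIntervals, n_frames: int) -> dict[int, float]:
    """Per-residue fraction of frames in dual-cutoff contact with ≥1 lipid
    (union over lipid molecules, never a sum)."""
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    per_res: dict[int, np.ndarray] = {}
    for (r, _m), iv in intervals.intervals.items():
        acc = per_res.setdefault(r, np.zeros(n_frames, dtype=bool))
        for a, b in iv:
            acc[a:b] = True
    occ = {int(r): 0.0 for r in intervals.residues}
    for r, acc in per_res.items():
        occ[int(r)] = float(acc.mean())
    return occ


@dataclass(frozen=True)
class ResidenceStats:
    """Mean binding duration and the survival-fit time constant 1/koff (ns)."""

    mean_ns: float
    tau_ns: float
    n_intervals: int
    fit_used: bool  # False when the fit degenerated to the mean


def residence_time(durations_ns: np.ndarray | Sequence[float]) -> ResidenceStats:
    """Residence time from binding-event durations.

    Reports (a) the mean duration and (b) 1/koff from an unweighted
    least-squares single-exponential fit to the log of the normalized
    survival curve over the first 90% of the duration mass.  With fewer
    than 10 events the fit degenerates to the mean (flagged).
    """
    durs = np.asarray(durations_ns, dtype=float)
    if durs.size == 0:
        raise NoIntervalsError("no binding intervals")
    mean = float(durs.mean())
    if durs.size < 10:
        return ResidenceStats(mean, mean, int(durs.size), fit_used=False)
    t = np.sort(durs)
    n = t.size
    surv = 1.0 - np.arange(n) / n  # S just below each observed duration
    q90 = np.quantile(t, 0.9)
    keep = (t <= q90) & (surv > 0)
    if keep.sum() < 2 or np.ptp(t[keep]) == 0:
        return ResidenceStats(mean, mean, n, fit_used=False)
    slope, _ = np.polyfit(t[keep], np.log(surv[keep]), 1)
    if slope >= 0:
        return ResidenceStats(mean, mean, n, fit_used=False)
    return ResidenceStats(mean, float(-1.0 / slope), n, fit_used=True)


def residue_residence_times(intervals: ContactIntervals) -> dict[int, ResidenceStats]:
    """Residence statistics per residue, pooling events over lipid molecules;
    residues with no events are omitted (no events ≠ zero residence)."""
    out: dict[int, ResidenceStats] = {}
    for r in intervals.residues:
        durs = intervals.durations_ns([int(r)])
        if durs.size:
            out[int(r)] = residence_time(durs)
    return out
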