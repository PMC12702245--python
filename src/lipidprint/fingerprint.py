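"""Occupancy-stratified residue enrichment and trajectory diagnostics.

Covers: classification of residues into high (>25% of simulation time) and
low (<5%) occupancy groups; amino-acid and chemistry-class composition of
each group; the mean end-to-end length of the LPS core polysaccharide;
lateral mean-squared displacement with a diffusion-coefficient fit; a 2D
radial distribution function; and a block-wise convergence check on the
contact profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactParams, SelectionError, residue_lipid_contacts
from .trajio import (
    BeadRecord,
    Topology,
    Trajectory,
    min_image_displacement,
)

__all__ = [
    "EnrichmentTable",
    "ConvergenceReport",
    "MSDResult",
    "PolysaccharideLength",
    "classify_residues",
    "composition_fractions",
    "enrichment_table",
    "polysaccharide_length",
    "msd",
    "rdf2d",
    "convergence",
]

CLASSES = ("positive", "negative", "aromatic", "polar", "hydrophobic")


def classify_residues(
    occupancy: dict[int, float],
    high: float = 0.25,
    low: float = 0.05,
) -> dict[str, set[int]]:
    """Split residues into high (> high), low (0 < occ < low) and neither.

    Inequalities are strict on both thresholds; residues that were never
    contacted (occ = 0) are excluded from the low group, and boundary
    equality falls into neither.
    """
    if high <= low:
        raise ValueError("need high > low")
    groups: dict[str, set[int]] = {"high": set(), "low": set(), "neither": set()}
    for r, occ in occupancy.items():
        if not 0.0 <= occ <= 1.0:
            raise ValueError(f"occupancy out of [0,1] for residue {r}: {occ}")
        if occ > high:
            groups["high"].add(r)
        elif 0.0 < occ < low:
            groups["low"].add(r)
        else:
            groups["neither"].add(r)
    return groups


@dataclass
class EnrichmentTable:
    """Residue-composition fractions per occupancy group.

    Amino-acid fractions within each group sum to 1; chemistry-class rows
    aggregate the amino-acid identities.
    """

    table: pd.DataFrame  # index: category; columns: groups
    sizes: dict[str, int]


def composition_fractions(
    group: Iterable[int],
    topology: Topology,
) -> tuple[dict[str, float], int]:
    """Per-amino-acid and per-class fraction of a residue group."""
    names = topology.residue_names()
    members = [names[r] for r in group if r in names]
    n = len(members)
    out: dict[str, float] = {}
    if n == 0:
        return out, 0
    counts = pd.Series(members).value_counts()
    for aa, c in counts.items():
        out[str(aa)] = c / n
    for cls in CLASSES:
        out[cls] = sum(
            v for aa, v in out.items() if topology.chemistry.get(aa) == cls
        )
    return out, n


def enrichment_table(
    occupancy: dict[int, float],
    topology: Topology,
    high: float = 0.25,
    low: float = 0.05,
) -> EnrichmentTable:
    groups = classify_residues(occupancy, high, low)
    cols: dict[str, dict[str, float]] = {}
    sizes: dict[str, int] = {}
    for g in ("high", "low"):
        fracs, n = composition_fractions(groups[g], topology)
        cols[g] = fracs
        sizes[g] = n
    table = pd.DataFrame(cols).fillna(0.0).sort_index()
    return EnrichmentTable(table=table, sizes=sizes)


@dataclass
class PolysaccharideLength:
    """Mean end-to-end polysaccharide length (nm) per frame, with the means
    over the first and last windows of the run."""

    per_frame: np.ndarray
    start_mean: float
    end_mean: float
    window_fraction: float


def polysaccharide_length(
    traj: Trajectory,
    first_bead: str = "S01",
    last_bead: str = "S39",
    species: str = "LPS",
    window_fraction: float = 0.1,
) -> PolysaccharideLength:
    """Per-frame minimum-image distance between the two named sugar beads,
    averaged across the species' molecules."""
    topo = traj.topology
    firsts: dict[int, int] = {}
    lasts: dict[int, int] = {}
    for i, b in enumerate(topo.beads):
        if b.species != species:
            continue
        if b.bead_name == first_bead:
            firsts[b.molecule_id] = i
        elif b.bead_name == last_bead:
            lasts[b.molecule_id] = i
    mols = sorted(firsts)
    if not mols:
        raise SelectionError(f"no {species} molecule carries bead {first_bead!r}")
    missing = [m for m in mols if m not in lasts] + [m for m in lasts if m not in firsts]
    if missing:
        raise SelectionError(
            f"molecule {missing[0]} lacks one of beads {first_bead!r}/{last_bead!r}"
        )
    ia = np.array([firsts[m] for m in mols])
    ib = np.array([lasts[m] for m in mols])
    pos = traj.positions()
    boxes = traj.boxes()[:, None, :]
    d = min_image_displacement(pos[:, ia] - pos[:, ib], boxes)
    lengths = np.sqrt((d ** 2).sum(axis=-1))  # (n_frames, n_mols)
    per_frame = lengths.mean(axis=1)
    w = max(1, int(round(window_fraction * traj.n_frames)))
    return PolysaccharideLength(
        per_frame=per_frame,
        start_mean=float(per_frame[:w].mean()),
        end_mean=float(per_frame[-w:].mean()),
        window_fraction=window_fraction,
    )


@dataclass
class MSDResult:
    """Lateral MSD(τ) with a least-squares diffusion coefficient."""

    tau_ns: np.ndarray
    msd_nm2: np.ndarray
    diffusion: float  # nm^2/ns, slope/4 over the fit window
    fit_window: tuple[float, float]


def _unwrap_xy(pos_xy: np.ndarray, boxes_xy: np.ndarray) -> np.ndarray:
    """Remove periodic jumps by accumulating minimum-image frame-to-frame
    displacements (exact while per-frame motion < box/2)."""
    steps = min_image_displacement(np.diff(pos_xy, axis=0), boxes_xy[1:, None, :])
    out = np.empty_like(pos_xy)
    out[0] = pos_xy[0]
    out[1:] = pos_xy[0] + np.cumsum(steps, axis=0)
    return out


def msd(
    traj: Trajectory,
    selection: np.ndarray | Callable[[BeadRecord], bool],
    fit_window: tuple[float, float] = (0.05, 0.4),
) -> MSDResult:
    """Lateral (xy) mean-squared displacement averaged over beads and all
    time origins (FFT algorithm), with D = slope/4 fitted over the window
    given as fractions of the maximum lag."""
    topo = traj.topology
    if callable(selection):
        mask = np.array([bool(selection(b)) for b in topo.beads], dtype=bool)
    else:
        mask = np.asarray(selection, dtype=bool)
    if mask.sum() == 0:
        raise SelectionError("empty MSD selection")
    if traj.n_frames < 10:
        raise ValueError("need at least 10 frames for an MSD")
    pos = traj.positions()[:, mask, :2]
    boxes = traj.boxes()[:, :2]
    un = _unwrap_xy(pos, boxes)  # (n_frames, n_beads, 2)
    n = un.shape[0]
    # per-bead MSD over all origins via the FFT autocorrelation identity
    sq = (un ** 2).sum(axis=2)  # (n, beads)
    fft_len = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(un, n=fft_len, axis=0)
    acf = np.fft.irfft((f * np.conj(f)).sum(axis=2), n=fft_len, axis=0)[:n].real
    sumsq = sq.sum(axis=0)
    cum_head = np.concatenate([np.zeros((1, sq.shape[1])), np.cumsum(sq, axis=0)])
    s1 = np.empty_like(acf)
    for m in range(n):
        # sum of |r_k|^2 + |r_{k+m}|^2 over valid origins
        s1[m] = 2 * sumsq - cum_head[m] - (cum_head[n] - cum_head[n - m])
    counts = (n - np.arange(n))[:, None]
    msd_per_bead = (s1 - 2 * acf) / counts
    curve = msd_per_bead.mean(axis=1)
    curve[0] = 0.0  # exact by definition
    tau = np.arange(n) * traj.frame_interval / 1000.0  # ns
    lo = max(1, int(fit_window[0] * (n - 1)))
    hi = max(lo + 2, int(fit_window[1] * (n - 1)))
    slope, _ = np.polyfit(tau[lo:hi], curve[lo:hi], 1)
    return MSDResult(tau, curve, float(slope / 4.0), fit_window)


def rdf2d(
    traj: Trajectory,
    selection_a: np.ndarray,
    selection_b: np.ndarray | None = None,
    bin_width: float = 0.1,
    r_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """2D radial distribution function g(r) in the membrane plane.

    Normalized by the ideal-gas annulus count at the observed areal density;
    self-pairs are excluded when the two selections coincide.  Returns
    (bin centres, g).
    """
    mask_a = np.asarray(selection_a, dtype=bool)
    mask_b = np.asarray(selection_b, dtype=bool) if selection_b is not None else mask_a
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise SelectionError("empty RDF selection")
    box = traj.frames[0].box
    half = min(box[0], box[1]) / 2.0
    if r_max is None:
        r_max = half
    if r_max > half + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half the box ({half})")
    same = np.array_equal(mask_a, mask_b)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    area = box[0] * box[1]
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    for frame in traj.frames:
        pa = frame.positions[mask_a, :2]
        pb = frame.positions[mask_b, :2]
        d = min_image_displacement(pa[:, None, :] - pb[None, :, :], np.asarray(frame.box[:2]))
        r = np.sqrt((d ** 2).sum(axis=-1))
        if same:
            iu = np.triu_indices(n_a, k=1)
            r = r[iu]
        else:
            r = r.ravel()
        h, _ = np.histogram(r, bins=edges)
        hist += h
    shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    if same:
        pairs_density = n_a * (n_a - 1) / 2.0 / area
    else:
        pairs_density = n_a * n_b / area
    ideal = pairs_density * shell * traj.n_frames
    centres = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, hist / ideal, 0.0)
    return centres, g


@dataclass
class ConvergenceReport:
    """Block-wise similarity of contact profiles.

    The convergence metric — Pearson correlation of per-residue contact
    profiles between time blocks, converged when the final consecutive pair
    reaches the threshold — is an implementation-defined criterion of this
    package, not a community standard.
    """

    n_blocks: int
    consecutive_r: list[float]  # r between block i and i+1 (nan if degenerate)
    vs_final_r: list[float]  # r between block i and the last block
    threshold: float
    converged: bool
    note: str = (
        "Convergence criterion: Pearson r of block-wise contact profiles; "
        "implementation-defined."
    )


def _block_profiles(
    traj: Trajectory, params: ContactParams, species: str, n_blocks: int
) -> list[np.ndarray]:
    bounds = np.linspace(0, traj.n_frames, n_blocks + 1).astype(int)
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        sub = Trajectory(
            traj.topology, traj.frames[a:b], frame_interval=traj.frame_interval
        )
        prof = residue_lipid_contacts(sub, params, species=[species])
        out.append(prof.values(species))
    return out


def _safe_r(a: np.ndarray, b: np.ndarray) -> float:
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def convergence(
    traj: Trajectory,
    params: ContactParams = ContactParams(),
    species: str | None = None,
    n_blocks: int = 4,
    threshold: float = 0.9,
) -> ConvergenceReport:
    """Split the run into time blocks, compute the contact profile per block
    and report Pearson correlations between consecutive blocks and against
    the final block."""
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if species is None:
        sps = traj.topology.lipid_species
        if len(sps) != 1:
            raise SelectionError(f"specify species; topology has {sps}")
        species = sps[0]
    profs = _block_profiles(traj, params, species, n_blocks)
    consecutive = [_safe_r(profs[i], profs[i + 1]) for i in range(n_blocks - 1)]
    vs_final = [_safe_r(profs[i], profs[-1]) for i in range(n_blocks - 1)]
    last = consecutive[-1]
    return ConvergenceReport(
        n_blocks=n_blocks,
        consecutive_r=consecutive,
        vs_final_r=vs_final,
        threshold=threshold,
        converged=bool(not np.isnan(last) and last >= threshold),
    )
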