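# Methods

`lipidprint` implements the analysis stack used to locate lipopolysaccharide
(LPS) binding sites on a β-barrel outer-membrane protein from coarse-grained
membrane trajectories, together with a synthetic trajectory generator that
plants binding sites with known ground truth.  This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Contact model

A *contact event* is a (frame, protein residue, lipid molecule) triple in
which the minimum-image distance between any selected bead of the lipid and
any bead of the residue falls below the contact cutoff (default 0.55 nm).
The event is counted once no matter how many bead pairs are inside the
cutoff, mirroring group-wise minimum-distance semantics.  The contact
profile normalizes the summed events by (number of lipids of that species ×
number of frames), so its values are directly comparable across species and
trajectory lengths, and replica merging is a denominator-weighted mean.
A phosphate-only bead selection is available and is the default framing for
site detection, since the phosphates sit at the membrane interface where the
discriminating contacts form.

Binding *events* use a separate dual-cutoff (hysteresis) scheme: a contact
opens when the pair distance drops below 0.475 nm and closes at the first
frame at or above 0.8 nm.  Hysteresis absorbs the rapid cutoff-crossing
flicker that a single threshold would fragment into many spurious events.
Occupancy is the fraction of frames a residue (or site) spends in
dual-cutoff contact with *at least one* lipid — a union over lipid
molecules, never a sum, so two lipids alternating at one site yield
occupancy 1.0, not 2.0.

Residence times are reported two ways: the mean event duration, and 1/koff
from an unweighted least-squares line through the log of the empirical
survival curve over the first 90% of the duration mass.  The two agree for
exponential kinetics; both are reported so the estimator choice is never
hidden.  With fewer than 10 events the fit is meaningless and degenerates,
flagged, to the mean.

## Site detection

Per-residue contact values are screened for peaks at least 2σ above the
mean of the *non-zero* background, where μ and σ are computed in a single
pass over all non-zero values, prospective peaks included; no iterative
re-estimation is done, so the procedure is deterministic and reproducible.
A uniform non-zero profile (σ = 0) yields no peaks by definition; fewer
than three non-zero values is treated as an error rather than a silent
empty result.  Peak residues are clustered into sites by connected
components of the "same or adjacent β-strand" relation, with adjacency
circular so that the β-seam (strand 22 next to strand 1) forms one site.
Peaks on residues outside the strand map (extracellular loops) survive as
flagged singleton sites.

Site occupancy combines all poses at a site: the union over site residues
and lipid molecules of in-contact frames.  The representative pose is the
(frame, lipid) pair with the most site residues simultaneously in contact,
ties broken to the earliest frame then the lowest molecule id — a
deterministic, oracle-checkable rule chosen in preference to density-based
pose clustering.  Detected sites are matched to externally labelled strand
ranges (e.g. "β11-13", wraparound "β21-β1") by greedy one-to-one matching
on strand-set intersection, largest intersection first.

2D density maps are plain histograms of selected bead xy positions over a
frame window (default the second half of the run), computed after rigid-body
alignment of every frame onto the protein backbone (Kabsch).  Full 3D
alignment is used; for a barrel fixed in a planar membrane this reduces in
practice to in-plane rotation.  Counts are conserved exactly: the map total
equals selected beads × frames used.

## Enrichment and diagnostics

Occupancy bands follow strict inequalities: high is occupancy > 0.25, low is
0 < occupancy < 0.05.  Residues never contacted are excluded from "low"
(absence of data is not weak binding), and boundary equality falls in
neither band.  Group composition is reported per amino-acid identity and
aggregated into five chemistry classes (positive: Arg/Lys/His, negative:
Asp/Glu, aromatic: Phe/Tyr/Trp, polar: Ser/Thr/Asn/Gln/Cys, hydrophobic:
the rest); within-group fractions sum to one.

Lateral MSD uses coordinates unwrapped by accumulating minimum-image
frame-to-frame displacements (exact while per-frame motion stays below half
the box, which the generator's step sizes guarantee), averaged over all time
origins via the FFT autocorrelation identity.  D is slope/4 over a
configurable lag window (default 5–40% of the maximum lag, inside the linear
regime but away from the noisy long-lag tail).  The 2D radial distribution
function normalizes pair counts by the ideal-gas annulus expectation at the
observed areal density, excluding self-pairs.

Convergence is assessed as the Pearson correlation of per-residue contact
profiles between consecutive time blocks (default 4 blocks), converged when
the final pair reaches r ≥ 0.9.  This block-correlation criterion is
implementation-defined — it is a reasonable stationarity check, not a
community standard — and the report says so explicitly.  All-zero block
profiles make r undefined; they are reported as NaN, never coerced.

## Synthetic generator

The generator builds what the analyses need and nothing more: a 22-strand
barrel scaffold (one backbone and one outward sidechain bead per residue) in
an asymmetric bilayer, with lipid species realized *exactly* from ratio
specifications (1:3 LPS:DMPE outer, 80:15:5 DMPE:DMPG:cardiolipin inner) by
largest-remainder rounding.  The sparse-LPS mode swaps the 3 phospholipids
nearest each of 10 equally spaced ring points for one LPS each, reproducing
the placement protocol of the study system.  Ion counts follow
concentration × N_A × volume (0.1 M NaCl, 0.025 M CaCl₂) plus exact
counter-ion neutralization against nominal molecular charges (DMPG −1,
cardiolipin −2, LPS −6, Arg/Lys +1, Asp/Glu −1).  An elastic-network builder
lists backbone bead pairs within 0.7 nm (excluding sequence neighbours) at
1000 kJ/mol/nm².

Dynamics are overdamped 2D Langevin: per lipid and substep,
Δr = F·D·Δt + √(2DΔt)·η, with the potential (in kT) a sum of planted
Gaussian wells, −ε·exp(−|r−c|²/2w²), and a soft half-harmonic wall
(10 kT/nm²) at the protein footprint.  Well centres sit 0.3 nm beyond the
barrel surface in the direction of the anchor strands' backbone centroid, so
contacts form at the lipid–protein interface.  Wells act only on their
species (default LPS) in their leaflet: they model LPS-specific binding
sites, and letting every phospholipid fall in would model nothing in the
study.  Lipid bead stacks translate rigidly; the LPS core-polysaccharide
end bead (S39) is redrawn each frame from a collapse model — a clipped
normal whose mean holds at 2.6 nm for the first 10% of the run, decays
linearly, and holds at 1.5 nm for the last 10% — giving the length analysis
a known schedule to recover.

Numerics: the internal step is 0.05 ns with frames written every 200 ps.
The step is set by wall stiffness — the explicit Euler update is stable for
k·D·Δt ≤ 0.5, and 0.05 ns leaves that margin at k = 10 kT/nm², D = 1 nm²/ns;
a displacement exceeding half the box in one substep raises a stability
error rather than wrapping silently.  Reproducibility comes from per-
molecule random substreams spawned from the single spec seed by stable
spawn keys, so results do not depend on iteration order.  Identical spec
and seed give bit-identical trajectories and byte-identical TSV reports.

Default geometry (all configurable): box 14 × 14 × 10 nm, barrel radius
2.4 nm (strand spacing 0.69 nm for 22 strands), 8 residues per strand at
0.35 nm rise, phosphate plane 1.0 nm from the bilayer midplane, protein
wall at barrel radius + 0.5 nm, area per lipid 0.6 nm², lateral diffusion
1.0 nm²/ns (cardiolipin 0.8).  These diffusion coefficients are one to two
orders of magnitude faster than real coarse-grained LPS dynamics — a
deliberate choice: with realistic LPS mobility an 8 kT site exchanges
lipids roughly once per microsecond of simulated time, well populations
stay frozen at their initial capture counts, and no analysis could
distinguish binding preference from capture history at desk scale.  Scaling
D up compresses the same binding/unbinding statistics into runs of a few
thousand frames.  The generator therefore reproduces the *statistical
structure* the analyses assume — slow-relative-to-frame-rate 2D diffusion,
localized reversible binding, leaflet asymmetry, sugar-chain collapse — and
explicitly not the force-field physics (no thermostat/barostat, no
lipid–lipid interactions or excluded volume between lipids, no flip-flop,
no explicit water, no protein flexibility).

## What the synthetic validation shows — and does not

Passing tests demonstrate that the analysis stack recovers planted ground
truth: three 8 kT wells are recovered exactly (one detected site per well,
no extras) in ≥18 of 20 seeds at 5000 frames; measured region occupancy of
a shallow (2 kT) well matches its Boltzmann prediction within ±0.05 — the
shallow depth matters, since an 8 kT well does not equilibrate within 5000
frames and a finite run cannot be asked to reproduce its equilibrium
occupancy; MSD recovers the input D within 10%; the survival fit recovers
1/koff of exponentially distributed durations within 15%; and the
polysaccharide analysis recovers the 2.6 → 1.5 nm collapse schedule within
±0.05 nm.  Null (well-free) runs are calibrated: per-strand binding-event
counts are χ²-consistent with uniform, and the 2σ detector reports
essentially no spurious sites (at most 1 across 20 seeds).  Uniformity is
tested on *binding events* (hysteresis contact runs merged across gaps
shorter than 5 ns) rather than raw per-frame counts, because one wall visit
contributes dozens of autocorrelated frame counts and a χ² on raw counts
would reject uniformity for any finite-diffusivity trajectory regardless of
isotropy.

None of this shows that the pipeline performs equally on real Martini
trajectories: real LPS binds with many-bead poses, background contacts are
richer (loops, annular lipids), site strengths are heterogeneous, and
convergence is far slower.  What the synthetic results do establish is that
each estimator is a faithful implementation of its definition and that the
detection chain has a calibrated false-positive rate under its own null.

## Known limitations

- Lipids are mutually non-interacting points in the plane; clustering in
  null runs arises only from planted attractions, so the RDF diagnostic is
  validated on constructed fixtures, not emergent aggregation.
- The 2σ detector inherits the weakness of its definition: when one site is
  much stronger than another, the strong site inflates the background σ and
  can mask the weak one.  The generator's equilibrating diffusion keeps
  planted wells comparable; on real data the merged multi-replica profile
  plays that role.
- GRO is the only trajectory format written; XTC reading, when available
  through an installed reader, is intentionally not byte-reproducible.
- Orthorhombic boxes only, by design: a triclinic box line is an error, not
  a warning.
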