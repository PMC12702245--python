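# lipidprint

Lipid–protein interaction fingerprinting for coarse-grained membrane
simulations: per-residue contact profiles, dual-cutoff occupancy and
residence times, 2D leaflet density maps, binding-site detection and
clustering on a β-barrel scaffold, and comparison of detected sites against
externally labelled strand ranges.  A synthetic trajectory generator with
*planted* binding sites makes the whole stack testable as a
parameter-recovery problem — no downloads, no production MD required.

The package is aimed at people analysing coarse-grained trajectories of
outer-membrane proteins (OMPs) in asymmetric lipopolysaccharide (LPS)
containing bilayers, and at anyone who wants a self-validating reference
implementation of the standard lipid-fingerprinting recipes.

## The analyses

- **Contacts** — a residue–lipid contact is a frame in which the minimum
  bead-pair distance falls below 0.55 nm; profiles are normalized per lipid
  and per frame, `value = events / (n_lipids × n_frames)`, and replicas
  merge as denominator-weighted means.
- **Occupancy / residence** — binding events use a dual-cutoff scheme
  (open below 0.475 nm, close at 0.8 nm); occupancy is the fraction of
  frames a residue or site is bound by ≥1 lipid (a union, so poses
  combine); residence time reports both the mean event duration and 1/k_off
  from a log-survival fit.
- **Sites** — residues whose contact value is ≥2σ above the mean of the
  non-zero background are peaks; peaks on the same or adjacent β-strands
  (circularly, so the β-seam strands 22/1 join) cluster into sites.
- **Fingerprint** — residues stratified into high (>25% of simulation
  time) and low (<5%) occupancy groups and summarized by amino-acid and
  chemistry-class composition; plus lateral MSD with a D fit, a 2D RDF and
  a block-correlation convergence check.
- **Synthetic generator** — a 22-strand barrel in an asymmetric bilayer
  (1:3 LPS:DMPE outer leaflet, 80:15:5 DMPE:DMPG:cardiolipin inner), a
  sparse ring of 10 LPS each replacing 3 phospholipids, ions at 0.1 M NaCl
  + 0.025 M CaCl₂, an elastic-network builder (1000 kJ/mol/nm², 0.7 nm),
  and seeded overdamped Langevin dynamics with Gaussian binding wells
  `U = −ε·exp(−|r−c|²/2w²)` planted at chosen strands.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

Build a sparse-ring system with one 8 kT well planted at strands β1–3,
simulate 2000 frames (200 ps apart) and run the full pipeline:

```python
from lipidprint import synthgen as sg, contacts as ct, sites

spec = sg.SyntheticSpec(wells=[sg.PlantedWell((1, 2, 3), depth=8.0, width=1.0)],
                        n_frames=2000, seed=1)
topo, frame0 = sg.build_system(spec)
traj = sg.simulate(topo, frame0, spec)

prof = ct.residue_lipid_contacts(
    traj, ct.ContactParams(lipid_selection=("phosphate",)), species=["LPS"])
peaks = sites.detect_peaks(prof, "LPS")
found = sites.cluster_sites(peaks, topo.strand_map, topo.n_strands, prof, "LPS")
iv = ct.contact_intervals(traj, species="LPS")
for s in found:
    occ = sites.site_occupancy(s, iv, traj.n_frames)
    print(f"site {s.site_id}: strands {sorted(s.strands)} "
          f"peak {s.peak_value:.3f} occupancy {occ:.2f}")
```

prints

```
site 1: strands [2] peak 0.526 occupancy 1.00
```

The one detected site sits on strand β2 — the centre of the planted β1–3
well — with a per-lipid contact rate of 0.526 at its peak residue and full
occupancy: some LPS molecule is bound at essentially every frame, as
expected for an 8 kT well.  Distal strands stay below 5% occupancy.

The same pipeline is scriptable from the shell:

```sh
lipidprint run --config pipeline.yaml --seed 42
```

which writes `contact_profile.tsv`, `occupancy.tsv`, `density_map.tsv`,
`sites.tsv`, `enrichment.tsv`, `msd.tsv`, `rdf.tsv`, `convergence.tsv`, a
`manifest.json` recording every parameter and seed, and a log.  Identical
config + seed reproduces every TSV byte for byte.

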