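# Methods

This note documents the models and numerical choices behind `obpdyn`: what
each descriptor computes, what the synthetic generator emulates, and the
decisions taken where a convention had to be fixed.

## Superposition, RMSD and RMSF

Rigid-body fits use the Kabsch/SVD solution on centred coordinates with a
determinant correction so only proper rotations are returned; inputs with
fewer than three atoms or a rank-deficient covariance raise a degenerate-fit
error.  Fits are unweighted by default (mass weighting is available but
off), and the RMSD fitting set defaults to the backbone atoms N, CA, C, O.

RMSF is measured at one atom per residue (Cα) against the *iterated mean
structure*: frames are fitted to frame 0 and averaged, then re-fitted to
that average and re-averaged (one refinement pass).  This removes rigid-body
drift without preferring any single frame.  Terminal segments can be
excluded simply by passing a smaller selection; nothing is dropped
implicitly.

Correctness is anchored to an independent rotational oracle: an Euler-angle
grid search refined to 0.1° must reproduce the SVD RMSD within 1e-3 Å on
small point sets.

## Geometric descriptors

* Region centres are arithmetic means of Cα coordinates; the radius of
  gyration is the root-mean-square distance of a backbone selection from its
  geometric centre.  Rg is cross-checked in the tests against the
  independent identity Rg² = (mean squared pairwise distance)/2.
* Entrance geometry: per frame, the cavity centre C_total and each
  entrance-component centre C_each are computed and their Euclidean
  distances reported, together with each component's distance to the
  *entrance centre*, defined as the mean of the four component centres.
  Since no canonical cavity residue list exists, the cavity set defaults to
  the union of the four entrance components, and C_total is recomputed per
  frame (a fixed-reference-frame option exists).  Default regions for the
  119-residue system: N-ter 3–14, α2 28–35, α4–α5 67–89, C-ter 111–119.
* Windowed distributions split a series into contiguous equal blocks
  (remainder to the last block) and histogram each block on a shared grid of
  0.25 Å bins spanning the series range, normalised to unit mass per window.
  Smoothing, when wanted for plots, is a cosmetic kernel density — never
  used in statistics.
* The disulfide plane is defined by the three S–S bond midpoints; the
  per-frame angle between its normal and the reference-frame normal is
  folded to [0°, 90°] via the absolute dot product because the orientation
  sign of a plane is arbitrary.  Collinear midpoints raise an error.

## Hydrogen bonds

The geometric criterion is donor–acceptor heavy-atom distance ≤ 3.0 Å and a
D–H···A angle within 20° of linear, choosing the best hydrogen on the
donor.  The "3.0 Å / 20°" cutoff pair is conventionally quoted without
saying which distance the 3.0 Å refers to; we apply it to the donor–acceptor
distance by default and provide a hydrogen–acceptor option.  Pairs within
the same residue or within two covalent bonds (1-2/1-3 neighbours, inferred
from interatomic distances) are excluded.

Crystal structures usually lack hydrogens.  In hydrogen-free mode, donors
are typed by residue chemistry (backbone N except proline; Ser/Thr/Tyr
hydroxyls; Lys/Arg/His/Trp/Asn/Gln side-chain nitrogens; Asp/Glu oxygens
only when the residue is marked protonated in an explicit per-residue map —
pKa prediction is out of scope) and the angle test is replaced by the
X–D···A ≥ 90° antecedent proxy, with records flagged approximate.  Terminal
oxygens named OT1/OT2/OXT are recognised as acceptors.

Occupancy is the percentage of frames a specific donor-atom/acceptor-atom
pair is bonded; the residue-level network keeps, for each residue pair, the
maximum-occupancy edge at or above a threshold.  Detection is validated
frame-by-frame against an all-pairs brute-force oracle.

## Secondary structure

The Kabsch–Sander electrostatic energy decides backbone H-bonds
(E < −0.5 kcal/mol); amide hydrogens are reconstructed 1.01 Å from N
anti-parallel to the preceding C=O when absent.  Helix (H) requires two
consecutive i+4→i turns; strand (E) requires a parallel or antiparallel
bridge pattern with both chain neighbours of each partner present (without
this neighbour guard, terminal residues acquire spurious bridges).  Output
is deliberately 3-state — H/E/C with priority H > E — because the supported
analyses only distinguish helix, sheet and loop.  Isolated bridges (DSSP
"B") map to E and 3-10/π helices to H.  Ideal helix and two-strand sheet
fixtures must agree with an independent DSSP implementation (mdtraj) on at
least 95% of residues; in practice agreement on both fixtures is 100%.

Note that a DSSP-style assignment can never label the first and last
residues of a helix fixture H (the defining turns need flanking residues),
so short ideal helices top out below 100% H; the 25-residue fixture used in
the tests reaches 92%.

## Free-energy combiner

Per window, ΔG = −kT ln⟨exp(−ΔU/kT)⟩ with kB = 0.0019872041 kcal/(mol·K),
evaluated by log-sum-exp so far-negative ΔU samples cannot overflow; window
estimates sum along a leg and the cycle closes as ΔΔG_bind = ΔG_complex −
ΔG_free, negative meaning binding is preferred in the perturbed (low-pH)
state.  Exponential averaging was chosen over BAR/MBAR for transparency and
because it admits the exact Gaussian check ΔG = μ − σ²/(2kT); per-window ΔU
histograms are exposed as an overlap diagnostic.  The text reader accepts
plain `λ_from λ_to ΔU` columns and NAMD fepout-style lines.

## Synthetic generator

The generator is the ground-truth side of every test:

* **Reference structure** — a 119-residue chain built from ideal peptide
  geometry (NeRF internal-coordinate construction), with six α-helical
  segments (torsions −57°/−47°), polyproline-II-like linkers, full backbone
  plus amide H, and three disulfide bridges whose SG pairs straddle their
  CB–CB midpoints, guaranteeing three non-collinear S–S midpoints.  It is an
  idealized topological stand-in for a compact helical OBP, not a physical
  model: helices are not packed into a bundle and side chains beyond the
  cysteine CB/SG are absent.
* **Dynamics** — per-atom, per-coordinate AR(1) noise
  d_t = ρ d_{t-1} + σ√(1−ρ²) ε_t started from the stationary distribution,
  ρ = 0.9 per step by default.  The stationary per-coordinate sd is exactly
  the region σ, so per-residue RMSF has the analytic value σ√3 and the
  effective sample size is n(1−ρ)/(1+ρ); tolerances in the recovery tests
  follow from this.  Time correlation is the one MD-like feature kept;
  anharmonicity, coupled modes and solvent effects are not modelled, so
  passing tests demonstrate estimator correctness, not force-field realism.
* **Scheduled H-bonds** — selected backbone N→O pairs are clamped to bonded
  geometry (2.9 Å, linear D–H···A) in Bernoulli(p) frames and pushed to
  4.5 Å otherwise.  The clamp is geometric, not energetic, and moves the
  acceptor oxygen to the donor's neighbourhood regardless of the reference
  separation; this inflates global RMSD/Rg relative to a real protein but
  leaves every tested contrast and recovery intact.
* **Presets** — "low_pH": uniform σ = 0.4 Å and high scheduled occupancies
  (50.6%, 19.3%, 22.4%, 8.4%, 12.2%, 16.7%, the occupancy pattern of a
  low-pH OBP condition); "neutral_pH": σ = 0.5 Å with the α2, α4–α5 and
  C-ter regions doubled to 1.0 Å and occupancies collapsed (≤ 17%).  These
  two configurations encode the qualitative low-vs-neutral pH contrast —
  a more compact, bonded, rigid protein at low pH — as testable structure.
  Default trajectory length is 2,000 frames at dt = 0.1 ps, the package's
  own down-sampled stand-in for production-scale MD output.
* **FEP samples** — Gaussian ΔU windows with the closed form
  ΔG = μ − σ²/(2kT); the −3.47 kcal/mol recovery target is built by placing
  the two legs' analytic values at −2.00 and +1.47 kcal/mol.

All randomness flows through a single integer-seeded `numpy` generator;
identical configurations produce identical trajectories on any platform.

## File formats

PDB reading is fixed-column (ATOM/HETATM/MODEL/ENDMDL), keeps altloc ' '/'A'
only, takes author residue numbering verbatim, and treats multi-model files
as a trajectory fallback.  The DCD reader handles little- and big-endian
files and the 8-byte Fortran-marker dialect (disambiguated by the position
of the 'CORD' magic), skips unit-cell blocks, and reports the number of
complete frames when a file is truncated.  Round-trip precision is the
format's own: 3 decimals for PDB, float32 for DCD.  The writer exists mainly
so tests and the generator can produce both endiannesses; MDAnalysis serves
as the independent read-back oracle in the test suite.

## Pipeline

`run_analysis` wipes and rebuilds its output directory, writes one TSV per
descriptor per replicate plus a manifest (config digest, inputs, version),
and averages replicates per-frame when frame counts align, else per-summary.
Categorical timelines (secondary structure) are averaged as per-residue
state fractions.  Any stage failure removes partial outputs and names the
stage.  All acceptance-grade checks target the TSV tables; plots are
advisory.

## Known limitations

* The hydrogen-free donor/acceptor typing covers standard amino acids only.
* The secondary-structure module does not emit turn/bend codes or
  discriminate 3-10/π helices, and solvent accessibility is out of scope.
* The generator's regions move independently; correlated inter-region
  motions (the interesting biology) are present only through the scheduled
  H-bond clamps.
* FEP input is trusted as given: no soft-core handling, no hysteresis
  correction, and the only overlap diagnostic is the per-window histogram.
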