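# Methods

This note records the scientific model behind each stage, the parameters
that matter, the numerical choices made where the design was open, and
what the synthetic validation does and does not establish.

## Trajectory preparation

Internally all coordinates are nanometres (PDB/DCD writers convert to Å).
Frames are ordered replica by replica; `concat_equilibrated` drops a
per-replica equilibration prefix, specified in frames because the mapping
from simulated time to frames depends on the output cadence of the
upstream simulation.

Alignment is a two-pass least-squares superposition (Kabsch): fit all
frames to frame 0 over the fit selection, average the fit atoms, then fit
the original frames onto that mean.  When the system contains
position-restrained chains, the pipeline fits on those chains instead of
on the analysis nodes: the restrained blocks are the static scaffold, and
fitting on mobile nodes would subtract their centre of motion each frame,
which demonstrably biases displacement correlations downward.  Restrained
chains are excluded from network nodes but are legitimate alignment
anchors.

## Conformational descriptors

RMSD series are computed after per-frame superposition over the same
selection.  Frame clustering is agglomerative (scipy linkage) on the
matrix of pairwise fitted RMSDs, cut at 0.15 nm by default.  The linkage
criterion is configurable (`cluster.linkage`, default `average`, the
least cutoff-sensitive of the common criteria) and frames may be strided
(`cluster.stride`) because the pairwise matrix is O(F²); a `max_frames`
guard (default 4000) fails loudly rather than exhausting memory.  Labels
are renumbered contiguously from 1 in order of first appearance.

## Contacts and typed interactions

A residue pair is in contact in a frame when any heavy-atom pair is within
`contacts.cutoff_nm` (default 0.45 nm, the conventional heavy-atom
criterion).  Reported quantities: per-pair frequencies, per-residue
marginals (contact with any partner), and signed per-residue differences
between systems (absent residues count 0, so the map is antisymmetric by
construction).

Interaction typing follows common geometric-profiler conventions, all
configurable: salt bridge = charged-group centroid distance ≤ 0.55 nm
between Lys/Arg (His if flagged protonated) side-chain nitrogens and
Asp/Glu carboxylates or nucleotide phosphates; hydrogen bond =
donor–acceptor N/O heavy-atom distance ≤ 0.35 nm, with a D–H···A angle
≥ 130° enforced only when the topology contains hydrogens (the output
flags distance-only records); hydrophobic = side-chain carbon pair of
apolar residues ≤ 0.40 nm.  Unknown residue names are skipped with a
warning.  The stability filter keeps interactions whose mean frequency
across systems is *strictly* greater than 0.75, with missing systems
counted as zero.

## Dynamical network

Nodes: one representative atom per residue of every non-restrained chain
(Cα; ligands via a residue-name → atom-name map, on by default so
nucleotides participate — a flag disables them).  Edges are gated by
persistent contact (cutoff 0.45 nm in ≥ 75 % of frames, the conventions of
the standard dynamical-network toolchain) and never connect sequence
neighbours (i, i±1 within a chain), which would otherwise dominate paths
through trivial backbone correlation.

Weights are generalized correlation coefficients
r = sqrt(1 − exp(−2I/3)) from the Kraskov (KSG-1) k-NN mutual-information
estimator on the 3-D displacement vectors, k = 5 (configurable).  Exact
coordinate ties are broken by a deterministic, seeded jitter ten orders of
magnitude below the signal.  Two numerical choices matter:

- **Significance floor.**  Near independence the square root amplifies
  estimator noise (r ≈ sqrt(2I/3)), so a raw KSG estimate of a few
  millinats maps to r ≈ 0.1.  The package calibrates the estimator's
  independence null once per (frame count, k) — 16 independent Gaussian
  replicates — and maps any MI below mean + 4·std of that null to exactly
  0.  Consequence: true correlations below roughly 0.15 are reported as 0;
  for contact-gated residue networks, where edges carry substantial
  correlation, this is the right trade.
- **Zero-variance series** (fully restrained residues) are defined as
  r = 0 with a warning rather than an error.

Optimal paths minimize summed −log w, i.e. maximize the product of edge
correlations.  A sum of raw correlations is not a usable objective —
longer paths accumulate larger sums — so the package adopts the product
convention of the standard dynamical-network formulation.  Path counting
uses Dijkstra plus Brandes-style accumulation on the shortest-path DAG
with float ties resolved at relative tolerance 1e-9, so families of
equal-length paths split σ(s,t) exactly; the test suite verifies exact
agreement with exhaustive simple-path enumeration on random graphs and
with networkx on tie-free graphs.  Normalization is multiplicative:
b = [2/((n−1)(n−2))]·Σ σ(s,t|i)/σ(s,t) for nodes and 2/(n(n−1)) for
edges, placing both in [0, 1].  Zero-weight edges (infinite length) are
excluded from path analysis and logged.

The knee of the descending ranked edge-betweenness curve is the point of
maximum perpendicular distance from the chord joining the first and last
points; an exactly linear curve returns the last value with a warning.
Across systems the minimum knee is the shared threshold, and `top_edges`
reports edges strictly above it with chain-interface annotations.

## Rigidity profiles

d_i(t) is the mean distance of node i to all other included nodes (no
sequence-neighbour exclusion by default; a window is configurable since
variants of the method differ).  k_i = 3·k_B·T / Var(d_i), with
k_B = 0.0083144621 kJ·mol⁻¹·K⁻¹ and T = 300 K by default.  Zero-variance
nodes are flagged infinite and excluded from rankings.  Multi-system runs
report the mean and min–max envelope per residue.

One convention is worth stating precisely: the 3·k_B·T numerator refers to
the *scalar* mean-distance coordinate.  For the synthetic benchmark — an
isotropic harmonic probe (per-axis Boltzmann variance k_B·T/k) read
against a one-sided static anchor cloud, where the mean-distance gradient
is a unit vector — Var(d) = k_B·T/k and the profile therefore reads 3k
for a well of constant k.  The validation compares the profile against
this analytic Boltzmann oracle (and checks exact linearity in T and the
closed form on engineered variances); relative rigidity across residues,
which is what the profile is used for, is unaffected by the factor.

## Conservation

Columns are scored after mapping residues onto six stereochemical classes
(aliphatic AVLIMC, aromatic FWYH, polar STNQ, basic KR, acidic DE, special
GP); NE = −Σ p_c ln p_c / ln 6.  Gaps are excluded from the counts rather
than treated as a seventh class (Valdar-style practice); columns that are
all gaps are NaN-flagged, columns above 50 % gaps are flagged unreliable,
and ambiguity codes (B, Z, X, …) are dropped with a warning.  Structure
annotation writes NE × 100 into the PDB B-factor column (two decimals);
residues whose name disagrees with the reference sequence get a −1
sentinel and are counted.  Sequence weighting (Henikoff) is deliberately
out of scope.

## Synthetic systems

The generators define the study conditions; their statistics are analytic.

- **Correlated ensembles**: single-bead residues whose per-axis
  displacements are multivariate normal with a user correlation matrix
  (eigen-decomposition sampling; PSD verified at 1e-10 eigenvalue
  tolerance, non-PSD designs rejected with a diagnostic).
- **Toy sheets**: an n_rows × n_cols grid of monomer blocks (rows are
  protofilament analogs), one chain per block, five beads per block
  (centre + four arms pointing at the lattice neighbours), 1 nm lattice
  spacing.  Couplings (longitudinal 0.9, lateral 0.7, seam 0.2 by
  default) are relative spring constants of a harmonic displacement
  network over the blocks; the implied correlation matrix is the
  diagonal-normalized inverse of the grounded graph Laplacian (restrained
  corner blocks act as rigid anchors; without restraints the translation
  zero mode is projected out).  This equilibrium-Gaussian construction is
  PSD by construction, keeps neighbour correlations rank-ordered by bond
  stiffness, and gives the weak seam column a genuinely lower lateral
  correlation rather than one explained away by detours.  Blocks move as
  rigid units plus independent per-bead jitter (σ/10) so bead-level and
  block-level correlations agree; per-axis amplitude σ = 0.05 nm; beads
  carry step-2 residue numbers so no intra-block pair is mistaken for a
  covalent neighbour.  Facing arms of adjacent blocks rest 0.20 nm apart
  (firmly inside the contact cutoff); across weak lateral interfaces the
  gap widens to 0.395 nm, placing the contact frequency near 0.8 — above
  the 0.75 network gate yet visibly depressed in difference maps.
- **Harmonic probes**: one bead Boltzmann-sampled from an isotropic well
  (per-axis variance k_B·T/k) plus a fixed 20-bead anchor cloud 5 nm away
  along +x, giving the mean-distance coordinate unit gradient (see
  Rigidity above).
- **Two-state ensembles**: a + − − + internal deformation pattern along z
  whose zeroth and first moments vanish, so superposition cannot hide the
  0.5 nm conformational change; per-state jitter 0.02 nm.
- **Toy MSAs**: per-column categorical sampling from target compositions
  with optional gap fractions.

All generators are bitwise deterministic for a fixed seed.

### What the synthetic validation shows — and does not

Passing tests establish that every estimator recovers the statistics the
generators encode (Gaussian correlations, Boltzmann variances, designed
contact fractions, class compositions) and that the pipeline's qualitative
seam phenotype — communication pathways avoiding the weak lateral column,
contact loss localized to it — follows from a weak-coupling design.  The
generators do not emulate anharmonicity, solvent, autocorrelated dynamics
(frames are i.i.d.), periodic boundaries, or real tubulin geometry, so the
tests validate the analysis machinery, not any biological conclusion about
microtubules.

## Problem sizes

The packaged study runs two 2 × 6-block sheets (40 mobile residue nodes,
42 edges) for 2000 frames, with clustering strided to ≤ 200 frames; the
estimator benchmarks use 5000 frames (correlation) and 50 000 frames
(rigidity).  These sizes put every designed effect several standard errors
away from its decision boundary while keeping a full run in minutes on a
single core.

## Known limitations

- The MI significance floor zeroes genuine correlations below ≈ 0.15; for
  sparsely coupled systems lower the `n_sigma` calibration or disable
  significance filtering.
- Hydrogen-bond typing without hydrogens is distance-only and marked so.
- Contact analysis assumes whole molecules (no PBC re-imaging beyond what
  the trajectory provides).
- Chain identifiers are single characters (PDB format); sheets beyond 62
  blocks are rejected.
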