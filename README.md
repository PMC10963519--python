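# sheetnet

Trajectory-based analysis of **mechanical communication in filament-wall
sheets** — lattices of protein monomers such as patches of the microtubule
wall, where laterally coupled protofilaments of α/β-tubulin heterodimers
transmit mechanical and vibrational signals through their contact network.
`sheetnet` takes a topology (PDB) plus MD trajectories (DCD/XTC), builds a
contact-gated, correlation-weighted residue network, extracts communication
pathways by betweenness centrality, and complements the picture with
contact/interaction profiling, per-residue rigidity (force constants) and
evolutionary conservation scoring.

Because real wall-sheet trajectories are far beyond desk scale, the package
ships a first-class synthetic-data module: sheets of monomer blocks whose
displacement correlations, contact geometry, seam-like weak interfaces and
restrained corners are known by construction, so every stage of the
pipeline can be validated against analytic ground truth.

## The model

**Network.** One node per residue (Cα, or a chosen atom for ligands such as
GTP/GDP); residues of position-restrained chains are excluded.  An edge
(i, j) exists when the residues are in heavy-atom contact (≤ 0.45 nm) in at
least 75 % of equilibrated frames and are not sequence neighbours.  The edge
weight is the *generalized correlation coefficient*

&nbsp;&nbsp;&nbsp;&nbsp;r<sub>ij</sub> = √(1 − e<sup>−2I<sub>ij</sub>/3</sup>) ∈ [0, 1],

where I<sub>ij</sub> is the mutual information between the two residues'
3-D displacement series, estimated with the Kraskov k-nearest-neighbour
estimator (k = 5).  For jointly Gaussian displacements with per-axis
correlation ρ this reduces to r = ρ exactly, while capturing nonlinear
coupling in general.

**Centrality.** The weighted degree dg<sub>i</sub> = Σ<sub>j</sub>
A<sub>ij</sub> w<sub>ij</sub> measures local influence.  An optimal
communication path maximizes the product of edge correlations (equivalently,
minimizes the summed edge length −log w).  Node and edge betweenness
b = C Σ<sub>s,t</sub> σ(s,t|·)/σ(s,t) are normalized with
C = 2/((n−1)(n−2)) for nodes and 2/(n(n−1)) for edges so values lie in
[0, 1].  The threshold separating "highly central" edges is the knee of the
ranked edge-betweenness curve (maximum distance from the chord); across
systems, the lowest knee is shared.

**Contacts & interactions.** Residue-pair contact frequencies, per-residue
marginals and between-system difference maps; geometric typing of salt
bridges (charged-group centroids ≤ 0.55 nm), hydrogen bonds (donor–acceptor
≤ 0.35 nm, D–H···A ≥ 130° when hydrogens exist) and hydrophobic contacts
(apolar carbons ≤ 0.40 nm).  An interaction is *stable* when its mean
frequency across systems is strictly greater than 0.75.

**Rigidity.** Per-residue force constants from mean-distance fluctuations,
k<sub>i</sub> = 3k<sub>B</sub>T / Var(d<sub>i</sub>) with d<sub>i</sub>(t)
the mean distance of residue i to all other nodes — rigid residues barely
change their mean distance to the rest of the structure.

**Conservation.** Normalized stereochemically sensitive Shannon entropy per
alignment column: residues pooled into six classes (aliphatic, aromatic,
polar, basic, acidic, special), NE = H/ln 6 ∈ [0, 1], gaps excluded.  The
rigid-set summary compares the median NE of residues with k above the
profile median against the overall median.

## Worked example

The packaged study configuration simulates two 2 × 6 sheets with restrained
corner blocks: a *uniform* sheet (all lateral bonds at coupling 0.7,
longitudinal 0.9) and a *seam* sheet whose central lateral column is weakly
coupled (0.2) and slightly loosened:

```python
from sheetnet import pipeline

config = pipeline.demo_config("demo_out", seed=5, n_frames=2000)
results = pipeline.run_pipeline(config)

seam = results["systems"]["seam"]
print("clusters per system:",
      {n: r["n_clusters"] for n, r in results["systems"].items()})
print("network size:", seam["n_nodes"], "nodes,", seam["n_edges"], "edges")
print("shared knee threshold: %.4f" % results["shared_knee_threshold"])
top = seam["top_edges"]
print(top[top.cross_interface].head(4).to_string(index=False))
print(seam["contact_difference"].nsmallest(2, "difference").to_string(index=False))
```

prints

```
clusters per system: {'uniform': 1, 'seam': 1}
network size: 40 nodes, 42 edges
shared knee threshold: 0.0692
 node_i  node_j   weight  betweenness
D:7:TUB J:9:TUB 0.516119     0.352564
C:3:TUA D:5:TUB 0.544084     0.256410
I:3:TUA J:5:TUB 0.552210     0.256410
B:3:TUB C:5:TUA 0.519521     0.192308
chain  resid resname  difference
    C      7     TUA     -0.2045
    I      9     TUA     -0.2045
```

Reading the numbers: each system stays in a single conformational cluster
at the 0.15 nm linkage cutoff (stable trajectories); the network over the
eight mobile blocks has 40 residue nodes and exactly the designed 42 edges.
Above the shared knee threshold, the most central cross-chain edge
(D:7–J:9, betweenness 0.35) is the *lateral* bridge one column away from
the seam — communication routes around the weak column, whose own lateral
edge carries much less traffic.  The contact-difference map (seam − uniform)
is negative only at the two facing seam residues (C:7, I:9 ≈ −0.20): the
weak interface loses a fifth of its contact frequency while every other
interface is unchanged.

The same run is available from the shell, stage by stage or end to end:

```bash
python -c "from sheetnet import pipeline; \
  pipeline.dump_config(pipeline.demo_config('demo_out', seed=5), 'demo.yaml')"
sheetnet run-all --config demo.yaml --out demo_out
sheetnet simulate|network|contacts|mechanics|conserve --config demo.yaml
```

All outputs are plain CSV/JSON/GraphML/PDB under the output directory,
with a `manifest.json` recording parameters and output hashes (fixed seed
⇒ byte-identical reruns).

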