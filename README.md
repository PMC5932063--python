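# allokit

Structure-encoded analysis of allosteric cross-talk between
post-translational modification (PTM) sites in multi-domain proteins such
as the Hsp90 chaperones.

Large chaperones carry dozens of experimentally validated phosphorylation
and acetylation sites scattered over their domains. Only a few of those
sites sit at evolutionarily conserved positions that control collective
dynamics; the rest ride along in flexible regions and report on
conformational change rather than drive it. `allokit` implements the
computational machinery needed to make that distinction from a structure,
a multiple sequence alignment, and a PTM annotation table:

1. **Conservation and coevolution** — per-column Kullback–Leibler
   conservation against database background frequencies,
   `KL_c = Σ_a P(a) ln(P(a)/Q(a))`; pairwise column mutual information
   `MI(i,j) = Σ P(a_i,b_j) ln[P(a_i,b_j)/(P(a_i)P(b_j))]` with
   average-product correction and a column-shuffle z-score; the
   per-residue cumulative score `cMI_x = Σ_{MI(x,y)>t} MI(x,y)` (t = 6.5
   on the standardized scale) and the proximity score `pMI_x` = mean cMI
   over residues within 5 Å (heavy-atom minimum distance).
2. **Coarse-grained dynamics** — event-driven discrete molecular dynamics
   of C-alpha beads in infinite square wells (`d ∈ [(1−σ)r⁰, (1+σ)r⁰]`,
   σ = 0.05 bonded / 0.1 nonbonded, r_c = 8 Å), and an elastic-network
   Gaussian surrogate whose covariance is the pseudo-inverse of the
   anisotropic network Hessian. Both feed the same reductions: the
   3N × 3N covariance `C = ⟨ΔR ΔRᵀ⟩`, B-factors `B = (8π²/3)·msf`, and
   normalized slow-mode displacement profiles whose local minima mark
   hinges.
3. **Perturbation response scanning (PRS)** — linear response
   `ΔR = C·F` to 250 random unit forces applied to one residue at a
   time; entry (i, j) of the response map is `⟨|ΔR_j|²⟩`. On the
   self-response-normalized map, row means give the effector profile
   (ability to move the rest of the protein) and column means the sensor
   profile (tendency to respond).
4. **Residue interaction networks** — generalized correlation
   coefficients `R_MI = sqrt(1 − exp(−2I/d))` from a Gaussian mutual
   information estimator on residue fluctuation vectors (optionally
   augmented with the pMI coevolution channel); edges for pairs with
   `R_MI > 0.5` in at least one independent ensemble, weighted
   `w = −log R_MI`; all-pairs shortest paths (Floyd–Warshall), edge
   betweenness, and ranked effector→sensor communication pathways.
5. **Classification** — PTM sites are flagged conserved when their KL
   score exceeds the alignment mean by one standard deviation and are
   assigned non-exclusive roles: *hinge* (near a slow-mode minimum),
   *effector* / *sensor* (high PRS z-scores), *carrier* (slow-mode
   maximum region or top sensor quartile).

A synthetic-data module generates every input with planted, recoverable
ground truth — a toy three-domain homodimer with a known hinge, a
globally coupled effector bead and a floppy sensor tail; alignments with
planted conserved columns and coevolving pairs; Gaussian ensembles from a
known covariance — so the full pipeline is testable without downloads.

## Worked example

Run the default synthetic study end to end (about two seconds):

```bash
allokit run --synth --seed 7 --out out/
```

`out/report.tsv` then holds one row per annotated PTM site
(abridged):

```
residue_index conserved  roles           effector_z sensor_z slow_mode
10            True       hinge               0.24    -0.32     0.0012
17            True       effector,hinge      5.34    -0.33     0.0001
28            False      carrier,sensor     -0.32     2.39     0.2563
29            False      carrier,sensor     -0.32     4.68     0.5167
0             False      none               -0.24    -0.28     0.0049
```

The ground truth for this seed plants the hinge at residue 10, the
effector at 17, and the floppy sensor tail at 26–29. The table shows the
classifier recovering all three: the hinge site sits at a slow-mode local
minimum with unremarkable PRS scores; the effector site combines a
conserved column (KL ≈ 3.2 vs an alignment mean near 0.2) with an
effector z-score of 5.3; and the tail sites carry the largest sensor
z-scores while scoring lowest as effectors. Background sites come out
`none` or `carrier`.

The same stages run on real inputs:

```bash
allokit run --structure protein.pdb --alignment family.fasta \
            --ptm-table sites.tsv --seed 1 --out out/
```

Individual stages are exposed as `allokit coevo | dmd | enm | surface |
fri | prs | network | classify`, and the library API mirrors them
(`allokit.coevolution`, `allokit.dynamics`, `allokit.prs`,
`allokit.network`, `allokit.classify`, `allokit.synth`).

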