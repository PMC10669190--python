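# Methods

## Scope and model

The package analyzes conformational ensembles of short capped peptides —
ACE + 21 residues + NME, 23 indexed units — through four residue-resolved
statistics: binary contact maps and their ensemble means, contact degrees
of freedom (DOFs) and their PCA/UMAP projections, 8-state secondary
structure fractions, and ligand fragment contact profiles. Ensembles come
either from multi-model PDB files (any sampling engine) or from the
built-in synthetic helix–coil generator.

Indexing: internal indices are 1-based and include the caps (ACE = 1,
first residue = 2, central Cys of a 21-mer = 12, NME = 23); parent-sequence
positions (e.g. C406 in the androgen-receptor AF1 region) map through
`internal_index(pos) = pos − (center − flank) + 2`.

## Contact statistics

A contact between units j and k is formed when the minimum over all
inter-atomic distances is ≤ the cutoff. Defaults and conventions:

- cutoff 4.2 Å, boundary **inclusive** ("within" a cutoff; ties are
  measure-zero but fixed);
- hydrogens count like any other atom when present;
- sequence-adjacent pairs (|j−k| = 1, 2) are retained — nothing but the
  diagonal is excluded, which is what makes 23 units yield exactly
  23·22/2 = 253 DOFs;
- ligand atoms never count toward their host residue's atom set, keeping
  peptide-fold maps comparable between liganded and native systems;
- the diagonal is fixed at 1 by convention and excluded from the DOFs;
- default analysis stride 10 ps (synthetic frames are generated at a
  nominal 10 ps stride, so every frame is analyzed by default).

The kernel is a vectorized min-reduction over an all-atom distance matrix;
the test suite holds it exactly equal to a brute-force all-pairs scan on
every ensemble it touches.

## Secondary structure

The assignment is Kabsch–Sander: backbone H-bonds from the electrostatic
model E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a
−0.5 kcal/mol threshold; two consecutive n-turns make the minimal helices
(n = 3, 4, 5 → G, H, I), bridge patterns make strands (ladder → E,
isolated → B), remaining turn interiors → T, virtual CA angle κ > 70° → S,
else none. Overlaps resolve by the canonical priority
H > E > B > G > I > T > S.

Conventions chosen where the canon is silent for capped peptides:

- **Caps receive no state** (DSSP states are defined for amino acids) and
  by default are **invisible to the H-bond search**. The alternative — the
  acetyl carbonyl accepting and the N-methylamide donating — is physically
  reasonable and available as `cap_hbonds=True`, but reference
  implementations treat caps as non-protein and skip them, and agreement
  with the mdtraj reference drops from ~99.6% to ~92% (all discrepancy at
  the two cap-adjacent residues) when cap bonds are on. The default keeps
  the implementation verifiable against an independent oracle.
- Missing amide H (external PDBs; never the generator's own frames) is
  reconstructed 1.0 Å from N anti-parallel to the preceding C=O, the
  reference reconstruction. Proline cannot donate.
- β-bulge extension of ladders is not implemented; single-chain ensembles
  of this size essentially never form them, and residual variant
  differences are absorbed by the ≥95% oracle-agreement tolerance.

"Helical fraction" always means the H+G+I mass, averaged over interior
internal indices 4–19 unless stated otherwise.

## Embeddings

Contact vectors enter the embedding raw (binary, not mean-subtracted);
PCA centers internally and uses **covariance** (not correlation) scaling —
all DOFs share the same 0/1 units, so per-DOF rescaling would only amplify
rare contacts. The implementation is an SVD of the centered data matrix;
component signs follow the largest-|loading|-positive convention so runs
are reproducible across BLAS backends. Invariants enforced in tests:
orthonormal components, non-increasing explained variances, eigenvalue sum
equal to the centered total variance within 1e−6 relative.

UMAP is delegated to umap-learn behind a seeded interface (defaults:
15 neighbors, min_dist 0.1, seed 42, recorded in every result). An input
in which all frames share one contact vector has no neighborhood graph to
optimize; it short-circuits to the all-zero embedding with a RuntimeWarning
rather than handing the backend a degenerate problem.

Joint embeddings fit once on the pooled frames of all named ensembles and
project each ensemble in the shared coordinate system; projections of the
same data therefore change when the pool changes, which is expected and
asserted (as non-identity, not as specific values) in the tests.

## Synthetic generator

The generator emulates what matters to the four statistics — backbone
geometry, cooperative helix–coil variation, and a reaching, fragment-
labeled ligand — and nothing else.

- **Representation:** backbone N, H, CA, C, O plus one CB pseudo-atom per
  residue (SG on Cys, the attachment point). No rotamers, no solvent, no
  energies.
- **Geometry:** NeRF placement with textbook internal coordinates
  (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, ω = 180°); carbonyl O and
  amide H on the sp2 bisector; CB by the standard ideal-chirality
  construction. Requested (φ, ψ) are realized exactly (< 1° by
  construction), and the ideal-helix build reproduces the α-helical
  O(i)···N(i+4) ≈ 3.1 Å hydrogen-bond geometry.
- **Helix–coil model:** per-residue helical marginals p_i with
  nearest-neighbor cooperativity c through a two-state Markov chain along
  the sequence, P(h_i|h_{i−1}) = p_i + c(1−p_i), P(h_i|c_{i−1}) =
  p_i(1−c), which preserves the marginals exactly. Helical states get the
  ideal helix dihedrals (−57°, −47°); coil states draw uniformly from two
  rectangular Ramachandran basins (β/PPII: φ ∈ [−160°, −60°],
  ψ ∈ [90°, 175°], weight 0.6; broad bridge: same φ, ψ ∈ [−50°, 30°],
  weight 0.4) — φ < 0 throughout, so the left-handed helix region is
  excluded and coil states reliably break helical H-bonding.
- **Cooperativity default c = 0.5** is a deliberate calibration point: runs
  must be long enough (mean run ≈ 1/(1−0.65) ≈ 3 residues at p = 0.3) for
  the four-residue DSSP α pattern to recover the marginal helicity within
  ±0.1, yet frame-to-frame total-helicity variance must stay small enough
  that ensembles at p = 0.3 and 0.9 separate in a 1-D contact-DOF PCA
  (measured: recovered fractions 0.21/0.91, midpoint-threshold overlap
  4%). Larger c (≥ 0.8) makes single frames of the two ensembles
  statistically indistinguishable; smaller c (≤ 0.4) fragments runs below
  the DSSP helix threshold.
- **Pseudo-ligand:** eight pseudo-atoms in three fragments (stem 2,
  A-ring 3, B-ring 3) chained off SG with ~1.7 Å spacing, total reach
  ~10 Å — the footprint of a dual-ring covalent ligand, not its chemistry
  (no element identities beyond C/S, no chirality; the real ligand's one
  chiral linker carbon is not modeled). Under a contact bias, the B-ring
  is placed 2.8 Å from the target residue's CA in a Bernoulli(fraction)
  subset of frames and pointed radially away from the peptide otherwise
  (with an outward-extension retry if the away placement still grazes the
  target). In the liganded *scenario*, the same Bernoulli draw scales the
  helical marginals of residues within one position of the target and of
  the attachment Cys by (1 − helix_penalty), so the structural and contact
  signatures are consistent frame by frame.
- **Determinism:** one `numpy` Generator seeded from the model seed drives
  states, coil dihedrals and bias draws; identical inputs give
  byte-identical coordinate streams.

**What passing tests do and do not show.** The generator produces ideal
bond geometry, uncorrelated frames, and a ligand whose "binding" is
imposed, not emergent. Tests against it validate the *measurement
machinery* — contact kernels, DSSP, embeddings, profiles, indexing, I/O —
and the internal consistency of the pipeline. They do not validate any
claim about real AR peptides, force fields, or ligand thermodynamics;
conclusions about those require real trajectories run through the same
machinery.

## Pipeline and registry

The packaged study registry lists the 14 simulated systems of the
motivating study design (notation, segment center 406/327/240, H/E start,
ligand XNN/XN0/XNB/XEN or native, run length, ion, water count); run
configurations must reference systems by registry notation. Default demo
sequences are synthetic stand-ins — only the anchors W (internal 5),
A (internal 9) and C (internal 12) of the 406 segment are meaningful — and
residue identity never enters the backbone-level analyses. Block analysis
splits frames into contiguous near-equal halves (`_1`, `_2`; earlier blocks
take the remainder). Every CSV artifact carries a `# config=<hash>
seed=<seed>` header, and reruns with identical configuration and seed are
byte-identical. Per-system seeds derive from the master seed and the
notation's CRC32, so systems are decorrelated but reproducible.

Problem sizes used by the shipped tests and demo (500–2000 frames per
ensemble, 23 units, 253 DOFs) were chosen so that every statistic's
sampling error is well inside the tolerances asserted, while a full suite
run stays comfortably interactive.

## Known limitations

- Single chain only: no inter-chain contacts, no β-sheet topology graphs,
  no solvent accessibility.
- The contact function is hard (binary); no distance-weighted or sigmoidal
  variants.
- PDB dialect is the fixed-column v3.3 subset with MODEL/ENDMDL framing;
  no altlocs, no AMBER prmtop/NetCDF.
- The helix–coil model has no temperature, no kinetics, and no coupling
  between secondary structure and tertiary contacts beyond what backbone
  geometry imposes.
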