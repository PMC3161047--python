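# Methods

## Contact model

Interfaces are detected in two stages. Stage one enumerates, for every
alphanumerically ordered pair of polymer chains (n chains → n(n−1)/2 pairs),
all inter-chain heavy-atom pairs with d < 6.05 Å using a kd-tree
(`scipy.spatial.cKDTree`); the radius is the maximum length of a
water-mediated hydrogen bond, and the boundary is strict. Stage two assigns
each proximal pair a non-exclusive fingerprint over twelve interaction types
(see the README table). Classification is deliberately equivocal: a short
salt bridge is simultaneously an ionic interaction, a hydrogen bond and a van
der Waals contact, and by construction covalent ⊆ vdW-clash ⊆ vdW. A pair
matching no criterion is retained as *proximal only* and excluded from all
downstream "interacting residue" definitions.

### Atomic radii and capabilities

Van der Waals radii are the residue-specific CSD-derived (ProtOr-class)
values: sp3 C 1.88 Å, sp2/aromatic C–H 1.76 Å, bare sp2 C 1.61 Å, N 1.64 Å,
carbonyl/carboxylate O 1.42 Å, hydroxyl O 1.46 Å, S 1.77 Å. Covalent radii
are element values (C 0.77, N 0.70, O 0.66, S 1.04 — note 2 × 1.04 = 2.08 Å,
the disulphide threshold). Capability flags encode fixed pH 7 chemistry:
carboxylates and the terminal OXT are anionic; LYS NZ and the arginine
guanidinium group are cationic; the histidine imidazole is cationic by
default (`his_cationic`, solution pKa near 7); hydrophobic atoms are carbons
without N/O neighbours plus CYS SG and MET SD; aromatic atoms are the planar
ring atoms of PHE/TYR/TRP/HIS, but only PHE/TYR/TRP rings accept
amino-aromatic bonds. Atoms able to both donate and accept are exactly
SER OG, THR OG1, HIS ND1, CYS SG, TRP NE1 and TYR OH. The full matrix ships
as a versioned TSV (`data/atom_properties.tsv`) with per-atom provenance in
its header; evaluating SMARTS patterns at run time would add a cheminformatics
dependency for an assignment that is fixed for 20 residue types.

### Hydrogen placement

Deposited structures rarely resolve hydrogens, and sanitization strips them,
so donors are re-hydrogenated geometrically: backbone amides and sp2 ring
nitrogens on the external bisector of their two antecedents (N–H 1.00 Å);
sp2 amide/guanidinium NH₂ groups with two in-plane hydrogens at 120° from
the stem bond; rotatable hydroxyls, thiols and the lysine ammonium by
sampling the rotor about the stem axis in 10° steps at the tetrahedral angle
(O–H 0.96 Å, S–H 1.34 Å), accepting a bond if **any** rotor position passes
all criteria. Donors with missing antecedent atoms are skipped and logged.
Acceptor-antecedent angle criteria are applied against every bonded heavy
atom of the acceptor (conservative for ring nitrogens with two antecedents).

Side chains of HIS, ASN and GLN are ambiguous in electron density; with
`flip_ambiguous` the detector also explores the alternative orientation
(coordinates of ND1/CD2 and NE2/CE1, or amide O/N, swapped) and reports a
bond if either orientation passes.

Water hydrogens are unresolvable free rotors. When a water donates, its
hydrogen is placed optimally along the O→acceptor axis (so the H-dependent
criteria reduce to d − 0.96 < 2.5 Å with a 180° donor angle); when a water
accepts, it has no antecedent and the antecedent-angle criteria are vacuous.
A water bridging atoms on two different chains necessarily engages in more
than one hydrogen bond, which is the "structured water" requirement. Bridged
protein atom pairs are annotated only if they are themselves within the
6.05 Å proximal radius (the radius was chosen as exactly the maximum
water-bridge span).

### Aromatic geometry

Ring normals use Newell's method over the perimeter cycle (tryptophan uses
the nine-atom indole perimeter), which stays defined for slightly non-planar
rings. An aromatic atom pair within 6.0 Å is confirmed as an aromatic
contact only if the ring centroids are also within 6.0 Å — the same
threshold, since the scheme states a single aromatic distance threshold.
Sub-classification: dihedral(normals) > 30° → edge-to-face; otherwise
face-to-face when the displacement angle (first ring's normal vs the
centroid–centroid vector) ≤ 20°, else displaced face-to-face. "First ring"
is the ring on the alphanumerically first chain.

## Sanitization

The reader (gemmi-backed) is lossless — all models, alternate locations,
hydrogens, lower-case/numeric chain ids and insertion codes survive parsing —
and captures resolution (REMARK 2) and the working-set R-factor (REMARK 3).
Sanitization then keeps the first model only, keeps the highest-occupancy
alternate per atom name (ties to the alphabetically first alt-loc), strips
hydrogens, optionally strips waters and ligands, and repairs the three
modified residues that dominate the archive: MSE→MET (SE renamed SD),
MLY→LYS and HYP→PRO, dropping modification atoms absent from the parent.
Unknown modified residues pass through unchanged, logged, and are excluded
from classification. Cα-only chains are kept but flagged; they cannot
contribute side-chain contacts. Residue identity is author numbering
(chain, number, insertion code) throughout; nothing is renumbered.

## Assemblies

The deposited asymmetric unit often is not the biological oligomer. The
assembly builder consumes a PISA-style XML of rotation–translation operations
grouped into ranked assembly sets with stability labels; only rank-1 sets'
members labelled "stable in solution" are used (a rank-1 set may legitimately
contain several assemblies). Before transformation, each water within 5 Å of
a polymer chain adopts that chain's identifier (nearest chain wins; exact
ties break alphanumerically) so waters ride along with their host chain.
Rotations are validated orthonormal to 1e-6; expansion preserves intra-chain
geometry exactly and maintains an ASU→assembly chain map. Assemblies needing
more than the 62 single-character ids use multi-character internal ids; PDB
serialization of those is refused in favour of the TSV outputs, a format
limit of the fixed-column chain field.

## Solvent accessibility

ASA uses Shrake–Rupley sphere sampling with a deterministic golden-spiral
point set, probe 1.4 Å, default 960 points/atom (two-fold refinement changes
totals by < 1% on peptide fixtures; the isolated-sphere closed form is
reproduced to < 0.5%). A Lee–Richards slicing implementation would serve
equally; sampling was chosen for its direct point-count oracle and because
all thresholds downstream are on *relative* values, so parity with any
particular reference implementation is not required. Waters and ligands are
excluded from the ASA context.

Interface size is ΔASA = ASA(A) + ASA(B) − ASA(AB) from three separate
calculations. Relative side-chain accessibility divides a residue's
side-chain ASA in the complex by the same type's side-chain ASA in an
extended Ala-X-Ala tripeptide. The reference tripeptides are generated
internally (NeRF extended backbone, φ = ψ = 180°, with CCD ideal side-chain
geometry rigidly superposed per residue) and their reference values computed
once per process and cached, rather than bundled as a frozen file. Glycine
uses the CA-as-side-chain convention.

Residues with at least one non-proximal-only inter-chain atom pair are
*interacting*; with relative side-chain accessibility below 7% (strict) they
are **interface core**, otherwise **interface periphery**; non-interacting
residues split into **core**/**exposed** at the same threshold. Accessibility
is evaluated in the complex state, matching how the annotations are stored;
the isolated-chain alternative would shift periphery/core boundaries and is
left to sensitivity analysis.

## Redundancy removal

Trivial interfaces (product of per-side interface residue counts ≤ 25) and
interfaces involving chains shorter than 15 valid residues are filtered.
Remaining interfaces are grouped by the ordered pair of UniProt accessions;
within a group two interfaces co-cluster when **both** sides share strictly
more than 75% of unique UniProt residue positions, and clusters are the
connected components (single linkage) of that relation. The overlap
denominator is Jaccard (|A∩B|/|A∪B|) — symmetric and conservative — with a
min-set denominator selectable (`mode="min"`). Records lacking a UniProt
mapping form singleton clusters.

Each cluster's representative is the interface from the structure with the
highest empirical quality score, −(resolution + 10·R + M), where M is the
proportion of missing internal residues judged from author-numbering gaps
(terminal disorder is invisible to this count and excluded). Absent
resolution (NMR) is penalized as 100, so any X-ray structure outranks an NMR
entry; absent R-factor is imputed as 0.4. Over realistic R-factors
(0.15–0.25) the resolution term dominates. The functional form is isolated
in one function for easy substitution. Exact score ties break to the
lexicographically smallest (entry, chain pair). The result is a
non-redundant set of *interfaces*, not of assemblies.

## Statistics

Propensities: B_i = F_i/ΣF over **all** residues of the included complexes
(not just interfaces), E_ei = F_ei/ΣF_e per environment, R_ei = E_ei/B_i.
Types absent from the background have undefined (reported absent, not zero)
propensity; an empty environment yields zero frequencies with a warning.
Σ_i B_i·R_ei = 1 per environment is asserted in the tests.

Contact preferences: C_ij counts unordered residue pairs (by identity, so a
residue contacting two partners counts once in U_i and twice across C rows);
P_ij = C_ij/ΣC over unordered pairs. Expected frequencies use the symmetric
multinomial convention — 2·Ŵ_i·Ŵ_j off-diagonal, Ŵ_i² on the diagonal — with
Ŵ_i ∝ U_i·asa_i (the tripeptide reference areas), which normalizes away the
greater contact opportunity of large residues; κ rescales the expected
matrix to unit total (identically 1 for this convention up to round-off).
L(i,j) = ln(P_ij/(κ·E_ij)), natural log by default. Cells with zero observed
or expected frequency are reported absent. Residue-level "contact" means any
atom-pair flag besides proximal-only — the same definition as the
environment classification.

## Synthetic data

The generator builds helix-dimer complexes: two 21-residue α-helices
(φ = −57°, ψ = −47°) with heptad-patterned sequences — positions a/d drawn
from {LEU, ILE, VAL, PHE, MET}, all other positions from a polar set
including LYS/GLU/ARG/ASP — rotated so their hydrophobic faces oppose,
packed at a 9.3 Å inter-axis distance typical of dimeric coiled coils, with
0.15 Å Gaussian coordinate jitter emulating coordinate error. This captures
the composition bias and tight hydrophobic packing of real interfaces, so
hydrophobic enrichment in the interface core and lysine depletion are
recoverable. It does **not** emulate β-sheet interfaces, bound waters,
crystal-packing artefacts, disorder, or a protein core outside the interface
(a two-helix dimer has essentially no non-interface buried residues), so
passing statistics tests demonstrates the machinery and the direction of the
effect, not archive-scale magnitudes, which require the full structure
corpus.

Geometric presets (disulphide separation, ring pairs at requested
dihedral/displacement, hydrogen-bond arrangements with one pinned antecedent
angle) realize their requested parameters to 1e-6 Å / 1e-4° and return the
realized geometry for independent verification.

## Numerical choices and scale

Distance boundaries are strict (<, >) exactly as the scheme prints them.
Angles are computed through clipped arccos; undirected axis angles are
folded into [0°, 90°]. ASA determinism follows from the fixed golden-spiral
point set; the pipeline contains no randomness at all — seeds only enter
fixture generation. Default problem sizes in the tests and the acceptance
script (16–20 complexes of 42 residues, 240 ASA points, 100-atom random
clouds) keep a full run in tens of seconds while leaving every statistic
well-determined; all sizes are parameters.

## Known limitations

- Hydrogen-bond detection re-derives hydrogens geometrically; an external
  placement program can differ near criterion boundaries. The rotor-sampling
  acceptance ("any position passes") is permissive for hydroxyls.
- The quality-score coefficients are an empirical surrogate preserving the
  stated dominance ordering, not a fitted model.
- The 6.0 Å centroid threshold for aromatic contacts reuses the atom-level
  aromatic threshold; the scheme states one threshold without restating the
  number for centroids.
- Water-mediated pairs whose protein atoms lie beyond 6.05 Å are not stored
  as atom pairs.
- mmCIF input, protein–nucleic-acid contacts and ligand chemistry beyond
  removal are out of scope.
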