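# Methods

`metscreen` re-implements, as an open and tested pipeline, a ligand-based
virtual-screening and hit-triage workflow for modulators of the
mechano-electrical transduction (MET) channel, whose pore is formed by
TMC1. The pipeline covers: 3D-pharmacophore perception and hypothesis
generation from known blockers, decoy-based model validation, two-pass
screening with score aggregation and threshold selection, fingerprint
clustering for diversity-aware hit picking, docking-pose contact-frequency
analysis, and pore-radius profiling of a channel structure. Docking itself,
MM-GBSA rescoring, MD simulation, and protonation-state enumeration are
out of scope; their outputs (poses, ΔG_bind tables, protomer records) are
consumed as inputs.

## Pharmacophore perception (`features`)

Features are the six classic types — hydrogen-bond acceptor (A), donor (D),
hydrophobe (H), negative (N), positive (P), aromatic ring (R) — assigned by
a versioned, editable SMARTS rule table (`data/feature_rules.tsv`) applied
to molecules with explicit hydrogens and resolved aromaticity. Commercial
feature definitions are proprietary; a declarative table keeps the
replacement auditable. Defaults:

- **A**: N/O atoms with a lone pair and no positive charge; amide and
  aniline nitrogens excluded. Direction: opposite the mean bond vector
  (idealised lone pair).
- **D**: N/O with ≥1 bound hydrogen, charged donors included (so a
  protonated amine is both P and D — co-located features are allowed, as
  the behaviour of commercial tools here is unknown). Direction: mean X–H
  vector.
- **P**: positively charged nitrogen (protonated amine, amidinium,
  guanidinium, pyridinium); N-oxide N⁺ excluded.
- **N**: carboxylate / sulfonate–sulfate / phosphate groups, placed at the
  centroid of the matched atoms.
- **H**: maximal connected clusters (≥2 atoms) of apolar carbons and
  halogens, at the cluster centroid. Aromatic carbons are excluded so H and
  R stay distinct.
- **R**: aromatic rings by aromaticity perception; centroid + ring normal
  (SVD of the ring coordinates; the normal's sign is fixed by a
  deterministic convention and treated as ± everywhere downstream).

Same-type features within 1.0 Å are merged to their centroid, preventing
double counting on fused rings and tautomer artifacts. All geometric
operations downstream of perception use heavy atoms only.

## Hypothesis generation (`hypotheses`)

A hypothesis is a 3–5-feature arrangement matched by at least a
`min_coverage` fraction (default 0.5) of the training molecules. The search
enumerates feature k-tuples on each training molecule as reference
arrangements, verifies every other molecule by type-preserving
correspondence search + Kabsch superposition within a tolerance (default
1.0 Å, the same value as the screening RMSD gate), deduplicates candidates
by signature and geometry (best-correspondence RMSD ≤ tolerance), and
returns the best 10 by score. This is exhaustive and reproducible at
training-set scale (tens of molecules, tens of features each); it is not
intended for hundreds of molecules.

**Quality score.** Commercial hypothesis scores are proprietary, so the
ranking uses a defined analog in [0, 1]:

    hypo_score = coverage × mean over matched molecules of
                 ( k/k_max + (1 − RMSD/RMSD_max) + vector_alignment ) / 3

with k the feature count, k_max = 5, RMSD_max = 2·tolerance, and
vector_alignment the mean cosine between hypothesis and superposed
molecule feature vectors (ring normals compared up to sign; pairs without
directions contribute 1). The site term k/k_max was a deliberate design
choice: without it, every 3-feature sub-arrangement of a good 4-point
pharmacophore outranks the full arrangement, because fewer points always
superpose with lower RMSD. With it, the complete planted arrangement wins
on synthetic data while sub-arrangements still appear further down the
list, which matches how multi-feature and sub-feature models co-exist in
published rankings. These scores are **not** numerically comparable to any
published hypothesis scores.

## Screening (`screening`)

Two passes, mirroring the study design:

1. **Geometric gate.** A molecule matches a hypothesis when some
   type-preserving feature correspondence superposes with RMSD ≤ 1 Å
   (`rmsd_max`); among correspondences inside the gate the one covering the
   most hypothesis features wins, RMSD breaking ties. Partial matching, when
   enabled, requires ≥ ⌈0.75·|h|⌉ features. Per hypothesis the `top_n`
   (default 5000) lowest-RMSD molecules are kept, and only molecules
   matching ≥ 2 hypotheses advance.
2. **Screen score.** For each (molecule, hypothesis) match:
   `scale·(w_site·matched_fraction + w_align·(1 − rmsd/rmsd_max) +
   w_vec·vector_alignment)/Σw`, defaults w = (1,1,1), scale = 1 — again a
   defined analog, not comparable to published screen scores.

Per-compound scores are summed across hypotheses into the total screen
score TPS_S, after collapsing protomers/conformers (ids of the form
`compound|tag`) by the per-hypothesis maximum. The docking threshold is

    D_T = X̄ + 2δ

with X̄ the library mean of TPS_S and δ its **sample** (n−1) standard
deviation — the source material does not state which SD variant was used;
sample SD was chosen and matters little at library scale. Selection is
inclusive (TPS_S ≥ D_T), with a 1e-12 absolute slack so affine rescaling of
scores cannot flip boundary cases through floating-point rounding. With
fewer than 2 molecules the threshold is undefined (error); zero variance
selects everyone at D_T equal to the common value.

Tie-breaking everywhere is score descending, then id lexicographic.
Conformers: the screening contract assumes up to ~10 pre-generated
conformers/protomers per compound arrive as separate records; a basic
seeded ETKDG embedding is provided for SMILES input.

## Validation metrics (`validation`)

ROC AUC uses the rank (Mann–Whitney) formulation, P(active > decoy) +
0.5·P(tie), equivalent to the trapezoidal ROC area. The Güner–Henry family
is computed from counts D (screened), A (actives), Ht (hits), Ha (active
hits):

    %Yield = 100·Ha/Ht        Ya = Ha/Ht       Se = Ha/A
    Sp = ((D−A)−(Ht−Ha))/(D−A)                EF = (Ha/Ht)/(A/D)
    GH = [Ha·(3A+Ht)/(4·Ht·A)] · [1 − (Ht−Ha)/(D−A)]

Models are labelled good (GH > 0.7), acceptable (GH > 0.5), else poor; both
inequalities strict, so GH = 0.5 is poor. Ht = 0 and D = A are explicit
errors. Decoy sets are inputs; the synthetic generator supplies
geometry-matched decoys (same feature-type inventory, randomised geometry
rejected at 2 Å RMSD from the planted arrangement). This validates the
metric code but is weaker than physicochemical property matching used by
dedicated decoy generators — passing tests here say nothing about decoy
bias on real libraries.

## Diversity clustering (`clustering`)

Radius-2 Morgan fingerprints (2048-bit hashed, chirality off), Tanimoto
similarity, average-linkage clustering on 1 − similarity. The *normalized*
cut threshold (0.75 / 0.85 defaults for the two library types) is read as a
fraction of the maximum merge height of the dendrogram, because linkage
heights vary per dataset while the stated thresholds are dataset-relative;
an absolute-height cut is available behind `absolute=True`. From each
cluster of ≥3 members, representatives are the compounds with the lowest
ΔG_bind (kcal/mol, without phospholipids), ties by id; a consistency report
flags whether each hit stays favorable when phospholipids are included in
the rescoring and whether it weakens.

## Pose contacts (`contacts`)

A residue is contacted by a ligand when any ligand heavy atom is within
5 Å of any residue heavy atom (KD-tree accelerated; an all-pairs scan is
the test oracle). Contact frequency is the fraction of ligands contacting
the residue; > 0.5 is high-contact, and exactly 0.5 is classified low
(strict inequality). Lipids (e.g. POPC) are residues like any other. The
default is one pose per ligand (best pose); an ensemble simply passes more
poses. Interaction typing uses configurable heavy-atom criteria: salt
bridge ≤ 4.0 Å (opposite formal charges), H-bond ≤ 3.5 Å (N/O pair),
cation-π ≤ 4.5 Å (cation to aromatic-ring centroid), hydrophobic ≤ 4.5 Å
(C–C); per (ligand, residue, type) the minimum distance is reported.
Charged receptor atoms come from residue templates (Asp/Glu carboxylates,
Lys/Arg/His side chains, aromatic rings of Phe/Tyr/Trp/His); for lipid-like
residues the choline nitrogen is cationic and oxygens within 1.9 Å of a
phosphorus are the phosphate acceptors (a geometric rule, robust to atom
naming). Unknown residues are skipped with a warning. Binding-site zones
(top/middle/bottom) are axial intervals; points outside the pore span are
labelled `outside`.

## Pore profiling (`pore`)

At each plane normal to the channel axis (step 0.5 Å), the pore radius is
the maximised value of min over atoms of (distance − vdW radius) over probe
centres in the plane — the classic sphere-fitting pore analysis. The
maximiser is Nelder–Mead with 8 seeded random restarts, bounded to a 15 Å
cylinder, warm-started from the previous plane's centre. A candidate
optimum is accepted only if the straight path from the previous centre
stays in open space; this keeps the probe inside the pore rather than
letting a restart beyond the wall "discover" the building exterior, which
is the standard failure mode of unconstrained sphere fitting on open
structures. Planes with no nearby atoms report the 15 Å cap and are
flagged. The element vdW table is Bondi-style and shipped in the module;
reported diameters are table-dependent, so comparisons against published
constriction sizes (≈4.5 Å for the TMC1 model) are approximate by nature.
Zone boundaries derive from the profile: the middle site is the contiguous
region around the narrowest plane where the radius stays below
r_min + 0.5·(r_max − r_min), widened to at least ±2 Å for V-shaped
constrictions; flat profiles (< 0.5 Å relief) fall back to a single zone.

## Synthetic data (`synth`)

All generators are seed-deterministic and return their ground truth:

- `gen_planted_set` — the default study conditions are a 4-point A-P-R-R
  arrangement (the archetypal blocker motif: protonatable amine plus
  aromatic rings), σ = 0.2 Å coordinate noise, 6 actives, 2 distractor
  features per molecule, 40 decoys per active; each active receives a
  random rigid motion. Decoys share the feature-type inventory with
  randomised geometry, rejection-sampled to > 2 Å best-correspondence RMSD
  from the planted arrangement. This emulates the geometry of a
  known-blocker training set, not its chemistry: no conformer flexibility,
  no physicochemical decoy matching, no protonation ambiguity. Passing
  recovery tests therefore demonstrates correctness of the search and
  scoring machinery, not screening performance on real libraries.
- `gen_toy_pore` — stacked rings of pseudo-atoms (24/ring, one global
  angular phase) with analytic radius R_ring − vdW at each ring.
- `gen_toy_poseset` — single-atom residues spaced 4× the contact cutoff
  apart, poses built to realise a prescribed contact map exactly.

## Pipeline and problem sizes

`run_pipeline` executes synth → hypo → validate → screen → cluster →
contacts → pore with a manifest (config hash, seeds, output checksums,
row counts); identical configs reproduce byte-identical tables. The test
suite and the acceptance script run the generators at their default
conditions (6 actives, 40 decoys per active, 20 recovery seeds, 33-plane
pore profiles), sizes chosen to keep the full synthetic loop at desk scale
while leaving the statistics stable across seeds.

## Known limitations

- Feature SMARTS defaults are sensible but not exhaustive (no tetrazole
  anion, no thiol donor tuning); the rule table is the extension point.
- The hypothesis search is exhaustive in k-tuples and not suitable for
  training sets much beyond ~20 molecules × ~30 features.
- Analog scores order compounds sensibly but are not calibrated to any
  commercial score scale.
- The contact-typing templates cover standard amino acids and lipid-like
  residues generically; exotic cofactors are skipped with a warning.
- Pore profiles are single-structure; trajectory averaging is plain
  iteration left to the caller.
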