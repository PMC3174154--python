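# Methods

This note records the models, parameter choices and numerical conventions
behind `xtalassoc`, and what the synthetic test fixtures do and do not
establish about real crystal structures.

## Coordinate model and I/O

Structures are flat, ordered atom lists with optional unit cell and
Hermann–Mauguin space-group symbol.  Residues are addressed only by author
numbering plus insertion code — no renumbering — because the interfaces of
interest are discussed in the literature by author residue numbers (e.g.
Asn 506, Ser 508 of ICA512).  Parsing is delegated to gemmi; writing is an
in-package fixed-column emitter restricted to CRYST1/ATOM/HETATM/TER/END,
with coordinates at three decimals, which makes read→write→read a fixed
point to 0.001 Å.  Alternate conformers: only blank and "A" altlocs are kept
by default, matching single-conformer analyses.  Hydrogens are retained on
read but excluded from surface and contact calculations; waters (HOH) parse
as hetero atoms because bridging waters are part of the interface
chemistry.

## Space-group symmetry

Operators come from gemmi's space-group tables keyed on the symbol, rather
than a hand-maintained three-group table: the database is exact, already a
dependency, and removes a class of transcription errors, while explicit
triplet strings ("-x,y+1/2,-z+1/2") still override or extend the symbol set.
The crystals motivating the package use P1, P2₁2₁2₁ and P4₁ only.
Fractional↔Cartesian conversion uses the standard PDB orthogonalization
(a along x, b in the xy-plane); the test suite pins the convention against
gemmi on triclinic cells.

Neighbour expansion applies every non-identity (operator, lattice shift)
pair within a ±1 cell window by default (protein diameter ≪ cell edge in
these crystals; the window is configurable and the oracle tests use ±2).
One record is produced per (operator, ASU chain, mate chain) with at least
one atom pair inside the cutoff.  Duplicate handling needs care: a contact
of chain A with the copy of chain B under g is the same interface as B with
the copy of A under g⁻¹, so cross-chain duplicates are collapsed onto the
lexicographically smaller chain ordering.  Same-chain contacts are *not*
collapsed at this level — a single atom in a small P1 cell correctly reports
six face neighbours, which is what lattice-coordination counting needs —
but the interface catalog, which counts physical interfaces, additionally
merges same-chain mates related by inverse operators.

## Accessible surface and buried area

Shrake–Rupley with a deterministic golden-spiral point set: no RNG, so
surface areas are bit-reproducible without seeds.  Defaults: probe 1.4 Å,
960 points per atom, van der Waals radii C 1.70, N 1.55, O 1.52, S 1.80 Å
(community values; per-name or per-element overrides accepted).  At 960
points an isolated sphere is within 0.5 % of 4π(r+p)².  Hydrogens, waters
and hetero atoms are excluded by default — bound Ca²⁺ and crystallographic
waters are not protein surface — and the switch is exposed.

Buried surface is ΔASA = ASA(A) + ASA(B) − ASA(AB) with identical
parameters for the three evaluations.  Both the total and the per-monomer
half value are reported, because "buries ~1100 Å² of monomer surface" style
statements in the literature are ambiguous between the two conventions.

## Interface catalog

Contacts: all cross-chain heavy-atom pairs within 6.5 Å (closed interval,
as for every distance cutoff in the package).  Hydrogen bonds: donor and
acceptor atoms from standard amino-acid N/O atom-name tables, heavy-atom
distance ≤ 3.5 Å and antecedent–donor–acceptor angle ≥ 90°, hydrogens
ignored — standard practice at the 1.3–1.8 Å resolutions this targets.  The
donor's antecedent is its nearest heavy atom in the same residue (< 2 Å),
which is the covalently bonded anchor for every standard donor and is
robust on schematic fixtures.  Bridging waters are water oxygens within
H-bond distance of polar atoms of both partners; donor/acceptor direction
through the water is not resolved (no hydrogens).  Metal sites: protein
N/O/S ligands within 3.0 Å of each metal hetero atom (upper bound of
observed Ca–O/N coordination); sites are attributed to an interface when
their ligands span both partners; bidentate carboxylates (both OD1/OD2 or
OE1/OE2 of one residue) are flagged.

Classification labels an interface "X—Y" by majority vote of each side's
contact residues over a secondary-structure annotation (chain → labelled
residue ranges).  A side whose winning element holds less than half the
contact residues, ties, or wins with "loop" yields "other".  Annotation
files take precedence; a phi/psi fallback assigner (helix φ∈[−100,−30],
ψ∈[−80,−5]; strand φ∈[−180,−40], ψ∈[90,180]∪[−180,−170]; runs ≥ 3) exists
for unannotated chains but is deliberately crude — exact element boundaries
must come from the user when classification matters.

The catalog enumerates ASU chain pairs plus lattice mates, keeps records
with total ΔASA ≥ 400 Å² by default (large enough to discard incidental
packing contacts while keeping the 800–1200 Å² interfaces of interest;
config-exposed) and sorts by descending buried surface.  Output is a
deterministic function of (model, config, annotation).

## Rigid-body geometry

Superposition is Kabsch via SVD with a reflection guard (det = +1 enforced),
so mirror-related sets keep a nonzero RMSD.  The C2 deviation of a dimer
superposes the chain-swapped coordinate stack [B;A] onto [A;B], pairing
atoms by author residue number; it is exactly symmetric in the chains and
invariant under global rigid motion.  The default atom selection for
symmetry and protomer RMSDs is backbone N, CA, C, O of residues present in
both partners, with a CA-only option; one consistent selection is used for
both statistics.  Pairwise protomer RMSD reports the full matrix and
mean ± sd (population sd over unordered pairs).

Dihedrals follow the IUPAC sign convention in (−180°, 180°]; φ/ψ are absent
at termini and residues with incomplete backbones are skipped with a
warning.  β-turns are typed by nearest canonical (φ,ψ) pair of the two
central residues (I: −60,−30/−90,0; I′: 60,30/90,0; II: −60,120/80,0;
II′: 60,−120/−80,0) with ±45° tolerance, one angle allowed ±55°.

Cell content: V_M = V_cell/(Z_asu·N_ops·MW) with N_ops the space-group
general-position count, and solvent fraction 1 − 1.23/V_M.  The constant
1.23 Å³/Da follows from a protein partial specific volume of 0.74 cm³/g and
reproduces the published V_M/solvent pairs of all four ICA512 crystal forms
within 0.11 percentage points (the bundled `reference.CRYSTAL_FORMS` table
carries those published values as inputs).

## Conservation

Column identity is the modal non-gap residue's frequency among non-gap
entries; all-gap columns score 0 and columns over 50 % gaps are flagged
low-confidence.  Treating gaps as missing rather than as mismatches is a
package decision (the convention is rarely stated in the literature this
emulates).  "Conserved" is strictly greater than the threshold (default
0.90: "more than 90 %").  Structure mapping is an exact ungapped
subsequence match between the alignment master and the chain sequence — no
fuzzy alignment, so failures are loud and show both sequences.  Interface
conservation reports, per catalog record, the conserved fraction of mapped
contact residues next to the chain-wide background fraction.  No enrichment
p-value is attached by default; the comparison is descriptive.

## Monomer–dimer equilibrium

Total concentration is monomer-equivalent (the SEC axis): c = [M] + 2[D],
K_D = [M]²/[D], giving [M] = (−K_D + √(K_D² + 8 K_D c))/4 in closed form;
at c = K_D the monomer weight fraction is exactly ½.  The observable is the
weight-fraction average R_s = f_M·R_M + (1−f_M)·R_D — the simplest model
consistent with a calibrated-column readout; signal weighting by size is a
configurable refinement left out of the default.  Chromatographic dilution
is not modelled; concentrations are taken as given.  Fitting optimises
(log K_D, R_M, R_D) by least squares from five log-spaced K_D starts
spanning the observed concentration range — deterministic, no RNG — and
flags flat isotherms as non-identifiable.  Noiseless synthetic isotherms
refit K_D to 1e-4 relative; at 1 % noise (of the radius span), 20 points
and 200 replicates the median relative bias is about 3 %.

## Synthetic fixtures: what they do and do not show

The generators emulate the *geometry* of the study conditions: C2 dimers
with controlled Gaussian perturbation, antiparallel strand ladders at 2.9 Å
O···N spacing with register shifts up to 2 (the lattice shows up to ~8 Å
relative strand displacements), 22-sequence alignments at the breadth of
the ICA512/phogrin ortholog set, isotherms generated at the 0.8 µM
wild-type K_D, and toy crystals in the three observed space groups with
designed contacts.  Chains are schematic backbone-only random walks, not
folded proteins: passing tests establish that the *measurements* are
correct (against closed forms, brute-force enumeration and independent
implementations), not that any particular biological interface is real.
Conclusions about the deposited ICA512 structures require the deposited
coordinates, which the package analyses but does not bundle.

Problem sizes used by the test and acceptance runs (20-residue monomers,
8-residue strands, 3-atom lattice fixtures, 200 fit replicates) were chosen
as the smallest sizes at which each oracle is non-trivial; all complete in
seconds.

## Known limitations

- No full space-group edge-case handling beyond gemmi's symbol database
  (rhombohedral/centred settings are untested here).
- SASA is atom-sphere based; no Connolly surface or per-residue relative
  accessibility normalisation.
- H-bond detection is geometric only — no energy term, no explicit
  hydrogens, no salt-bridge/π-interaction typology.
- The fallback secondary-structure assigner is φ/ψ-box based, not a DSSP
  reimplementation; supply annotations for publication-grade classification.
- The equilibrium model stops at dimers; higher oligomers and heterodimer
  competition are out of scope.
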