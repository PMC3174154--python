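# xtalassoc

Crystal-lattice association analysis for small protein domains.

When a protein crystallizes, every chain-chain contact in the lattice is a
candidate dimerization interface — most are crystallization artifacts, a few
may be biologically meaningful.  Deciding which is which requires measuring,
for every contact: how much surface it buries, how it is held together
(hydrogen bonds, bridging waters, metal ions), whether it obeys the two-fold
symmetry typical of low-energy homodimers, whether its residues are
evolutionarily conserved, and whether the association is detectable in
solution.  `xtalassoc` packages that whole workflow, motivated by the
receptor-type protein tyrosine phosphatase ICA512 (PTPRN/IA-2), whose mature
ectodomain crystallizes in orthorhombic and tetragonal forms with competing
β-strand (β2—β2, β4—β4) and helix (α2—α2) pairing modes.

## What it computes

- **Lattice contacts.**  Space-group operators (P1, P2₁2₁2₁, P4₁ out of the
  box; any Hermann–Mauguin symbol or explicit triplet list) are applied over
  a lattice-shift window; every symmetry mate with an atom within a cutoff
  of the asymmetric unit is enumerated.
- **Buried surface.**  Shrake–Rupley solvent-accessible surface area with a
  deterministic golden-spiral point set (probe 1.4 Å, 960 points/atom by
  default), and the standard buried-surface difference
  ΔASA(A,B) = ASA(A) + ASA(B) − ASA(AB).
- **Interface chemistry.**  Cross-chain contacts (6.5 Å), hydrogen bonds
  (heavy-atom donor–acceptor ≤ 3.5 Å, antecedent angle ≥ 90°), bridging
  waters, and metal coordination sites (Ca–O/N ≤ 3.0 Å, bidentate
  carboxylates flagged), with β/α secondary-structure classification of each
  interface.
- **Symmetry deviation.**  The C2 deviation of a dimer: superpose the
  chain-swapped copy onto the original (Kabsch, proper rotations only); the
  post-fit RMSD is 0 for a perfect two-fold dimer.  All-pairs protomer RMSD,
  backbone dihedrals and β-turn typing (I/I′/II/II′), and cell-content
  arithmetic (Matthews coefficient V_M = V_cell/(Z·N_ops·MW), solvent
  fraction 1 − 1.23/V_M).
- **Conservation.**  Per-column identity of a multiple alignment, strict
  ">90 %" conservation calls, mapped onto structure residues and interface
  membership.
- **Solution equilibrium.**  The monomer–dimer model
  [M] = (−K_D + √(K_D² + 8 K_D c))/4 with weight-average observable
  R_s(c) = f_M R_M + (1 − f_M) R_D, fit by deterministic multi-start least
  squares.

Synthetic generators (`xtalassoc.synth`) build every fixture the pipeline
needs — sphere sets with analytic surface areas, exact and perturbed C2
dimers, antiparallel β-strand pairs with known hydrogen-bond ledgers, toy
crystals with designed lattice contacts, alignments with designed conserved
columns, and isotherms with known K_D — so each stage is testable against
construction, offline.

## Worked example

```python
from xtalassoc import c2_deviation, find_hbonds, matthews
from xtalassoc.equilibrium import fit_kd
from xtalassoc.synth import make_beta_pair, make_c2_dimer, make_isotherm

dimer, _ = make_c2_dimer(monomer_size=20, noise_sd=0.5, seed=7)
print("C2 deviation:", round(c2_deviation(dimer, "A", "B"), 3), "A")

strands, ledger = make_beta_pair(8, register_shift=1)
print("H-bonds:", len(find_hbonds(strands, {"A"}, {"B"})),
      "designed:", len(ledger.bonds))

iso, _ = make_isotherm(k_d=0.8, noise_sd=0.01, seed=3)
fit = fit_kd(iso)
print("K_D:", round(fit.k_d, 3), "uM")
```

prints

```
C2 deviation: 0.836 A
H-bonds: 14 designed: 14
K_D: 0.799 uM
```

The C2 deviation is the residual RMSD a 0.5 Å-noise dimer keeps after the
best chain-swap superposition; the 14 recovered hydrogen bonds are exactly
the designed ladder of an 8-residue antiparallel pair shifted by one
register step (7 residue pairings × 2 main-chain bonds); and the fitted
dissociation constant recovers the 0.8 µM used to generate the noisy
isotherm.  The bundled crystal-form table
(`xtalassoc.reference.CRYSTAL_FORMS`) supports the cell-content arithmetic:
the tetragonal form (P4₁, a = b = 44.66 Å, c = 168.67 Å, four chains per
ASU) at a 9.4 kDa chain mass gives V_M = 2.23 Å³/Da and 44.8 % solvent.

A command-line front end covers the same workflow on files:

```sh
xtalassoc analyze crystal.pdb --symmetry --sse annotation.tsv --out report/
xtalassoc compare form1.pdb form2.pdb
xtalassoc fit-kd isotherm.tsv
xtalassoc fixtures --kind beta-pair --out fixture.pdb
```

`analyze` writes `report.json`, `interfaces.tsv` and `geometry.tsv`; apart
from one provenance timestamp the outputs are a pure function of the input
file and configuration.

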