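# Methods

## Model and assumptions

The design target is the highest-probability peptide of length n for an
ordered path of n grid boxes on a protein surface.  Two independence
assumptions make the problem tractable:

1. **Markov sequence statistics.**  Binding preferences couple only
   consecutive residues: the 20 first-grid energies E_i and the 400
   energies E_ij(t) per grid pair fully parameterize the chain.  Weights
   u = exp(−E/kT) feed the rotational-isomeric-state transfer-matrix
   product Z = J*·U(1)···U(n−1)·J; pair marginals come from the same
   product with U(t) zeroed except one element, and conditional transitions
   a(j|i) are their row-normalizations.  This ignores longer-range
   coupling along the peptide (side chains three or more grids apart).

2. **Torsion-state emissions.**  The docked pose's backbone dihedrals are
   summarized by an 11-state classification of the (φ_t, ψ_t) and
   (ψ_t, φ_{t+1}) planes; coil-library frequencies give the a-priori
   probability of those states, as a proxy for the unfolded-state
   propensities of short peptides.  Residue-specific region shapes are not
   used: one region geometry serves all 20 residues.

The decoder is a standard Viterbi dynamic program over m = 20 hidden
amino-acid states per grid: O(n·m²) time and O(n·m) memory, with
backpointers stored during induction.  The per-run operation count is
recorded in the result (`op_count = (n−1)·m²`) so the scaling is checkable.

## Region geometry

The eleven torsion states are axis-aligned rectangles with half-open
[lo, hi) intervals, loaded from an editable YAML file
(`src/pepdesign/data/regions.yaml`).  Published depictions of the
eleven-state taxonomy are graphical, not numeric, so the shipped table is
this package's own rectangle set, chosen to contain the standard anchor
conformations (α_R at (−63, −43), α_L at (57, 47), β_s at (−120, 130),
etc.) and to leave the sterically strained origin region uncovered.  Both
axes wrap with period 360°, so the extended state ε is two rectangles that
are contiguous on the torus.  Any published boundary set can be substituted
by editing the YAML; the classifier only requires pairwise-disjoint
rectangles.  About 22% of the uniform (φ, ψ) square is uncovered and
classifies as state 0 (unclassified) — comparable in spirit to the few
percent of strained conformations a native-protein map leaves out.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| temperature_K | 298.15 | K | ambient; only the product kT matters |
| kB | 0.0019872 | kcal/(mol·K) | gas constant in molar units, matching kcal/mol energies |
| pseudocount | 0.5 | counts/state | keeps sparse coil libraries from producing zero emissions; at 1,000 records/row it shifts frequencies by < 0.006 |
| emission floor | 1e-4 | probability | substituted for unclassified torsion states at decode time, so one strained pose cannot veto a sequence; 0 restores a hard veto |
| transition_mode | conditional | — | Viterbi uses a(j|i); "joint" uses p_ij directly (both exposed because either reading of the update is defensible) |
| singlet_index | i | — | the singlet emission factor is indexed by the residue at grid t; "j" switches it to the following residue |

Design choices where the design was genuinely open:

* **First-grid weights and Z.**  The partition function and pair marginals
  use pair matrices only (J* = ones); first-grid energies enter solely
  through the initialization distribution p1.  This keeps the two energy
  sets in distinct, non-overlapping roles; `include_first=True` folds the
  first-grid weights into the chain as a diagonal prefactor for
  sensitivity checks.
* **Tie-breaking** is toward the lowest canonical alphabet index
  (`ACDEFGHIKLMNPQRSTVWY`), recorded in the result, so runs reproduce.
* **Degeneracy.**  An induction step raises an error only when *no*
  residue is viable at the next grid; individual impossible residues
  (−inf columns) are legal, which is what lets zero-floor adversarial
  observations reroute rather than abort the decode.

## Numerical choices

All chain products and the entire dynamic program run in the log domain:
with pair energies near −13 kcal/mol a single weight is ≈ exp(22), and a
9-residue linear-domain product overflows double precision.  Marginals are
computed by prefix/suffix log-sum-exp vector products, algebraically equal
to the literal zeroed-matrix formula (verified against brute-force
enumeration to relative 1e-10 on small alphabets).  log(0) = −inf is used
deliberately; probability-domain outputs are renormalized exactly.  Angles
are degrees wrapped to (−180, 180]; the dihedral is the four-point atan2
form, invariant under rigid motion to < 1e-9 degrees.

## What the synthetic generators emulate — and what they do not

`synthkit` generates every input format the pipeline reads, with known
ground truth: planted-optimum energy tables (planted cells sit `margin`
below a flat baseline; competitor noise is Gaussian, clipped at −margin/2
so any path deviating from the planted one loses at least margin/2 per
deviation — hence the documented sufficient recovery condition
margin > 4·noise_sd), coil libraries drawn from known categorical state
laws with angles uniform inside the target rectangles, docked-pose
observations (fixed helical point, random classifiable triples, or
adversarial vetoes), ideal-geometry backbones built by natural-extension
forward kinematics, toy PDB files and docking logs.

These fixtures are deliberately idealized: energies are i.i.d. around a
flat baseline rather than physically correlated; torsion angles are
uniform within a state rather than clustered at basin centers; docked
poses are built from ideal bond geometry.  Passing tests therefore
certify the *algorithmic* contracts — optimality of the decoder,
correctness of the chain algebra, fidelity of parsing and classification —
not the physical quality of any docking scoring function, which this
package treats as given.

## Problem sizes used in tests and the acceptance script

Exhaustive-enumeration checks use the full alphabet at n = 3 (8,000
sequences) and n = 4 (160,000, evaluated by tensor broadcasting), plus
alphabets of 2–3 letters up to n = 5 for the chain marginals; planted
recovery uses 50 seeded pentapeptide instances at margin 1 kcal/mol and
noise 0.2 kcal/mol; coil-table recovery uses 1,000 records per row/cell.
These sizes keep the whole suite and the acceptance script within a couple
of minutes on one CPU while exercising every contract at full alphabet
width somewhere.

## Known limitations

* Binding energies are inputs; no docking, scoring or structure
  preparation is performed.  The docking-log parser targets a tolerant
  line-oriented dialect; the TSV results format is the canonical
  interchange.
* The emission model conditions the (ψ_t, φ_{t+1}) state on both residue
  identities but uses a single region geometry for all residues.
* Only the 20 L-amino acids are supported; k-best / posterior decoding
  variants are out of scope.
* The chain and decoder support reduced alphabets (used by the enumeration
  oracles); emission tables always index the canonical 20.
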