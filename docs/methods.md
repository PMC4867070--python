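# Methods

## The screening model

The package operationalises a qualitative idea — "this bacteriocin looks
like azurin" — as three successive quantitative filters. Each filter is a
pure function of its inputs, and the pipeline is their composition; a
candidate must pass all three to be called azurin-like.

### Stage 1: annotation-odds similarity

Functional-annotation predictors of the ProtFun family emit, per sequence
and per functional category, a probability and an *odds number* (the
probability relative to the category's prior; the parser treats it as an
opaque non-negative real). With azurin as control, the control's top-odds
category is found in each of the three groups — cellular function (F),
enzyme class (EZ), gene ontology (GO); for azurin these are cell envelope
(odds 9.71), nonenzyme (1.147) and immune response (5.877), odds product
65.5. Each candidate is then scored

    score(seq) = log10(odds_F · odds_EZ · odds_GO)

over the odds it attains in those same three categories, unweighted, and
candidates with score > 0 are selected. Design points:

* **Logarithm base.** Unstated in the original description; selection
  (score > 0 ⟺ product > 1) and ranking are base-invariant, so base 10 is
  used for readability and stated in report headers. A property test checks
  base-invariance of the selection.
* **Zero odds.** Mapped to a −∞ sentinel with a warning, not an error, so
  one failed category cannot abort a batch; sentinels rank last and are
  never selected.
* **Weights.** The three factors enter unweighted; `score_all` exposes an
  exponent-weight hook defaulting to (1, 1, 1).
* **Probability score.** Computed with the same formula over the
  probabilities (the original work computes it but gives no formula; this
  is the package's interpretation, documented here). Its Pearson
  correlation with the odds score is reported as a consistency diagnostic
  via `scipy.stats.pearsonr`.
* **Ties** in the control's top category are broken lexicographically with
  a logged warning, so runs are deterministic.

### Stage 2: hydrophobic percentage (HPP)

HPP is 100 × (residues in {F, I, L, M, V, W, G, C, A}) / length. The
nine-letter binary alphabet is the package's only hydrophobicity notion —
deliberately no GRAVY or other continuous scale, since the screen is
defined on the binary count.

* **Rounding is half-up to the nearest integer, before filtering.** This is
  forced by the screen's own arithmetic: one retained candidate (p2seq20)
  has raw HPP 51.22%, outside the [44, 51] window, and is retained only if
  the filter operates on the rounded value 51. All computation is done in
  exact rational arithmetic (`fractions.Fraction`), so ties and boundary
  cases are reproducible. No .5 tie occurs anywhere in the bundled panel,
  so half-up vs half-even is not observable there.
* **Window.** `[min(ref HPPs) − t, max(ref HPPs) + t]`, inclusive, with
  t = 2 by default. Anchored on azurin (49) and p28 (46) this gives
  [44, 51]. The window is re-derived from whatever reference sequences the
  run supplies, so a non-azurin control changes the window accordingly.
* **Reference anchoring.** p28 is located in azurin by exact substring
  match (unique occurrence required) rather than by hard-coded offsets; the
  bundled azurin sequence is the 148-residue precursor, in which p28 starts
  at position 70 (mature numbering 50, signal-peptide offset 20). p18 is
  the first 18 residues of the matched p28 span.
* **Non-standard residues** (B, Z, X, U, O) are rejected with an error
  naming the record and character; silently classifying them would corrupt
  the count.

### Stage 3: binding-interface comparison

* **Contact criterion.** Heavy-atom Euclidean distance ≤ 5.0 Å, inclusive,
  between the receptor and ligand chains. No contact rule is stated with
  the original interface listings; 5.0 Å heavy-atom is the common
  convention and the cutoff is a CLI/config parameter (`--cutoff`) so users
  can match alternatives (4.5 Å etc.). The neighbour search uses a k-d tree
  (`scipy.spatial.cKDTree`) but the contract is the brute-force all-pairs
  result; the test suite checks exact set equality against an independent
  all-pairs scan on 100 random complexes.
* **Residue identity.** (chain id, residue number, insertion code) on the
  receptor; all compared complexes share the same receptor numbering, so no
  alignment is attempted.
* **Overlap.** shared = |query ∩ reference| receptor residues; percent =
  100 × shared / |reference|, half-up to 2 d.p. in exact arithmetic.
* **Classification.** Azurin-like ⟺ shared ≥ 1 with *both* the p28 and the
  azurin reference interfaces. A candidate overlapping only one reference
  (the p2seq33 pattern: 0 shared with p28, 4 with azurin) is rejected.
* **Polarity.** N/O polar, C/S nonpolar, other heavy elements polar with a
  logged warning; hydrogens are an error at this level and are ignored by
  all interface operations (docked models typically lack them). Sulfur's
  assignment is debatable; the rule is isolated in `atom_polarity` for
  substitution. Composition percentages count *unique* interface atoms, not
  contact-pair participations — the alternative reading is noted as
  unresolved.
* **PDB input.** Read with Biopython's `PDBParser`: first model only;
  alternate locations resolved to the highest-occupancy conformer (ties fall
  back to the first-encountered altloc, normally 'A').

### Reference interface sizes

The published per-candidate overlap table reports shared counts and
percentages but not the reference interface sizes. The sizes are implied:
`datasets.recover_reference_sizes` searches all integer denominators up to
400 for the unique value reproducing every printed percentage to half a
unit in the last decimal place, yielding 30 (p28 reference) and 25 (azurin
reference). The search demands uniqueness and fails loudly otherwise.
Notably, the narrative residue ranges given alongside the table enumerate
33 and 29 residues — inconsistent with the printed percentages; the package
follows the table's own arithmetic and otherwise reports whatever its set
operations yield on actual inputs.

## Synthetic data: what it emulates, what it does not

Two pipeline inputs have no redistributable real counterpart: the
81-sequence annotation table of the original screen, and the docked
candidate/p53 poses. The `synthetic` module generates stand-ins whose
ground truth is known by construction:

* **Annotation tables** (default 81 sequences, 28 planted): planted ids
  draw all three category odds from (1.1, 10.0), guaranteeing product > 1;
  background ids draw from (0.1, 0.9), product < 1. The margin around 1
  makes selection recovery exact by construction. Probabilities are odds
  times a fixed per-group prior (F 0.05, EZ 0.08, GO 0.1 — chosen so
  probability ≤ 1 for any drawable odds), making the probability score an
  exact affine shift of the odds score, hence Pearson r = 1. This is a
  structural analogue of the original screen's strong odds/probability
  agreement, not a reproduction of its r = 0.998.
* **Peptides**: length uniform in a range, exactly round(L × target/100)
  hydrophobic residues planted and shuffled; the demo screen plants decoys
  at 70% HPP so the window filter's rejection branch is exercised.
* **Complexes**: the receptor is a line of single-atom pseudo-residues
  spaced 2.5 × cutoff apart (no accidental contacts possible); planted
  contact atoms sit at cutoff − 0.5 Å and decoy ligand atoms at 5 × cutoff.
  The ±0.5 Å margin makes recovery insensitive to floating-point noise.
  One heavy atom per receptor residue keeps the brute-force oracle trivially
  auditable. Elements of contact atoms are assignable to realise any
  polar/nonpolar composition. The geometry is deliberately unphysical — no
  rotamers, sterics or energetics — so passing tests certify the contact
  and set arithmetic, not docking realism.
* **Demo screen** (`generate_demo_screen` / `azulike simulate`): bundles
  the real 14-candidate panel with synthetic stages planting the published
  structure end to end — 28 of 81 selected by score, 14 retained by the
  window, per-candidate interface overlaps equal to the published shared
  counts (references planted as receptor residues 1–30 and 20–44, matching
  the recovered sizes 30 and 25), and hence 8 final candidates.

All generators take one seeded `numpy.random.Generator` per spec; no global
RNG state, and identical spec + seed gives byte-identical FASTA/TSV/PDB.

## What passing tests do and do not show

Exact reproduction is achieved for everything derivable from the bundled
panel: all 16 published HPP integers, the control odds product 65.5, the
[44, 51] window retaining all 14 candidates, the overlap percentages and
the 8-candidate classification. The parts of the original study that
depend on unavailable inputs — the real 28-of-81 annotation selection, its
r = 0.998, structure-model quality statistics, and the identity of the real
docked interface residues and their atom compositions — are *not*
reproduced; the synthetic analogues demonstrate that the implemented
operations recover planted truths exactly, which is a statement about the
code, not about the original data.

## Problem sizes and numerical choices

The test suite runs synthetic studies at the study's own scale (81
annotated sequences, 14-candidate panels, complexes up to ~500 atoms, 100
random complexes for oracle equivalence) and completes in a few seconds.
Percentages are rounded half-up (integer for HPP, 2 d.p. for interface
percentages) in exact rational arithmetic; distance comparisons are
inclusive at the cutoff; interface equality tests assert exact set
equality, with 1e−9-scale epsilons only where a rigid-motion test crosses
floating-point rotation error.

## Known limitations

* The screen is correlative: none of the three stages models binding
  energetics, and "same region" is a set-intersection statement, not an
  affinity statement.
* The annotation-odds score inherits whatever biases the upstream
  functional predictor has; the package never re-implements or validates
  that predictor.
* The hydrophobicity filter is a binary residue count; amphipathicity,
  charge and structure are out of scope.
* Interface extraction assumes the docked poses share the receptor's
  numbering; comparing across different receptor constructs would require
  alignment the package does not attempt.
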