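# Methods

## The assessment model

A fold-switching pair consists of two experimentally determined
reference structures that share one sequence but differ in secondary
and/or tertiary structure over a defined *fold-switching region*
(author-numbered, inclusive intervals, one spec per reference).  Every
predicted model of the pair is scored against both references over that
region and labeled:

- region TM-score > 0.6 against exactly one reference → that fold;
- above 0.6 against both → the larger score wins (an exact tie is
  broken to Fold1, deterministically);
- otherwise, including equality with 0.6, → OTHER (an experimentally
  unobserved conformation).

Fold1 is the reference with the higher region TM-score in a majority of
a designated baseline run (with the canonical 5-model baseline this is
the at-least-3-of-5 rule); even-split votes fall back to the larger
mean region TM-score and are flagged.  A conformation counts as
predicted when at least one model carries its label (N_ij ≥ 1); a pair
succeeds when both conformations are predicted; the success rate is the
fraction of pairs that succeed.  Pairs are labeled Complex when the
whole-structure backbone RMSD between the two references exceeds 10 Å,
**or** the region TM-score between them falls below 0.5, **or** the pair
is an amyloid / domain swap; otherwise Easy.  The disjunctive reading
is deliberate: either criterion alone marks a hard structural change,
and the amyloid route is an independent addition.  The false-positive
rate is the fraction of confident models (mean plDDT ≥ 70) labeled
OTHER, undefined (reported absent) when no model is confident.

## TM-score without structural alignment

Predicted and experimental structures share a sequence, so the
residue-to-residue correspondence is fixed by identity (positional when
sequences are equal, otherwise by author numbering) rather than found
by sequence-independent structural alignment.  The TM-score therefore
optimizes only the superposition:

    TM = max over superpositions of (1/L) Σᵢ 1 / (1 + (dᵢ/d₀(L))²)
    d₀(L) = 1.24 (L − 15)^⅓ − 1.8, floored at 0.5 Å

Superpositions are seeded from the full correspondence and from
contiguous fragments of length L/2 and L/4 (minimum 4; start, middle
and end placements).  Each seed is refined by re-superposing (Kabsch)
on the residues whose current distance lies below an inclusion cutoff
that starts at d₀ and escalates ×1.5 whenever fewer than 4 residues
qualify, iterating to a fixed point (50-iteration cap).  The best seed
wins; exact ties keep the earliest seed.  L is the number of reference
residues in the assessed region, i.e. scores are normalized by the
reference, and the normalization is recorded in the result object.
This is a deliberate, documented divergence from full dynamic-
programming structural alignment, which is out of scope.  The d₀ floor
keeps short fold-switching regions scorable.

Backbone RMSD uses atoms {N, CA, C, O} of all corresponding residues
(pairs incomplete for the atom set are dropped with a warning) and the
closed-form Kabsch minimum.  Correctness of the superposition is tested
against an independent oracle: an exhaustive Euler-angle grid search
(10° sweep, 1° local refinement) on small point sets.

## Confidence machinery

Per-residue plDDT is read from the CA B-factor column; a chain whose
maximum is ≤ 1.0 is treated as the 0–1 dialect and rescaled (the
detection can be overridden).  The confidence fraction is the percent of
residues with plDDT ≥ 70 (boundary inclusive); categories are Medium /
Good / High at ≥ 70 / 80 / 90% and pools are cumulative (Medium
contains Good contains High).  Reranking is fully deterministic:
descending confidence fraction, ties by descending mean plDDT, then
model id; Top1/Top10 are prefixes of this order, and an ensemble
smaller than 10 is its own Top10.  The exact one-sided binomial test
(scipy's exact tail sums) backs enrichment comparisons between pools;
the complement identity P(X ≤ k) + P(X ≥ k+1) = 1 is property-tested
against an exact rational-arithmetic enumeration.

## Alanine masking

An 11-residue window slides in steps of 1 across the fold-switching
region (region length − 10 windows; shorter regions are an error).
For each window, the masked set is every chain position with a heavy
atom within 4.0 Å of any window-residue heavy atom **and** more than 4
positions from every window residue in primary sequence — so the window
itself and its sequence neighborhood are never masked.  Contacts are
computed on the Fold1 reference by default (configurable).  In every
MSA row except the target, the corresponding match columns become 'A';
gaps and A3M lowercase insertions are untouched, and non-standard
letters (B/Z/X) are masked like any residue.  Byte-identical masked
alignments from nearby windows collapse to the earliest window.  On
side-chain-free synthetic backbones the 4 Å all-atom scale has no
geometric meaning, so synthetic sweeps use an 8 Å backbone-contact
probe; the cutoff is a parameter everywhere and is stamped into
manifests.

## Template preparation and fold ranking

Templates keep only {N, CA, C, O, CB}.  Glycine receives an ideal Cβ:
direction from the standard local-frame construction (linear
combination of CA−N, C−CA and their cross product), placed at exactly
1.522 Å from CA so the bond length is independent of small
backbone-geometry deviations; the construction is rigid-motion
equivariant.  MSE → MET (SE → SD) and SEC → CYS (SE → SG), retyping
selenium to sulfur.  The fold-ranking composite is
(plDDT/100)ᵃ · pTMᵇ · TMᶜ with default unit exponents — the three
ingredients are fixed but their combination is this package's
documented choice; reports record the formula used.  The per-pair
preference is simply the larger composite, with exact ties flagged
undecided.

## Flexibility and contact probes

Normalized B-factors use the sample (n−1) standard deviation
(recorded in the profile); constant B-factors are a degenerate-input
error, not a silent zero.  A residue is flexible at BF_norm ≥ 2.0
(inclusive).  Region summaries report both readings of "flexible
region" — any residue over the cutoff, and the fraction over it — so
either convention can be checked.  Contact maps default to Cβ atoms
(Cα for glycine), 8 Å cutoff, minimum intrachain sequence separation 5;
interchain contacts are unrestricted and tagged intermolecular.  All
parameters are stamped into the map and compared maps warn on
mismatched parameters.

## Synthetic data: what it emulates and what it does not

Backbones are grown by natural-extension-reference-frame placement with
ideal bond geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; trans
peptide) and canonical dihedrals: helix φ=−57°, ψ=−47°; strand φ=−139°,
ψ=+135°; coil sampled from broad allowed Ramachandran basins under the
seed.  A toy pair shares one random sequence; its two secondary-
structure strings differ exactly and only inside the fold-switching
region (default: 80 residues, region 25–60, helix vs strand, short coil
linkers so geometry varies with seed), regenerated until the region
TM-score between references is below 0.5.

Ensembles plant a three-class mixture: near-fold classes are the
reference perturbed by Gaussian noise rescaled to a target backbone
RMSD (within 5%; default 0.8 Å, the scale of a good prediction's
deviation from its target), decoys are independently generated shuffled-
secondary-structure folds regenerated until their region TM-score to
both references is ≤ 0.5 — so the returned ground-truth labels are true
by construction.  The class composition matches the mixture weights
exactly (largest-remainder rounding, seeded shuffle of assignment
order), making planted fractions sharp ground truth for recovery tests
rather than adding a layer of sampling noise.  Per-residue plDDT is
drawn per class (aligned polarity: correct classes ~85/82, decoys ~55;
anti-correlated polarity: decoys ~88, correct classes ~60; sd 4–8,
clipped to [0, 100]) and written into the B-factor column.

These toys reproduce the statistical structure of a benchmark —
mixture fractions, confidence/correctness correlation, region-
restricted structural differences — with protein-like local geometry.
They do **not** carry side chains, packing, or physical energetics, so
passing tests demonstrate the correctness of the assessment machinery,
not predictor behavior on real proteins.

## Numerical and interface choices

- Thresholds: region TM 0.6 (equality → OTHER, strict inequality);
  plDDT 70/80/90 boundaries inclusive; flexibility 2.0 inclusive;
  difficulty wRMSD strictly > 10 Å, region TM strictly < 0.5.
- Altlocs resolve to highest occupancy, ties to the alphabetically
  first altloc id.  HETATM residues are dropped except MSE/SEC.
  Residues missing requested atoms are excluded with a logged warning;
  regions with no aligned residues are errors, not empty results.
- All user-facing regions use author numbering (inclusive; insertion
  codes preserved in I/O but ignored for interval membership); a
  contiguous 0-based index is maintained internally.
- Every generator takes an explicit seed; derived seeds stay below
  2³¹.  Reports echo effective configuration.
- Problem sizes in the test suite and the acceptance script (500-model
  ensembles over five seeds, six-pair success benchmark, 100-model
  confidence studies) are chosen so the full study runs in about a
  minute on one CPU while keeping binomial intervals tight.

## Known limitations

- No sequence-independent structural alignment: chains must share a
  sequence or a consistent author numbering.
- The TM-score superposition search is heuristic (fragment seeds +
  refinement); it is exact on self/rigid pairs and validated against
  construction oracles, but is not guaranteed to find the global
  optimum on pathological inputs.
- Template preparation annotates but does not model chain breaks, and
  no gap rebuilding is attempted.
- Coevolution couplings are read from externally computed pair lists,
  never computed here; predictors are never executed.
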