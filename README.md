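# foldswitch

Dual-conformation assessment of structure-prediction ensembles for
**fold-switching proteins** — proteins whose single sequence adopts two
experimentally determined folds with distinct secondary or tertiary
structure over a *fold-switching region*.

Deep-learning structure predictors emit one model (or an ensemble) per
sequence, so judging them on fold switchers needs machinery that scores
every predicted model against **both** experimental references and asks
whether the ensemble captures each conformation, whether the model
confidence tracks correctness, and how hard each pair is.  This package
provides that machinery for computational structural biologists
benchmarking predictors (AlphaFold-style ensembles or otherwise):

- **Structure I/O** (`foldswitch.structure_io`): PDB/mmCIF chains with
  altloc resolution, per-residue backbone coordinates and plDDT read
  from the B-factor column.
- **Superposition metrics** (`foldswitch.superpose`): Kabsch rigid
  superposition, backbone RMSD, and the TM-score

  TM = (1/L) Σᵢ 1 / (1 + (dᵢ/d₀(L))²),  d₀(L) = 1.24 (L−15)^⅓ − 1.8 (floor 0.5 Å)

  over a same-sequence residue correspondence, restricted to
  author-numbered regions and normalized by the reference length.
- **Dual-fold assessment** (`foldswitch.assessment`): Fold1/Fold2
  ordering by baseline majority (the 3-of-5 rule), per-model labels
  FOLD1 / FOLD2 / OTHER at region TM-score threshold 0.6, pair success
  (a conformation is predicted if N_ij ≥ 1), Easy/Complex difficulty
  (wRMSD > 10 Å or region TM < 0.5 or amyloid/domain swap), and the
  false-positive rate of confident-but-unobserved predictions
  (mean plDDT ≥ 70, label OTHER).
- **Confidence reranking** (`foldswitch.confidence`): percent of
  residues with plDDT ≥ 70, Medium/Good/High categories (≥70/80/90%),
  Top1/Top10/All tabulation, exact one-sided binomial tests.
- **MSA alanine masking** (`foldswitch.msa`): 11-residue windows sliding
  over the fold-switching region; residues within 4 Å of a window but
  more than 4 positions away in sequence are mutated to alanine in every
  row except the target, erasing their coevolutionary signal.
- **Template preparation** (`foldswitch.template_prep`): backbone+Cβ
  templates (ideal Cβ added to glycine, MSE/SEC standardized) and the
  composite fold-ranking score (plDDT/100)·pTM·TM.
- **Structure probes** (`foldswitch.probes`): normalized B-factors
  BF_norm = (BF − μ)/σ with flexibility at ≥ 2.0, contact-map
  comparison with coevolution overlays, residue-distance probes.
- **Synthetic data** (`foldswitch.synthetic`): idealized backbones from
  canonical dihedrals, fold-switch pairs, and prediction ensembles with
  planted class mixtures and confidence polarity — ground truth for
  validating every stage.

The public face is the Python API plus the narrative scripts in
`examples/`; a thin `foldswitch` CLI (subcommands `simulate`, `assess`,
`rerank`, `mask-msa`, `template-prep`, `bfactor`, `contacts`, `probe`)
wraps the same pipeline functions for shell use.

## Worked example

`examples/01_assess_synthetic_ensemble.py` builds a synthetic pair
(helix↔strand switch over residues 25–60 of an 80-residue chain), draws
a 100-model ensemble planted at 60% near-fold-A / 10% near-fold-B /
30% decoys, and assesses it:

```
fold order: reference A is Fold1
label counts: {'FOLD1': 60, 'FOLD2': 10, 'OTHER': 30}
planted:      A=60 B=10 OTHER=30
success (fold1, fold2, both): True, True, True
difficulty: COMPLEX
```

The assessment recovers the planted mixture exactly: each model is
labeled by its fold-switching-region TM-score against both references
(>0.6 claims a fold, the larger score wins when both exceed it), and
the pair is Complex because its two references differ by >10 Å
whole-structure RMSD with region TM < 0.5.  The pair succeeds because
at least one model matches each fold.

`examples/02_rerank_by_confidence.py` plants confidence *against*
correctness and shows the confident-but-wrong regime the reranking
machinery is built to expose:

```
OTHER fraction, All pool:  0.30
OTHER fraction, Top1 pool: 1.00
false positive rate among confident models: 1.00
```

The other examples cover the masking sweep (46 windows over a
56-residue region), template preparation with composite fold ranking,
and the flexibility/contact probes.

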