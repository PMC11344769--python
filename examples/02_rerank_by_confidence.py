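"""Confidence reranking when plDDT opposes correctness.

Plants an ensemble whose decoys carry the *highest* confidence
(anti-correlated polarity), reranks by percent of confident residues,
and compares the OTHER fraction in the Top1 pool vs the whole pool —
the confident-but-wrong regime.
"""

from foldswitch.pipeline import assess_ensemble
from foldswitch.synthetic import EnsembleSpec, ToyPairSpec, make_ensemble, make_toy_pair

pair = make_toy_pair(ToyPairSpec(seed=0))
models, _ = make_ensemble(
    pair,
    EnsembleSpec(n_models=100, weights=(0.4, 0.3, 0.3),
                 plddt_polarity="against", seed=8),
)
assessments, summary, tab = assess_ensemble(pair, models, fold_order="A")

top1 = tab.pool_fraction("Top1", "OTHER")
allp = tab.pool_fraction("All", "OTHER")
print(f"OTHER fraction, All pool:  {allp:.2f}")
print(f"OTHER fraction, Top1 pool: {top1:.2f}")
print(f"false positive rate among confident models: "
      f"{summary.false_positive_rate:.2f}")

# When confidence anti-correlates with correctness, reranking by plDDT
# pushes experimentally unobserved conformations to the top: the Top1
# OTHER fraction exceeds the ensemble-wide fraction, and essentially all
# confident (mean plDDT >= 70) models are wrong.
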