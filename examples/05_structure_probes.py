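"""Flexibility, contact-map and distance probes.

Normalized B-factors flag flexible residues (BF_norm >= 2.0); contact
maps of two conformations are partitioned into unique/common sets; a
residue-pair distance tracks an open/closed conformational coordinate.
"""

import numpy as np

from foldswitch.probes import (
    compare_contact_maps,
    contact_map,
    normalize_bfactors,
    region_flexibility,
    residue_distance,
)
from foldswitch.synthetic import ToyPairSpec, make_ideal_backbone, make_toy_pair

# flexibility: a chain with one mobile tail residue
model = make_ideal_backbone("H" * 12, seed=0)
bfs = [12.0] * 11 + [55.0]
for res, v in zip(model.residues, bfs):
    for a in res.atoms.values():
        a.bfactor = v
prof = normalize_bfactors(model)
print(f"BF mean {prof.mu:.1f}, sd {prof.sigma:.1f} ({prof.sd_convention})")
print(f"max BF_norm {prof.bf_norm.max():.2f}; "
      f"flexible residues: {int(prof.flexible.sum())}")
print(f"core region 1-11: {region_flexibility(prof, model, [(1, 11)])}")

# contact maps of the two folds of a pair
pair = make_toy_pair(ToyPairSpec(seed=0))
cm_a = contact_map(pair.ref_A, cutoff=10.0, atom_mode="CA")
cm_b = contact_map(pair.ref_B, cutoff=10.0, atom_mode="CA")
ua, ub, common = compare_contact_maps(cm_a, cm_b)
print(f"contacts unique to fold A: {len(ua)}, unique to fold B: {len(ub)}, "
      f"common: {len(common)}")

# a domain-closure style distance probe
d = residue_distance(pair.ref_A, 10, 70)
print(f"CA distance 10-70 in fold A: {d:.1f} Å")
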