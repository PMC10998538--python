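"""Select reliable negative pairs with the three PU-learning strategies.

Only positive associations are curated; every other pair is unlabelled.
Spy, PU bagging and two-step each nominate pairs that are safe to treat
as negatives; the combined set is their union.
"""

from pirdap import RunConfig, disease_similarity, pirna_similarity
from pirdap.pul import (PairFeatureMap, bagging_select, combine_union,
                        spy_select, two_step_select)
from pirdap.synthetic import SyntheticSpec, generate

dataset, ontology, truth = generate(
    SyntheticSpec(m=60, n=10, density=0.1, reveal_frac=0.7, seed=4))
config = RunConfig(rf_estimators=100, bag_estimators=30, n_bags=10,
                   bag_rounds=2)

S_p = pirna_similarity(dataset.pirnas, dataset.A)
S_d = disease_similarity(ontology, dataset.diseases, dataset.A)
feats = PairFeatureMap(S_p.M, S_d.M)
positives = dataset.positive_pairs()
unlabelled = dataset.unlabelled_pairs()
hidden = {p for p in unlabelled if truth[p] == 1}

selections = {
    "spy": spy_select(positives, unlabelled, feats, config, seed=0),
    "bagging": bagging_select(positives, unlabelled, feats, config, seed=1),
    "two-step": two_step_select(positives, unlabelled, feats, config, seed=2),
}
union = combine_union(list(selections.values()))

print(f"{len(positives)} known positives, {len(unlabelled)} unlabelled pairs "
      f"({len(hidden)} of them hidden true positives)")
for method, s in selections.items():
    caught = len(s.pairs & hidden)
    print(f"{method:>9}: {len(s):4d} reliable negatives "
          f"({caught}/{len(hidden)} hidden positives wrongly included)")
print(f" combined: {len(union):4d} (union)")
# a selective method keeps hidden positives out of its negative set;
# spy and bagging discriminate while two-step is deliberately permissive
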