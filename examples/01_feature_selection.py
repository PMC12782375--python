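"""Dual-filter feature selection on a synthetic descriptor table.

Generates 1,000 compounds x 200 descriptors with 10 planted informative
descriptors, ranks every descriptor by mutual information, forest impurity
and boosting gain, fuses the three rankings by average rank, and selects
the top 20.
"""

from dffs_qsar import SyntheticConfig, generate_dataset, select_features

cfg = SyntheticConfig.dffs_benchmark(seed=0)
descriptors, activity, _, truth = generate_dataset(cfg)

result = select_features(descriptors, activity.pic50, k=20, seed=0)
hits = set(result.selected_names) & set(truth.informative_activity)

print(f"selected {result.k} of {descriptors.n_descriptors} descriptors")
print("top 5 by fused average rank:", result.selected_names[:5])
print(f"planted informative recovered: {len(hits)}/{len(truth.informative_activity)}")
print(
    "\nEvery selected descriptor carried signal for the activity target in at\n"
    "least one of the three filters; recovering all 10 planted descriptors\n"
    "means the fused ranking separated signal from the 190 noise columns."
)
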