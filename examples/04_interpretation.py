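"""Association analysis and Shapley attributions.

Computes the endpoint-by-endpoint phi coefficient matrix with chi-square
significance stars, then explains a fitted activity model with exact
tree-Shapley attributions and a global mean-|attribution| ranking.
"""

import numpy as np

from dffs_qsar import (
    RegressorSpec,
    SyntheticConfig,
    compute_attributions,
    fit_regressor,
    generate_dataset,
    global_importance,
    phi_association_matrix,
)

cfg = SyntheticConfig(n_compounds=3000, n_descriptors=60,
                      n_informative_activity=6, n_informative_admet=9,
                      n_constant_zero=0, seed=2)
descriptors, activity, admet, truth = generate_dataset(cfg)

print("phi association matrix (stars: *** p<0.001, ** p<0.01, * p<0.05):")
print(phi_association_matrix(admet).annotated().to_string())

model = fit_regressor(
    RegressorSpec("hist_boosted_trees", seed=2), descriptors, activity.pic50
)
attr = compute_attributions(model, descriptors.subset_compounds(
    descriptors.compound_ids[:500]))
ranking, _export = global_importance(attr)
print("\ntop 5 descriptors by mean |attribution| (pIC50 units):")
for name, value in zip(ranking.descriptor_names[:5],
                       ranking.mean_abs_attribution[:5]):
    flag = "planted" if name in truth.informative_activity else "noise"
    print(f"  {name}  {value:.4f}  ({flag})")
check = np.abs(attr.attributions.sum(axis=1) + attr.base_value
               - model.predict(descriptors.values[:500])).max()
print(f"\nlocal accuracy: max |sum(phi)+base-prediction| = {check:.2e}")
print(
    "A positive attribution pushes that compound's predicted pIC50 above the\n"
    "training mean; the planted informative descriptors should dominate the\n"
    "ranking, and the attributions reconstruct every prediction exactly."
)
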