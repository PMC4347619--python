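"""Fit a lasso-logistic regularization path with inner-CV penalty selection.

Shows the sparsity/deviance trade-off along the penalty grid and which
features the selected model keeps.
"""

import numpy as np

from omicstack import SubtypeSpec, SyntheticConfig, generate_dataset
from omicstack.folds import make_inner_folds
from omicstack.lasso import fit_lambda_path

config = SyntheticConfig(
    n_samples=150,
    n_features_gep=400,
    n_features_dmp=10,
    subtypes=[SubtypeSpec("target", 0.25, 25, 0, 2.5, 0.0, "gep_only")],
    seed=4,
)
gep, _, labels, truth = generate_dataset(config)
y = labels.y("target")

path = fit_lambda_path(
    gep.values, y, make_inner_folds(y, k=5, seed=0),
    grid_size=30, feature_ids=gep.feature_ids,
)

print("lambda      nnz   cv-deviance")
for i in range(0, 30, 4):
    print(f"{path.grid[i]:.5f}  {path.models[i].n_selected:4d}   {path.cv_deviance[i]:.4f}")
print(f"\nnull-model deviance: {path.null_deviance:.4f}")
print(f"selected lambda: {path.selected_lambda:.5f} "
      f"(grid point {path.selected_index}, {path.selected_model.n_selected} features)")

selected = set(path.selected_model.nonzero_index.tolist())
planted = set(truth.planted_gep["target"])
print(f"planted-feature recall: {len(selected & planted) / len(planted):.2f}, "
      f"precision: {len(selected & planted) / len(selected):.2f}")
# The first grid point (lambda_max) keeps zero features; the selected lambda
# sits where held-out binomial deviance bottoms out, recovering most of the
# planted columns with few false selections.
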