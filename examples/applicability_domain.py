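"""Leverage-based applicability domain and Williams-plot data.

A model is only trusted where its training data supports it: compounds
with leverage above h* = 3(p+1)/n are structurally outside the training
space, and |standardized residual| > 3 marks response outliers.
"""
import pandas as pd

from qsarforge import fit_ols, warning_leverage, williams_data
from qsarforge.synthetic import SyntheticSpec, generate_dataset

dataset, truth = generate_dataset(
    SyntheticSpec(n_compounds=30, n_descriptors=4, n_informative=2, noise_sd=0.1, seed=5)
)
partition = pd.Series(
    ["train"] * 22 + ["test"] * 8, index=dataset.table.data.index
)
dataset = dataset.with_partition(partition)

# push one test compound far outside the training descriptor space
dataset.table.data.iloc[-1] += 8.0

train = dataset.subset("train")
model = fit_ols(train.table, train.y)
h_star = warning_leverage(p=4, n=22)
print(f"warning leverage h* = 3(4+1)/22 = {h_star:.4f}\n")
print(f"{'compound':>9s} {'leverage':>9s} {'std.resid':>10s}  in domain")
for r in williams_data(model, dataset):
    flag = "yes" if r.in_domain else "NO"
    print(f"{r.compound_id:>9s} {r.leverage:9.4f} {r.standardized_residual:10.3f}  {flag}")
print("\nCompounds marked NO lie outside the model's applicability domain;")
print("predictions for them should not be trusted.")
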