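"""Recompute the published QSAR headline numbers from the bundled tables.

The model equation's ETA_Shape_P coefficient lost its decimal point in
print; the package recovers it by a one-unknown least-squares solve over
the eight external-validation rows, then checks every printed statistic.
"""
from qsarforge import load_fixture, paper_model, predict, reproduce_paper

model = paper_model()
print("completed model:")
for name, coef in zip(model.descriptor_names, model.coefficients):
    print(f"  {name:12s} {coef:+.6f}")
print(f"  intercept    {model.intercept:+.6f}")

table5 = load_fixture("table5")
pred = predict(model, table5.table.select(list(model.descriptor_names)))
print("\nexternal test-set predictions (computed vs printed):")
for cid, yhat, printed in zip(
    table5.compound_ids, pred, table5.table.data["pIC50_pred"]
):
    print(f"  compound {cid:>2s}: {yhat:.4f} vs {printed:.4f}")

report = reproduce_paper()
print("\npublished-value checks:")
for key, row in report["targets"].items():
    status = "PASS" if row["pass"] else "FAIL"
    print(f"  {status}  {key}: {row['computed']:.4f}")
print("\nEvery PASS line means the package recomputed that printed")
print("statistic from the bundled tables within its stated tolerance.")
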