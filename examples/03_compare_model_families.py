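"""Compare the seven tree-based model families on the held-out 20%.

Reports R2, MAE, RMSE, MSD and MAPE per family; tree-ensemble regression
is typically the strongest on this dataset.
"""

from budcast import compare_families, load_packaged_dataset

ds = load_packaged_dataset()
table = compare_families(ds, seed=4)
print(table[["r2", "mae", "rmse", "msd", "mape"]].round(3).to_string())
best = table["r2"].astype(float).idxmax()
print(f"\nBest family on held-out R2: {best} (R2={table.loc[best, 'r2']:.3f})")
# MAPE is a proportion (0.18 = 18% mean relative error); MSD near 0 means
# little systematic over/under-prediction.
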