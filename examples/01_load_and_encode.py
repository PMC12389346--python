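"""Load the packaged stability dataset and encode it as feature rows.

Prints the dataset summary, the composite classes of one API, and the
computed-vs-printed class delta report.
"""

from budcast import (
    dataset_summary,
    delta_report,
    featurize_dataset,
    load_packaged_dataset,
    molecular_structure_class,
    molecule_class,
)

ds = load_packaged_dataset()
print("Dataset summary:", dataset_summary(ds))
# 53 experimental records, 22 APIs, 6 excipients; storage from -20 to 40 degC.

mel = ds.apis["Melatonin"]
print(f"Melatonin MC={molecule_class(mel)} MSC={molecular_structure_class(mel)}")
# MC sums the MW/LogP/rotatable-bond classes (31); MSC the polar-surface,
# H-bond-donor/acceptor and aromatic-ring classes (6).

features = featurize_dataset(ds)
print(f"Encoded {features.shape[0]} records x {features.shape[1] - 1} features (+ bud_days)")

report = delta_report(ds)
n_off = ((report["mc_delta"] != 0) | (report["msc_delta"] != 0)).sum()
print(f"APIs whose printed MC/MSC disagree with the binning convention: {n_off}/22")
print(report[report["mc_delta"] != 0].head().to_string(index=False))
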