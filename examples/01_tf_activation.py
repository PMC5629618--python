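"""Fold changes and activated-TF calls on a tiny hand-built dataset.

A TF is activated when the mean fold change of its three most up-regulated
target genes (or all of them, if it has fewer than three) reaches 2.0.
"""

import pandas as pd

import moarank as mr
from moarank.io import TFTargetMap

# two tumour replicates vs two normal replicates, five genes
values = pd.DataFrame(
    {
        "T1": [8.0, 9.0, 10.0, 2.0, 10.0],
        "T2": [12.0, 11.0, 10.0, 2.0, 10.0],
        "N1": [2.0, 2.5, 10.0, 2.0, 10.0],
        "N2": [2.0, 2.5, 10.0, 2.0, 10.0],
    },
    index=["MYC", "CCND1", "GAPDH", "CDKN1A", "ACTB"],
)
expr = mr.ExpressionMatrix(
    values=values,
    groups={"T1": "case", "T2": "case", "N1": "control", "N2": "control"},
)
tfmap = TFTargetMap(
    targets={
        "E2F1": frozenset({"MYC", "CCND1", "GAPDH"}),   # proliferation targets
        "TP53": frozenset({"CDKN1A", "GAPDH"}),         # checkpoint targets
    }
)

profile = mr.compute_fold_change(expr)
print("fold changes:")
print(profile.values.round(2).to_string())

for act in mr.identify_activated_tfs(profile, tfmap, threshold=2.0):
    flag = "ACTIVATED" if act.activated else "not activated"
    print(f"{act.tf}: score {act.score:.2f} ({flag}); "
          f"contributing targets {', '.join(act.contributing_targets)}")

up = mr.upregulated_targets(
    mr.identify_activated_tfs(profile, tfmap), profile, tfmap, fc_threshold=2.0
)
print(f"up-regulated targets of activated TFs (fold change >= 2): {sorted(up)}")
# E2F1's top-3 targets average well above 2 -> activated; TP53's do not.
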