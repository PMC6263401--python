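"""Class balancing and correlation-based feature selection (CFS).

Balancing gives every class the same total instance weight while keeping
the grand total. CFS then searches feature subsets (forward best-first)
for high feature-class but low feature-feature correlation; redundant and
irrelevant columns are screened out.
"""

import numpy as np

import engage_fuse as ef
from engage_fuse.model import cfs_merit, cfs_select_table, class_correlations

cfg = ef.SimulationConfig(n_participants=2, n_trials=30, seed=9)
sessions = ef.generate_sessions(cfg)
table = ef.build_feature_table(sessions)

bw = ef.balance_weights(table["label"].to_numpy())
print("class totals before balancing:", dict(table["label"].value_counts()))
print("per-class weight totals after:", {k: round(v, 1) for k, v in bw.per_class_total.items()})

cols = ef.feature_columns("hybrid")
selected = cfs_select_table(table, cols)
X = table[cols].to_numpy(float)
y01 = (table["label"] == "high").astype(float).to_numpy()
r_cf, r_ff = class_correlations(X, y01)
merit = cfs_merit([cols.index(c) for c in selected], r_cf, r_ff)
print(f"\nCFS kept {len(selected)}/{len(cols)} features (subset merit {merit:.3f}):")
for c in selected:
    print(f"  {c}  (|r_cf| = {r_cf[cols.index(c)]:.3f})")
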