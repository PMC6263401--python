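"""Extract the 59-feature multimodal table for every labeled window.

34 EEG features (17 per electrode), 7 ECG features and 18 NIRS Hjorth
features per window; the class means below show how the latent state
shapes the physiology (engaged: more beta, faster heart, less vagal HF
power, larger hemodynamic slow waves).
"""

import engage_fuse as ef

cfg = ef.SimulationConfig(n_participants=1, n_trials=20, seed=3)
session = ef.generate_session(cfg, "P01")
labels = ef.label_session(session)
table = ef.extract_features(session, labels, "hybrid")

n_feat = len(ef.feature_columns("hybrid"))
print(f"{len(table)} windows x {n_feat} features")
show = ["eeg_relative_alpha_fz", "eeg_relative_beta_fz",
        "ecg_hr", "ecg_hf", "nirs_activity_oxy_fp1"]
print(table.groupby("label")[show].mean().T.round(3).to_string())

rel = [c for c in table.columns if c.startswith("eeg_relative") and c.endswith("fz")]
print("\nrelative band powers sum to", table[rel].sum(axis=1).round(12).unique())
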