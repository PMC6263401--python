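"""End-to-end experiment: simulate, label, extract, select, classify.

Runs the full pipeline for the hybrid table and each stand-alone modality
under stratified 10-fold cross-validation. Balancing weights and the CFS
subset are re-fit inside every training fold; the classifier is the
weighted-vote KNN with k = 9. Accuracies are mean +/- sd over folds.
"""

import engage_fuse as ef

cfg = ef.SimulationConfig(n_participants=4, n_trials=40, seed=5)
results = ef.run_experiment(
    ef.ExperimentConfig(cfg, split=ef.SplitPlan("kfold", folds=10, seed=5))
)

for modality, res in results.items():
    print(f"{modality:7s} accuracy {100 * res.accuracy_mean:6.2f} "
          f"+/- {100 * res.accuracy_sd:5.2f}%   "
          f"(features selected per fold: "
          f"{sorted(res.selected_counts.values(), reverse=True)[:3]}... )")

rep = results["hybrid"].report
print("\nhybrid per-class panel (pooled over folds):")
print(rep.to_frame().round(3).to_string())
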