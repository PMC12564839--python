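"""Run a small preprocess x selector x model experiment grid end to end.

Every cell preprocesses, selects bands on the training boxes only, trains,
and evaluates on the held-out boxes; artifacts land under the run directory
with a manifest. Desk-scale sizes keep this to about a minute.
"""

from grainspec.pipeline import ExperimentConfig, run_experiment, summarize_best

cfg = ExperimentConfig(
    n_varieties=5,
    boxes_per_variety=4,
    grid_rows=3,
    grid_cols=4,
    preprocess_methods=["RAW", "SNV"],
    selectors=["NONE", "CARS"],
    models=["PLS-DA", "SVM"],
    test_boxes_per_class=1,
    run_cv=False,
    seed=2,
    out_dir="runs/demo_grid",
    selector_params={"CARS": {"n_runs": 15, "n_folds": 3, "n_components": 5}},
    model_params={"PLS-DA": {"n_components": 6}, "SVM": {"C": 10.0, "gamma": "scale"}},
)
report = run_experiment(cfg)
cols = ["preprocess", "selector", "model", "n_selected", "reduction_pct",
        "test_accuracy", "f1"]
print(report.table[cols].to_string(index=False))
best = summarize_best(report)
print(f"\nbest cell: {best['preprocess']}-{best['selector']}-{best['model']} "
      f"(F1 {best['f1']:.2f}%)")
# One row per grid cell; selection JSON, confusion matrices, per-class metrics
# and predictions are written under runs/demo_grid/cells/<cell>/.
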