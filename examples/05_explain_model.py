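"""Explain the fused-feature classifier: Shapley ranking + tree export.

Because the fused set is only 10 columns wide, Shapley values are
computed exactly (all 2^10 feature subsets enumerated) rather than
approximated.  The tree export prints a hand-traversable outline of one
forest member.
"""

from rfgr import (
    ClassifierSpec,
    RFGRConfig,
    SynthConfig,
    export_decision_tree,
    fit_spec,
    generate_balanced_dataset,
    generate_transfer_features,
    stratified_split,
    transfer_feature_importance,
)

dataset = generate_balanced_dataset(5, SynthConfig(master_seed=0))
train, test = stratified_split(dataset, 0.8, seed=0)
config = RFGRConfig(n_trees=50, recurrent_units=32, epochs=5, seed=0)
train_fs, test_fs, _ = generate_transfer_features(train, test, config)
fitted = fit_spec(ClassifierSpec("rf", seed=0), train_fs.X, train.y)

report = transfer_feature_importance(fitted, test_fs, test.y, method="shapley", seed=0)
print("transfer features ranked by mean |Shapley value|:")
print(report.to_frame().to_string(index=False))

export = export_decision_tree(fitted, tree_index=0, feature_names=train_fs.feature_names)
print("\nfirst two levels of tree 0:")
print(export.to_text(max_depth=2))
# High-ranked features are the class-probability columns the downstream
# forest actually splits on; the outline shows those thresholds directly.
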