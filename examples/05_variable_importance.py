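"""Out-of-bag permutation variable importance of a fitted forest.

For each trained-on feature j, VI_j is the ratio of the mean squared
prediction shift caused by permuting column j (on out-of-bag predictions)
to the post-permutation mean squared error.  Signal features move the
predictions a lot; noise features barely at all.
"""

from dcforest import (
    ForestConfig,
    SimulationSetting,
    fit_forest,
    generate,
    permutation_importance,
)

setting = SimulationSetting(model=1, setting=1, p=10, rho=0.5, seed=31)
train, _ = generate(setting)

model = fit_forest(train.X, train.y, ForestConfig(n_trees=300, seed=2))
report = permutation_importance(model, train.X, train.y, n_permutations=3, seed=4)

print("permutation importance VI_j (true signal: columns 0-3, "
      "coefficient 5 on column 0):")
for fid, vi in sorted(zip(report.feature_ids, report.vi), key=lambda t: -t[1]):
    bar = "#" * int(40 * vi / max(report.vi))
    print(f"  feature {fid:2d}: {vi:7.4f} {bar}")
print()
print("Column 0 dominates (largest coefficient); columns 1-3 follow; the")
print("noise columns' importances sit near zero.")
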