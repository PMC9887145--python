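"""Random-forest yield estimation with and without the lodging index.

Draws the default 132-plot feature table (yields carry a lodging penalty),
fits the 80/20 random-forest model with and without the LI column, and
prints test-set accuracy plus the residual-vs-LI slope for both.
"""

from uavyield.model import ModelConfig, compare_feature_sets, residual_vs_lodging
from uavyield.synthetic import ScenarioConfig, make_feature_table

table = make_feature_table(ScenarioConfig(), seed=1)
reports = compare_feature_sets(table, ModelConfig(rng_seed=15))
for fs, rep in reports.items():
    trend = residual_vs_lodging(rep, table[["plot_id", "LI"]])
    print(
        f"{fs:10s}: R2={rep.r2:.3f}  RMSE={rep.rmse:7.1f} kg/ha  "
        f"rRMSE={rep.rrmse:5.2f}%  residual-vs-LI slope={trend.slope:7.1f}"
    )
top = reports["with_LI"].importances.head(5)
print("\ntop-5 variable importances (with LI):")
print(top.round(3).to_string(index=False))
print("\nWithout LI the model overestimates heavily lodged plots (positive")
print("slope); adding LI recovers that yield loss and shrinks RMSE.")
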