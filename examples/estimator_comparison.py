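"""Small-sample estimator shoot-out: RMSE, MAE and bias at n = 5.

Reruns the estimator-comparison protocol at desk scale: 1000 exact
finite-T simulations with r = 0.5, T = 40, lambda ~ U[r, 1+r], all five
implemented estimators applied to each sample.
"""

from bdgrowth import StudyConfig, run_simulation_study

config = StudyConfig(
    n_values=(5,),
    r_values=(0.5,),
    T_values=(40.0,),
    replicates=1000,
    seed=7,
)
result = run_simulation_study(config)
table = result.summary.set_index("estimator")[["rmse", "mae", "bias"]].round(3)
print(table)
print(
    "\nReading the table: the mse-calibrated estimator buys the lowest RMSE "
    "with a deliberate downward bias; the bias-calibrated one is nearly "
    "unbiased; branch-length and MLE estimators overshoot at this n; 'inv' "
    "is the compromise with an exactly computable constant."
)
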