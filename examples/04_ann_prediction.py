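"""Train the neural-network defined approaches and predict EC3 with a CI.

Generates an 80-chemical synthetic training population with a known monotone
endpoint-potency relationship, fits a 25-run ensemble of the three-input
network (DPRA + h-CLAT + KeratinoSens), benchmarks it on the held-out split
and predicts one chemical's EC3 with its 95% ensemble interval.

The production configuration is 100 runs x 10,000 iterations (as used by
scripts/acceptance.py); this example trims both for a quick demonstration.
"""

from sensipod import (ANNConfig, ANNEnsemble, SyntheticSpec, benchmark,
                      generate_training_table, ghs_classify)

spec = SyntheticSpec(n_chemicals=80, seed=7)
table = generate_training_table(spec)

config = ANNConfig(variant="D_hC_KS", iterations=5000, seed=17)
ensemble = ANNEnsemble.fit(table, config, n_runs=25)

res = benchmark(ensemble, table, split="test")
print(f"held-out benchmark (n={res.n}): R^2 = {res.r_squared:.2f}, "
      f"RMSE_log10 = {res.rmse_log10:.2f}")

row = table[table.split == "test"].iloc[0]
pred = ensemble.predict({"avg_lys_cys": row.avg_lys_cys,
                         "mit_ug_ml": row.mit_ug_ml, "imax": row.imax})
print(f"chemical {row.chemical}: predicted EC3 = {pred.mean_ec3:.3f}% "
      f"(95% CI {pred.ci_low:.3f}-{pred.ci_high:.3f}, {pred.n_runs} runs)")
print(f"observed EC3 = {row.ec3_pct:.3f}%  ->  GHS {ghs_classify(pred.mean_ec3)} "
      f"predicted vs {ghs_classify(row.ec3_pct)} observed")

# The benchmark is computed in log10 EC3 space (the convention for potency
# models); the ensemble CI spans only the variability due to random weight
# initialization, which is why it is much narrower than inter-study LLNA CIs.
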