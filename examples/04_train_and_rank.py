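"""Train the per-drug model ensemble and rank drugs in held-out cell lines.

The full study: normalize, split 80/20 at the cell-line level, discover
markers on training lines only, compute and normalize D, select 14-60
predictor D features per drug by Spearman correlation, tune regressors by
repeated 10-fold cross-validation (leave-one-out for PLS/PCR), then predict
and rank drugs within each held-out line. Takes a few minutes on one core.
"""

import drugrank as dr
from drugrank.ranking import rank_drugs

omics, responses, truth = dr.generate_panel(dr.reference_settings())
config = dr.RunConfig(roster=("random_forest", "pls", "pcr"),
                      prediction_algorithms=("random_forest", "consensus"),
                      seed=1)
result = dr.run_study(omics, responses, config)
print(f"train lines: {len(result.train_lines)}, "
      f"held-out lines: {result.validation_lines}")

truth_val = truth.aac[result.validation_lines]
for algo in ("random_forest", "consensus"):
    rep = dr.evaluate(result.predictions[algo], truth_val)
    print(f"{algo:14s} median per-line Spearman rho = {rep.summary['median_rho']:.3f}, "
          f"max per-line MSE = {rep.summary['max_mse']:.3f}")
# rho compares the predicted drug ranking within each held-out line with the
# true one; MSE is on the AAC scale (0-1).

line = result.validation_lines[0]
ranking = rank_drugs(result.predictions["consensus"][line])
true_rank = rank_drugs(truth.aac[line])
print(f"\ntop 5 predicted drugs for {line}: {ranking[:5]}")
print(f"top 5 truly best drugs       : {true_rank[:5]}")
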