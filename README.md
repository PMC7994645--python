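# drugrank

Rank drugs by predicted efficacy within a single cancer sample from its
omics profile (phosphoproteomics, proteomics or transcriptomics).

Large drug screens measure the response of cell-line panels to hundreds of
compounds as AAC — the area above the dose–response curve, scaled so 0 means
no effect and 1 maximum cell killing. `drugrank` learns from such panels how
molecular profiles encode drug response, then predicts and ranks the
anti-proliferative efficacy of every modeled drug in a new sample, a step
toward choosing treatments from a tumor's proteomic phenotype rather than
its mutations alone.

## The method

For each drug *d* the pipeline:

1. **Discovers empirical markers of drug response (EMDRs).** Cell lines are
   split at the median AAC into relatively sensitive and resistant
   populations; each population is resampled into ten 90% subsets
   (`createMultiFolds`-style), the 10 × 10 subset pairs whose AAC values do
   not separate (Welch t, p ≥ 0.05) are discarded, and an empirical-Bayes
   moderated t-test contrasts feature abundance within each retained pair.
   Features with contrast coefficient ≥ +0.8 (on the centered/scaled
   abundance scale) and p < 0.05 in ≥ 80% of retained pairs become
   *sensitivity markers*; ≤ −0.8 gives *resistance markers*.

2. **Collapses markers into the distance metric D.** For sample *b*,

   D(d, b) = (S<sup>Q2</sup> − R<sup>Q2</sup>) + (S<sup>Q3</sup> − R<sup>Q3</sup>),

   the median (Q2) and third-quartile (Q3) of the sample's sensitivity-marker
   values minus the same statistics of its resistance-marker values. D is
   internally normalized — no reference sample is needed and adding a
   constant to a sample's profile leaves it unchanged — and tolerates
   missing markers (≥ 5 per side required).

3. **Selects predictors and trains an ensemble.** Each drug's D profile is
   Spearman-correlated with every drug's responses over training lines; per
   target drug the top 14–60 D features (≤ 30 per correlation direction,
   ≥ 7 per direction) become inputs to a roster of regressors — random
   forest, boosted rule committee, Bayesian ridge, PLS, PCR, RBF-SVR and two
   multilayer perceptrons — each tuned by repeated 10-fold cross-validation
   (3 repeats, RMSE loss; leave-one-out for PLS/PCR) on an 80% cell-line
   training partition. A consensus prediction averages random forest, PCR
   and PLS.

4. **Ranks and evaluates.** Drugs are ordered by predicted AAC within each
   sample; evaluation reports per-sample Spearman rho, RMSE/MSE,
   absolute-error bins (0.05/0.1/0.15/0.25) and rank-position differences,
   all also restricted to each sample's top-20 drugs.

A companion module profiles mode of action: hypergeometric enrichment
[a/b]/[c/d] of marker sets in pathway/kinase-substrate collections (GMT),
delta enrichment (sensitivity minus resistance side), and drug–drug
similarity scores from rescaled Pearson correlations of delta-enrichment
profiles.

Because discovery, selection, normalization and training must never see
held-out lines, the pipeline records which lines each stage touched and a
leakage guard aborts any contaminated run.

## Worked example

No external data are needed: `drugrank.generate_panel` builds cell-line
panels with planted ground truth (latent per-drug sensitivities that *are*
the AAC, markers tracking them linearly, drug clusters, replicates,
missingness). From `examples/04_train_and_rank.py`:

```python
import drugrank as dr

omics, responses, truth = dr.generate_panel(dr.reference_settings())
config = dr.RunConfig(roster=("random_forest", "pls", "pcr"), seed=1)
result = dr.run_study(omics, responses, config)
```

prints, on the five held-out cell lines:

```
random_forest  median per-line Spearman rho = 0.719, max per-line MSE = 0.057
consensus      median per-line Spearman rho = 0.788, max per-line MSE = 0.045

top 5 predicted drugs for CL04: ['drug22', 'drug16', 'drug04', 'drug10', 'drug09']
top 5 truly best drugs       : ['drug22', 'drug09', 'drug04', 'drug21', 'drug17']
```

rho compares the predicted within-line drug ranking against the true one
(1 = identical order); MSE is on the 0–1 AAC scale, so 0.05 corresponds to a
typical prediction error of ~0.2 AAC units. The other scripts in `examples/`
walk through panel simulation, marker discovery (with precision/recall
against the planted truth), the D metric, and enrichment/similarity.

The same stages are available from the shell:

```bash
drugrank simulate --out panel/
drugrank run-all --omics panel/omics.tsv --responses panel/responses.tsv \
    --replicate-map panel/replicate_map.tsv --out run/ --seed 1
```

## Limitations

The synthetic panels are the only validation target here: they emulate the
statistical structure the method assumes, not mass-spectrometric reality
(intensity distributions, batch effects, correlated features). See
`docs/methods.md` for the model, parameter and design details, and for what
passing tests do and do not establish about real panels.
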