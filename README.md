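# xprediction

Per-sample gene regulatory network estimation and explainable drug-response
classification for cancer cell-line screens.

Given a gene expression matrix, a drug-sensitivity table and a CRISPR
gene-dependency screen over common cell lines, the pipeline:

1. **Estimates one regulatory network per sample** by a kernel-weighted
   elastic net: for each anchor sample, other samples are weighted by a
   Gaussian kernel on drug-sensitivity distance and each target gene is
   regressed on candidate regulators, yielding coefficients that vary with
   the sensitivity score (`network_profiler`).
2. **Selects target genes** whose dependency profile correlates with the
   drug's sensitivity, computes per-sample **regulatory effects**
   (coefficient x regulator expression) and labels samples
   sensitive/resistant by the P10/P90 percentiles (`feature_builder`).
3. **Classifies** sensitive vs resistant cells from the flattened
   regulatory-effect matrices with an RBF-kernel SVM, random forest, or a
   six-hidden-layer neural network, evaluated by repeated stratified
   k-fold cross-validation (`predictor`).
4. **Explains** the classifier by ablating each edge's feature column,
   re-running repeated CV, and testing the accuracy shift with a pooled
   two-sample t-test; edges with p < 0.01 are the crucial interactions
   (`xprediction_explain`).
5. Derives **downstream marker sets**: edges present in every sample's
   network, drug-drug similarity by shared crucial edges, and
   class-exclusive sensitive/resistant marker edges (`marker_analysis`).

A fully seeded synthetic-data generator (`synthetic_data`) produces
datasets matching the generative model — sparse regulator-target
coefficients that vary smoothly with the modulator, linear-Gaussian
expression, and dependency scores correlated with the modulator for a
planted gene subset — with complete ground truth for recovery testing.

## Command line

Each stage is an `xpredict` subcommand writing plain-text artifacts
(CSV matrices, TSV edge tables, JSON manifests):

```sh
xpredict simulate --config sim.yaml -o data/
xpredict align --expr E.csv --sens S.csv --dep D.csv --drugs afatinib,gefitinib -o aligned/
xpredict networks --data aligned/ --modulator-drug afatinib -o stack/
xpredict features --stack stack/ --expr E.csv --sens S.csv --response-drug gefitinib -o feats/
xpredict predict --features feats/ --model ksvm --cv 10 --repeats 50 --seed 7 -o cv.json
xpredict explain --features feats/ --model ksvm --repeats 50 --alpha 0.01 --seed 7 -o importance.tsv
xpredict markers --stack stack/ --expr E.csv --sens S.csv --response-drug gefitinib -o markers/
```

`xpredict simulate` accepts a YAML file with `SimulationConfig` fields
(`n_samples`, `n_regulators`, `n_targets`, `edge_density`, `noise_sd`,
`coefficient_profile`, `seed`, ...). `xpredict networks` accepts a YAML file
with a `bandwidth` value (omit for leave-one-out selection) and a `penalty`
mapping (`lam`, `mixing`, `n_lambdas`, `cv_folds`, `cv_rule`, ...).

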