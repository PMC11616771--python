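# elisl

Early–late integrated ensemble learning for **synthetic-lethality (SL)
prediction** of gene pairs from multi-omics features.

Two genes are synthetic lethal when losing both kills a cancer cell while
losing either alone is tolerated — the mechanism behind PARP inhibitors in
BRCA-deficient tumours. This package predicts SL for a gene pair from five
heterogeneous data sources: context-free protein-sequence and PPI-network
embeddings, CRISPR gene-dependency profiles of cell lines conditioned on
mutation or expression alterations in the partner gene, and patient tissue
features (co-mutation survival, conditional expression, co-expression and
copy-number correlation). It is aimed at computational biologists who want
a supervised SL predictor that does not rely on the topology of known SL
labels, together with evaluation protocols that expose gene-selection
bias.

## The model

Each pair is described by k = 5 per-source feature matrices
X_i ∈ R^{N×f_i} (f = 1024, 64, 4, 4, 13). The framework trains k
single-source tree ensembles plus one early-integration model on the
concatenation X_{k+1} ∈ R^{N×Σf_i}, all with one shared hyperparameter
configuration chosen by sequential model-based search with 5-fold
cross-validated AUPRC. Each submodel's weight is its validation AUPRC
normalized over all submodels,

    w_i = p_i / Σ_{j=1..k+1} p_j,

and the prediction is the late-integration weighted average of class
probabilities,

    ŷ = Σ_{i=1..k+1} w_i ŷ_i.

Both random-forest (ELISL-RF) and gradient-boosted (ELISL-GB) submodels
are supported. Evaluation protocols include balanced 10-run train/test
splits, **double gene holdout** (zero gene overlap between train and test,
probing robustness to selection bias), cross-label-source evaluation, and
permutation feature-category importance (permuted/original error ratio,
error = 1 − AUPRC). A built-in synthetic multi-omics generator plants
recoverable SL signal in every source so the whole pipeline runs without
any external downloads. See `docs/methods.md` for the full model account.

## Worked example

Generate a synthetic world at the default study conditions (200 genes,
300 cell lines, 600 patients, 80 SL + 80 non-SL pairs, dependency shift
δ = 1.0, co-expression r = 0.6, survival hazard ratio h = 0.5), check the
planted effects, then train and evaluate an ELISL-RF model on one balanced
held-out split:

```python
from elisl import FitConfig, SyntheticWorldConfig, fit, generate_world, predict, verify_planted_effects
from elisl.evaluation import auprc, auroc, make_standard_runs
from elisl.pipeline import featurize_world

world = generate_world(SyntheticWorldConfig(seed=1))
print(verify_planted_effects(world).to_string(index=False))

blocks = featurize_world(world)
run = make_standard_runs(world.labels, n_runs=1, seed=1001)[0]
train = [b.subset(run.train.pairs) for b in blocks]
test = [b.subset(run.test.pairs) for b in blocks]
model = fit(train, run.train, FitConfig("rf", search_budget=2, seed=1,
    grid={"n_estimators": [200], "max_depth": [8], "min_samples_leaf": [1, 5]}))
for s, w in zip(model.sources, model.weights):
    print(f"{s:12s} w = {w:.3f}")
y = run.test.frame["label"].to_numpy()
scores = predict(model, test)
print(f"held-out AUPRC = {auprc(y, scores):.3f}  AUROC = {auroc(y, scores):.3f}")
```

Output:

```
   parameter  configured  estimated       se  flag
       delta         1.0   0.996013 0.003926 False
    r_target         0.6   0.593932 0.002676 False
hazard_ratio         0.5   0.497658 0.142855 False
seq          w = 0.131
ppi          w = 0.162
crispr_mut   w = 0.199
crispr_expr  w = 0.129
tissue       w = 0.181
concat       w = 0.199
held-out AUPRC = 1.000  AUROC = 1.000
```

The diagnostics confirm each planted parameter is recovered by its natural
estimator within sampling error. The weights show the integration at work:
the mutation-conditioned CRISPR source (where the generator plants its
strongest signal) and the concatenation model carry the largest weights,
and the ensemble separates held-out SL from non-SL pairs perfectly at
these effect sizes.

The same pipeline is scriptable from the shell:

```bash
elisl --seed 1 --out world/ simulate
elisl --seed 1 --out feats/ featurize --data world/
elisl --seed 1 --out model/ train --features feats/ --labels world/labels.tsv --ensemble rf
elisl --seed 1 --out preds/ predict --model model/ --features feats/
elisl --seed 1 --out eval/ evaluate --features feats/ --labels world/labels.tsv --protocol double_holdout
elisl --seed 1 --out imp/ importance --model model/ --features feats/ --labels world/labels.tsv
```

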