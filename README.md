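# mvmwgl — multi-view multi-way graph learning for survival prediction

`mvmwgl` predicts breast-cancer survival time (in months) from gene
expression by exploiting two complementary graph views of a cohort — a
**gene-interaction graph** (how features relate) and a **patient-similarity
graph** (how instances relate) — chained through three learning paradigms:

1. **Unsupervised:** patients are connected when the cosine similarity of
   their standardized expression vectors reaches a threshold η; spectral
   clustering of that graph's unnormalized Laplacian L = D − A yields a
   pseudo-label c<sub>i</sub> per patient.
2. **Self-supervised:** every patient is a copy of one shared
   gene-interaction graph with node inputs g<sup>std</sup>; two
   message-passing layers (GCN, H′ = ReLU(D̂<sup>−1/2</sup>(M + I)D̂<sup>−1/2</sup> H W),
   or single-head GAT), global mean pooling and a softmax head are trained
   to classify the pseudo-labels. Concatenating the final-layer gene
   representations gives a learned patient feature H.
3. **Semi-supervised (transductive):** the patient graph is rebuilt from
   standardized H, and a node-level GCN/GAT with an MLP head regresses
   survival with MSE on training nodes only, aggregating over train,
   validation *and* test neighbors; the epoch with minimum validation loss
   is returned.

Gene selection uses the univariate statistic
F<sub>j</sub> = ρ<sub>j</sub>²/(1 − ρ<sub>j</sub>²)·(n − 2) of each gene's
Pearson correlation with survival, computed on training patients only.
Reports give MSE and MAE with per-patient error spread, overall and
stratified by survival term (short ≤ 12 < medium ≤ 60 < long months).

Because the cohorts this method targets are not redistributable, the package
ships a first-class synthetic-cohort generator (latent patient groups,
survival means plus noise, block-structured gene graph with co-regulated
modules) used throughout the tests; see `docs/methods.md` for the model,
parameter defaults, and the generator's scope and limits.

The numerical core — message-passing layers, attention, training loops — runs
on a small numpy reverse-mode autodiff engine included in the package and
validated against per-node brute-force oracles and finite differences.

## Worked example

```python
from mvmwgl import CohortSpec, TrainingConfig, generate_cohort, run_mvmwgl

spec = CohortSpec(
    n_patients=300, n_genes=60, n_informative_genes=45, n_groups=4,
    group_survival_means=(10.0, 30.0, 70.0, 120.0), survival_noise_sd=5.0,
    seed=1,
)
expr, interactions, surv, truth = generate_cohort(spec)

config = TrainingConfig(k_genes=40, n_clusters=4, seed=1)  # GCN/GCN
result = run_mvmwgl(expr, interactions, surv, config)
overall = result.report["overall"]
print(f"{config.model_tag}: test MSE {overall['mse']:.2f}, "
      f"MAE {overall['mae']:.2f} over {overall['n']} patients")
print(f"selected epoch: {result.bsg_result.selected_epoch}")
```

prints

```
MVMWGL-GCNCN: test MSE 63.87, MAE 6.13 over 59 patients
selected epoch: 104
```

i.e. on a held-out test set of 59 patients the model predicts survival with
a mean absolute error of about 6 months against a between-group survival
spread of 10–120 months (the train-mean predictor errs by ~40 months on the
same split), using the weights from epoch 104 where validation loss was
minimal. The same cohort is available from the shell:

```sh
mvmwgl simulate --out cohort/ --seed 1
mvmwgl run --expr cohort/expression.tsv --interactions cohort/interactions.tsv \
           --surv cohort/survival.tsv --seed 1 --out rundir/
```

Other subcommands (`select`, `graph`, `cluster`, `baseline`, `evaluate`,
`sweep`) expose the individual stages, the single-view GIG/BSG baselines and
the η / n_clusters / ssl_epochs sensitivity sweeps.

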