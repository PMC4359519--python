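# gsas

Gene Set Activity Score (GSAS) pipeline: rank-based single-sample gene set
scoring with permutation normalization, followed by Cox/Kaplan-Meier
survival screening, cross-cohort robustness intersection, random-forest
metastasis classification, gene-set overlap network construction with
core-gene-set extraction, and a core-gene ablation experiment.  A synthetic
multi-cohort generator with planted ground truth makes every stage testable
offline.

## Method

For each sample, genes are ranked by relative expression (per-gene z-score
across samples by default, descending, ties broken by gene id).  A gene
set's **preliminary score** is the signed maximum deviation between the
empirical CDF of the set's genes and of the complement's genes along the
ranking — a signed KS-style D statistic in [-1, 1].  It is divided by the
mean absolute preliminary score of `n_perm` random size-matched gene sets
(default 1,000), producing the **GSAS**: positive = high set activity,
negative = low, with |GSAS| of a random set calibrated to ~1.

Downstream stages:

- **survival**: per-set univariate (or clinically adjusted) Cox
  proportional-hazards screen (Efron ties, Wald p, BH FDR), Kaplan-Meier /
  log-rank comparison of samples dichotomized about GSAS = 0, hierarchical
  sample clustering on activity profiles (display capped to ±3).
- **robust**: sets with Cox p < 0.05 in *every* cohort screened.
- **classify**: Wilcoxon rank-sum feature selection (FDR < 0.01) + random
  forest, repeated stratified 10-fold CV, mean AUC; feature lists transfer
  across cohorts (the model is retrained in the evaluation cohort).
- **network**: Jaccard overlap graph over FDR-significant sets, split by
  hazard-ratio direction (hr >= 1 "negative", hr < 1 "positive"), edges at
  overlap >= 0.20; the module richest in robust sets yields the **core gene
  set** = genes in >= 40% of the module's sets.
- **ablate**: remove (or size-preservingly substitute) the core genes in
  every set, rescore, rescreen, and report before/after significant-set
  counts per cohort.

## CLI

Every stage is a subcommand of `gsas`, driven by a YAML config plus an
optional `--seed` override; each output directory receives a
`manifest.json` with the seed, thresholds, input SHA-256 digests, and
package version.

```bash
gsas simulate -c sim.yaml -o out/sim             # synthetic cohorts + GMT
gsas score    -c score.yaml -o out/score         # GSAS matrix (TSV + sidecar)
gsas survival -c surv.yaml -o out/surv           # per-set Cox screen CSV, KM plot
gsas robust   --screen a.csv --screen b.csv -o out/robust
gsas classify -c clf.yaml -o out/clf             # features, AUCs, ROC, importances
gsas network  --screen screen.csv --gmt sets.gmt -o out/net   # GraphML/SIF + core GMT
gsas ablate   -c ablate.yaml -o out/abl          # before/removed/substituted counts
```

Example `sim.yaml`:

```yaml
n_genes: 2000
n_samples: 200
n_sets: 150
n_program_sets: 20
n_cohorts: 3
seed: 11
```

## Layout

```
src/gsas/
  io.py         expression / GMT / clinical containers and readers-writers
  simulate.py   synthetic cohorts, collections, multi-cohort benchmarks
  engine.py     ranking, preliminary score, normalization, GSAS matrices
  survival.py   Cox screen, KM/log-rank, BH FDR, robust intersection, clustering
  classify.py   Wilcoxon feature selection + random-forest CV evaluation
  network.py    overlap networks, module selection, core gene set
  ablation.py   core removal / substitution and the re-screening experiment
  cli.py        click-based subcommands and run manifests
tests/          unit, property, and acceptance suites (tests/test_acceptance.py)
scripts/acceptance.py
```
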