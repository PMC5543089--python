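# eventrsa

Representational similarity analysis (RSA) for event-related fMRI, built
around three pattern statistics with pair-exclusion rules and
permutation-labeling inference:

* **semantic RSA** — an entity-by-entity similarity matrix is computed from
  trial-pair cosine similarities (pairs presented at the same screen location
  are excluded), averaged over subjects, and rank-correlated with a model
  similarity matrix; significance comes from jointly permuting the model's
  row+column labels;
* **object identity** — mean cosine over same-entity trial pairs at
  different locations; the null permutes entity labels within runs;
* **location** — mean cosine over same-location trial pairs of different
  entities; the null permutes location labels within runs.

The package also builds model similarity matrices (concept-feature cosine,
normalized Levenshtein phonological similarity, family block matrices,
per-layer encoder feature matrices), extracts per-trial response patterns as
the 2–8 s BOLD integral, constructs volumes of interest (MNI spheres,
gray-matter filtering, probability-map thresholding with size equating), and
ships a synthetic-data generator that embeds controllable semantic /
identity / location structure so the whole pipeline is testable end to end.

## Python API

```python
import eventrsa as er

model = er.random_model_matrix(24, seed=1)
cfg = er.GeneratorConfig(n_subjects=10, n_voxels=500, model=model,
                         semantic_gain=1.0, noise_sd=1.0, seed=7)
subjects, trials, truth = er.generate_dataset(cfg)
result = er.analyze_dataset(subjects, trials, model, n_perm=10000, seed=7)
print(result["rsa"].observed, result["rsa"].p)
print(result["identity"].p, result["location"].p)
```

`er.recovery_report(...)` sweeps an effect-size grid and reports rejection
frequencies (power / null calibration) for the full pipeline.

## Command line

```sh
eventrsa simulate --subjects 5 --voxels 200 --semantic-gain 1 --seed 3 --out ds/
eventrsa report --dataset ds/ --out results/ --n-perm 10000 --seed 3
eventrsa rsa --dataset ds/ --out rsa.json          # one statistic only
eventrsa extract --dataset ds/ --out patterns/     # trial x voxel CSVs
eventrsa compare --ranks-a a.tsv --ranks-b b.tsv --tail one
```

`report` writes, per volume of interest: per-subject and group similarity
matrices (CSV), a JSON record and null-sample CSV per statistic, subject
rank tables, normality diagnostics, pairwise between-VOI signed-rank
comparisons, and a `manifest.json` holding every seed used.  A YAML config
(`eventrsa report --config cfg.yaml`) exposes the remaining switches
(analysis window, integration substep, high-pass cutoff, similarity cell
variant, explicit VOI mask paths).

## Layout

| module                | contents |
| --------------------- | -------- |
| `eventrsa.matrices`   | `SimilarityMatrix`, model matrix builders, matrix correlation + permutation test |
| `eventrsa.response`   | `TrialTable`, nuisance regression, BOLD-integral pattern extraction |
| `eventrsa.stats`      | fMRI similarity matrices, identity/location statistics, subject ranks, signed-rank / Mann-Whitney comparisons, diagnostics |
| `eventrsa.masks`      | grids, sphere/probability-map VOIs, gray-matter filter, size equating |
| `eventrsa.simulate`   | generator config, entity-pattern factory, dataset simulation, recovery report |
| `eventrsa.io`         | TSV/CSV/NIfTI readers and writers, dataset round-trip |
| `eventrsa.pipeline`   | `analyze_dataset` (in memory) and `run_pipeline` (file to file) |
| `eventrsa.cli`        | `eventrsa` console entry point |
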