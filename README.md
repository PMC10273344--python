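# stabbench

Benchmarking machinery for comparing **protein stability predictions
(ΔΔG)** with **deep mutational scanning (DMS) functional scores**.

Computational stability predictors (FoldX, Rosetta, ENCoM, RaSP, …)
estimate the change in folding free energy, ΔΔG (kcal/mol), caused by a
single amino acid substitution; DMS experiments measure the functional
consequence of the same substitutions at scale. How well ΔΔG ranks
functional damage — and which predictors and assay types agree best —
is a rank-correlation benchmarking problem. `stabbench` implements that
benchmark as a reusable pipeline for anyone with per-variant score
tables:

- **Harmonization** — sign conventions (higher = more destabilizing /
  more damaging), Rosetta REU → kcal/mol rescaling (÷ 2.94), |ΔΔG| as a
  general-perturbation metric, and the *Foldetta* consensus: the
  per-variant mean of FoldX and rescaled Rosetta predictions.
- **Complete-observation Spearman matrices** — ρ computed only on the
  variants scored by both sources, pooled across genes
  (predictor–predictor) or per DMS dataset (predictor–DMS), with
  undefined entries flagged rather than zeroed.
- **Tournament ranking** — every predictor duels every other on every
  DMS dataset: each predictor's ρ with the assay is computed on the
  three-way shared variant subset, rounded to two decimals, the larger
  value wins a point (draws split it). Scores are normalized by each
  predictor's own comparison count with 95% Wilson binomial intervals.
- **Assay-class aggregation** — DMS datasets grouped into five classes
  (abundance, growth, binding, activity, viral replication); per-class
  means of per-dataset ρ with Fisher-z confidence intervals, plus
  class-restricted tournament reruns.
- **Agreement maps** — DMS and |ΔΔG| columns rank-normalized to [0, 1]
  after removing gain-of-function variants; δ = DMS − |ΔΔG| per variant
  (positive = stability underpredicts the functional effect), per-
  position medians, and ChimeraX defattr / B-factor exports for
  structure coloring.
- **Variant→structure mapping** — chains eligible at > 90% identity to
  the human protein over ≥ 50 aligned residues; non-human chains
  additionally require the variant residue and its aligned neighbors to
  match the human wild type; candidates ranked by resolution, then
  first-biological-assembly size; AlphaFold positional fallback.
- **Synthetic data** — a Gaussian-copula generator that plants an exact
  Spearman correlation matrix under ΔΔG-like and bimodal fitness-like
  marginals, with per-source missingness and direction flips, plus
  minimal PDB fixture structures. Every pipeline stage is testable
  against planted truth.

## Worked example

Simulate a benchmark — one pseudo-DMS dataset and three predictors that
all track the assay at a planted Spearman ρ = 0.45 — then run the full
pipeline:

```sh
stabbench simulate --n-variants 2000 --n-predictors 3 --rho 0.45 --seed 11 --outdir demo
stabbench run-all --scores demo/scores.tsv --meta demo/meta.yaml --metric ddg --outdir demo/out
```

The manifest reports `"mean_benchmark_rho": 0.464634` — the average
predictor–DMS Spearman across the benchmark, close to the planted 0.45
(the consensus column pulls it slightly above). `demo/out/ranking_ddg.tsv`
holds the tournament result:

```
predictor   metric  points  n_comparisons  normalized_score  ci_low    ci_high
foldetta    ddg     3       3              1                 0.438503  1
rosetta     ddg     2       3              0.666667          0.20766   0.938508
foldx       ddg     0.5     3              0.166667          0.0176528 0.690012
pred3       ddg     0.5     3              0.166667          0.0176528 0.690012
```

`foldetta` — the untrained mean of the foldx and rosetta columns — wins
all three of its duels: averaging two independently noisy estimates of
the same effect cancels noise, so the consensus correlates better with
the assay than either input. The `ci_low`/`ci_high` columns are 95%
Wilson intervals on each normalized score; with only three comparisons
they are wide, which is exactly what they should convey.

The same stages are importable as a library (`stabbench.run_tournament`,
`stabbench.build_agreement_map`, …); the CLI is a thin wrapper.

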