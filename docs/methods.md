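# Methods

## The benchmark model

The pipeline treats every input as a long-format table of per-variant
scores: a variant is a single amino acid substitution
(gene, position, wild-type, mutant; 1-based positions in the reference
protein, canonical residues only), and a source is either a stability
predictor (ΔΔG in kcal/mol, or Rosetta Energy Units before rescaling),
a DMS dataset (unitless fitness/abundance/binding scores), or a
sequence-based variant effect predictor. All agreement is measured with
Spearman's rank correlation on *complete observations*: a pair of
sources is compared only on the variants both of them score. This makes
every statistic invariant to monotone rescaling of any source, which is
the reason the harmonization layer only needs to fix *directions* and
*units*, never distributional shape.

Conventions after harmonization: higher predictor value = more
destabilizing; higher DMS value = more damaging. Sources whose raw
convention is opposite carry a direction flag of −1 in their metadata
and are negated once (the applied transform is logged, making the
operation idempotent and exactly reversible). Rosetta REU values are
divided by 2.94 to reach the kcal/mol scale. The Foldetta consensus is
the per-variant arithmetic mean of FoldX and rescaled Rosetta; in
absolute mode the moduli are taken *before* averaging. The alternative
reading — absolute value of the raw mean — is available via the mode
switch but is not the default, because strong stabilization and strong
destabilization should both register as perturbation before they can
cancel. Variants missing either input get no consensus value and are
counted, not imputed.

## Tournament ranking

For each DMS dataset and each unordered predictor pair present on it,
both predictors' Spearman ρ against the assay are computed on the
three-way shared subset (variants with both predictions *and* the assay
value). The values are rounded to two decimals (half away from zero;
banker's rounding is a config option), the larger signed value wins a
point, draws split it. A predictor entirely missing a dataset sits out
all duels there; a ρ undefined on the shared subset (too few variants
or zero rank variance) skips that duel for both sides. Final score =
points / own comparison count, with a 95% Wilson interval treating that
ratio as a binomial proportion. Half-points make it a pseudo-proportion;
the interval is the standard approximation, and Wilson was chosen for
its behavior at the 0 and 1 boundaries (other binomial CI methods are
selectable). Because duel correlations are computed per pair, a
predictor's ρ may legitimately differ across its duels on one dataset;
the per-predictor full-shared-set alternative is available as
`subset="per_predictor"`.

Minimum shared observations for any correlation: 3 by default
(configurable, logged) — below that rank correlation is degenerate.

## Assay-class statistics

DMS datasets carry one of five assay-class labels in their metadata
(abundance, growth, binding, activity, viral_replication — classes are
user metadata, never inferred). Per predictor and class, per-dataset
correlations are aggregated on the Fisher-z scale: z = atanh ρ, mean
z̄ ± 1.96·sd(z)/√m, back-transformed with tanh. The interval describes
dataset-to-dataset dispersion (m = number of datasets), not the
per-correlation 1/√(n−3) sampling error; it answers "how consistent is
this predictor across datasets of this assay type". Both the z-scale
mean and the plain mean of ρ are reported, since either could be the
plotted quantity in a downstream figure. |ρ| = 1 is an error (infinite
z); m = 1 yields a defined mean with an explicitly undefined CI.

## Agreement maps

For one (DMS dataset, predictor) pair: variants indicating *improved*
function relative to the wild-type reference score (strictly beyond it,
in the direction given by the source's convention) are removed first;
both remaining columns — DMS oriented damage-positive, and |ΔΔG| by
default — are rank-normalized to [0, 1] via (average rank − 1)/(n − 1);
δ = normalized DMS − normalized stability. Positive δ: the predictor
underpredicts the functional effect; negative: it overpredicts.
Normalization after filtering is the default (the filter defines the
comparison population); the pre-filter alternative is a switch.
Per-position medians use the midpoint convention for even counts.
Structure exports write a ChimeraX defattr file and a copy of the
structure with B-factors set to 100·δ clamped to ±99.99; residues
without a δ get the sentinel 999.90, which no real δ can reach.

## Variant→structure mapping

Chains are aligned to the full human reference sequence with an
affine-gap (open −11, extend −1) BLOSUM62 local alignment; identity is
computed over aligned (non-gap) columns. Eligibility requires identity
strictly greater than 90% over at least 50 aligned residues. Non-human
chains additionally require the variant residue and both aligned
immediate neighbors to equal the human wild type; a neighbor that does
not exist (sequence or alignment terminus) is simply skipped — the
alternative, rejecting all terminal variants, would discard mappable
data. Among admissible candidates the order is: best (lowest)
resolution; structures without resolution (NMR ensembles, models) after
all resolved ones; then largest first biological assembly; then
lexicographic structure id — the last tie-break exists purely so the
mapping is a total order and therefore deterministic. Structure files
are reduced on reading: first altloc per residue, first NMR model,
assemblies in file order (so "first assembly" is well defined). Variants
with no admissible chain fall back to AlphaFold-model coordinates at
the UniProt position; variants beyond the reference sequence, or whose
stated wild type contradicts it, are unmapped with the reason recorded
in provenance.

## Synthetic data

The generator is a Gaussian copula: a target Spearman matrix is
converted to the latent Pearson matrix via r = 2·sin(πρ_s/6), validated
for positive semi-definiteness (a non-PSD matrix is an error naming the
smallest eigenvalue — no silent repair, because planted-truth tests
depend on the matrix being exactly what was asked), and multivariate
normal draws are pushed through per-source quantile transforms:

- `gaussian` — identity;
- `ddg_like` — shifted gamma (shape 2, scale 1.2, mode near 0, long
  positive tail), emulating destabilization-heavy ΔΔG distributions;
- `fitness_like` — a two-component normal mixture (functional mode at
  1.0, sd 0.12, weight 0.55; null mode at 0.0, sd 0.2), the bimodal
  shape typical of loss-of-function DMS scores, inverted by monotone
  interpolation of the mixture CDF on a 4096-point grid.

All transforms are strictly increasing, so the planted rank structure
survives the marginals exactly (up to grid resolution ~1e−4 in the
mixture quantile). Missingness is MCAR per source; direction flips
negate a source and set its metadata flag, so harmonization can be
exercised end-to-end. Identical specs give byte-identical tables.
The one-factor helper (`factor_model_spearman`, `generate_benchmark`)
plants a shared latent effect: with the DMS latent as the factor
(loading 1), each predictor's loading *is* its latent correlation with
the assay, and predictor–predictor structure follows as the product of
loadings — guaranteeing a valid joint distribution for any planted
predictor–DMS profile.

What the generator does *not* emulate: per-gene idiosyncrasies of real
score distributions, informative missingness (real predictors fail on
specific structural contexts), position-level correlation along the
sequence, or measurement error in the DMS scores themselves. Passing
tests demonstrate that the pipeline's statistics recover planted rank
structure under realistic marginals and ragged coverage — not that any
particular real predictor ranks anywhere.

Fixture structures are deliberately minimal PDB files (SEQRES, CA-only
ATOM records, REMARK 2 resolution, REMARK 350 assembly transforms,
optional altlocs and multi-MODEL ensembles) — just enough for the
mapping rules to have something real to parse.

## Verification problem sizes

The acceptance checks use n = 50,000 variants for copula fidelity
(sampling error ≈ 1/√n ≈ 0.0045, against a 0.03 band), 5 datasets ×
2,000 variants × 20 replicates for ranking recovery (adjacent planted
correlations differ by 0.15 ≈ 7 sampling standard deviations), and
n = 20,000 for the consensus check, where two predictors with latent
Pearson 1/√2 to a common truth have a mean whose latent correlation is
1/√1.5 ≈ 0.8165 (variance algebra: corr = (λ₁+λ₂)/2 ÷ sd of the mean),
i.e. an expected Spearman of (6/π)·arcsin(r/2) ≈ 0.803. Observed values
in `results/acceptance.json` sit within 0.001 of that prediction.

## Known limitations

- The tournament CI treats half-points as binomial successes; the
  interval is approximate whenever draws occur.
- Identity is computed over aligned columns only; a heavily gapped
  alignment can reach high identity over a short effective region (the
  ≥ 50-column floor is the only guard).
- The mixture quantile's interpolation grid bounds tail resolution;
  irrelevant for rank statistics, visible only in extreme quantiles.
- `read_structure` keeps standard amino acid residues only; modified
  residues are invisible to mapping rather than translated to parents.
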