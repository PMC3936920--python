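# matrisig

Tools for asking whether **maternal kin groups leave acoustic signatures in
the calls of a solitary forager** — built around the gray mouse lemur
(*Microcebus murinus*), a standard model for the dispersed social networks
of ancestral primates. Solitary foragers forage alone but keep social
networks alive through scent and vocalizations, and females sleep in groups
of close maternal kin. If calls carry matrilineal signatures, kin could be
recognized at a distance, in darkness, through foliage — a prerequisite for
maternal kin selection.

The package implements the full analysis chain for this question, plus a
synthetic-population generator with known ground truth so that every stage
can be validated without field data:

- **Microsatellite genetics** (`matrisig.msat`) — Queller–Goodnight pairwise
  relatedness r̂ (ratio-of-sums over loci and both focal directions); a
  simulation-based likelihood-ratio test of maternal kinship
  (H₁: r_maternal = 0.5, r_paternal = 0 against unrelatedness, per-line IBD
  probability 2·r); probability of identity PI = Σp_i⁴ + Σ_{i<j}(2p_ip_j)²;
  Jamieson–Taylor parentage exclusion probabilities; unbiased Hₑ, Hₒ and
  F_is with allele-randomization p-values and Bonferroni screening.
- **mtDNA haplotypes** (`matrisig.mtdna`) — pairwise differences under
  pairwise deletion, haplotype collapsing, minimum-spanning haplotype graph.
- **Kin-group assignment** (`matrisig.kin_groups`) — the three-criterion
  rule (shared haplotype, observed co-sleeping, relatedness significantly
  maternal) with principled handling of *unknown* evidence: unknowns
  abstain, a known haplotype mismatch vetoes, and the relatedness criterion
  is enforced group-wide.
- **Acoustics** (`matrisig.acoustics`) — derived call parameters
  (StartBandwidth = SB_Max − SB_Min, CallDuration = E − S,
  TimeToPeak = P − S, InterCallInterval = N − E), quartile summaries, and
  `CallPCA`: PCA on the correlation matrix of the seven call parameters with
  Kaiser retention and loadings reported as parameter–component
  correlations.
- **Nested pDFA** (`matrisig.pdfa`) — `NestedPDFA` classifies calls by kin
  group with leave-one-out cross-validated LDA and permutes *individuals*
  (the control factor) between groups, all calls moving together; the
  chance level is the mean permuted correct rate and
  p = (#{permuted ≥ observed} + 1)/(n + 1).
- **Mantel test** (`matrisig.mantel`) — `MantelTest` for acoustic distance
  (|mean PC1ᵢ − mean PC1ⱼ|) against relatedness: Z = ΣᵢⱼXᵢⱼYᵢⱼ, matrix
  correlation r, and g = (Z − E[Z])/√Var[Z] with exact closed-form
  permutational moments.
- **Synthetic data** (`matrisig.simulate`) — matriline pedigrees under
  promiscuous mating (fresh sire per daughter), Hardy–Weinberg founder
  genotypes at 7 loci with 9–25 alleles, maternally inherited haplotype
  sequences, co-sleeping records among maternal kin, and call parameters
  with matriline-, individual- and call-level Gaussian variance whose
  pooled quartiles match published ranges.

The statistical models follow a statsmodels-style pattern: build a model
object from data, call `fit()`, get a results object with `summary()`.

## Worked example

The package ships the published pairwise matrices of the 16 study females
(upper triangle relatedness, lower triangle acoustic distance). Testing the
directional hypothesis that acoustic distance falls as relatedness rises:

```python
from matrisig import MantelTest
from matrisig.datasets import load_study_matrices

relatedness, acoustic_distance = load_study_matrices()
result = MantelTest(relatedness, acoustic_distance).fit(n_permutations=1000, seed=1)
print(result.summary())
```

```
Mantel matrix-permutation test
  Z = 4.628 (full sum; E[Z] = 9.243, SD = 2.877)
  r = -0.1248
  g = -1.6041 (closed moments)
  p = 0.04995 (lower-tailed, 1000 permutations)
```

The cross-product sum Z sits 1.6 permutational standard deviations below
its expectation (g = −1.60): more closely related females tend to sound
more alike, a trend at the edge of significance — matching the published
r = −0.13, Z = 4.61, g = −1.61, p = 0.058 to within the rounding of the
published matrix.

The same analysis runs end-to-end on synthetic data with known truth:

```python
from matrisig import SimConfig, simulate_population, simulate_calls, CallPCA, NestedPDFA

cfg = SimConfig(seed=2)                      # six matrilines, 10 calls/female
pop = simulate_population(cfg)
calls = simulate_calls(pop.pedigree, cfg)
pca = CallPCA(calls).fit()
scores = pca.scores.assign(group=lambda d: d["id"].map(pop.pedigree.matriline_of))
print(NestedPDFA(scores, predictors="PC1").fit(n_permutations=10_000, seed=2).summary())
```

```
Nested permuted discriminant function analysis
  calls: 190, groups: 6
  correctly cross-classified: 58.9%
  chance level (mean of 10000 permutations): 25.2%
  p = 9.999e-05
```

Calls classify to their matriline far above the ~25% chance level, as they
should under the generator's moderate matriline effect.

A `matrisig` command-line tool wraps each stage
(`simulate`, `relatedness`, `locus-stats`, `haplotypes`, `acoustics`,
`pdfa`, `mantel`, `pipeline`); `matrisig pipeline --seed 0 --out runs/demo`
executes the whole chain on a synthetic population and writes each stage's
artifact next to a JSON provenance record.

## Further reading

`docs/methods.md` documents the models and their assumptions, the
synthetic-data generator's design and calibration, numerical conventions
(quantile rule, p-value conventions, tie-breaking) and known limitations.
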