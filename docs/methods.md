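# Methods

This note documents the models implemented in `matrisig`, the assumptions
behind them, the synthetic-data generator that stands in for field data,
and the numerical conventions that matter for reproducing results.

## The scientific setting

Female gray mouse lemurs are philopatric and sleep in groups of close
maternal kin; males disperse. A matriline therefore shares a mitochondrial
haplotype, co-sleeps, and is tied together by mother–daughter and maternal
half-sib links. The package tests whether such matrilines also share an
acoustic signature in agonistic calls, using three data layers that must be
integrated: microsatellite genotypes (biparental relatedness),
mitochondrial D-loop sequences (maternal lineage), and sleeping-site
telemetry (social association). Acoustic structure is summarized by seven
call parameters — three fundamental-frequency measurements (F0S, F0Peak,
F0E, Hz), the start bandwidth (Hz), and three temporal measures
(CallDuration, TimeToPeak, InterCallInterval, ms).

## Microsatellite statistics

**Queller–Goodnight relatedness.** For a dyad (x, y) with genotypes (a, b)
and (c, d) at a locus with population frequencies p:

    num(x→y) = ½(δac + δad + δbc + δbd) − pa − pb
    den(x)   = 1 + δab − pa − pb

r̂ is the ratio of sums: numerators and denominators are accumulated over
loci *and both focal directions* before dividing. Ratio-of-sums is more
stable than averaging per-locus ratios when denominators are small and
makes the estimator exactly symmetric. Expectation is 0.5 for
parent–offspring and 0 for unrelated dyads (verified by simulation in the
test suite to ±0.05 and ±0.02 at 7 loci / 1000 dyads). Loci with a missing
allele in either member are dropped from both sums for that dyad only;
allele frequencies are computed once from the full sample, including the
focal pair (no leave-out correction — deterministic and simple; a
leave-one-dyad-out variant can be had by passing custom frequencies).

**Maternal-kinship likelihood test.** The hypothesis H = (r_m, r_p)
specifies relatedness through the maternal and paternal lines; the
probability that the dyad's maternal (paternal) alleles are identical by
descent is 2·r_line, so H₁ = (0.5, 0) makes the maternal allele IBD with
certainty and H₀ = (0, 0) is independence. Phase is unobserved, so the
likelihood averages the four phase assignments; non-IBD alleles are
population draws. The per-locus likelihood ratio is mixed with a small
genotyping-error/mutation allowance ε (default 0.01):

    ratio = (1 − ε) · L_H/L₀ + ε

Without it, a single locus at which a dyad shares no allele makes the
mother–offspring likelihood exactly zero; with seven highly polymorphic
loci virtually every unrelated dyad hits such a locus, the statistic
collapses to −∞ and the test degenerates. The mixture is the standard
device of likelihood-based kinship software: an allele-sharing-free locus
contributes the small non-IBD term (ratio ε < 1) instead of vetoing the
whole genotype. The test statistic is the summed log ratio; its null
distribution comes from `n_sim` dyads simulated under H₀ from the
frequency table, and p is the proportion of null statistics ≥ observed.
Simulated type-I error at α = 0.05 is 5% ± 1.5% (test suite). p-value
tiers a/b/c correspond to p < 0.001, < 0.01, < 0.05.

**PI, exclusion, heterozygosity.** Probability of identity per locus is
Σp_i⁴ + Σ_{i<j}(2p_ip_j)², multiplied across loci. Parentage exclusion uses
the Jamieson–Taylor closed forms for three cases — a single alleged parent
(other parent unknown), a second parent given one known parent, and a
parent pair — combined across loci as 1 − Π(1 − E). All three forms are
verified against brute-force genotype-trio enumeration to 1e-12.
Hₑ is the unbiased gene diversity 2n(1 − Σp̂²)/(2n − 1); F_is = 1 − Hₒ/H_s
with the small-sample H_s of Nei & Chesser. The heterozygote-deficit p is
the proportion of allele randomizations (alleles shuffled among individuals
within a locus) with F_is *strictly greater* than observed — the
convention of the randomization software the field uses. Because ties
count as not-greater, the null law of this p is discretely sub-uniform;
the test suite checks it against an independently coded oracle rather than
continuous uniformity. Locus screening applies a Bonferroni-corrected
threshold α/n_loci (0.05/7 = 0.00714): loci with a significant deficit are
dropped before relatedness estimation.

## mtDNA haplotypes

Differences between aligned sequences are counted under pairwise deletion:
columns with a gap or N in either sequence are ignored for that pair
(ambiguity N is treated as missing; the alignment software's deletion
option is not recorded in the source data, and pairwise deletion is the
common default). Haplotypes are zero-difference classes, closed
transitively — sequences of unequal trimmed coverage can merge through an
intermediate, which is documented behavior, not an accident. Labels are
H1, H2, … by decreasing frequency with ties broken by smallest member id.
The haplotype graph is a minimum spanning tree over the difference matrix
with deterministic (weight, label) tie-breaking — a deliberate
simplification of a median-joining network: it shows relatedness structure
among haplotypes but does not infer unobserved intermediate haplotypes.

## Kin-group assignment

Three criteria admit a dyad to a kin group: (1) same mitochondrial
haplotype, (2) observed co-sleeping, (3) relatedness significantly
consistent with maternal r = 0.5. Field evidence is incomplete, so each
criterion evaluates to yes/no/unknown and **unknown abstains** — the only
reading under which a female with an undetermined haplotype but strong
behavioral and genetic evidence joins her group. The admission rule: a
known haplotype mismatch vetoes; otherwise a dyad is groupable when
relatedness is significant and at least one of the other two criteria
passes while the other passes, fails or is unknown — but not when both
abstain or fail. Tier-c significance (p < 0.05) qualifies only when the
dyad also co-sleeps; tiers a/b always qualify (configurable).

Groups are the connected components of the groupable-dyad graph. A
component may legitimately contain a pair that is not directly groupable —
two females never seen to co-sleep, linked through a third — which is why
components, not cliques, are the right aggregation: the clique reading
would split a documented group whose members connect only through a shared
relative. Criterion 3 is then enforced group-wide: every member pair must
be significantly related; violating components are trimmed by repeatedly
removing the member with the most failing pairs (ties broken toward the
lexicographically last id) and re-splitting, so the procedure is
deterministic and needs no seed. A female whose membership would bridge
two known different haplotypes raises an explicit incompatibility error.

## Acoustic PCA

PCA is performed on the correlation matrix of the seven parameters
(standardization uses n−1 SDs). Components are retained by the Kaiser
criterion (eigenvalue > 1) unless a count is given; loadings are reported
as parameter–component correlations (eigenvector × √eigenvalue); scores
are standardized to unit variance; each component's sign is fixed so its
largest-|loading| parameter loads positive. Correlation-matrix PCA makes
scores invariant to affine rescaling of any input (e.g. Hz vs kHz — the
source tables disagree on the unit; the package standardizes on Hz, and
the PCA is indifferent). Series-final calls have no following call and
hence no InterCallInterval; they are kept by imputing the individual's
median interval, flagged in an `ici_imputed` column, preserving the
10-calls-per-female design. Quartiles use linear interpolation (type 7);
statistical packages differ here and the choice is configurable.

## Nested pDFA

Calls repeat within individuals and individuals nest within kin groups, so
permuting calls would wildly overstate significance. The permutation unit
is the **individual**: each permutation reassigns whole individuals to kin
groups preserving the observed distribution of group sizes in individuals,
with all of an individual's calls attached. The classifier is a
pooled-covariance LDA with equal priors; cross-validation leaves out one
*call* (the conventional DFA cross-validation; a stricter
leave-individual-out is available as `_loo_correct_nd` composition but the
single-call variant is the default). With one predictor, equal priors and
a common pooled variance, LDA reduces exactly to nearest-group-mean
classification, which the implementation exploits for a vectorized
leave-one-out over thousands of permutations; the generic multi-predictor
path refits Mahalanobis discriminants per held-out call and is
cross-checked against scikit-learn's LDA in the tests. Ties in the
posterior break toward the lower group label. The predictor count may not
exceed the smallest group's individual count minus one — with groups of
two individuals that means a single principal component, PC1 by default.
The chance level is the mean permuted correct rate (with unbalanced groups
this exceeds the max-prior rate, which is why it is reported from the
permutations rather than from priors), and
p = (#{permuted ≥ observed} + 1)/(n + 1), so p is never zero.

## Mantel test

Z = Σ XᵢⱼYᵢⱼ over dyads; the printed Z uses the full double sum (both
triangles), matching the convention of the classic Mantel software —
the upper-triangle variant is available and all inference is identical, Z
merely scales by two. r is the Pearson correlation of the dyad vectors.
g = (Z − E[Z])/√Var[Z] uses exact closed-form permutational moments,
derived by classifying dyad pairs as identical / one-shared-index /
disjoint; the tests verify them against exhaustive enumeration at n = 4, 5
to 1e-12 and against Monte-Carlo moments at n = 10 (a permutation-moment
estimate is also available). The p-value jointly permutes rows and columns
of one matrix; the default tail follows the direction of the observed
deviation of Z from E[Z] (here: negative association expected), two-tailed
on request; add-one convention. r is invariant to separate affine
transforms of either matrix; Z and g are not.

The packaged study matrices are printed to two decimals. Statistics
recomputed from them therefore differ from the originally computed values
by the propagated quantization error — about ±0.005 per entry across 120
dyads, i.e. ~0.005–0.02 on r, g and Z. The package reproduces r = −0.125,
g = −1.604, Z = 4.628, p ≈ 0.057 against the published −0.13 / −1.61 /
4.61 / 0.058.

## Synthetic data: what it emulates, and what it does not

`SimConfig` defaults describe the study conditions: six matrilines of 2–4
adult females, 20 unrelated males, seven loci with 9–25 alleles (allele
frequencies drawn from a symmetric Dirichlet, concentration 1, which
yields expected heterozygosities in the observed 0.74–0.94 range), seven
haplotype sequences of 531 bp with mean pairwise divergence 6 sites, 118
telemetry days with a matriline gathering probability of 0.5/day, and 10
calls per female in 2–3 series.

Founder females draw Hardy–Weinberg genotypes; each daughter receives one
allele of her mother and one of a *fresh* unrelated sire (promiscuous
mating with possible multiple paternity, so within-matriline dyads are
mother–daughter or maternal half-sibs and paternal relatedness within
matrilines is negligible). Haplotypes copy down the maternal line, one
distinct founder haplotype per matriline — haplotype identity is then an
equivalence relation that coincides exactly with matriline membership,
which the tests exploit.

Call parameters follow a three-level Gaussian model per parameter:
value = mean + matriline effect + individual effect + residual, effects
independent across parameters. Parameter means are the published medians
(F0S 11133 Hz, F0Peak 13770 Hz, F0E 11523 Hz, StartBandwidth 3749 Hz,
CallDuration 40 ms, TimeToPeak 20 ms, InterCallInterval 148 ms); total SDs
derive from the published interquartile ranges (IQR/1.349 under
normality). The split of total variance among levels is not identified by
any published number; it was calibrated once so that the default
population produces a *moderate* matriline signature — nested-pDFA correct
classification near the reported ~47% against a ~27% chance level — giving
fractions (0.55, 0.15, 0.30) for matriline/individual/residual. A single
global seed drives per-stage substreams (population, haplotypes,
co-sleeping, calls), so stages re-run independently and reproducibly.

What the generator does **not** model: vocal-tract biomechanics (no
source–filter model — the matriline effect jointly absorbs inheritance and
social learning, which the field data cannot separate either); covariance
between acoustic parameters beyond that induced by shared effects;
observation noise in telemetry; genotyping error (the kinship test's ε
allows for it, the generator never produces it); null alleles; age or
seasonal structure. Passing tests on synthetic data therefore demonstrate
calibration and recovery under the stated model, not robustness to these
real-data complications.

A one-way nested ANOVA (method of moments) recovers the configured
variance components; at 50 matrilines × 5 females × 10 calls the estimates
are unbiased with ~11% replicate-to-replicate noise, so the recovery test
averages a few replicates.

## Numerical conventions and degenerate inputs

- Missing genotype data: "?" or blank in CSVs; a half-called genotype is
  treated as fully missing. A dyad with no co-typed locus gets NaN
  relatedness, flagged, and excluded from downstream matrices.
- Constant acoustic parameter → explicit error naming the parameter
  (correlation undefined). Zero eigenvalues get zero scores.
- A group with a single call in LDA leave-one-out has no own-group
  training mean; the call is classified among the remaining groups.
- Randomization/permutation p-values: the F_is deficit p follows the
  strictly-greater convention (can be 0); the pDFA and Mantel p-values use
  add-one (never 0). Both conventions are deliberate and documented where
  they apply.
- All seeds are integers feeding `numpy.random.default_rng`; derived
  substreams use `SeedSequence.spawn`.

## Known limitations

- The kin-group trimming rule (drop the member with most failing pairs) is
  one deterministic resolution of an under-determined aggregation problem;
  alternative resolutions (e.g. maximum-weight significant subgroup) could
  differ on pathological evidence patterns that the documented data never
  produce.
- The minimum-spanning haplotype graph underestimates reticulation
  relative to a median-joining network.
- The pDFA assumes every individual belongs to exactly one kin group and
  that group sizes in individuals are fixed by design; crossed designs are
  out of scope.
- With six matrilines the pooled median of a call parameter wanders
  noticeably between simulated populations (matriline effects do not
  average out at n = 6); calibration checks therefore average replicates.
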