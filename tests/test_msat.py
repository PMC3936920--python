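"""Microsatellite statistics: relatedness, kinship test, PI, exclusion,
heterozygosity."""

import numpy as np
import pytest
from scipy import stats as sps

from matrisig import (
    AlleleFrequencyTable,
    GenotypeTable,
    allele_frequencies,
    bonferroni_threshold,
    exclusion_probabilities,
    locus_stats,
    probability_of_identity,
    queller_goodnight_r,
    significance_tier,
)
from matrisig.msat import kinship_log_likelihood_ratio, queller_goodnight_pairs


def table(ids, loci, genos):
    return GenotypeTable(ids, loci, np.array(genos))


# ------------------------------------------------------------------ allele freqs

def test_allele_frequencies_counts_typed_individuals():
    g = table(["i1", "i2"], ["L"], [[[1, 1]], [[1, 2]]])
    f = allele_frequencies(g)
    assert f["L"] == {1: 0.75, 2: 0.25}

    g = table(["i1", "i2"], ["L"], [[[1, 1]], [[1, 1]]])
    assert allele_frequencies(g)["L"] == {1: 1.0}


def test_allele_frequencies_error_names_empty_locus():
    g = table(["i1"], ["Lbad"], [[[-1, -1]]])
    with pytest.raises(ValueError, match="Lbad"):
        allele_frequencies(g)


def test_allele_frequency_estimates_within_binomial_error():
    rng = np.random.default_rng(5)
    p_true = np.array([0.5, 0.3, 0.2])
    n = 107
    draws = rng.choice(3, size=(n, 1, 2), p=p_true) + 1
    g = GenotypeTable([f"i{k}" for k in range(n)], ["L"], draws)
    f = allele_frequencies(g)["L"]
    for a, p in zip([1, 2, 3], p_true):
        se = np.sqrt(p * (1 - p) / (2 * n))
        assert abs(f[a] - p) < 4 * se


# ------------------------------------------------------------------ QG r

def test_qg_two_locus_toy_matches_hand_oracle():
    # dyad x=(1/2, 1/1), y=(1/3, 1/2); value frozen from a directly coded
    # single-locus evaluation of the estimator (ratio of summed terms)
    freqs = AlleleFrequencyTable(
        ["A", "B"], {"A": {1: 0.5, 2: 0.25, 3: 0.25}, "B": {1: 0.5, 2: 0.5}}
    )
    g = table(["x", "y"], ["A", "B"], [[[1, 2], [1, 1]], [[1, 3], [1, 2]]])
    r, used, excl = queller_goodnight_pairs(g, freqs, [[0, 1]])
    assert r[0] == pytest.approx(-1.0 / 3.0, abs=1e-12)
    assert used[0] == 2 and excl[0] == 0


def test_qg_self_similarity_limit_with_rare_alleles():
    # identical heterozygotes at every locus with rare alleles -> r -> 1
    freqs = AlleleFrequencyTable(
        ["L1", "L2"],
        {"L1": {1: 0.02, 2: 0.03, 3: 0.95}, "L2": {1: 0.05, 2: 0.05, 3: 0.90}},
    )
    g = table(["x", "y"], ["L1", "L2"], [[[1, 2], [1, 2]], [[1, 2], [1, 2]]])
    r, _, _ = queller_goodnight_pairs(g, freqs, [[0, 1]])
    assert r[0] == pytest.approx(1.0, abs=0.02)


def test_qg_no_shared_alleles_is_negative_and_counted():
    freqs = AlleleFrequencyTable(["L"], {"L": {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}})
    g = table(["x", "y"], ["L"], [[[1, 2]], [[3, 4]]])
    r, _, excl = queller_goodnight_pairs(g, freqs, [[0, 1]])
    assert r[0] < 0
    assert excl[0] == 1


def test_qg_matrix_symmetric_and_relabel_invariant():
    rng = np.random.default_rng(0)
    n, L = 12, 5
    alleles = rng.integers(1, 6, size=(n, L, 2))
    g = GenotypeTable([f"i{k}" for k in range(n)], [f"L{j}" for j in range(L)], alleles)
    res = queller_goodnight_r(g)
    assert np.allclose(res.r.values, res.r.values.T, equal_nan=True)
    # relabel alleles with an arbitrary injective map
    g2 = GenotypeTable(
        list(g.individuals), list(g.loci), 100 + 7 * g.alleles
    )
    res2 = queller_goodnight_r(g2)
    assert np.allclose(res.r.values, res2.r.values, equal_nan=True)


def test_qg_missing_locus_is_local_to_the_dyad():
    rng = np.random.default_rng(1)
    n, L = 8, 4
    alleles = rng.integers(1, 5, size=(n, L, 2))
    g = GenotypeTable([f"i{k}" for k in range(n)], [f"L{j}" for j in range(L)], alleles)
    base = queller_goodnight_r(g)
    alleles2 = alleles.copy()
    alleles2[0, 2] = -1  # individual 0 loses locus 2
    g2 = GenotypeTable(list(g.individuals), list(g.loci), alleles2)
    # frequencies held fixed so only the dyad computation changes
    freqs = allele_frequencies(g)
    pairs = [[i, j] for i in range(n) for j in range(i + 1, n) if i != 0 and j != 0]
    r1, _, _ = queller_goodnight_pairs(g, freqs, pairs)
    r2, _, _ = queller_goodnight_pairs(g2, freqs, pairs)
    assert np.allclose(r1, r2)


# ------------------------------------------------------------------ kinship test

def test_kinship_llr_is_zero_when_hypotheses_coincide():
    freqs = AlleleFrequencyTable(["L"], {"L": {1: 0.5, 2: 0.5}})
    g = table(["x", "y"], ["L"], [[[1, 2]], [[1, 1]]])
    llr = kinship_log_likelihood_ratio(g, freqs, [[0, 1]], h1=(0.0, 0.0), h0=(0.0, 0.0))
    assert llr[0] == 0.0


def test_kinship_unshared_locus_penalizes_maternal_hypothesis():
    # no shared allele: only the non-IBD term survives under H1, ratio < 1
    freqs = AlleleFrequencyTable(["L"], {"L": {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}})
    g = table(["x", "y"], ["L"], [[[1, 2]], [[3, 4]]])
    llr = kinship_log_likelihood_ratio(g, freqs, [[0, 1]])
    assert llr[0] < 0


def test_kinship_mother_offspring_certainty_shares_allele():
    # under H1=(0.5, 0) the maternal allele is IBD with certainty, so a
    # shared rare allele should strongly favor H1
    freqs = AlleleFrequencyTable(["L"], {"L": {1: 0.01, 2: 0.01, 3: 0.98}})
    g = table(["x", "y"], ["L"], [[[1, 2]], [[1, 2]]])
    llr = kinship_log_likelihood_ratio(g, freqs, [[0, 1]])
    assert llr[0] > np.log(10)


def test_kinship_rejects_overcommitted_relatedness():
    freqs = AlleleFrequencyTable(["L"], {"L": {1: 0.5, 2: 0.5}})
    g = table(["x", "y"], ["L"], [[[1, 2]], [[1, 1]]])
    with pytest.raises(ValueError, match="IBD"):
        kinship_log_likelihood_ratio(g, freqs, [[0, 1]], h1=(0.6, 0.0))


def test_significance_tiers():
    assert significance_tier(0.0005) == "a"
    assert significance_tier(0.005) == "b"
    assert significance_tier(0.04) == "c"
    assert significance_tier(0.2) is None


# ------------------------------------------------------------------ PI / exclusion

def _enumerate_genotypes(p):
    k = len(p)
    for i in range(k):
        for j in range(i, k):
            prob = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            yield (i, j), prob


def test_probability_of_identity_closed_form_cases():
    f = AlleleFrequencyTable(["L"], {"L": {1: 0.5, 2: 0.5}})
    per, overall = probability_of_identity(f)
    assert per["L"] == pytest.approx(0.375, abs=1e-15)

    mono = AlleleFrequencyTable(["L"], {"L": {1: 1.0}})
    assert probability_of_identity(mono)[1] == 1.0

    seven = AlleleFrequencyTable(
        [f"L{i}" for i in range(7)],
        {f"L{i}": {1: 0.5, 2: 0.5} for i in range(7)},
    )
    _, ov = probability_of_identity(seven)
    assert ov == pytest.approx(0.375**7, rel=1e-12)


def test_probability_of_identity_matches_enumeration():
    # PI = sum over genotype pairs of (genotype frequency)^2
    for p in ([0.5, 0.5], [0.6, 0.3, 0.1], [0.4, 0.3, 0.2, 0.1]):
        f = AlleleFrequencyTable(["L"], {"L": {i + 1: v for i, v in enumerate(p)}})
        per, _ = probability_of_identity(f)
        brute = sum(prob**2 for _, prob in _enumerate_genotypes(p))
        assert per["L"] == pytest.approx(brute, abs=1e-12)


def _brute_exclusion(p):
    """Trio enumeration oracle under HWE for the three exclusion cases."""
    genos = list(_enumerate_genotypes(p))
    single = second = pair = 0.0
    for M, pM in genos:
        for F, pF in genos:
            for ma in M:
                for fa in F:
                    pO = pM * pF * 0.25
                    O = {ma, fa}
                    single += pO * sum(
                        pC for C, pC in genos if not (set(C) & O)
                    )
                    o1, o2 = min(ma, fa), max(ma, fa)
                    paternal = set()
                    if o1 in M:
                        paternal.add(o2)
                    if o2 in M:
                        paternal.add(o1)
                    second += pO * sum(
                        pC for C, pC in genos if not (set(C) & paternal)
                    )
                    pair += pO * sum(
                        p1 * p2
                        for C1, p1 in genos
                        for C2, p2 in genos
                        if not any({x, y} == O for x in C1 for y in C2)
                    )
    return single, second, pair


@pytest.mark.parametrize(
    "p", [[0.5, 0.5], [0.6, 0.3, 0.1], [0.4, 0.3, 0.2, 0.1], [0.7, 0.1, 0.1, 0.1]]
)
def test_exclusion_matches_brute_force_enumeration(p):
    f = AlleleFrequencyTable(["L"], {"L": {i + 1: v for i, v in enumerate(p)}})
    df, _ = exclusion_probabilities(f)
    single, second, pair = _brute_exclusion(p)
    assert df.loc["L", "single_parent"] == pytest.approx(single, abs=1e-12)
    assert df.loc["L", "second_parent"] == pytest.approx(second, abs=1e-12)
    assert df.loc["L", "parent_pair"] == pytest.approx(pair, abs=1e-12)


def test_exclusion_monomorphic_and_monotone():
    mono = AlleleFrequencyTable(["L"], {"L": {1: 1.0}})
    df, comb = exclusion_probabilities(mono)
    assert df.loc["L"].abs().max() < 1e-12

    one = AlleleFrequencyTable(["L1"], {"L1": {1: 0.5, 2: 0.5}})
    two = AlleleFrequencyTable(
        ["L1", "L2"], {"L1": {1: 0.5, 2: 0.5}, "L2": {1: 0.6, 2: 0.4}}
    )
    _, c1 = exclusion_probabilities(one)
    _, c2 = exclusion_probabilities(two)
    for k in c1:
        assert c2[k] >= c1[k]


# ------------------------------------------------------------------ locus stats

def test_locus_stats_excess_heterozygotes():
    g = GenotypeTable(
        [f"i{k}" for k in range(10)],
        ["L"],
        np.tile(np.array([[[1, 2]]]), (10, 1, 1)),
    )
    df = locus_stats(g, n_randomizations=300, seed=0)
    assert df.loc["L", "Ho"] == 1.0
    assert df.loc["L", "Ho"] > df.loc["L", "He"]
    assert df.loc["L", "Fis"] < 0
    assert df.loc["L", "P"] > 0.9  # deficit p near 1 for an excess


def test_bonferroni_threshold_for_seven_loci():
    assert bonferroni_threshold(0.05, 7) == pytest.approx(0.00714, abs=5e-6)
    # the screening rule: an observed deficit p below the threshold flags a locus
    assert 0.0003 < bonferroni_threshold(0.05, 7)


def _oracle_deficit_p(alleles, n_rand, rng):
    """Independent route: at fixed allele counts F_is is strictly decreasing
    in Ho, so P(F_is_perm > F_is_obs) = P(Ho_perm < Ho_obs)."""
    flat = alleles.ravel()
    ho_obs = (alleles[:, 0] != alleles[:, 1]).mean()
    hits = 0
    for _ in range(n_rand):
        perm = rng.permutation(flat).reshape(-1, 2)
        hits += (perm[:, 0] != perm[:, 1]).mean() < ho_obs
    return hits / n_rand


def test_fis_deficit_p_matches_independent_oracle():
    rng = np.random.default_rng(12)
    for _ in range(8):
        alleles = rng.choice(4, size=(40, 1, 2), p=[0.4, 0.3, 0.2, 0.1]) + 1
        g = GenotypeTable([f"i{k}" for k in range(40)], ["L"], alleles)
        p_impl = locus_stats(g, n_randomizations=400, seed=rng).loc["L", "P"]
        p_oracle = _oracle_deficit_p(alleles[:, 0, :], 400, rng)
        se = np.sqrt(max(p_oracle * (1 - p_oracle), 0.01) / 400)
        assert p_impl == pytest.approx(p_oracle, abs=4 * se + 0.01)


def test_fis_deficit_p_null_distribution_matches_oracle_law():
    """Under HWE the randomization p follows a (slightly sub-uniform,
    because ties are counted as not-greater) discrete law; the
    implementation's p sample must match an independently coded oracle's."""
    rng = np.random.default_rng(13)

    def dataset():
        return rng.choice(4, size=(40, 1, 2), p=[0.4, 0.3, 0.2, 0.1]) + 1

    p_impl, p_oracle = [], []
    for _ in range(220):
        alleles = dataset()
        g = GenotypeTable([f"i{k}" for k in range(40)], ["L"], alleles)
        p_impl.append(locus_stats(g, n_randomizations=120, seed=rng).loc["L", "P"])
        p_oracle.append(_oracle_deficit_p(dataset()[:, 0, :], 120, rng))
    d, p = sps.ks_2samp(p_impl, p_oracle)
    assert p > 0.01
    # and the law is close to uniform: mean within a tie-mass allowance
    assert abs(np.mean(p_impl) - 0.5) < 0.08
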