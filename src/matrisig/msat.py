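"""Microsatellite statistics.

Pairwise relatedness (Queller & Goodnight 1989), a simulation-based
likelihood-ratio test for maternal kinship, probability of identity,
parentage exclusion probabilities (Jamieson & Taylor 1997) and per-locus
heterozygosity statistics with randomization p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencyTable, GenotypeTable, allele_frequencies
from .matrices import PairwiseMatrix

__all__ = [
    "RelatednessResult",
    "queller_goodnight_pairs",
    "queller_goodnight_r",
    "kinship_log_likelihood_ratio",
    "maternal_kinship_test",
    "significance_tier",
    "probability_of_identity",
    "exclusion_probabilities",
    "locus_stats",
    "bonferroni_threshold",
]


# --------------------------------------------------------------------------
# Queller & Goodnight relatedness
# --------------------------------------------------------------------------

@dataclass
class RelatednessResult:
    """Pairwise Queller–Goodnight relatedness with per-dyad bookkeeping.

    ``r`` may slightly exceed [-1, 1]; raw values are kept.  ``significance``
    is filled by :func:`maternal_kinship_test` (NaN until then).
    ``allelic_exclusions`` counts co-typed loci at which the dyad shares no
    allele.
    """

    r: PairwiseMatrix
    n_loci_used: PairwiseMatrix
    allelic_exclusions: PairwiseMatrix
    significance: PairwiseMatrix

    @property
    def labels(self) -> list[str]:
        return self.r.labels


def _freq_lookup(freqs: AlleleFrequencyTable, locus: str, alleles: np.ndarray) -> np.ndarray:
    table = freqs[locus]
    return np.array([table.get(int(a), 0.0) for a in alleles.ravel()]).reshape(alleles.shape)


def queller_goodnight_pairs(
    genotypes: GenotypeTable,
    frequencies: AlleleFrequencyTable,
    pairs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Queller–Goodnight r for an ``(m, 2)`` array of individual index pairs.

    Both focal directions are combined by summing numerators and
    denominators over loci and directions (ratio of sums).  Loci at which
    either individual is untyped are skipped for that dyad.

    Returns ``(r, n_loci_used, allelic_exclusions)``; r is NaN for dyads
    with no co-typed locus.
    """
    pairs = np.asarray(pairs, dtype=int)
    m = len(pairs)
    num = np.zeros(m)
    den = np.zeros(m)
    n_used = np.zeros(m, dtype=int)
    n_excl = np.zeros(m, dtype=int)
    typed = genotypes.typed_mask()
    for j, locus in enumerate(genotypes.loci):
        i1, i2 = pairs[:, 0], pairs[:, 1]
        ok = typed[i1, j] & typed[i2, j]
        if not ok.any():
            continue
        a, b = genotypes.alleles[i1, j, 0], genotypes.alleles[i1, j, 1]
        c, d = genotypes.alleles[i2, j, 0], genotypes.alleles[i2, j, 1]
        pa = _freq_lookup(frequencies, locus, a)
        pb = _freq_lookup(frequencies, locus, b)
        pc = _freq_lookup(frequencies, locus, c)
        pd_ = _freq_lookup(frequencies, locus, d)
        share = ((a == c).astype(float) + (a == d) + (b == c) + (b == d))
        # focal 1: 0.5*share - pa - pb ; focal 2: 0.5*share - pc - pd
        num_l = share - pa - pb - pc - pd_
        den_l = (1.0 + (a == b) - pa - pb) + (1.0 + (c == d) - pc - pd_)
        num += np.where(ok, num_l, 0.0)
        den += np.where(ok, den_l, 0.0)
        n_used += ok
        n_excl += ok & (share == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(n_used > 0, num / den, np.nan)
    return r, n_used, n_excl


def queller_goodnight_r(
    genotypes: GenotypeTable,
    frequencies: AlleleFrequencyTable | None = None,
) -> RelatednessResult:
    """All-dyads symmetric Queller–Goodnight relatedness matrix.

    Frequencies default to the full-sample estimates from ``genotypes``
    (no leave-out correction; see package docs).
    """
    if frequencies is None:
        frequencies = allele_frequencies(genotypes)
    n = genotypes.n_individuals
    iu = np.triu_indices(n, 1)
    pairs = np.column_stack(iu)
    r, used, excl = queller_goodnight_pairs(genotypes, frequencies, pairs)

    def square(vec, fill=0.0):
        M = np.full((n, n), fill, dtype=float)
        M[iu] = vec
        M[(iu[1], iu[0])] = vec
        return M

    labels = list(genotypes.individuals)
    return RelatednessResult(
        r=PairwiseMatrix(labels, square(r), check_symmetry=False),
        n_loci_used=PairwiseMatrix(labels, square(used)),
        allelic_exclusions=PairwiseMatrix(labels, square(excl)),
        significance=PairwiseMatrix(labels, square(np.full(len(r), np.nan)),
                                    check_symmetry=False),
    )


# --------------------------------------------------------------------------
# Maternal kinship likelihood-ratio test
# --------------------------------------------------------------------------

def _pair_locus_likelihood_ratio(a, b, c, d, pa, pb, pc, pd_, r_m, r_p,
                                 error_rate=0.0):
    """Per-locus likelihood ratio L(H)/L(independence) for genotype pairs.

    Under hypothesis H = (r_m, r_p) the maternal (paternal) alleles of the
    two individuals are identical by descent with probability 2*r_m (2*r_p);
    non-IBD alleles are independent draws from the population.  Phase is
    unknown, so both phase assignments of each individual are averaged.
    The factor P(G1) is common to H and the null and cancels.

    ``error_rate`` mixes in the independence likelihood,
    ``(1 - e) * L_H/L_0 + e``, so that a locus at which the dyad shares no
    allele (impossible under strict mother-offspring transmission, but
    expected occasionally from mutation or scoring error) contributes the
    small non-IBD term instead of a zero that would dominate the whole
    multilocus statistic.
    """
    pm, pp = 2.0 * r_m, 2.0 * r_p
    if pm > 1.0 + 1e-12 or pp > 1.0 + 1e-12:
        raise ValueError("per-line relatedness above 0.5 implies IBD probability > 1")
    total = np.zeros(np.broadcast(a, c).shape, dtype=float)
    phases1 = ((a, b), (b, a))
    phases2 = ((c, d, pc, pd_), (d, c, pd_, pc))
    for m1, p1 in phases1:
        for m2, p2, pm2, pp2 in phases2:
            mat = (1.0 - pm) * pm2 + pm * (m2 == m1)
            pat = (1.0 - pp) * pp2 + pp * (p2 == p1)
            total += mat * pat
    total /= 4.0
    ratio = total / (pc * pd_)
    if error_rate:
        ratio = (1.0 - error_rate) * ratio + error_rate
    return ratio


def kinship_log_likelihood_ratio(
    genotypes: GenotypeTable,
    frequencies: AlleleFrequencyTable,
    pairs: np.ndarray,
    h1: tuple[float, float] = (0.5, 0.0),
    h0: tuple[float, float] = (0.0, 0.0),
    error_rate: float = 0.01,
) -> np.ndarray:
    """Summed log likelihood ratio H1/H0 across co-typed loci per dyad."""
    pairs = np.asarray(pairs, dtype=int)
    llr = np.zeros(len(pairs))
    typed = genotypes.typed_mask()
    for j, locus in enumerate(genotypes.loci):
        i1, i2 = pairs[:, 0], pairs[:, 1]
        ok = typed[i1, j] & typed[i2, j]
        if not ok.any():
            continue
        a, b = genotypes.alleles[i1, j, 0], genotypes.alleles[i1, j, 1]
        c, d = genotypes.alleles[i2, j, 0], genotypes.alleles[i2, j, 1]
        pa = _freq_lookup(frequencies, locus, a)
        pb = _freq_lookup(frequencies, locus, b)
        pc = _freq_lookup(frequencies, locus, c)
        pd_ = _freq_lookup(frequencies, locus, d)
        r1 = _pair_locus_likelihood_ratio(a, b, c, d, pa, pb, pc, pd_, *h1,
                                          error_rate=error_rate)
        r0 = _pair_locus_likelihood_ratio(a, b, c, d, pa, pb, pc, pd_, *h0,
                                          error_rate=error_rate)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.log(r1) - np.log(r0)
        llr += np.where(ok, contrib, 0.0)
    return llr


def _simulate_null_dyads(frequencies, loci, n_sim, rng):
    """Genotype table of 2*n_sim unrelated individuals drawn under HWE."""
    arrays = frequencies.as_arrays()
    alleles = np.empty((2 * n_sim, len(loci), 2), dtype=int)
    for j, locus in enumerate(loci):
        labels, p = arrays[locus]
        alleles[:, j, :] = rng.choice(labels, size=(2 * n_sim, 2), p=p)
    ids = [f"sim{i}" for i in range(2 * n_sim)]
    return GenotypeTable(ids, list(loci), alleles)


def maternal_kinship_test(
    genotypes: GenotypeTable,
    frequencies: AlleleFrequencyTable,
    pairs: np.ndarray,
    n_sim: int = 10000,
    seed: int | np.random.Generator | None = None,
    h1: tuple[float, float] = (0.5, 0.0),
    h0: tuple[float, float] = (0.0, 0.0),
    error_rate: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulation test of maternal kinship for each dyad.

    H1 defaults to (r_maternal = 0.5, r_paternal = 0) against a null of
    unrelatedness.  The null distribution of the summed log likelihood
    ratio is built from ``n_sim`` dyads simulated under H0 from the
    population allele frequencies; ``p = proportion of null statistics >=
    observed``.  Dyads with missing loci are compared against a null
    restricted to the same co-typed loci.  ``error_rate`` is the
    mutation/scoring-error allowance that keeps an allele-sharing-free
    locus from zeroing the maternal likelihood.

    Returns ``(p_values, observed_llr)``.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = np.asarray(pairs, dtype=int)
    typed = genotypes.typed_mask()
    observed = kinship_log_likelihood_ratio(
        genotypes, frequencies, pairs, h1, h0, error_rate=error_rate
    )

    patterns = typed[pairs[:, 0]] & typed[pairs[:, 1]]
    p_values = np.empty(len(pairs))
    null_cache: dict[bytes, np.ndarray] = {}
    for key in np.unique(patterns, axis=0):
        mask = (patterns == key).all(axis=1)
        loci = [l for l, keep in zip(genotypes.loci, key) if keep]
        if not loci:
            p_values[mask] = np.nan
            continue
        cache_key = key.tobytes()
        if cache_key not in null_cache:
            sub = AlleleFrequencyTable(loci, {l: frequencies[l] for l in loci})
            sim = _simulate_null_dyads(sub, loci, n_sim, rng)
            sim_pairs = np.arange(2 * n_sim).reshape(n_sim, 2)
            null_cache[cache_key] = kinship_log_likelihood_ratio(
                sim, sub, sim_pairs, h1, h0, error_rate=error_rate
            )
        null = null_cache[cache_key]
        obs = observed[mask]
        p_values[mask] = (null[None, :] >= obs[:, None]).mean(axis=1)
    return p_values, observed


def significance_tier(p: float) -> str | None:
    """Map a kinship-test p-value to the a/b/c significance tiers
    (p < 0.001, < 0.01, < 0.05); None if not significant."""
    if np.isnan(p):
        return None
    if p < 0.001:
        return "a"
    if p < 0.01:
        return "b"
    if p < 0.05:
        return "c"
    return None


# --------------------------------------------------------------------------
# Probability of identity and exclusion probabilities
# --------------------------------------------------------------------------

def probability_of_identity(frequencies: AlleleFrequencyTable) -> tuple[dict[str, float], float]:
    """Per-locus and overall probability that two random individuals share a
    genotype under HWE: PI = sum p_i^4 + sum_{i<j} (2 p_i p_j)^2; overall is
    the product across loci."""
    per_locus = {}
    for locus in frequencies.loci:
        p = np.array(list(frequencies[locus].values()))
        pi = float(np.sum(p**4))
        outer = np.outer(p, p)
        iu = np.triu_indices(len(p), 1)
        pi += float(np.sum((2.0 * outer[iu]) ** 2))
        per_locus[locus] = pi
    overall = float(np.prod(list(per_locus.values())))
    return per_locus, overall


def _exclusion_single(a2, a3, a4, a5, a6):
    """Closed-form per-locus exclusion probabilities (Jamieson & Taylor 1997)
    in terms of power sums a_k = sum_i p_i^k.

    Returns (single alleged parent with the other parent unknown,
    second parent given one known parent, parent pair).
    """
    p_single = 1 - 4 * a2 + 2 * a2**2 + 4 * a3 - 3 * a4
    p_second = 1 - 2 * a2 + a3 + 2 * a4 - 3 * a5 - 2 * a2**2 + 3 * a2 * a3
    p_pair = 1 + 4 * a4 - 4 * a5 - 3 * a6 - 8 * a2**2 + 8 * a2 * a3 + 2 * a3**2
    return p_single, p_second, p_pair


def exclusion_probabilities(
    frequencies: AlleleFrequencyTable,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Parentage exclusion probabilities per locus and combined across loci.

    Three cases: ``single_parent`` (an alleged parent tested with the other
    parent unknown), ``second_parent`` (alleged parent tested with one
    parent known) and ``parent_pair``.  Loci combine as 1 - prod(1 - E).
    """
    rows = []
    for locus in frequencies.loci:
        p = np.array(list(frequencies[locus].values()))
        a = [float(np.sum(p**k)) for k in range(2, 7)]
        rows.append((locus,) + _exclusion_single(*a))
    df = pd.DataFrame(rows, columns=["locus", "single_parent", "second_parent", "parent_pair"])
    df = df.set_index("locus")
    combined = {c: float(1.0 - np.prod(1.0 - df[c].to_numpy())) for c in df.columns}
    return df, combined


# --------------------------------------------------------------------------
# Heterozygosity, F_is and randomization p-values
# --------------------------------------------------------------------------

def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 7) -> float:
    return alpha / n_tests


def _fis_components(alleles: np.ndarray) -> tuple[float, float, float]:
    """(Ho, Hs, He_unbiased) for an (n, 2) typed allele array.

    Hs is the Nei & Chesser (1983) small-sample gene diversity used in the
    F_is estimate ``f = 1 - Ho/Hs``; He is the unbiased expected
    heterozygosity 2n(1 - sum p^2)/(2n - 1).
    """
    n = len(alleles)
    ho = float((alleles[:, 0] != alleles[:, 1]).mean())
    _, counts = np.unique(alleles.ravel(), return_counts=True)
    p = counts / (2 * n)
    sp2 = float(np.sum(p**2))
    he = 2 * n * (1.0 - sp2) / (2 * n - 1)
    hs = (n / (n - 1)) * (1.0 - sp2 - ho / (2 * n)) if n > 1 else np.nan
    return ho, hs, he


def locus_stats(
    genotypes: GenotypeTable,
    n_randomizations: int = 7000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-locus He, Ho, F_is and heterozygote-deficit p-value, plus an
    overall row pooling loci.

    The p-value is the proportion of allele randomizations (alleles permuted
    among individuals within a locus) giving a strictly larger F_is than
    observed.  Loci with fewer than two typed individuals are skipped with a
    warning column.  The Bonferroni-corrected threshold alpha/n_loci is
    attached as DataFrame metadata (``df.attrs['bonferroni']``).
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    typed = genotypes.typed_mask()
    rows = []
    kept = []  # (n, ho, hs) plus permuted (ho, hs) arrays, for pooling
    for j, locus in enumerate(genotypes.loci):
        mask = typed[:, j]
        n = int(mask.sum())
        if n < 2:
            import warnings

            warnings.warn(f"locus {locus!r} has fewer than 2 typed individuals; skipped")
            rows.append((locus, n, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        alleles = genotypes.alleles[mask, j, :]
        ho, hs, he = _fis_components(alleles)
        fis = 1.0 - ho / hs if hs > 0 else np.nan
        # permute alleles among individuals; allele counts (hence p and He)
        # are invariant under the shuffle, only Ho moves
        flat = alleles.ravel()
        sp2 = _sum_p2(flat)
        perm_ho = np.empty(n_randomizations)
        for k in range(n_randomizations):
            perm = rng.permutation(flat).reshape(-1, 2)
            perm_ho[k] = (perm[:, 0] != perm[:, 1]).mean()
        perm_hs = (n / (n - 1)) * (1.0 - sp2 - perm_ho / (2 * n))
        perm_fis = 1.0 - perm_ho / perm_hs
        p_deficit = float((perm_fis > fis).mean())
        rows.append((locus, n, len(np.unique(flat)), he, ho, fis, p_deficit))
        kept.append((n, ho, hs, perm_ho, perm_hs))

    df = pd.DataFrame(rows, columns=["locus", "N", "alleles", "He", "Ho", "Fis", "P"])
    df = df.set_index("locus")

    if kept:
        ho_sum = sum(n * ho for n, ho, _, _, _ in kept)
        hs_sum = sum(n * hs for n, _, hs, _, _ in kept)
        fis_overall = 1.0 - ho_sum / hs_sum
        perm_ho_sums = sum(n * pho for n, _, _, pho, _ in kept)
        perm_hs_sums = sum(n * phs for n, _, _, _, phs in kept)
        perm_fis_overall = 1.0 - perm_ho_sums / perm_hs_sums
        p_overall = float((perm_fis_overall > fis_overall).mean())
        sub = df.dropna(subset=["Fis"])
        df.loc["overall"] = (
            sub["N"].mean(),
            sub["alleles"].mean(),
            sub["He"].mean(),
            sub["Ho"].mean(),
            fis_overall,
            p_overall,
        )
    df.attrs["bonferroni"] = bonferroni_threshold(alpha, max(len(genotypes.loci), 1))
    return df


def _sum_p2(flat_alleles: np.ndarray) -> float:
    _, counts = np.unique(flat_alleles, return_counts=True)
    p = counts / counts.sum()
    return float(np.sum(p**2))
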