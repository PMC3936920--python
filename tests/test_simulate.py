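"""Synthetic-population generator: determinism, structure, calibration."""

import numpy as np
import pandas as pd
import pytest

from matrisig import (
    SimConfig,
    allele_frequencies,
    collapse_haplotypes,
    estimate_variance_components,
    simulate_calls,
    simulate_population,
)
from matrisig.acoustics import ACOUSTIC_PARAMETERS


def test_config_validation():
    with pytest.raises(ValueError, match="matriline"):
        SimConfig(n_matrilines=0).validate()
    with pytest.raises(ValueError, match="locus"):
        SimConfig(loci_spec=[]).validate()
    with pytest.raises(ValueError, match="negative SD"):
        cfg = SimConfig()
        cfg.variance_components["F0S"] = (-1.0, 0.0, 0.0)
        cfg.validate()
    with pytest.raises(ValueError, match="cosleep"):
        SimConfig(cosleep_rate_kin=0.1, cosleep_rate_nonkin=0.5).validate()


def test_simulation_is_deterministic_under_seed():
    cfg = SimConfig(seed=123)
    p1, p2 = simulate_population(cfg), simulate_population(cfg)
    assert np.array_equal(p1.genotypes.alleles, p2.genotypes.alleles)
    assert p1.haplotype_sequences.seqs == p2.haplotype_sequences.seqs
    assert p1.cosleep.equals(p2.cosleep)
    c1 = simulate_calls(p1.pedigree, cfg)
    c2 = simulate_calls(p2.pedigree, cfg)
    assert c1.equals(c2)


def test_pedigree_structure_and_haplotype_inheritance(default_population):
    pop = default_population
    ped = pop.pedigree
    for child, mother in ped.mother_of.items():
        assert ped.matriline_of[child] == ped.matriline_of[mother]
        assert pop.haplotype_of[child] == pop.haplotype_of[mother]
        # Mendelian: child carries at least one maternal allele at every locus
        ci = pop.genotypes.individuals.index(child)
        mi = pop.genotypes.individuals.index(mother)
        for j in range(pop.genotypes.n_loci):
            child_alleles = set(pop.genotypes.alleles[ci, j])
            mother_alleles = set(pop.genotypes.alleles[mi, j])
            assert child_alleles & mother_alleles
    # founder matrilines carry distinct haplotypes
    founder_haps = {}
    for f in ped.females():
        founder_haps.setdefault(ped.matriline_of[f], set()).add(pop.haplotype_of[f])
    haps = [next(iter(s)) for s in founder_haps.values()]
    assert all(len(s) == 1 for s in founder_haps.values())
    assert len(set(haps)) == len(haps)


def test_haplotype_partition_equals_matriline_partition(default_population):
    pop = default_population
    haps = collapse_haplotypes(pop.female_sequences())
    by_hap = {frozenset(m) for m in haps.members.values()}
    by_mat = {}
    for f in pop.pedigree.females():
        by_mat.setdefault(pop.pedigree.matriline_of[f], set()).add(f)
    assert by_hap == {frozenset(s) for s in by_mat.values()}


def test_founder_genotypes_track_configured_frequencies():
    cfg = SimConfig(n_matrilines=1, females_per_matriline=(1, 1),
                    n_unrelated_males=500, n_haplotypes=1, seed=9)
    pop = simulate_population(cfg)
    est = allele_frequencies(pop.genotypes)
    for locus, p_true in pop.allele_frequencies_true.items():
        for a, p in enumerate(p_true):
            if p < 1e-3:
                continue
            se = np.sqrt(p * (1 - p) / (2 * 501))
            assert abs(est[locus].get(a, 0.0) - p) < 5 * se


def test_zero_variance_gives_exact_parameter_means():
    cfg = SimConfig(seed=3).with_variance_split(0.0, 0.0, 0.0)
    pop = simulate_population(cfg)
    calls = simulate_calls(pop.pedigree, cfg)
    for p in ACOUSTIC_PARAMETERS:
        assert np.allclose(calls[p], cfg.parameter_means[p])


def test_call_counts_and_series_structure(default_calls, default_population):
    cfg = default_population.config
    counts = default_calls.groupby("id").size()
    assert (counts == cfg.calls_per_female).all()
    n_series = default_calls.groupby("id")["series"].nunique()
    lo, hi = cfg.series_per_female
    assert n_series.between(lo, hi).all()
    assert (default_calls[ACOUSTIC_PARAMETERS] >= 0).all().all()


def test_default_medians_fall_in_published_quartile_ranges():
    """Medians of pooled default-population calls sit inside the reported
    interquartile ranges (averaged over replicate populations to damp the
    six-matriline sampling noise)."""
    bands = {
        "F0S": (10156, 12061),
        "F0Peak": (12500, 16602),
        "F0E": (10156, 12891),
        "StartBandwidth": (3062, 4646),
        "CallDuration": (32, 48),
        "TimeToPeak": (17, 26),
        "InterCallInterval": (101, 197),
    }
    medians = []
    for seed in range(8):
        cfg = SimConfig(seed=seed)
        pop = simulate_population(cfg)
        medians.append(simulate_calls(pop.pedigree, cfg)[list(bands)].median())
    med = pd.DataFrame(medians).mean()
    for p, (lo, hi) in bands.items():
        assert lo <= med[p] <= hi, f"{p}: {med[p]:.1f} outside [{lo}, {hi}]"


def test_variance_component_recovery():
    """Nested decomposition recovers the configured variances within 15%
    at 50 matrilines x 5 females x 10 calls (averaged over replicates)."""
    ratios = []
    for seed in (100, 101, 102, 103):
        cfg = SimConfig(
            n_matrilines=50, females_per_matriline=(5, 5), n_haplotypes=50, seed=seed
        )
        pop = simulate_population(cfg)
        calls = simulate_calls(pop.pedigree, cfg)
        est = estimate_variance_components(calls, pop.pedigree.matriline_of, "F0S")
        true = tuple(v**2 for v in cfg.variance_components["F0S"])
        ratios.append([e / t for e, t in zip(est, true)])
    mean_ratio = np.mean(ratios, axis=0)
    assert np.all(np.abs(mean_ratio - 1.0) < 0.15)


def test_cosleep_records_pair_same_matriline_only():
    cfg = SimConfig(seed=6)  # nonkin rate 0 by default
    pop = simulate_population(cfg)
    mat_of = pop.pedigree.matriline_of
    for (_, site), members in pop.cosleep.groupby(["date", "site"])["id"]:
        assert len({mat_of[m] for m in members}) == 1


def test_population_writers_round_trip(tmp_path, default_population):
    from matrisig import AlignedSequences, GenotypeTable

    paths = default_population.write(tmp_path)
    g = GenotypeTable.from_csv(paths["genotypes"])
    assert np.array_equal(g.alleles, default_population.genotypes.alleles)
    aln = AlignedSequences.from_fasta(paths["haplotypes"])
    assert len(aln) == len(default_population.pedigree.females())
    cos = pd.read_csv(paths["cosleep"], comment="#")
    assert list(cos.columns) == ["date", "site", "id"]
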