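"""End-to-end pipeline runner.

Stage order follows the analysis dependency chain: genetics (locus
screening, relatedness, kinship tests) -> haplotypes -> kin groups -> call
PCA -> nested pDFA -> Mantel test.  Each stage writes its artifact plus a
JSON provenance record (inputs hash, seed, parameters) into the output
directory; a failing stage halts its dependents.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import msat
from .acoustics import CallPCA
from .genotypes import GenotypeTable, allele_frequencies
from .kin_groups import assign_kin_groups, build_cosleep_graph
from .mantel import MantelTest, acoustic_distance_matrix
from .mtdna import AlignedSequences, collapse_haplotypes
from .pdfa import NestedPDFA
from .simulate import SimConfig, simulate_calls, simulate_population


@dataclass
class PipelineConfig:
    """Either a simulation config or paths to real input files."""

    outdir: str
    simulation: SimConfig | None = None
    genotypes_csv: str | None = None
    fasta: str | None = None
    telemetry_csv: str | None = None
    calls_csv: str | None = None
    alpha: float = 0.05
    n_kinship_sim: int = 2000
    n_pdfa_permutations: int = 10_000
    n_mantel_permutations: int = 1000
    n_fis_randomizations: int = 7000
    seed: int = 0

    def validate(self) -> None:
        real = [self.genotypes_csv, self.fasta, self.telemetry_csv, self.calls_csv]
        if self.simulation is not None and any(real):
            raise ValueError("configure either simulation or real inputs, not both")
        if self.simulation is None and not any(real):
            raise ValueError("no inputs: set simulation or real input paths")


def _sha(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def _provenance(outdir: Path, stage: str, seed, params: dict, inputs) -> None:
    rec = {"stage": stage, "seed": seed, "parameters": params, "inputs_hash": _sha(inputs)}
    (outdir / f"{stage}.provenance.json").write_text(json.dumps(rec, indent=2, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all runnable stages; returns a bundle of in-memory results."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    bundle: dict = {}

    # ----- inputs -------------------------------------------------------
    if config.simulation is not None:
        sim = config.simulation
        population = simulate_population(sim)
        calls = simulate_calls(population.pedigree, sim)
        population.write(outdir)
        with open(outdir / "calls.csv", "w") as fh:
            fh.write(f"# seed={sim.seed}\n")
            calls.to_csv(fh, index=False)
        genotypes = population.genotypes
        sequences = population.female_sequences()
        telemetry = population.cosleep
        _provenance(outdir, "simulate", sim.seed, asdict(sim), sim)
    else:
        genotypes = (
            GenotypeTable.from_csv(config.genotypes_csv) if config.genotypes_csv else None
        )
        sequences = AlignedSequences.from_fasta(config.fasta) if config.fasta else None
        telemetry = (
            pd.read_csv(config.telemetry_csv, comment="#") if config.telemetry_csv else None
        )
        calls = pd.read_csv(config.calls_csv, comment="#") if config.calls_csv else None
    bundle["calls"] = calls

    # ----- genetics -----------------------------------------------------
    relatedness = None
    if genotypes is not None:
        stats = msat.locus_stats(
            genotypes,
            n_randomizations=config.n_fis_randomizations,
            seed=int(seeds[0].generate_state(1)[0] % 2**31),
            alpha=config.alpha,
        )
        stats.to_csv(outdir / "locus_stats.csv")
        bundle["locus_stats"] = stats
        # drop loci with a significant heterozygote deficit (Bonferroni)
        threshold = stats.attrs["bonferroni"]
        drop = [
            l for l in genotypes.loci
            if l in stats.index and stats.loc[l, "P"] < threshold
        ]
        bundle["dropped_loci"] = drop
        if drop:
            genotypes = genotypes.drop_loci(drop)
        freqs = allele_frequencies(genotypes)
        relatedness = msat.queller_goodnight_r(genotypes, freqs)
        relatedness.r.to_csv(outdir / "relatedness.csv")
        n = genotypes.n_individuals
        iu = np.triu_indices(n, 1)
        pairs = np.column_stack(iu)
        pvals, _ = msat.maternal_kinship_test(
            genotypes,
            freqs,
            pairs,
            n_sim=config.n_kinship_sim,
            seed=int(seeds[1].generate_state(1)[0] % 2**31),
        )
        sig = relatedness.significance.values
        sig[iu] = pvals
        sig[(iu[1], iu[0])] = pvals
        pi_locus, pi_overall = msat.probability_of_identity(freqs)
        excl, excl_combined = msat.exclusion_probabilities(freqs)
        bundle["probability_of_identity"] = pi_overall
        bundle["exclusion_combined"] = excl_combined
        bundle["relatedness"] = relatedness
        _provenance(
            outdir, "genetics",
            config.seed,
            {"alpha": config.alpha, "dropped": drop, "n_kinship_sim": config.n_kinship_sim},
            genotypes.alleles.tobytes(),
        )

    # ----- haplotypes ---------------------------------------------------
    haplotypes = None
    if sequences is not None:
        haplotypes = collapse_haplotypes(sequences)
        pd.Series(haplotypes.haplotype_of()).rename("haplotype").to_csv(
            outdir / "haplotypes.csv", index_label="id"
        )
        bundle["haplotypes"] = haplotypes
        _provenance(outdir, "haplotypes", None, {}, sequences.seqs)

    # ----- kin groups ---------------------------------------------------
    assignment = None
    if telemetry is not None and relatedness is not None and haplotypes is not None:
        cosleep = build_cosleep_graph(telemetry)
        hap_of = haplotypes.haplotype_of()
        females = [f for f in relatedness.labels if f in hap_of or f in cosleep.effort]
        p_tier = {}
        for i, a in enumerate(females):
            for b in females[i + 1:]:
                p_tier[(a, b)] = msat.significance_tier(relatedness.significance[a, b])
        rel = {
            (a, b): relatedness.r[a, b]
            for i, a in enumerate(females)
            for b in females[i + 1:]
        }
        assignment = assign_kin_groups(females, hap_of, cosleep, p_tier, rel)
        assignment.to_csv(outdir / "kin_groups.csv")
        bundle["kin_groups"] = assignment
        _provenance(outdir, "kin_groups", None, {}, (females, p_tier))

    # ----- acoustics / PCA ---------------------------------------------
    pca = None
    if calls is not None:
        pca = CallPCA(calls).fit()
        pca.scores.to_csv(outdir / "pca_scores.csv", index=False)
        bundle["pca"] = pca
        _provenance(outdir, "pca", None, {"n_retained": pca.n_retained}, len(calls))

    # ----- pDFA ---------------------------------------------------------
    if pca is not None and assignment is not None:
        group_of = assignment.group_of()
        scored = pca.scores[pca.scores["id"].isin(group_of)].copy()
        scored["group"] = scored["id"].map(group_of)
        if scored["group"].nunique() >= 2:
            pdfa_seed = int(seeds[2].generate_state(1)[0] % 2**31)
            result = NestedPDFA(scored, predictors="PC1").fit(
                n_permutations=config.n_pdfa_permutations, seed=pdfa_seed
            )
            (outdir / "pdfa.json").write_text(
                json.dumps(
                    {
                        "observed_correct_pct": result.observed_correct,
                        "chance_level_pct": result.chance_level,
                        "p": result.p_value,
                        "n_permutations": result.n_permutations,
                        "seed": pdfa_seed,
                    },
                    indent=2,
                )
            )
            result.by_individual().to_csv(outdir / "pdfa_by_individual.csv", index=False)
            bundle["pdfa"] = result
            _provenance(
                outdir, "pdfa", pdfa_seed,
                {"n_permutations": config.n_pdfa_permutations}, len(scored),
            )

    # ----- Mantel -------------------------------------------------------
    if pca is not None and relatedness is not None and assignment is not None:
        group_of = assignment.group_of()
        means = pca.mean_scores().loc[lambda s: s.index.isin(group_of)]
        if len(means) >= 4:
            dist = acoustic_distance_matrix(means)
            rel = relatedness.r.reorder(list(dist.labels))
            mantel_seed = int(seeds[3].generate_state(1)[0] % 2**31)
            res = MantelTest(rel, dist).fit(
                n_permutations=config.n_mantel_permutations, seed=mantel_seed
            )
            (outdir / "mantel.json").write_text(
                json.dumps(
                    {
                        "Z": res.z,
                        "r": res.r,
                        "g": res.g,
                        "p": res.p_value,
                        "tail": res.tail,
                        "n_permutations": res.n_permutations,
                        "seed": mantel_seed,
                    },
                    indent=2,
                )
            )
            bundle["mantel"] = res
            _provenance(
                outdir, "mantel", mantel_seed,
                {"n_permutations": config.n_mantel_permutations}, len(means),
            )

    return bundle
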