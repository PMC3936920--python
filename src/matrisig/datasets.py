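"""Packaged study fixtures.

Two small published tables from the study system ship with the package:
the combined pairwise matrix of the 16 kin-group females (relatedness in
the upper triangle, acoustic distance in the lower) and the within-group
dyad evidence (co-sleeping, relatedness tiers, haplotypes).  Raw genotypes
and raw call measurements were not published, so those stages are exercised
on synthetic data instead.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .kin_groups import UNKNOWN
from .matrices import PairwiseMatrix


def _data_path(name: str):
    return resources.files("matrisig.data").joinpath(name)


def load_study_matrices() -> tuple[PairwiseMatrix, PairwiseMatrix]:
    """(relatedness, acoustic_distance) for the 16 study females.

    The packaged CSV stores both triangles of one square table; each is
    mirrored into a full symmetric matrix.
    """
    with _data_path("study_female_matrices.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0, comment="#")
    labels = [str(c) for c in df.columns]
    M = df.to_numpy(float)
    iu = np.triu_indices(len(labels), 1)
    R = np.zeros_like(M)
    D = np.zeros_like(M)
    R[iu] = M[iu]
    R += R.T
    D.T[iu] = M.T[iu]
    D += D.T
    return PairwiseMatrix(labels, R), PairwiseMatrix(labels, D)


def load_study_kin_group_evidence() -> tuple[pd.DataFrame, dict[str, str]]:
    """(within-group dyad table, haplotype map) for the study females."""
    with _data_path("study_kin_group_dyads.csv").open() as fh:
        dyads = pd.read_csv(fh, comment="#")
    with _data_path("study_haplotypes.csv").open() as fh:
        haps = pd.read_csv(fh, comment="#")
    return dyads, dict(zip(haps["id"].astype(str), haps["haplotype"].astype(str)))


def study_evidence_maps() -> tuple[
    list[str],
    dict[str, str | None],
    dict[tuple[str, str], str],
    dict[tuple[str, str], str | None],
    dict[tuple[str, str], float],
]:
    """Evidence in the form :func:`matrisig.kin_groups.assign_kin_groups`
    consumes: females, haplotypes, per-dyad co-sleep status, significance
    tiers and relatedness.

    Within-group dyads carry the published evidence; all females were
    radio-tracked, so dyads never seen at a shared site count as co-sleep
    'no'.  Cross-group significance tiers come from the published
    relatedness matrix (one tier-c dyad; all others non-significant).
    """
    relmat, _ = load_study_matrices()
    dyads, haplotype_of = load_study_kin_group_evidence()
    females = list(relmat.labels)

    hap_map: dict[str, str | None] = {
        f: (None if h == "??" else h) for f, h in haplotype_of.items()
    }
    cosleep: dict[tuple[str, str], str] = {}
    p_tier: dict[tuple[str, str], str | None] = {}
    relatedness: dict[tuple[str, str], float] = {}
    for i, a in enumerate(females):
        for b in females[i + 1:]:
            cosleep[(a, b)] = "no"
            p_tier[(a, b)] = None
            relatedness[(a, b)] = relmat[a, b]
    for row in dyads.itertuples():
        key = (row.a, row.b) if (row.a, row.b) in cosleep else (row.b, row.a)
        cosleep[key] = UNKNOWN if row.cosleep == "unknown" else row.cosleep
        p_tier[key] = row.p_tier
    # the one significant between-group dyad in the published matrix
    p_tier[("41-11", "45-10")] = "c"
    return females, hap_map, cosleep, p_tier, relatedness
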