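"""Mitochondrial D-loop haplotypes.

Pairwise differences between aligned sequences, collapsing identical
sequences into haplotypes, and a minimum-spanning haplotype graph (a
deliberately simple stand-in for a full median-joining network).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrices import PairwiseMatrix

_GAPLIKE = (ord("-"), ord("N"))


@dataclass
class AlignedSequences:
    """Equal-length aligned sequences over {A, C, G, T, -, N}."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
        self.seqs = [s.upper() for s in self.seqs]

    def __len__(self) -> int:
        return len(self.ids)

    def as_matrix(self) -> np.ndarray:
        """(n, L) uint8 matrix of character codes."""
        return np.frombuffer("".join(self.seqs).encode(), dtype=np.uint8).reshape(
            len(self.seqs), -1
        )

    @classmethod
    def from_fasta(cls, path) -> "AlignedSequences":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path, header_comment: str | None = None) -> None:
        records = [SeqRecord(Seq(s), id=i, description=header_comment or "")
                   for i, s in zip(self.ids, self.seqs)]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class HaplotypeSet:
    """A partition of sequences into identical-sequence haplotypes.

    Labels are H1, H2, ... in decreasing frequency, ties broken by the
    lexicographically smallest member id.
    """

    members: dict[str, list[str]]  # label -> member ids
    representatives: dict[str, str]  # label -> representative sequence
    differences: PairwiseMatrix  # haplotype x haplotype pairwise differences

    @property
    def labels(self) -> list[str]:
        return list(self.members)

    def haplotype_of(self) -> dict[str, str]:
        return {ind: lab for lab, ids in self.members.items() for ind in ids}


def pairwise_differences(seqs: AlignedSequences, ignore_gaps: bool = True) -> PairwiseMatrix:
    """Number of differing sites for every pair of aligned sequences.

    With ``ignore_gaps`` (pairwise deletion), columns where either sequence
    has a gap or N are excluded from that pair's comparison; otherwise every
    character mismatch counts.
    """
    M = seqs.as_matrix()
    n = len(seqs)
    diff = np.zeros((n, n), dtype=float)
    if ignore_gaps:
        valid = ~np.isin(M, _GAPLIKE)
    else:
        valid = np.ones_like(M, dtype=bool)
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diff_row = ((M[i] != M[i + 1:]) & both).sum(axis=1)
        diff[i, i + 1:] = diff_row
        diff[i + 1:, i] = diff_row
    return PairwiseMatrix(list(seqs.ids), diff)


def collapse_haplotypes(seqs: AlignedSequences, ignore_gaps: bool = True) -> HaplotypeSet:
    """Group sequences with zero pairwise differences into haplotypes.

    Zero-difference is evaluated under the same pairwise-deletion rule as
    :func:`pairwise_differences`; with incomplete coverage this relation is
    closed transitively (sequences of unequal trimmed coverage can merge).
    """
    if len(seqs) == 0:
        raise ValueError("empty alignment")
    diff = pairwise_differences(seqs, ignore_gaps=ignore_gaps)
    G = nx.Graph()
    G.add_nodes_from(seqs.ids)
    n = len(seqs)
    for i in range(n):
        for j in range(i + 1, n):
            if diff.values[i, j] == 0:
                G.add_edge(seqs.ids[i], seqs.ids[j])
    groups = [sorted(c) for c in nx.connected_components(G)]
    # decreasing size, ties by smallest member id
    groups.sort(key=lambda c: (-len(c), c[0]))
    members = {f"H{k + 1}": g for k, g in enumerate(groups)}
    seq_of = dict(zip(seqs.ids, seqs.seqs))
    representatives = {lab: seq_of[g[0]] for lab, g in members.items()}
    rep_aln = AlignedSequences(list(members), [representatives[l] for l in members])
    hap_diff = pairwise_differences(rep_aln, ignore_gaps=ignore_gaps)
    return HaplotypeSet(members, representatives, hap_diff)


def spanning_network(haps: HaplotypeSet) -> list[tuple[str, str, float]]:
    """Minimum-spanning tree over the haplotype difference matrix.

    Returns ``(label_a, label_b, differences)`` edges; deterministic
    tie-breaking by label order (edges are offered to Kruskal's algorithm
    sorted by weight, then label pair).
    """
    labels = haps.labels
    if len(labels) <= 1:
        return []
    G = nx.Graph()
    G.add_nodes_from(labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            G.add_edge(a, b, weight=haps.differences[a, b])
    edges = sorted(G.edges(data="weight"), key=lambda e: (e[2], e[0], e[1]))
    tree: list[tuple[str, str, float]] = []
    uf = {l: l for l in labels}

    def find(x):
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    for a, b, w in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            uf[ra] = rb
            tree.append((a, b, float(w)))
    return tree
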