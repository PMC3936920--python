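"""Rule-based matrilineal kin-group assignment.

Females are grouped when three lines of evidence agree: (1) a shared
mitochondrial haplotype, (2) observed co-sleeping, and (3) pairwise
relatedness significantly consistent with maternal relatedness of 0.5.
Field data is rarely complete, so evidence may be *unknown* — an unknown
never counts as failure, it abstains.  A dyad is directly groupable when
all three criteria pass, or when relatedness is significant and exactly one
of the other two criteria abstains or fails while the other passes.  A
known haplotype mismatch is a hard veto regardless of relatedness.

Groups are the connected components of the groupable-dyad graph; the
relatedness criterion is then enforced group-wide (every member must be
significantly related to every other member), so a component may legally
contain a dyad that is not directly groupable — e.g. two females that were
never seen to co-sleep — as long as their relatedness supports membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "CoSleepGraph",
    "build_cosleep_graph",
    "DyadEvidence",
    "KinGroupAssignment",
    "assign_kin_groups",
]

UNKNOWN = "unknown"


@dataclass
class CoSleepGraph:
    """Co-sleeping observations: edge weights count shared-site days."""

    graph: nx.Graph
    effort: dict[str, int]  # days each individual was tracked

    def count(self, a: str, b: str) -> int:
        if self.graph.has_edge(a, b):
            return int(self.graph[a][b]["days"])
        return 0

    def status(self, a: str, b: str) -> str:
        """'yes' if ever observed in the same site on the same day; 'no' if
        both were tracked but never together; 'unknown' if either was never
        tracked."""
        if self.count(a, b) >= 1:
            return "yes"
        if self.effort.get(a, 0) == 0 or self.effort.get(b, 0) == 0:
            return UNKNOWN
        return "no"


def build_cosleep_graph(records: pd.DataFrame) -> CoSleepGraph:
    """Aggregate telemetry records (date, site, id) into a co-sleep graph.

    Two females co-sleep on a date iff they share a site on that date.
    Duplicate (date, id) rows with conflicting sites raise.
    """
    for c in ("date", "site", "id"):
        if c not in records.columns:
            raise ValueError(f"telemetry records lack column {c!r}")
    dup = records.drop_duplicates(["date", "id", "site"]).duplicated(
        ["date", "id"], keep=False
    )
    if dup.any():
        bad = records.drop_duplicates(["date", "id", "site"])[dup]
        pairs = bad[["date", "id"]].drop_duplicates().to_records(index=False)
        raise ValueError(f"conflicting sites for (date, individual): {list(pairs)[:5]}")
    records = records.drop_duplicates(["date", "id", "site"])

    G = nx.Graph()
    effort = records.groupby("id")["date"].nunique().to_dict()
    G.add_nodes_from(effort)
    for (_, _), members in records.groupby(["date", "site"])["id"]:
        ids = sorted(members.unique())
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if G.has_edge(a, b):
                    G[a][b]["days"] += 1
                else:
                    G.add_edge(a, b, days=1)
    return CoSleepGraph(G, effort)


@dataclass
class DyadEvidence:
    """Audit record for one female dyad."""

    a: str
    b: str
    haplotype_match: str  # yes / no / unknown
    cosleep: str  # yes / no / unknown
    p_tier: str | None  # 'a' (<0.001), 'b' (<0.01), 'c' (<0.05) or None
    relatedness: float | None = None

    @property
    def relatedness_significant(self) -> bool:
        """Criterion 3: tiers a/b always qualify; tier c only when the dyad
        also co-sleeps (the weakest tier needs behavioral corroboration)."""
        if self.p_tier in ("a", "b"):
            return True
        return self.p_tier == "c" and self.cosleep == "yes"

    @property
    def groupable(self) -> bool:
        if self.haplotype_match == "no":  # hard veto when known
            return False
        if not self.relatedness_significant:
            return False
        if self.haplotype_match == "yes" and self.cosleep == "yes":
            return True
        # one of the two abstains/fails while the other passes
        return self.haplotype_match == "yes" or self.cosleep == "yes"


@dataclass
class KinGroupAssignment:
    """Kin-group memberships plus per-dyad evidence for audit."""

    groups: dict[str, list[str]]
    evidence: list[DyadEvidence] = field(default_factory=list)

    def group_of(self) -> dict[str, str]:
        return {m: g for g, members in self.groups.items() for m in members}

    def sizes(self) -> list[int]:
        return sorted((len(m) for m in self.groups.values()), reverse=True)

    def evidence_table(self) -> pd.DataFrame:
        rows = [
            {
                "a": e.a,
                "b": e.b,
                "haplotype_match": e.haplotype_match,
                "cosleep": e.cosleep,
                "p_tier": e.p_tier or "",
                "relatedness": e.relatedness,
                "groupable": e.groupable,
            }
            for e in self.evidence
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        group_of = self.group_of()
        df = self.evidence_table()
        df.insert(0, "group_a", df["a"].map(group_of).fillna(""))
        df.insert(1, "group_b", df["b"].map(group_of).fillna(""))
        df.to_csv(path, index=False)


def _haplotype_status(hap_a: str | None, hap_b: str | None) -> str:
    unknown = {None, "", "??", UNKNOWN}
    if hap_a in unknown or hap_b in unknown:
        return UNKNOWN
    return "yes" if hap_a == hap_b else "no"


def assign_kin_groups(
    females: list[str],
    haplotype_of: dict[str, str | None],
    cosleep: CoSleepGraph | dict[tuple[str, str], str],
    p_tier: dict[tuple[str, str], str | None],
    relatedness: dict[tuple[str, str], float] | None = None,
) -> KinGroupAssignment:
    """Assign females to matrilineal kin groups.

    ``cosleep`` may be a :class:`CoSleepGraph` or an explicit per-dyad
    status map; ``p_tier`` maps (unordered) dyads to the kinship-test
    significance tier.  Deterministic: no randomness anywhere.

    Raises if a connected set of groupable dyads contains a member pair
    with a known haplotype mismatch or without significant relatedness
    (criteria 1 and 3 enforced group-wide).
    """

    def lookup(d, a, b, default=None):
        return d.get((a, b), d.get((b, a), default))

    evidence: dict[frozenset, DyadEvidence] = {}
    for i, a in enumerate(females):
        for b in females[i + 1:]:
            if isinstance(cosleep, CoSleepGraph):
                cs = cosleep.status(a, b)
            else:
                cs = lookup(cosleep, a, b, UNKNOWN)
            ev = DyadEvidence(
                a=a,
                b=b,
                haplotype_match=_haplotype_status(haplotype_of.get(a), haplotype_of.get(b)),
                cosleep=cs,
                p_tier=lookup(p_tier, a, b, None),
                relatedness=lookup(relatedness or {}, a, b, None),
            )
            evidence[frozenset((a, b))] = ev

    G = nx.Graph()
    G.add_nodes_from(females)
    for ev in evidence.values():
        if ev.groupable:
            G.add_edge(ev.a, ev.b)

    def significant(a: str, b: str) -> bool:
        return evidence[frozenset((a, b))].relatedness_significant

    # Criterion 3 is group-wide: every member must be significantly related
    # to every other.  A component whose members all pass stays whole; one
    # that does not is trimmed by repeatedly dropping the member with the
    # most failing pairs (ties: the lexicographically last id) and
    # re-splitting by groupable connectivity.  Deterministic throughout.
    def trim(comp: set[str]) -> set[str]:
        comp = set(comp)
        while len(comp) >= 2:
            violations = {m: 0 for m in comp}
            ordered = sorted(comp)
            bad = False
            for i, a in enumerate(ordered):
                for b in ordered[i + 1:]:
                    if not significant(a, b):
                        violations[a] += 1
                        violations[b] += 1
                        bad = True
            if not bad:
                break
            worst = max(ordered, key=lambda m: (violations[m], m))
            comp.discard(worst)
        return comp

    members_kept: set[str] = set()
    for comp in nx.connected_components(G):
        if len(comp) >= 2:
            members_kept |= trim(comp)
    final = [
        sorted(c)
        for c in nx.connected_components(G.subgraph(members_kept))
        if len(c) >= 2
    ]
    final.sort(key=lambda c: c[0])

    for comp in final:
        for i, a in enumerate(comp):
            for b in comp[i + 1:]:
                if evidence[frozenset((a, b))].haplotype_match == "no":
                    # an unknown-haplotype member bridging two known,
                    # different haplotypes is admissible to two
                    # incompatible groups
                    raise ValueError(
                        f"members {a} and {b} of one group have different known "
                        "haplotypes (incompatible group memberships)"
                    )

    groups = {str(k + 1): comp for k, comp in enumerate(final)}
    return KinGroupAssignment(groups, list(evidence.values()))
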