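"""Grouping EVE loci into endogenization events.

Two loci are tied to the same event by either of two edge types:

* **colocation** — they sit on the same scaffold of the same species;
  co-occurrence of viral insertions on one host scaffold is very
  unlikely for independent events;
* **homology-clade** — they are copies of the same viral gene family
  that fall inside the same supported wasp clade of that family's gene
  tree, i.e. they descend from a single insertion even when scaffold
  colocation is absent in one assembly.

Applying both transitively (if A and B colocate in species 1, and B and
C colocate in species 2, then A, B and C derive from the same ancestral
event) partitions the catalog into connected components: the events.
Loci of unclassifiable families with no colocation partner remain
unassigned rather than becoming spurious single-locus events.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .homology import EveLocus
from .trees import TopologyCall, UNCLASSIFIED


@dataclass(frozen=True)
class Edge:
    a: str
    b: str
    kind: str        # 'colocation' | 'homology-clade'
    provenance: str  # scaffold id or family id


@dataclass
class EvidenceGraph:
    nodes: list[str]
    edges: list[Edge]
    loci: dict[str, EveLocus]


@dataclass
class EndogenizationEvent:
    event_id: str
    loci: list[str]
    families: frozenset[str]
    species: frozenset[str]
    donor_lineage: str | None
    conflict: bool
    notes: list[str] = field(default_factory=list)
    age_lower: float | None = None
    age_upper: float | None = None

    @property
    def n_loci(self) -> int:
        return len(self.loci)


class UnionFind:
    """Disjoint-set forest with path compression and union by size."""

    def __init__(self, items):
        self.parent = {x: x for x in items}
        self.size = {x: 1 for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]

    def components(self) -> list[list]:
        groups = defaultdict(list)
        for x in self.parent:
            groups[self.find(x)].append(x)
        return [sorted(members) for members in groups.values()]


def default_tip_map(catalog: list[EveLocus]) -> dict[str, str]:
    """Map locus ids to gene-tree tip labels by the shared naming convention.

    Tips are named ``species|family|k`` with k the 1-based rank of the
    locus among that (species, family) pair's loci ordered by
    (scaffold, start) — the same rule the synthetic generator uses when
    labelling tree tips, so catalog and trees line up without an
    external cross-reference file.
    """
    by_group: dict[tuple[str, str], list[EveLocus]] = defaultdict(list)
    for locus in catalog:
        by_group[(locus.species, locus.family)].append(locus)
    tip_map: dict[str, str] = {}
    for (species, family), group in by_group.items():
        for k, locus in enumerate(sorted(group, key=lambda l: (l.scaffold, l.start)), start=1):
            tip_map[locus.locus_id] = f"{species}|{family}|{k}"
    return tip_map


def build_graph(
    catalog: list[EveLocus],
    topology_calls: dict[str, TopologyCall],
    tip_map: dict[str, str] | None = None,
) -> EvidenceGraph:
    """Assemble the evidence graph over catalog loci.

    Colocation edges connect consecutive loci per (species, scaffold);
    homology-clade edges connect loci of one family that map into the
    same supported wasp clade of that family's topology call.
    UNCLASSIFIED families contribute no homology edges.
    """
    for locus in catalog:
        if locus.family not in topology_calls:
            raise KeyError(f"locus {locus.locus_id} references family {locus.family!r} "
                           "with no topology call")
    if tip_map is None:
        tip_map = default_tip_map(catalog)

    edges: list[Edge] = []

    by_scaffold: dict[tuple[str, str], list[EveLocus]] = defaultdict(list)
    for locus in catalog:
        by_scaffold[(locus.species, locus.scaffold)].append(locus)
    for (_, scaffold), group in sorted(by_scaffold.items()):
        group = sorted(group, key=lambda l: l.start)
        for prev, cur in zip(group, group[1:]):
            edges.append(Edge(prev.locus_id, cur.locus_id, "colocation", scaffold))

    by_family: dict[str, list[EveLocus]] = defaultdict(list)
    for locus in catalog:
        by_family[locus.family].append(locus)
    for family, group in sorted(by_family.items()):
        call = topology_calls[family]
        if call.type == UNCLASSIFIED and not call.clades:
            continue
        for clade in call.clades:
            members = sorted(
                l.locus_id for l in group if tip_map[l.locus_id] in clade.tips
            )
            for prev, cur in zip(members, members[1:]):
                edges.append(Edge(prev, cur, "homology-clade", family))

    return EvidenceGraph(
        nodes=sorted(l.locus_id for l in catalog),
        edges=edges,
        loci={l.locus_id: l for l in catalog},
    )


def group_events(
    graph: EvidenceGraph,
    topology_calls: dict[str, TopologyCall],
) -> tuple[list[EndogenizationEvent], list[str]]:
    """Union-find connected components of the evidence graph.

    Returns (events, unassigned_locus_ids).  A singleton component whose
    family is UNCLASSIFIED carries no evidence tying it to anything and
    is reported as unassigned, not as a one-locus event.  Events are
    ordered by decreasing size and numbered event_1, event_2, ...
    """
    uf = UnionFind(graph.nodes)
    for edge in graph.edges:
        uf.union(edge.a, edge.b)

    events: list[EndogenizationEvent] = []
    unassigned: list[str] = []
    components = sorted(uf.components(), key=lambda c: (-len(c), c))
    for component in components:
        if len(component) == 1:
            locus = graph.loci[component[0]]
            if topology_calls[locus.family].type == UNCLASSIFIED:
                unassigned.append(component[0])
                continue
        events.append(summarize_event(component, topology_calls, graph.loci))
    for i, event in enumerate(events, start=1):
        event.event_id = f"event_{i}"
    return events, sorted(unassigned)


def summarize_event(
    component: list[str],
    topology_calls: dict[str, TopologyCall],
    loci: dict[str, EveLocus],
) -> EndogenizationEvent:
    """Summarize one connected component into an event record.

    The donor lineage is the majority over member families' nearest
    viral relative tags, restricted to the clades that actually contain
    this component's loci; disagreement between members sets the
    conflict flag instead of being silently resolved.
    """
    if not component:
        raise ValueError("empty component")
    members = [loci[lid] for lid in component]
    families = frozenset(l.family for l in members)
    species = frozenset(l.species for l in members)

    tip_map = default_tip_map(list(loci.values()))
    lineage_votes: Counter[str] = Counter()
    notes: list[str] = []
    for family in sorted(families):
        call = topology_calls[family]
        member_tips = {tip_map[l.locus_id] for l in members if l.family == family}
        for clade in call.clades:
            if clade.nearest_lineage and member_tips & clade.tips:
                lineage_votes[clade.nearest_lineage] += 1
        if call.type == UNCLASSIFIED:
            notes.append(f"family {family} assigned by colocation only (unresolved tree)")

    donor = None
    conflict = False
    if lineage_votes:
        top = lineage_votes.most_common()
        donor = top[0][0]
        conflict = len(top) > 1
        if conflict:
            notes.append(
                "donor-lineage disagreement among member families: "
                + ", ".join(f"{tag}x{n}" for tag, n in top)
            )
    return EndogenizationEvent(
        event_id="event_?",
        loci=sorted(component),
        families=families,
        species=species,
        donor_lineage=donor,
        conflict=conflict,
        notes=notes,
    )
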