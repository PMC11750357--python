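"""Gene-tree topology classification for endogenization events.

Each viral gene family with wasp homologues has a phylogeny containing
wasp EVE tips and virus tips.  A horizontal transfer from virus to wasp
leaves a characteristic signature: the wasp sequences form a supported
monophyletic clade *nested within* the virus diversity, sister to the
donor lineage.  Three patterns are distinguished:

* TYPE_I   — one wasp clade (all wasp tips), nearest viral relative in
  the LhFV-like lineage: the ancestral, clade-wide acquisition.
* TYPE_II  — the only wasp presence is a single-species clade (possibly
  a single tip) whose nearest relative is LbFV-like: the recent,
  species-specific acquisition.
* TYPE_III — both patterns co-occur in one tree: the family was acquired
  in both events.
* UNCLASSIFIED — no supported wasp clade, unresolved nearest relative,
  or a pattern outside the three above.

Support is read from "aLRT/UFboot" internal-node labels; the ultrafast
bootstrap (second) component is thresholded, strictly greater than 80 by
default.  Singleton wasp tips are admissible clades whose support
requirement is vacuously met — the species-specific pattern concerns a
single sequence in the canonical case.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import dendropy

from .io import TipMetadata

DEFAULT_MIN_SUPPORT = 80.0
LINEAGE_ANCESTRAL = "LhFV-like"
LINEAGE_RECENT = "LbFV-like"
LINEAGE_OUTGROUP = "outgroup"

TYPE_I = "TYPE_I"
TYPE_II = "TYPE_II"
TYPE_III = "TYPE_III"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class WaspClade:
    """A maximal supported all-wasp clade with its nearest viral relative."""

    tips: frozenset[str]
    support: float | None
    species: frozenset[str]
    nearest_lineage: str | None
    note: str = ""


@dataclass
class TopologyCall:
    family: str
    type: str
    clades: list[WaspClade] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def parse_support(label: str | None) -> float | None:
    """Parse an internal-node support label.

    ``"97.3/100"`` (aLRT/UFboot) yields the ultrafast-bootstrap component
    100; a single number is returned as-is; empty or missing labels yield
    None.  Non-numeric content raises ValueError.
    """
    if label is None or label == "":
        return None
    part = label.split("/")[-1] if "/" in label else label
    try:
        value = float(part)
    except ValueError as exc:
        raise ValueError(f"cannot parse support label {label!r}") from exc
    if not (0.0 <= value <= 100.0):
        raise ValueError(f"support {value} outside [0, 100]")
    return value


def read_gene_tree(path) -> dendropy.Tree:
    """Read a newick gene tree, keeping underscores and support labels."""
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    return tree


def write_gene_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


def _leaf_labels(node) -> list[str]:
    return [leaf.taxon.label for leaf in node.leaf_iter()]


def _require_meta(label: str, meta: dict[str, TipMetadata]) -> TipMetadata:
    try:
        return meta[label]
    except KeyError:
        raise KeyError(f"tip {label!r} has no metadata entry") from None


def root_for_classification(
    tree: dendropy.Tree,
    meta: dict[str, TipMetadata],
    outgroup_lineage: str = LINEAGE_OUTGROUP,
) -> dendropy.Tree:
    """Root on outgroup-tagged virus tips when present, else at midpoint.

    Idempotent: a tree already rooted so that the outgroup is one child
    of the root is returned unchanged.
    """
    if len(tree.leaf_nodes()) < 3:
        raise ValueError("tree must have at least 3 tips to be rooted")
    outgroup = {
        leaf.taxon.label
        for leaf in tree.leaf_node_iter()
        if _require_meta(leaf.taxon.label, meta).lineage == outgroup_lineage
    }
    if not outgroup:
        # skip when the root already balances the two deepest directions,
        # which makes repeated rooting idempotent
        def depth(node):
            if node.is_leaf():
                return 0.0
            return max((c.edge.length or 0.0) + depth(c) for c in node.child_nodes())

        kids = tree.seed_node.child_nodes()
        if len(kids) == 2:
            d = [(c.edge.length or 0.0) + depth(c) for c in kids]
            if abs(d[0] - d[1]) < 1e-9:
                return tree
        tree.reroot_at_midpoint(update_bipartitions=True)
        tree.is_rooted = True
        return tree
    all_tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for child in tree.seed_node.child_nodes():
        tips = set(_leaf_labels(child))
        if tips == outgroup or tips == all_tips - outgroup:
            return tree  # already rooted on the outgroup split
    taxa = [tree.taxon_namespace.get_taxon(t) for t in sorted(outgroup)]
    mrca = tree.mrca(taxa=taxa) if len(taxa) > 1 else tree.find_node_with_taxon_label(taxa[0].label)
    if mrca is tree.seed_node:
        # outgroup not monophyletic from the current rooting; fall back to
        # rooting on one outgroup tip's edge
        mrca = tree.find_node_with_taxon_label(sorted(outgroup)[0])
    tree.reroot_at_edge(mrca.edge, update_bipartitions=True)
    tree.is_rooted = True
    return tree


def _is_wasp_leafset(node, meta: dict[str, TipMetadata]) -> bool:
    return all(_require_meta(t, meta).kind == "wasp" for t in _leaf_labels(node))


def wasp_clades(
    tree: dendropy.Tree,
    meta: dict[str, TipMetadata],
    min_support: float = DEFAULT_MIN_SUPPORT,
) -> list[tuple[dendropy.Node, WaspClade]]:
    """Maximal all-wasp clades whose subtending support exceeds min_support.

    Traversal is root-to-tip: the first supported all-wasp node on each
    path is taken and not descended into; an unsupported all-wasp node is
    split into its children.  Wasp leaves always qualify (singleton
    clades, support vacuously sufficient), so every wasp tip belongs to
    exactly one returned clade.
    """
    found: list[tuple[dendropy.Node, WaspClade]] = []

    def visit(node):
        if node.is_leaf():
            label = node.taxon.label
            if _require_meta(label, meta).kind == "wasp":
                found.append(
                    (node, WaspClade(
                        tips=frozenset({label}),
                        support=None,
                        species=frozenset({meta[label].species}),
                        nearest_lineage=None,
                    ))
                )
            return
        if _is_wasp_leafset(node, meta):
            support = parse_support(node.label)
            if support is not None and support > min_support:
                tips = frozenset(_leaf_labels(node))
                found.append(
                    (node, WaspClade(
                        tips=tips,
                        support=support,
                        species=frozenset(meta[t].species for t in tips),
                        nearest_lineage=None,
                    ))
                )
                return
        for child in node.child_nodes():
            visit(child)

    visit(tree.seed_node)
    return found


def nearest_viral_relative(
    tree: dendropy.Tree,
    clade_node: dendropy.Node,
    meta: dict[str, TipMetadata],
) -> tuple[str, str]:
    """Lineage tag of the nearest viral relative of a wasp clade.

    The sister group is inspected first: if it contains only virus tips,
    the majority lineage tag among them is returned.  A mixed or
    wasp-only sister triggers a walk toward the root, taking the first
    sister group that contains virus tips (majority tag, with a note
    recording the indirect resolution).

    Returns (lineage, note).  Raises ValueError when the tree contains no
    virus tip above the clade.
    """
    note = ""
    node = clade_node
    first = True
    while node.parent_node is not None:
        sister_tips: list[str] = []
        for sib in node.parent_node.child_nodes():
            if sib is not node:
                sister_tips.extend(_leaf_labels(sib))
        virus_tips = [t for t in sister_tips if _require_meta(t, meta).kind == "virus"]
        if virus_tips:
            pure = len(virus_tips) == len(sister_tips)
            if not (first and pure):
                note = "nearest relative resolved above the immediate sister"
            counts = Counter(meta[t].lineage for t in virus_tips)
            top = counts.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                note = (note + "; " if note else "") + "lineage tie broken lexicographically"
                lineage = min(tag for tag, n in top if n == top[0][1])
            else:
                lineage = top[0][0]
            return lineage, note
        node = node.parent_node
        first = False
    raise ValueError("no virus tips found in the tree above the wasp clade")


def classify_gene_tree(
    family: str,
    tree: dendropy.Tree,
    meta: dict[str, TipMetadata],
    min_support: float = DEFAULT_MIN_SUPPORT,
    lineage_i: str = LINEAGE_ANCESTRAL,
    lineage_ii: str = LINEAGE_RECENT,
) -> TopologyCall:
    """Classify one gene-family tree into TYPE_I/II/III or UNCLASSIFIED.

    The tree is first rooted (outgroup-else-midpoint), wasp clades are
    extracted at the support threshold, and each clade is annotated with
    its nearest viral relative.  The decision then depends only on the
    multiset of (clade, nearest lineage) annotations, which makes it
    insensitive to tip rotation and re-serialization.
    """
    call = TopologyCall(family=family, type=UNCLASSIFIED)
    has_virus = any(
        _require_meta(l.taxon.label, meta).kind == "virus" for l in tree.leaf_node_iter()
    )
    tree = root_for_classification(tree, meta)
    raw = wasp_clades(tree, meta, min_support=min_support)
    if not raw:
        call.notes.append("no wasp tips in tree")
        return call
    if not has_virus:
        call.notes.append("no viral context: tree contains no virus tips")
        call.clades = [c for _, c in raw]
        return call

    annotated: list[WaspClade] = []
    for node, clade in raw:
        lineage, note = nearest_viral_relative(tree, node, meta)
        annotated.append(WaspClade(
            tips=clade.tips, support=clade.support, species=clade.species,
            nearest_lineage=lineage, note=note,
        ))
    call.clades = annotated

    pattern_i = [c for c in annotated if c.nearest_lineage == lineage_i]
    pattern_ii = [
        c for c in annotated
        if c.nearest_lineage == lineage_ii and len(c.species) == 1
    ]
    other = [c for c in annotated if c not in pattern_i and c not in pattern_ii]

    if other:
        call.notes.append(
            "wasp clade(s) adjacent to neither canonical lineage or with an "
            "unexpected species span"
        )
        return call
    if len(pattern_i) == 1 and not pattern_ii:
        call.type = TYPE_I
    elif len(pattern_ii) == 1 and not pattern_i:
        call.type = TYPE_II
    elif len(pattern_i) == 1 and len(pattern_ii) == 1:
        call.type = TYPE_III
    else:
        call.notes.append(
            f"pattern outside the three recognized types: {len(pattern_i)} "
            f"{lineage_i} clade(s), {len(pattern_ii)} single-species {lineage_ii} clade(s)"
        )
    return call
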