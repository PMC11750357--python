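"""Core-gene enrichment and chronogram-based event dating.

**Enrichment.**  Domesticated viral gene sets are expected to be
enriched for core genes (genes conserved across the dsDNA arthropod
viruses) relative to the donor genome.  The 2x2 table (event genes vs
donor-genome genes, core vs non-core) is tested with Fisher's exact
test.  The reported odds ratio is the conditional maximum-likelihood
estimate under the noncentral hypergeometric model — the convention of
standard statistical software — not the sample cross-product ratio; both
are returned.  The two-sided p-value follows the point-probability rule:
the sum of probabilities of all tables no more probable than the one
observed.

**Dating.**  An endogenization event that is shared by a set of species
happened on the branch subtending their most recent common ancestor:
its age is bounded below by the crown age of the MRCA (0 for a
single-species event) and above by the age of the split between the
recipient clade and its closest EVE-negative relative.  Node ages come
from a fossil-calibrated chronogram supplied as an ultrametric newick
tree with branch lengths in Myr; credibility intervals ride along as
node comments ``[&age=76.4,ci={55.0,100.0}]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import dendropy
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float          # conditional MLE (primary)
    odds_ratio_sample: float   # cross-product a*d / (b*c); inf when b*c == 0
    p_value: float             # two-sided, point-probability rule
    table: tuple[tuple[int, int], tuple[int, int]]


def fisher_exact(table, include_odds_ratio: bool = True) -> FisherResult:
    """Fisher's exact test on a 2x2 contingency table.

    ``table`` is [[a, b], [c, d]] with non-negative integer counts and at
    least one positive marginal in each dimension (a zero row or column
    raises ValueError).  ``include_odds_ratio=False`` skips the
    conditional-MLE root finding (by far the most expensive part) and
    reports NaN for it — useful when only the p-value is needed in bulk.
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("table has a zero marginal; the test is undefined")
    t = [[a, b], [c, d]]
    cmle = (_scipy_odds_ratio(t, kind="conditional").statistic
            if include_odds_ratio else float("nan"))
    sample = float("inf") if b * c == 0 else (a * d) / (b * c)
    _, p = _scipy_fisher(t, alternative="two-sided")
    return FisherResult(
        odds_ratio=float(cmle),
        odds_ratio_sample=sample,
        p_value=float(p),
        table=((a, b), (c, d)),
    )


def core_gene_enrichment(
    event_families: set[str],
    donor_genes: set[str],
    core_genes: set[str],
) -> FisherResult:
    """Enrichment of core genes in an event's family set vs the donor genome.

    Rows: event genes vs donor-genome genes; columns: core vs non-core.
    The donor row uses the full donor repertoire, as in the published
    comparison of an 18-gene event set against a 110-gene donor genome.
    """
    a = len(event_families & core_genes)
    b = len(event_families - core_genes)
    c = len(donor_genes & core_genes)
    d = len(donor_genes - core_genes)
    return fisher_exact([[a, b], [c, d]])


_CI_RE = re.compile(r"ci=\{\s*([0-9.eE+-]+)\s*,\s*([0-9.eE+-]+)\s*\}")


@dataclass(frozen=True)
class AgeInterval:
    """Event age bounds in Myr, with credibility intervals when annotated."""

    lower: float               # crown age of the recipient clade (0 if single species)
    upper: float               # split from the closest negative relative
    lower_ci: tuple[float, float] | None = None
    upper_ci: tuple[float, float] | None = None


class Chronogram:
    """A calibrated ultrametric species tree with node ages in Myr."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._ages: dict[int, float] = {}
        self._compute_ages()

    @classmethod
    def read(cls, path) -> "Chronogram":
        tree = dendropy.Tree.get(
            path=str(path), schema="newick",
            preserve_underscores=True, suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
        tree.is_rooted = True
        return cls(tree)

    @classmethod
    def from_string(cls, newick: str) -> "Chronogram":
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            preserve_underscores=True, suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
        tree.is_rooted = True
        return cls(tree)

    def _compute_ages(self) -> None:
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                age = 0.0
            else:
                child_ages = []
                for child in node.child_nodes():
                    if child.edge.length is None:
                        raise ValueError("chronogram has a branch without a length")
                    child_ages.append(self._ages[id(child)] + child.edge.length)
                age = max(child_ages)
                spread = age - min(child_ages)
                if spread > 1e-6 * max(age, 1.0):
                    raise ValueError(
                        f"chronogram is not ultrametric (age spread {spread:.6g} Myr)"
                    )
            self._ages[id(node)] = age
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            if parent is not None and self._ages[id(parent)] <= self._ages[id(node)] - 1e-9:
                raise ValueError("node ages must strictly decrease root to tips")

    def age(self, node) -> float:
        return self._ages[id(node)]

    def ci(self, node) -> tuple[float, float] | None:
        for comment in node.comments or []:
            m = _CI_RE.search(comment)
            if m:
                return float(m.group(1)), float(m.group(2))
        return None

    @property
    def species(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def _tip(self, species: str):
        node = self.tree.find_node_with_taxon_label(species)
        if node is None:
            raise KeyError(f"species {species!r} not found in the chronogram")
        return node

    def mrca(self, species: set[str]):
        tips = [self._tip(s) for s in sorted(species)]
        if len(tips) == 1:
            return tips[0]
        taxa = [t.taxon for t in tips]
        return self.tree.mrca(taxa=taxa)

    def root_age(self) -> float:
        return self.age(self.tree.seed_node)


def date_event(
    event_species: set[str],
    chronogram: Chronogram,
    negative_species: set[str] | None = None,
) -> AgeInterval:
    """Age interval for an event from the recipient species set.

    ``negative_species`` are the species known to lack the event; by
    default every chronogram tip outside ``event_species``.  The lower
    bound is the crown age of the MRCA of the event's species (0 for a
    single-species event); the upper bound is the age of the first
    ancestor whose descendants include a negative species — the split
    from the closest negative relative.  When the event spans all tips
    the upper bound is the root age.
    """
    if not event_species:
        raise ValueError("event has no species")
    all_species = set(chronogram.species)
    missing = set(event_species) - all_species
    if missing:
        raise KeyError(f"species missing from chronogram: {sorted(missing)}")
    if negative_species is None:
        negative_species = all_species - set(event_species)

    mrca = chronogram.mrca(set(event_species))
    lower = chronogram.age(mrca)
    lower_ci = chronogram.ci(mrca) if not mrca.is_leaf() else None

    node = mrca
    upper_node = None
    while node.parent_node is not None:
        node = node.parent_node
        tips = {leaf.taxon.label for leaf in node.leaf_iter()}
        if tips & negative_species:
            upper_node = node
            break
    if upper_node is None:
        upper_node = chronogram.tree.seed_node
    upper = chronogram.age(upper_node)
    upper_ci = chronogram.ci(upper_node)
    return AgeInterval(lower=lower, upper=upper, lower_ci=lower_ci, upper_ci=upper_ci)
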