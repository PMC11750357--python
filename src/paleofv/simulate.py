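"""Synthetic endogenization scenarios with machine-readable ground truth.

The generator emits, for a configurable scenario, everything the
pipeline consumes — genome scaffolds with planted EVE ORFs, per-scaffold
coverage, viral-protein and TE homology hits, predicted-protein
taxonomy, per-family gene trees with "aLRT/UFboot" support labels, codon
alignments evolved under a specified dN/dS, and a calibrated chronogram
— together with a truth table recording which locus belongs to which
endogenization event, which gene families each event carried, and each
family's true gene-tree topology type.

Everything is driven by one integer seed through a single numpy
Generator; identical seeds give byte-identical datasets.

Codon evolution uses a single-omega (M0-like) continuous-time process
simulated by the Gillespie algorithm along each branch: single-
nucleotide codon changes occur at a rate proportional to the target
nucleotide frequency, multiplied by kappa for transitions and by omega
for amino-acid-changing steps; stop codons are unreachable.  Branch
lengths are in expected substitutions per codon.  The default kappa is 1
(no transition bias): that is the regime in which the downstream
Nei-Gojobori counting estimator is approximately unbiased, so the
calibration of simulator against estimator is clean by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .dating import Chronogram
from .io import TipMetadata, write_tip_metadata, write_tsv, write_json
from .homology import START_CODONS
from .selection import _STOPS  # sense/stop codon partition shared with the estimator
from .trees import LINEAGE_ANCESTRAL, LINEAGE_RECENT, LINEAGE_OUTGROUP

TRUTH_FORMAT_VERSION = "paleofv-truth-v1"

_NUCS = "ACGT"
_SENSE_CODONS = tuple(
    c for c in ("".join(p) for p in itertools.product(_NUCS, repeat=3)) if c not in _STOPS
)
_CODON_INDEX = {c: i for i, c in enumerate(_SENSE_CODONS)}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class ConfigurationError(ValueError):
    """A scenario configuration violates one of its invariants."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Virus:
    name: str
    lineage: str
    genes: tuple[str, ...]
    core_genes: tuple[str, ...] = ()

    def __post_init__(self):
        unknown = set(self.core_genes) - set(self.genes)
        if unknown:
            raise ConfigurationError(
                f"virus {self.name}: core_genes not in repertoire: {sorted(unknown)}"
            )


@dataclass(frozen=True)
class VirusPanel:
    viruses: tuple[Virus, ...]

    def by_name(self, name: str) -> Virus:
        for v in self.viruses:
            if v.name == name:
                return v
        raise ConfigurationError(f"unknown virus {name!r}")

    def donor_for(self, lineage: str) -> Virus:
        """The representative donor for a lineage tag (first panel entry)."""
        for v in self.viruses:
            if v.lineage == lineage:
                return v
        raise ConfigurationError(f"events: no virus in the panel has lineage {lineage!r}")


@dataclass(frozen=True)
class EventSpec:
    """One planned endogenization event.

    ``recipient_species`` lists the extant species descending from the
    insertion branch that still carry the event; per-species losses and
    extra paralog copies adjust the per-(species, family) copy counts;
    ``pseudogenized`` marks (species, family, copy) triples that receive
    a premature stop codon.  Scaffold colocation groups are derived
    automatically: within each species the event's families are paired
    onto shared scaffolds, with the family order rotated per species so
    that the transitive closure of colocation spans the whole event.
    """

    event_id: str
    donor_lineage: str
    recipient_species: tuple[str, ...]
    gene_families: tuple[str, ...]
    losses: tuple[tuple[str, tuple[str, ...]], ...] = ()          # (species, families)
    paralog_extra: tuple[tuple[str, str, int], ...] = ()          # (species, family, extra)
    pseudogenized: tuple[tuple[str, str, int], ...] = ()          # (species, family, copy)
    families_per_scaffold: int = 2
    #: optional explicit scaffold partition per species: (species, (group, ...))
    #: where each group lists family names, repeated once per copy placed
    #: there; needed e.g. to chain a single-species event across scaffolds
    #: by splitting paralog copies
    colocation_groups: tuple[tuple[str, tuple[tuple[str, ...], ...]], ...] = ()

    def explicit_groups(self, species: str) -> tuple[tuple[str, ...], ...] | None:
        for sp, groups in self.colocation_groups:
            if sp == species:
                return groups
        return None

    def losses_of(self, species: str) -> set[str]:
        for sp, fams in self.losses:
            if sp == species:
                return set(fams)
        return set()

    def copies(self, species: str, family: str) -> int:
        if species not in self.recipient_species:
            return 0
        if family not in self.gene_families or family in self.losses_of(species):
            return 0
        extra = sum(n for sp, fam, n in self.paralog_extra if sp == species and fam == family)
        return 1 + extra


@dataclass(frozen=True)
class GenomeParams:
    busco_scaffolds_per_species: int = 10
    plain_scaffolds_per_species: int = 5
    busco_scaffold_length: tuple[int, int] = (1500, 3000)
    plain_scaffold_length: tuple[int, int] = (2000, 6000)
    gc_mean: float = 0.35
    insert_gc_offset: float = 0.0     # nonzero creates envelope-failing negative controls
    coverage_mean: float = 30.0
    coverage_sd_busco: float = 3.0
    coverage_sd_other: float = 2.0
    flank_length: int = 300
    spacer_length: int = 200
    n_decoy_hits_per_negative: int = 2
    minus_strand_every: int = 5       # every k-th planted locus goes on the minus strand


@dataclass(frozen=True)
class TreeNoise:
    true_boot: tuple[float, float] = (90.0, 100.0)
    low_boot: tuple[float, float] = (30.0, 75.0)
    true_alrt: tuple[float, float] = (85.0, 100.0)
    low_alrt: tuple[float, float] = (10.0, 70.0)
    backbone_branch: tuple[float, float] = (0.05, 0.4)


@dataclass(frozen=True)
class OmegaParams:
    default_omega: float = 0.15
    family_omega: tuple[tuple[str, float], ...] = ()
    kappa: float = 1.0
    n_codons: int = 200
    subs_per_myr: float = 0.002       # chronogram-to-substitutions scaling
    paralog_branch: float = 0.03      # within-species cherry depth
    single_species_branch: float = 0.15   # star depth for one-species clades
    event_root_branch: float = 0.25
    pseudogene_stop_fraction: float = 0.3
    busco_omega: float = 0.08
    n_busco_genes: int = 12

    def omega_of(self, family: str) -> float:
        for fam, om in self.family_omega:
            if fam == family:
                return om
        return self.default_omega


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int
    chronogram_newick: str
    wasp_species: tuple[str, ...]          # all sequenced wasps (chronogram tips)
    virus_panel: VirusPanel
    events: tuple[EventSpec, ...] = ()
    orphan_loci: tuple[tuple[str, str], ...] = ()   # (species, family) unassignable loci
    orphan_neighbor_virus: str = ""        # virus tip the orphan attaches next to
    unclassified_families: tuple[str, ...] = ()     # trees emitted with low support
    alt_start_codons: tuple[tuple[str, str, str], ...] = ()  # (species, family, codon)
    genome: GenomeParams = field(default_factory=GenomeParams)
    tree_noise: TreeNoise = field(default_factory=TreeNoise)
    omega: OmegaParams = field(default_factory=OmegaParams)

    def validate(self) -> Chronogram:
        chron = Chronogram.from_string(self.chronogram_newick)  # checks ultrametricity/ages
        tips = set(chron.species)
        missing = set(self.wasp_species) - tips
        if missing:
            raise ConfigurationError(f"wasp_species missing from chronogram: {sorted(missing)}")
        for ev in self.events:
            donor = self.virus_panel.donor_for(ev.donor_lineage)
            bad = set(ev.gene_families) - set(donor.genes)
            if bad:
                raise ConfigurationError(
                    f"{ev.event_id}: gene_families not in donor {donor.name} repertoire: "
                    f"{sorted(bad)}"
                )
            unknown_sp = set(ev.recipient_species) - set(self.wasp_species)
            if unknown_sp:
                raise ConfigurationError(
                    f"{ev.event_id}: recipient_species unknown: {sorted(unknown_sp)}"
                )
            for sp, fams in ev.losses:
                if sp not in ev.recipient_species:
                    raise ConfigurationError(f"{ev.event_id}: loss in non-recipient {sp}")
                if not set(fams) <= set(ev.gene_families):
                    raise ConfigurationError(f"{ev.event_id}: loss of unknown family in {sp}")
            for sp, fam, copy in ev.pseudogenized:
                if ev.copies(sp, fam) < copy:
                    raise ConfigurationError(
                        f"{ev.event_id}: pseudogenized copy {(sp, fam, copy)} does not exist"
                    )
        from collections import Counter

        for ev in self.events:
            for sp, groups in ev.colocation_groups:
                placed = Counter(f for group in groups for f in group)
                expected = Counter({
                    f: ev.copies(sp, f) for f in ev.gene_families if ev.copies(sp, f)
                })
                if placed != +expected:
                    raise ConfigurationError(
                        f"{ev.event_id}: colocation_groups for {sp} do not partition "
                        f"the event's copies (placed {dict(placed)}, "
                        f"expected {dict(expected)})"
                    )
        for sp, fam, codon in self.alt_start_codons:
            if codon not in START_CODONS:
                raise ConfigurationError(
                    f"alt_start_codons: {codon!r} is not a recognized start codon"
                )
        return chron

    def config_hash_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

@dataclass
class TruthLocus:
    species: str
    scaffold: str
    start: int
    end: int
    strand: str
    family: str
    copy: int
    event_id: str | None
    orf_status: str
    start_codon: str
    tip: str


@dataclass
class TruthTable:
    loci: list[TruthLocus]
    family_types: dict[str, str]
    events: dict[str, dict]

    def event_loci(self, event_id: str) -> list[TruthLocus]:
        return [l for l in self.loci if l.event_id == event_id]


@dataclass
class SyntheticDataset:
    root: Path
    panel_tsv: Path
    scaffolds_fasta: Path
    coverage_tsv: Path
    busco_list: Path
    viral_hits_tsv: Path
    te_hits_tsv: Path
    taxonomy_tsv: Path
    tip_metadata_tsv: Path
    tree_dir: Path
    alignment_dir: Path
    busco_alignment_dir: Path
    chronogram_newick: Path
    truth_tsv: Path
    manifest_json: Path
    truth: TruthTable


# ---------------------------------------------------------------------------
# codon process
# ---------------------------------------------------------------------------

class CodonProcess:
    """Single-omega continuous-time codon substitution process."""

    def __init__(self, omega: float, kappa: float = 1.0, gc: float = 0.35):
        if omega <= 0:
            raise ValueError("omega must be positive")
        pi = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}
        n = len(_SENSE_CODONS)
        from .selection import _translate

        rates = np.zeros((n, n))
        for i, ci in enumerate(_SENSE_CODONS):
            for pos in range(3):
                for nuc in _NUCS:
                    if nuc == ci[pos]:
                        continue
                    cj = ci[:pos] + nuc + ci[pos + 1 :]
                    if cj in _STOPS:
                        continue
                    r = pi[nuc]
                    if (ci[pos], nuc) in _TRANSITIONS:
                        r *= kappa
                    if _translate(ci) != _translate(cj):
                        r *= omega
                    rates[i, _CODON_INDEX[cj]] = r
        pi_codon = np.array([pi[c[0]] * pi[c[1]] * pi[c[2]] for c in _SENSE_CODONS])
        pi_codon /= pi_codon.sum()
        total = rates.sum(axis=1)
        mu = float(pi_codon @ total)  # expected substitutions per codon per unit time
        rates /= mu
        self.pi_codon = pi_codon
        self.total_rate = rates.sum(axis=1)
        with np.errstate(invalid="ignore"):
            probs = rates / self.total_rate[:, None]
        self.cum_probs = np.cumsum(probs, axis=1)

    def root_sequence(self, n_codons: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(len(_SENSE_CODONS), size=n_codons, p=self.pi_codon)

    def evolve(self, seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
        """Evolve a codon-index sequence for branch length t (subs/codon)."""
        if t < 0:
            raise ValueError("negative branch length")
        out = seq.copy()
        for site in range(out.size):
            c = out[site]
            remaining = t
            while True:
                rate = self.total_rate[c]
                if rate <= 0:
                    break
                dt = rng.exponential(1.0 / rate)
                if dt > remaining:
                    break
                remaining -= dt
                c = int(np.searchsorted(self.cum_probs[c], rng.random(), side="right"))
            out[site] = c
        return out


def codons_to_str(seq: np.ndarray) -> str:
    return "".join(_SENSE_CODONS[i] for i in seq)


def simulate_codon_alignment(
    guide_tree: dendropy.Tree,
    omega: float,
    kappa: float = 1.0,
    n_codons: int = 200,
    seed: int | np.random.Generator = 0,
    gc: float = 0.35,
) -> dict[str, str]:
    """Evolve an in-frame, gap-free codon alignment along a guide tree.

    Branch lengths are expected substitutions per codon.  Returns a
    mapping tip label -> nucleotide sequence of length 3*n_codons with
    no internal stop codons.
    """
    if n_codons < 50:
        raise ValueError("n_codons must be >= 50")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    process = CodonProcess(omega=omega, kappa=kappa, gc=gc)
    root_seq = process.root_sequence(n_codons, rng)
    sequences: dict[str, str] = {}

    def descend(node, seq):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            child_seq = process.evolve(seq, t, rng) if t > 0 else seq.copy()
            if child.is_leaf():
                sequences[child.taxon.label] = codons_to_str(child_seq)
            else:
                descend(child, child_seq)

    descend(guide_tree.seed_node, root_seq)
    return sequences


def insert_premature_stop(sequence: str, fraction: float = 0.3) -> str:
    """Replace the codon at the given fractional position with TAA."""
    n_codons = len(sequence) // 3
    pos = max(1, int(n_codons * fraction))
    return sequence[: pos * 3] + "TAA" + sequence[pos * 3 + 3 :]


# ---------------------------------------------------------------------------
# deterministic locus layout
# ---------------------------------------------------------------------------

@dataclass
class PlannedLocus:
    species: str
    family: str
    copy: int              # 1-based per (species, family), in placement order
    event_id: str | None
    pseudogenized: bool
    scaffold: str = ""
    start: int = -1
    end: int = -1
    strand: str = "+"
    sequence: str = ""     # codon region, no start/stop codons
    start_codon: str = "ATG"

    @property
    def tip(self) -> str:
        return f"{self.species}|{self.family}|{self.copy}"

    @property
    def orf_status(self) -> str:
        return "premature_stop" if self.pseudogenized else "complete"


def _chunk_families(families: list[str], size: int) -> list[list[str]]:
    """Split into runs of `size`; a trailing singleton is merged into the
    previous run so every scaffold carries at least two families (one
    family's copies are never stranded without a colocation partner)."""
    runs = [families[i : i + size] for i in range(0, len(families), size)]
    if len(runs) > 1 and len(runs[-1]) == 1:
        runs[-2].extend(runs.pop())
    return runs


def plan_layout(config: ScenarioConfig) -> dict[str, list[list[PlannedLocus]]]:
    """Assign every planned EVE copy to a scaffold, per species.

    Within each species and event, the event's present families are
    rotated by the species' index and grouped `families_per_scaffold`
    per scaffold; all copies of a grouped family share that scaffold.
    The rotation staggers the grouping across species, so the transitive
    closure of colocation (plus same-clade homology) spans each event.
    Orphan loci get private scaffolds.  Copy indices are assigned in
    placement order, which by construction equals coordinate order.
    """
    layout: dict[str, list[list[PlannedLocus]]] = {sp: [] for sp in config.wasp_species}
    copy_counter: dict[tuple[str, str], int] = {}

    def next_copy(species: str, family: str) -> int:
        key = (species, family)
        copy_counter[key] = copy_counter.get(key, 0) + 1
        return copy_counter[key]

    for sp_index, sp in enumerate(config.wasp_species):
        for ev in config.events:
            present = [f for f in ev.gene_families if ev.copies(sp, f) > 0]
            if not present:
                continue
            pseudo = {(f, c) for s, f, c in ev.pseudogenized if s == sp}
            explicit = ev.explicit_groups(sp)
            if explicit is not None:
                runs: list[list[str]] = [list(g) for g in explicit]
            else:
                rot = sp_index % len(present)
                rotated = present[rot:] + present[:rot]
                runs = [
                    [f for family in run for f in [family] * ev.copies(sp, family)]
                    for run in _chunk_families(rotated, ev.families_per_scaffold)
                ]
            for run in runs:
                group: list[PlannedLocus] = []
                for family in run:
                    copy = next_copy(sp, family)
                    group.append(PlannedLocus(
                        species=sp, family=family, copy=copy,
                        event_id=ev.event_id,
                        pseudogenized=(family, copy) in pseudo,
                    ))
                layout[sp].append(group)
        for osp, fam in config.orphan_loci:
            if osp == sp:
                layout[sp].append([PlannedLocus(
                    species=sp, family=fam, copy=next_copy(sp, fam),
                    event_id=None, pseudogenized=False,
                )])
    alt = {(sp, fam): codon for sp, fam, codon in config.alt_start_codons}
    for sp in layout:
        for group in layout[sp]:
            for locus in group:
                locus.start_codon = alt.get((locus.species, locus.family), "ATG")
    return layout


def family_event_copies(
    layout: dict[str, list[list[PlannedLocus]]],
) -> dict[str, dict[str | None, list[PlannedLocus]]]:
    """Group planned loci by family, then by event (None = orphan)."""
    out: dict[str, dict[str | None, list[PlannedLocus]]] = {}
    for sp in layout:
        for group in layout[sp]:
            for locus in group:
                out.setdefault(locus.family, {}).setdefault(locus.event_id, []).append(locus)
    return out


# ---------------------------------------------------------------------------
# gene-tree and guide-tree construction
# ---------------------------------------------------------------------------

def _induced_clade_newick(
    chron: Chronogram,
    copies_by_species: dict[str, list[str]],
    subs_per_myr: float,
    paralog_branch: float,
    support_fn,
) -> str:
    """Newick fragment for a wasp clade shaped by the species chronogram.

    The chronogram topology is restricted to the species that carry
    copies; branch lengths are Myr * subs_per_myr; paralogous copies
    hang as a shallow multifurcation under their species tip.  Internal
    nodes are labelled by ``support_fn()`` (empty string for none).
    Returns the fragment without a trailing branch length.
    """

    def build(node):
        # returns (fragment, age_in_subs) or None if no member species below
        if node.is_leaf():
            sp = node.taxon.label
            tips = copies_by_species.get(sp)
            if not tips:
                return None
            if len(tips) == 1:
                return tips[0], 0.0
            inner = ",".join(f"{t}:{paralog_branch:.6f}" for t in tips)
            return f"({inner}){support_fn()}", paralog_branch
        kids = [build(c) for c in node.child_nodes()]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        age = chron.age(node) * subs_per_myr
        parts = []
        for frag, kid_age in kids:
            bl = max(age - kid_age, paralog_branch / 10.0)
            parts.append(f"{frag}:{bl:.6f}")
        return f"({','.join(parts)}){support_fn()}", age

    built = build(chron.tree.seed_node)
    if built is None:
        raise ValueError("no member species found in the chronogram")
    return built[0]


def _support_label(rng: np.random.Generator, noise: TreeNoise, high: bool) -> str:
    alrt = rng.uniform(*(noise.true_alrt if high else noise.low_alrt))
    boot = rng.uniform(*(noise.true_boot if high else noise.low_boot))
    return f"{alrt:.1f}/{boot:.0f}"


def simulate_gene_tree(
    family: str,
    config: ScenarioConfig,
    rng: np.random.Generator,
    layout: dict[str, list[list[PlannedLocus]]] | None = None,
) -> tuple[str, dendropy.Tree]:
    """Simulate one gene-family tree under the configured scenario.

    Wasp copies of each event form a clade grafted sister to the donor
    lineage's representative virus tip; orphan copies attach next to the
    configured neighbour virus.  Clade supports come from the true-clade
    distribution unless the family is configured as unclassifiable, in
    which case every wasp-internal support is drawn from the low
    distribution.  Returns (newick string with "aLRT/UFboot" labels, the
    wasp-copy guide tree used for sequence evolution).
    """
    chron = config.validate()
    if layout is None:
        layout = plan_layout(config)
    by_family = family_event_copies(layout)
    if family not in by_family:
        raise ValueError(f"family {family!r} has no planned copies in this scenario")
    noise = config.tree_noise
    om = config.omega
    classified = family not in config.unclassified_families

    # wasp clade fragment per event, attached to its donor virus tip
    attach: dict[str, list[str]] = {}  # virus name -> clade fragments
    guide_frags: list[str] = []
    event_by_id = {ev.event_id: ev for ev in config.events}
    for event_id in sorted(by_family[family], key=lambda e: (e is None, e)):
        loci = by_family[family][event_id]
        if event_id is None:
            virus = config.orphan_neighbor_virus
            for locus in loci:
                attach.setdefault(virus, []).append(locus.tip)
                guide_frags.append(f"{locus.tip}:{om.event_root_branch:.6f}")
            continue
        ev = event_by_id[event_id]
        donor = config.virus_panel.donor_for(ev.donor_lineage)
        copies_by_species: dict[str, list[str]] = {}
        for locus in loci:
            copies_by_species.setdefault(locus.species, []).append(locus.tip)
        # a one-species clade is a star over paralog copies; give it more
        # depth than a within-species cherry so pairwise divergence is
        # informative for the selection analysis
        cherry = (om.single_species_branch if len(copies_by_species) == 1
                  else om.paralog_branch)
        frag = _induced_clade_newick(
            chron, copies_by_species, om.subs_per_myr, cherry,
            support_fn=lambda: _support_label(rng, noise, high=classified),
        )
        attach.setdefault(donor.name, []).append(frag)
        guide_frags.append(f"{frag}:{om.event_root_branch:.6f}")

    # virus backbone: outgroup sister to a ladder over the remaining panel
    def bl() -> float:
        return float(rng.uniform(*noise.backbone_branch))

    def virus_subtree(virus: Virus) -> str:
        tip = f"{virus.name}:{bl():.6f}"
        for frag in attach.get(virus.name, []):
            tip = f"({tip},{frag}:{bl():.6f}){_support_label(rng, noise, True)}:{bl():.6f}"
        return tip

    ingroup = [v for v in config.virus_panel.viruses if v.lineage != LINEAGE_OUTGROUP]
    outgroup = [v for v in config.virus_panel.viruses if v.lineage == LINEAGE_OUTGROUP]
    if not ingroup:
        raise ConfigurationError("virus panel has no ingroup viruses")
    ladder = virus_subtree(ingroup[-1])
    for virus in reversed(ingroup[:-1]):
        ladder = (
            f"({virus_subtree(virus)},{ladder}){_support_label(rng, noise, True)}:{bl():.6f}"
        )
    if outgroup:
        og_tips = ",".join(f"{v.name}:{bl():.6f}" for v in outgroup)
        og = f"({og_tips}){_support_label(rng, noise, True)}" if len(outgroup) > 1 else og_tips
        newick = f"({og}:{bl():.6f},{ladder});"
    else:
        newick = f"({ladder});"

    guide_newick = (
        f"({','.join(guide_frags)});" if len(guide_frags) > 1 else f"({guide_frags[0]});"
    )
    guide = dendropy.Tree.get(
        data=guide_newick, schema="newick",
        preserve_underscores=True, suppress_internal_node_taxa=True,
    )
    return newick, guide


# ---------------------------------------------------------------------------
# full scenario generation
# ---------------------------------------------------------------------------

def _random_host_sequence(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(_NUCS))[rng.choice(4, size=n, p=p)])


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_scenario(config: ScenarioConfig, outdir) -> SyntheticDataset:
    """Generate the full synthetic dataset for a scenario.

    Writes scaffolds (FASTA), coverage and BUSCO-scaffold lists, viral
    and TE hit tables, per-protein taxonomy, gene trees, codon
    alignments (EVE families and BUSCO reference genes), tip metadata,
    the chronogram, the truth table, and a JSON manifest.  The same
    config and seed always produce byte-identical files.
    """
    chron = config.validate()
    rng = np.random.default_rng(config.seed)
    root = Path(outdir)
    tree_dir = root / "trees"
    aln_dir = root / "alignments"
    busco_aln_dir = root / "busco_alignments"
    for d in (root, tree_dir, aln_dir, busco_aln_dir):
        d.mkdir(parents=True, exist_ok=True)
    gp, om = config.genome, config.omega

    layout = plan_layout(config)
    by_family = family_event_copies(layout)
    families = sorted(by_family)

    # --- gene trees and codon alignments -------------------------------
    tip_meta: list[TipMetadata] = []
    for virus in config.virus_panel.viruses:
        tip_meta.append(TipMetadata(virus.name, "virus", virus.name, virus.lineage))
    planned_index: dict[str, PlannedLocus] = {}
    for sp in layout:
        for group in layout[sp]:
            for locus in group:
                planned_index[locus.tip] = locus
                tip_meta.append(TipMetadata(locus.tip, "wasp", locus.species, "-"))

    gene_tree_paths: dict[str, Path] = {}
    for family in families:
        newick, guide = simulate_gene_tree(family, config, rng, layout=layout)
        path = tree_dir / f"{family}.nwk"
        path.write_text(newick + "\n")
        gene_tree_paths[family] = path

        sequences = simulate_codon_alignment(
            guide, omega=om.omega_of(family), kappa=om.kappa,
            n_codons=om.n_codons, seed=rng, gc=gp.gc_mean + gp.insert_gc_offset,
        )
        with open(aln_dir / f"{family}.fasta", "w") as fh:
            for tip in sorted(sequences):
                seq = sequences[tip]
                if planned_index[tip].pseudogenized:
                    seq = insert_premature_stop(seq, om.pseudogene_stop_fraction)
                planned_index[tip].sequence = seq
                fh.write(f">{tip}\n{seq}\n")

    # --- BUSCO reference codon alignments -------------------------------
    busco_guide_frag = _induced_clade_newick(
        chron, {sp: [sp] for sp in config.wasp_species},
        om.subs_per_myr, om.paralog_branch, support_fn=lambda: "",
    )
    busco_guide = dendropy.Tree.get(
        data=f"({busco_guide_frag});", schema="newick",
        preserve_underscores=True, suppress_internal_node_taxa=True,
    )
    for k in range(om.n_busco_genes):
        sequences = simulate_codon_alignment(
            busco_guide, omega=om.busco_omega, kappa=om.kappa,
            n_codons=om.n_codons, seed=rng, gc=gp.gc_mean,
        )
        with open(busco_aln_dir / f"busco_{k + 1:04d}.fasta", "w") as fh:
            for tip in sorted(sequences):
                fh.write(f">{tip}\n{sequences[tip]}\n")

    # --- scaffolds, coverage, hits, taxonomy, TE ------------------------
    fasta_records: list[tuple[str, str]] = []
    coverage_rows: list[tuple[str, str]] = []
    busco_ids: list[str] = []
    hit_rows: list[str] = []
    te_rows: list[str] = []
    tax_rows: list[tuple[str, str, str]] = []
    truth_loci: list[TruthLocus] = []
    planted_counter = 0

    def hit_line(scaffold, sseqid, pident, length_aa, start, end, strand, evalue, bitscore):
        if strand == "+":
            qstart, qend = start + 1, end
        else:
            qstart, qend = end, start + 1
        mismatch = int(round(length_aa * (100 - pident) / 100))
        return "\t".join(str(x) for x in (
            scaffold, sseqid, f"{pident:.1f}", length_aa, mismatch, 0,
            qstart, qend, 1, length_aa, f"{evalue:.3g}", f"{bitscore:.1f}",
        ))

    event_by_id = {ev.event_id: ev for ev in config.events}
    for sp in config.wasp_species:
        scaf_no = 0
        eve_ordinal = 0
        for group in layout[sp]:
            scaf_no += 1
            scaffold = f"{sp}|scaf{scaf_no:03d}"
            eve_ordinal += 1
            pieces = [_random_host_sequence(gp.flank_length, gp.gc_mean, rng)]
            pos = gp.flank_length
            for i, locus in enumerate(group):
                orf = locus.start_codon + locus.sequence + "TAA"
                planted_counter += 1
                strand = "-" if planted_counter % gp.minus_strand_every == 0 else "+"
                pieces.append(orf if strand == "+" else _revcomp(orf))
                locus.scaffold, locus.start, locus.end, locus.strand = (
                    scaffold, pos, pos + len(orf), strand,
                )
                pos += len(orf)
                if i < len(group) - 1:
                    pieces.append(_random_host_sequence(gp.spacer_length, gp.gc_mean, rng))
                    pos += gp.spacer_length
                if locus.event_id is not None:
                    donor = config.virus_panel.donor_for(
                        event_by_id[locus.event_id].donor_lineage
                    )
                else:
                    donor = config.virus_panel.by_name(config.orphan_neighbor_virus)
                sseqid = f"{donor.name}|{locus.family}"
                pident = float(rng.uniform(75, 95))
                evalue = 10.0 ** -float(rng.uniform(20, 60))
                bits = om.n_codons * 2 * pident / 100
                hit_rows.append(hit_line(
                    scaffold, sseqid, pident, om.n_codons,
                    locus.start, locus.end, strand, evalue, bits,
                ))
                if planted_counter % 7 == 0:  # a second, weaker overlapping hit
                    mid = (locus.start + locus.end) // 2
                    hit_rows.append(hit_line(
                        scaffold, sseqid, pident - 5, om.n_codons // 2,
                        locus.start, mid, strand, evalue * 1e3, bits / 2,
                    ))
                truth_loci.append(TruthLocus(
                    species=sp, scaffold=scaffold, start=locus.start, end=locus.end,
                    strand=strand, family=locus.family, copy=locus.copy,
                    event_id=locus.event_id, orf_status=locus.orf_status,
                    start_codon=locus.start_codon, tip=locus.tip,
                ))
            pieces.append(_random_host_sequence(gp.flank_length, gp.gc_mean, rng))
            seq = "".join(pieces)
            fasta_records.append((scaffold, seq))
            coverage_rows.append(
                (scaffold, f"{max(1.0, rng.normal(gp.coverage_mean, gp.coverage_sd_other)):.2f}")
            )
            if eve_ordinal % 2 == 1:  # half the EVE scaffolds carry eukaryotic genes
                for g in range(2):
                    tax_rows.append((scaffold, f"{scaffold}|pred{g + 1}", "Insecta"))
            else:  # the other half carry a merged-able pair of TE hits
                te_rows.append(hit_line(scaffold, "TE|gypsy-like", 80.0, 150,
                                        10, 460, "+", 1e-20, 200.0))
                te_rows.append(hit_line(scaffold, "TE|gypsy-like", 78.0, 140,
                                        300, 720, "+", 1e-18, 180.0))
            for i, locus in enumerate(group):
                tax_rows.append((scaffold, f"{scaffold}|vpred{i + 1}", "Viruses"))

        for _ in range(gp.busco_scaffolds_per_species):
            scaf_no += 1
            scaffold = f"{sp}|scaf{scaf_no:03d}"
            n = int(rng.integers(*gp.busco_scaffold_length))
            fasta_records.append((scaffold, _random_host_sequence(n, gp.gc_mean, rng)))
            coverage_rows.append(
                (scaffold, f"{max(1.0, rng.normal(gp.coverage_mean, gp.coverage_sd_busco)):.2f}")
            )
            busco_ids.append(scaffold)
            for g in range(3):
                tax_rows.append((scaffold, f"{scaffold}|pred{g + 1}", "Insecta"))

        is_negative = not layout[sp]
        for p in range(gp.plain_scaffolds_per_species):
            scaf_no += 1
            scaffold = f"{sp}|scaf{scaf_no:03d}"
            n = int(rng.integers(*gp.plain_scaffold_length))
            fasta_records.append((scaffold, _random_host_sequence(n, gp.gc_mean, rng)))
            coverage_rows.append(
                (scaffold, f"{max(1.0, rng.normal(gp.coverage_mean, gp.coverage_sd_other)):.2f}")
            )
            if is_negative and p == 0 and config.events:
                donor = config.virus_panel.viruses[0]
                for _ in range(gp.n_decoy_hits_per_negative):
                    start = int(rng.integers(0, max(1, n - 400)))
                    evalue = 10.0 ** -float(rng.uniform(0.5, 2.5))
                    hit_rows.append(hit_line(
                        scaffold, f"{donor.name}|{donor.genes[0]}", 35.0, 60,
                        start, start + 180, "+", evalue, 25.0,
                    ))

    # --- truth table -----------------------------------------------------
    family_types = _true_family_types(config)
    truth = TruthTable(
        loci=truth_loci,
        family_types=family_types,
        events={
            ev.event_id: {
                "donor_lineage": ev.donor_lineage,
                "families": sorted(
                    {l.family for l in truth_loci if l.event_id == ev.event_id}
                ),
                "species": sorted(
                    {l.species for l in truth_loci if l.event_id == ev.event_id}
                ),
            }
            for ev in config.events
        },
    )

    # --- write everything -------------------------------------------------
    paths = SyntheticDataset(
        root=root,
        panel_tsv=root / "virus_panel.tsv",
        scaffolds_fasta=root / "scaffolds.fasta",
        coverage_tsv=root / "coverage.tsv",
        busco_list=root / "busco_scaffolds.txt",
        viral_hits_tsv=root / "viral_hits.tsv",
        te_hits_tsv=root / "te_hits.tsv",
        taxonomy_tsv=root / "taxonomy.tsv",
        tip_metadata_tsv=root / "tip_metadata.tsv",
        tree_dir=tree_dir,
        alignment_dir=aln_dir,
        busco_alignment_dir=busco_aln_dir,
        chronogram_newick=root / "chronogram.nwk",
        truth_tsv=root / "truth.tsv",
        manifest_json=root / "manifest.json",
        truth=truth,
    )
    write_tsv(
        paths.panel_tsv,
        ["#virus", "lineage", "gene", "is_core"],
        [(v.name, v.lineage, g, int(g in set(v.core_genes)))
         for v in config.virus_panel.viruses for g in v.genes],
    )
    with open(paths.scaffolds_fasta, "w") as fh:
        for name, seq in fasta_records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_tsv(paths.coverage_tsv, ["#scaffold_id", "mean_coverage"], coverage_rows)
    paths.busco_list.write_text("".join(s + "\n" for s in busco_ids))
    paths.viral_hits_tsv.write_text(
        "# qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore\n"
        + "".join(r + "\n" for r in hit_rows)
    )
    paths.te_hits_tsv.write_text("".join(r + "\n" for r in te_rows))
    write_tsv(paths.taxonomy_tsv, ["#scaffold_id", "protein_id", "taxon"], tax_rows)
    write_tip_metadata(paths.tip_metadata_tsv, tip_meta)
    paths.chronogram_newick.write_text(config.chronogram_newick.strip() + "\n")
    write_tsv(
        paths.truth_tsv,
        [f"#{TRUTH_FORMAT_VERSION}:species", "scaffold", "start", "end", "strand",
         "family", "copy", "event_id", "orf_status", "start_codon", "tip"],
        [(l.species, l.scaffold, l.start, l.end, l.strand, l.family, l.copy,
          l.event_id or "-", l.orf_status, l.start_codon, l.tip) for l in truth_loci],
    )
    manifest = {
        "seed": config.seed,
        "truth_format": TRUTH_FORMAT_VERSION,
        "n_truth_loci": len(truth_loci),
        "family_types": family_types,
        "events": truth.events,
        "paths": {
            "panel_tsv": paths.panel_tsv.name,
            "scaffolds_fasta": paths.scaffolds_fasta.name,
            "coverage_tsv": paths.coverage_tsv.name,
            "busco_list": paths.busco_list.name,
            "viral_hits_tsv": paths.viral_hits_tsv.name,
            "te_hits_tsv": paths.te_hits_tsv.name,
            "taxonomy_tsv": paths.taxonomy_tsv.name,
            "tip_metadata_tsv": paths.tip_metadata_tsv.name,
            "tree_dir": tree_dir.name,
            "alignment_dir": aln_dir.name,
            "busco_alignment_dir": busco_aln_dir.name,
            "chronogram_newick": paths.chronogram_newick.name,
            "truth_tsv": paths.truth_tsv.name,
        },
    }
    write_json(paths.manifest_json, manifest)
    return paths


def _true_family_types(config: ScenarioConfig) -> dict[str, str]:
    """Ground-truth topology type per family implied by the scenario."""
    from .trees import TYPE_I, TYPE_II, TYPE_III, UNCLASSIFIED

    ancestral = {
        f for ev in config.events if ev.donor_lineage == LINEAGE_ANCESTRAL
        for f in ev.gene_families
    }
    recent = {
        f for ev in config.events if ev.donor_lineage == LINEAGE_RECENT
        for f in ev.gene_families
    }
    out: dict[str, str] = {}
    for sp, fam in config.orphan_loci:
        out[fam] = UNCLASSIFIED
    for fam in sorted(ancestral | recent):
        if fam in config.unclassified_families:
            out[fam] = UNCLASSIFIED
        elif fam in ancestral and fam in recent:
            out[fam] = TYPE_III
        elif fam in ancestral:
            out[fam] = TYPE_I
        else:
            out[fam] = TYPE_II
    return out
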