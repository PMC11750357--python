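"""File-based orchestration of the detection-to-dating pipeline.

Each stage consumes files and writes files, so stages can be re-run
individually; ``run_all`` chains them.  The expected input layout is the
one the synthetic generator emits (see its JSON manifest); a real
dataset can be analysed by arranging the same files.

Stage outputs (all under the chosen output directory):

* detect   -> ``catalog.tsv`` (EVE loci with ORF calls), ``evidence.tsv``
* classify -> ``topology_calls.json`` / ``topology_calls.tsv``
* assign   -> ``events.json``, ``presence_matrix.tsv``
* select   -> ``omega.tsv``, ``selection_comparison.json``
* date     -> ``dated_events.json`` (also folded back into events)
* report   -> ``report.json``
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from . import events as events_mod
from . import homology, scaffolds, selection, trees
from .dating import Chronogram, core_gene_enrichment, date_event
from .io import (
    read_hits, read_json, read_taxonomy_tsv, read_tip_metadata, read_tsv,
    read_two_column_tsv, sha256_of_file, write_json, write_tsv,
)

log = logging.getLogger("paleofv")


@dataclass
class PipelineConfig:
    """Thresholds for a pipeline run; defaults follow the methods note."""

    e_max: float = homology.DEFAULT_E_MAX
    min_support: float = trees.DEFAULT_MIN_SUPPORT
    envelope_k: float = 5.0
    alpha: float = 0.05

    def __post_init__(self):
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")
        if not (0 <= self.min_support <= 100):
            raise ValueError("min_support must be within [0, 100]")
        if self.envelope_k <= 0 or self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("envelope_k must be positive and alpha in (0, 1)")


@dataclass
class DatasetPaths:
    """Input file locations, resolvable from a generator manifest."""

    root: Path
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
    panel_tsv: Path

    @classmethod
    def from_manifest(cls, dataset_dir) -> "DatasetPaths":
        root = Path(dataset_dir)
        manifest = read_json(root / "manifest.json")
        p = manifest["paths"]
        return cls(
            root=root,
            scaffolds_fasta=root / p["scaffolds_fasta"],
            coverage_tsv=root / p["coverage_tsv"],
            busco_list=root / p["busco_list"],
            viral_hits_tsv=root / p["viral_hits_tsv"],
            te_hits_tsv=root / p["te_hits_tsv"],
            taxonomy_tsv=root / p["taxonomy_tsv"],
            tip_metadata_tsv=root / p["tip_metadata_tsv"],
            tree_dir=root / p["tree_dir"],
            alignment_dir=root / p["alignment_dir"],
            busco_alignment_dir=root / p["busco_alignment_dir"],
            chronogram_newick=root / p["chronogram_newick"],
            panel_tsv=root / p["panel_tsv"],
        )


# ---------------------------------------------------------------------------
# detect
# ---------------------------------------------------------------------------

def stage_detect(data: DatasetPaths, outdir, config: PipelineConfig | None = None):
    """Filter hits, call loci with ORF integrity, and score scaffolds."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    hits = homology.filter_hits(read_hits(data.viral_hits_tsv), e_max=config.e_max)
    catalog = homology.call_loci(hits)
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(data.scaffolds_fasta), "fasta")}
    catalog = homology.annotate_orf_status(catalog, seqs)
    log.info("detect: %d loci on %d scaffolds", len(catalog),
             len({l.scaffold for l in catalog}))

    write_tsv(
        outdir / "catalog.tsv",
        ["#locus_id", "species", "scaffold", "start", "end", "strand",
         "family", "best_virus", "orf_status", "start_codon"],
        [(l.locus_id, l.species, l.scaffold, l.start, l.end, l.strand,
          l.family, l.best_virus, l.orf_status, l.start_codon or "-") for l in catalog],
    )

    coverage = read_two_column_tsv(data.coverage_tsv, float)
    busco_ids = set(data.busco_list.read_text().split())
    taxonomy = read_taxonomy_tsv(data.taxonomy_tsv)
    te_hits = defaultdict(list)
    for h in read_hits(data.te_hits_tsv):
        te_hits[h.qseqid].append(h)

    records = {
        sid: scaffolds.ScaffoldRecord(
            id=sid, length=len(seq), gc=scaffolds.gc_content(seq),
            coverage=coverage[sid], is_busco=sid in busco_ids,
        )
        for sid, seq in seqs.items()
    }
    envelopes = {}
    for species in sorted({homology.species_of_scaffold(s) for s in records}):
        busco = [r for r in records.values()
                 if r.is_busco and homology.species_of_scaffold(r.id) == species]
        if len(busco) >= 5:
            envelopes[species] = scaffolds.busco_envelope(busco, k=config.envelope_k)

    evidence_rows = []
    for scaffold in sorted({l.scaffold for l in catalog}):
        species = homology.species_of_scaffold(scaffold)
        envelope = envelopes.get(species)
        if envelope is None:
            raise ValueError(f"no BUSCO envelope available for species {species}")
        ev = scaffolds.classify_scaffold(
            records[scaffold], envelope,
            gene_labels=[taxon for _, taxon in taxonomy.get(scaffold, [])],
            te_hits=te_hits.get(scaffold, []),
        )
        evidence_rows.append((
            ev.scaffold_id, int(ev.gc_ok), int(ev.coverage_ok),
            ev.n_eukaryotic_genes, ev.n_te_intervals, ev.contig_taxon, ev.verdict,
        ))
    write_tsv(
        outdir / "evidence.tsv",
        ["#scaffold_id", "gc_ok", "coverage_ok", "n_eukaryotic_genes",
         "n_te_intervals", "contig_taxon", "verdict"],
        evidence_rows,
    )
    return catalog


def load_catalog(outdir) -> list[homology.EveLocus]:
    _, rows = read_tsv(Path(outdir) / "catalog.tsv")
    return [
        homology.EveLocus(
            locus_id=r[0], species=r[1], scaffold=r[2], start=int(r[3]), end=int(r[4]),
            strand=r[5], family=r[6], best_virus=r[7], orf_status=r[8],
            start_codon=None if r[9] == "-" else r[9],
        )
        for r in rows
    ]


# ---------------------------------------------------------------------------
# classify
# ---------------------------------------------------------------------------

def stage_classify(data: DatasetPaths, outdir, config: PipelineConfig | None = None):
    """Classify every gene-family tree in the tree directory."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = read_tip_metadata(data.tip_metadata_tsv)

    calls: dict[str, trees.TopologyCall] = {}
    for path in sorted(data.tree_dir.glob("*.nwk")):
        family = path.stem
        tree = trees.read_gene_tree(path)
        calls[family] = trees.classify_gene_tree(
            family, tree, meta, min_support=config.min_support
        )
    log.info("classify: %d families", len(calls))

    write_json(outdir / "topology_calls.json", {
        fam: {
            "type": call.type,
            "notes": call.notes,
            "clades": [
                {
                    "tips": sorted(c.tips),
                    "support": c.support,
                    "species": sorted(c.species),
                    "nearest_lineage": c.nearest_lineage,
                    "note": c.note,
                }
                for c in call.clades
            ],
        }
        for fam, call in calls.items()
    })
    write_tsv(
        outdir / "topology_calls.tsv",
        ["#family", "type", "n_clades", "clade_supports", "nearest_lineages"],
        [(fam, call.type, len(call.clades),
          ",".join("-" if c.support is None else f"{c.support:g}" for c in call.clades),
          ",".join(c.nearest_lineage or "-" for c in call.clades))
         for fam, call in sorted(calls.items())],
    )
    return calls


def load_calls(outdir) -> dict[str, trees.TopologyCall]:
    raw = read_json(Path(outdir) / "topology_calls.json")
    calls = {}
    for fam, rec in raw.items():
        calls[fam] = trees.TopologyCall(
            family=fam,
            type=rec["type"],
            notes=list(rec["notes"]),
            clades=[
                trees.WaspClade(
                    tips=frozenset(c["tips"]),
                    support=c["support"],
                    species=frozenset(c["species"]),
                    nearest_lineage=c["nearest_lineage"],
                    note=c["note"],
                )
                for c in rec["clades"]
            ],
        )
    return calls


# ---------------------------------------------------------------------------
# assign
# ---------------------------------------------------------------------------

def stage_assign(catalog, calls, outdir):
    """Group loci into events and write the event report and matrix."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph = events_mod.build_graph(catalog, calls)
    event_list, unassigned = events_mod.group_events(graph, calls)
    log.info("assign: %d events, %d unassigned loci", len(event_list), len(unassigned))

    write_json(outdir / "events.json", {
        "events": [
            {
                "event_id": ev.event_id,
                "n_loci": ev.n_loci,
                "loci": ev.loci,
                "families": sorted(ev.families),
                "species": sorted(ev.species),
                "donor_lineage": ev.donor_lineage,
                "conflict": ev.conflict,
                "notes": ev.notes,
            }
            for ev in event_list
        ],
        "unassigned": unassigned,
    })

    by_cell: dict[tuple[str, str], list] = defaultdict(list)
    for locus in catalog:
        by_cell[(locus.species, locus.family)].append(locus)
    species_order = sorted({l.species for l in catalog})
    family_order = sorted({l.family for l in catalog})
    rows = []
    for sp in species_order:
        row = [sp]
        for fam in family_order:
            loci = by_cell.get((sp, fam), [])
            if not loci:
                row.append(".")
                continue
            cell = str(len(loci))
            if any(l.orf_status in ("premature_stop", "incomplete") for l in loci):
                cell += "*"   # at least one defective copy
            if any(l.orf_status == "complete" and l.start_codon not in (None, "-", "ATG")
                   for l in loci):
                cell += "#"   # complete ORF with an alternative start codon
            row.append(cell)
        rows.append(row)
    write_tsv(outdir / "presence_matrix.tsv", ["#species"] + family_order, rows)
    return event_list, unassigned


# ---------------------------------------------------------------------------
# select
# ---------------------------------------------------------------------------

def _alignment_sequences(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def stage_select(data: DatasetPaths, outdir, config: PipelineConfig | None = None):
    """Per-family omega estimates and the EVE-vs-BUSCO group comparison."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def estimate_dir(directory) -> dict[str, selection.OmegaEstimate]:
        out = {}
        for path in sorted(Path(directory).glob("*.fasta")):
            seqs = _alignment_sequences(path)
            if len(seqs) < 2:
                est = selection.OmegaEstimate(
                    family=path.stem, pairs=[], omega_mean=None, omega_se=None,
                    n_defined=0, regime="undetermined",
                    notes=["n/a: fewer than 2 sequences"],
                )
            else:
                est = selection.family_omega(seqs, family=path.stem, alpha=config.alpha)
            out[path.stem] = est
        return out

    eve = estimate_dir(data.alignment_dir)
    busco = estimate_dir(data.busco_alignment_dir)

    write_tsv(
        outdir / "omega.tsv",
        ["#family", "group", "n_pairs_defined", "omega_mean", "omega_se", "regime", "notes"],
        [(fam, group, est.n_defined,
          "-" if est.omega_mean is None else f"{est.omega_mean:.4f}",
          "-" if est.omega_se is None else f"{est.omega_se:.4f}",
          est.regime, ";".join(est.notes))
         for group, table in (("eve", eve), ("busco", busco))
         for fam, est in sorted(table.items())],
    )

    eve_omegas = [w for est in eve.values() for w in selection.pairwise_omegas(est.pairs)]
    busco_omegas = [w for est in busco.values() for w in selection.pairwise_omegas(est.pairs)]
    comparison = None
    if len(eve_omegas) >= 2 and len(busco_omegas) >= 2:
        cmp_result = selection.compare_groups(eve_omegas, busco_omegas)
        comparison = {
            "eve_mean": cmp_result.mean_a,
            "busco_mean": cmp_result.mean_b,
            "t_statistic": cmp_result.t_statistic,
            "df": cmp_result.df,
            "p_value": cmp_result.p_value,
            "n_eve_pairs": cmp_result.n_a,
            "n_busco_pairs": cmp_result.n_b,
        }
    write_json(outdir / "selection_comparison.json", {
        "comparison": comparison,
        "regimes": {fam: est.regime for fam, est in sorted(eve.items())},
    })
    return eve, busco, comparison


# ---------------------------------------------------------------------------
# enrichment + dating
# ---------------------------------------------------------------------------

def _read_panel(panel_tsv):
    _, rows = read_tsv(panel_tsv)
    genes: dict[str, set[str]] = defaultdict(set)
    core: dict[str, set[str]] = defaultdict(set)
    lineage_of: dict[str, str] = {}
    for virus, lineage, gene, is_core in rows:
        genes[virus].add(gene)
        lineage_of.setdefault(virus, lineage)
        if int(is_core):
            core[virus].add(gene)
    return genes, core, lineage_of


def stage_date(data: DatasetPaths, outdir, config: PipelineConfig | None = None):
    """Enrichment and age intervals for the events found by `assign`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events_doc = read_json(outdir / "events.json")
    chron = Chronogram.read(data.chronogram_newick)
    genes, core, lineage_of = _read_panel(data.panel_tsv)

    dated = []
    for ev in events_doc["events"]:
        interval = date_event(set(ev["species"]), chron)
        entry = {
            "event_id": ev["event_id"],
            "age_lower_myr": interval.lower,
            "age_upper_myr": interval.upper,
            "age_lower_ci": interval.lower_ci,
            "age_upper_ci": interval.upper_ci,
        }
        candidates = [v for v in sorted(genes) if lineage_of[v] == ev["donor_lineage"]]
        # the lineage's representative donor: largest annotated repertoire
        donor = max(candidates, key=lambda v: len(genes[v]), default=None)
        if donor is not None and core.get(donor):
            fisher = core_gene_enrichment(set(ev["families"]), genes[donor], core[donor])
            entry["core_enrichment"] = {
                "donor": donor,
                "table": fisher.table,
                "odds_ratio": fisher.odds_ratio,
                "odds_ratio_sample": fisher.odds_ratio_sample,
                "p_value": fisher.p_value,
            }
        dated.append(entry)
    write_json(outdir / "dated_events.json", {"events": dated})
    return dated


# ---------------------------------------------------------------------------
# report / run_all
# ---------------------------------------------------------------------------

def stage_report(outdir):
    """Fold all stage outputs into one JSON report."""
    outdir = Path(outdir)
    for name in ("catalog.tsv", "topology_calls.json", "events.json",
                 "dated_events.json", "selection_comparison.json"):
        if not (outdir / name).exists():
            raise FileNotFoundError(f"stage output missing: {name} (run its stage first)")
    catalog = load_catalog(outdir)
    calls = load_calls(outdir)
    events_doc = read_json(outdir / "events.json")
    dated = read_json(outdir / "dated_events.json")["events"]
    sel = read_json(outdir / "selection_comparison.json")

    type_counts = defaultdict(int)
    for call in calls.values():
        type_counts[call.type] += 1
    report = {
        "n_loci": len(catalog),
        "n_families": len({l.family for l in catalog}),
        "n_species_positive": len({l.species for l in catalog}),
        "topology_type_counts": dict(sorted(type_counts.items())),
        "events": [
            {**ev, **next((d for d in dated if d["event_id"] == ev["event_id"]), {})}
            for ev in events_doc["events"]
        ],
        "unassigned": events_doc["unassigned"],
        "selection": sel,
    }
    write_json(outdir / "report.json", report)
    return report


def run_all(dataset_dir, outdir, config: PipelineConfig | None = None) -> dict:
    """Run detect -> classify -> assign -> select -> date -> report."""
    config = config or PipelineConfig()
    data = DatasetPaths.from_manifest(dataset_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = stage_detect(data, outdir, config)
    calls = stage_classify(data, outdir, config)
    stage_assign(catalog, calls, outdir)
    stage_select(data, outdir, config)
    stage_date(data, outdir, config)
    write_json(outdir / "run_manifest.json", {
        "inputs": {
            name: sha256_of_file(getattr(data, name))
            for name in ("scaffolds_fasta", "coverage_tsv", "viral_hits_tsv",
                         "te_hits_tsv", "taxonomy_tsv", "tip_metadata_tsv",
                         "chronogram_newick", "panel_tsv")
        },
        "thresholds": {
            "e_max": config.e_max, "min_support": config.min_support,
            "envelope_k": config.envelope_k, "alpha": config.alpha,
        },
    })
    return stage_report(outdir)
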