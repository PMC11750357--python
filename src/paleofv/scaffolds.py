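"""Chromosomal-integration evidence for candidate viral scaffolds.

A scaffold carrying viral hits may be a genuine endogenous viral element
(EVE) locus or exogenous viral contamination (free virions, infecting
particles) co-assembled with the host.  Three independent lines of
evidence argue for chromosomal integration:

* GC content and sequencing coverage inside the envelope spanned by
  BUSCO-containing scaffolds, which are host chromosome by definition;
* predicted eukaryotic genes on the same scaffold (majority-vote
  taxonomy over its predicted proteins);
* transposable-element (TE) hits, since viral genomes almost never carry
  TEs.

The envelope is median +/- k*MAD per metric (default k=5), a robust rule
that tolerates the skewed coverage distributions of real assemblies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .io import TabularHit

#: taxonomy labels counted as eukaryotic in the gene-content evidence
EUKARYOTIC_TAXA = frozenset(
    {"eukaryota", "eukaryote", "insecta", "insect", "arthropoda", "hymenoptera", "metazoa"}
)

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class ScaffoldRecord:
    """Per-scaffold summary used for the GC/coverage envelope test."""

    id: str
    length: int
    gc: float
    coverage: float
    is_busco: bool = False

    def __post_init__(self):
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError(f"GC fraction {self.gc} outside [0, 1]")
        if self.coverage < 0:
            raise ValueError("negative coverage")
        if self.length <= 0:
            raise ValueError("non-positive length")


@dataclass(frozen=True)
class Envelope:
    """Acceptance intervals for GC and coverage derived from BUSCO scaffolds."""

    gc_low: float
    gc_high: float
    cov_low: float
    cov_high: float
    k: float
    n_reference: int

    def gc_ok(self, gc: float) -> bool:
        return self.gc_low <= gc <= self.gc_high

    def coverage_ok(self, cov: float) -> bool:
        return self.cov_low <= cov <= self.cov_high


@dataclass(frozen=True)
class EndogenizationEvidence:
    scaffold_id: str
    gc_ok: bool
    coverage_ok: bool
    n_eukaryotic_genes: int
    n_te_intervals: int
    contig_taxon: str
    verdict: str  # endogenized | ambiguous | likely_exogenous


def gc_content(sequence: str) -> float:
    """GC fraction of a sequence, ignoring N and other ambiguity codes.

    Raises ValueError when no unambiguous base is present.
    """
    counts = Counter(sequence.upper())
    total = sum(counts[b] for b in _UNAMBIGUOUS)
    if total == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    return (counts["G"] + counts["C"]) / total


def busco_envelope(busco_records: list[ScaffoldRecord], k: float = 5.0) -> Envelope:
    """Median +/- k*MAD acceptance intervals from BUSCO reference scaffolds.

    At least 5 reference scaffolds are required; with fewer, the MAD is
    too unstable to define a meaningful envelope.
    """
    if len(busco_records) < 5:
        raise ValueError(
            f"need >=5 BUSCO reference scaffolds to build an envelope, got {len(busco_records)}"
        )
    gc = np.array([r.gc for r in busco_records], dtype=float)
    cov = np.array([r.coverage for r in busco_records], dtype=float)
    gc_med, cov_med = np.median(gc), np.median(cov)
    gc_mad = np.median(np.abs(gc - gc_med))
    cov_mad = np.median(np.abs(cov - cov_med))
    return Envelope(
        gc_low=float(gc_med - k * gc_mad),
        gc_high=float(gc_med + k * gc_mad),
        cov_low=float(cov_med - k * cov_mad),
        cov_high=float(cov_med + k * cov_mad),
        k=k,
        n_reference=len(busco_records),
    )


def majority_vote_taxonomy(labels: list[str]) -> str:
    """Strict-majority taxon over a scaffold's predicted-protein labels.

    Ties and empty inputs yield ``"unassigned"`` — deliberately
    conservative, so a scaffold is never called eukaryotic on a split
    vote.
    """
    if not labels:
        return "unassigned"
    counts = Counter(labels)
    (top, n), *rest = counts.most_common()
    if rest and rest[0][1] == n:
        return "unassigned"
    if n * 2 <= len(labels):
        return "unassigned"
    return top


def te_intervals(
    hits: list[TabularHit],
    e_max: float = 1e-10,
    min_len_aa: int = 100,
) -> list[tuple[int, int]]:
    """Filter TE hits and merge the survivors into disjoint intervals.

    Keeps hits with e-value strictly below ``e_max`` and alignment length
    strictly above ``min_len_aa``, then unions overlapping intervals.
    Book-ended intervals (end == next start, 0-based half-open) are merged
    as well.  Returned sorted by start.
    """
    kept = sorted(
        ((h.start, h.end) for h in hits if h.evalue < e_max and h.length > min_len_aa),
    )
    merged: list[tuple[int, int]] = []
    for start, end in kept:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def classify_scaffold(
    record: ScaffoldRecord,
    envelope: Envelope,
    gene_labels: list[str] | None = None,
    te_hits: list[TabularHit] | None = None,
    eukaryotic_taxa: frozenset[str] = EUKARYOTIC_TAXA,
) -> EndogenizationEvidence:
    """Combine envelope, gene-content and TE evidence into one verdict.

    ``endogenized`` when the scaffold sits inside both envelope intervals,
    or carries at least one eukaryotic gene, or at least one merged TE
    interval; ``likely_exogenous`` when none of the evidence lines fire at
    all; ``ambiguous`` otherwise (e.g. one envelope metric in, one out).
    """
    gene_labels = gene_labels or []
    intervals = te_intervals(te_hits) if te_hits else []
    gc_ok = envelope.gc_ok(record.gc)
    cov_ok = envelope.coverage_ok(record.coverage)
    n_euk = sum(1 for lab in gene_labels if lab.lower() in eukaryotic_taxa)
    taxon = majority_vote_taxonomy(gene_labels)
    if (gc_ok and cov_ok) or n_euk >= 1 or len(intervals) >= 1:
        verdict = "endogenized"
    elif not gc_ok and not cov_ok:
        verdict = "likely_exogenous"
    else:
        verdict = "ambiguous"
    return EndogenizationEvidence(
        scaffold_id=record.id,
        gc_ok=gc_ok,
        coverage_ok=cov_ok,
        n_eukaryotic_genes=n_euk,
        n_te_intervals=len(intervals),
        contig_taxon=taxon,
        verdict=verdict,
    )
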