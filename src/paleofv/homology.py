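"""EVE catalog construction from viral-protein homology hits.

Raw tabular hits of wasp scaffolds against a filamentovirus proteome
panel are filtered on e-value, merged into loci by same-strand interval
union, labelled with the viral gene family of their best hit, and given
an ORF-integrity call (complete / premature_stop / incomplete) from the
underlying nucleotide sequence.

Subject identifiers are expected as ``VIRUS|FAMILY`` (e.g.
``LhFV|lef-5``), the convention used throughout the pipeline to carry
both the source virus and the gene family of a panel protein.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import groupby

from Bio.Seq import Seq

from .io import TabularHit

#: recognized ORF start codons; filamentoviruses use TTG and CTG starts
#: in addition to ATG (lef-5 is the canonical example)
START_CODONS = ("ATG", "TTG", "CTG", "GTG")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: a premature stop is called when the best ORF covers less than this
#: fraction of the hit-supported span
MIN_COMPLETE_FRACTION = 0.8

DEFAULT_E_MAX = 1e-3


@dataclass(frozen=True)
class EveLocus:
    """One candidate virally derived locus on a wasp scaffold."""

    locus_id: str
    species: str
    scaffold: str
    start: int            # 0-based half-open, forward strand
    end: int
    strand: str
    family: str           # viral gene family of the best hit
    best_virus: str       # source virus of the best hit
    orf_status: str = "unknown"   # complete | premature_stop | incomplete | unknown
    start_codon: str | None = None

    @property
    def span(self) -> int:
        return self.end - self.start


def split_subject(sseqid: str) -> tuple[str, str]:
    """Split a ``VIRUS|FAMILY`` subject id into its two components."""
    virus, sep, family = sseqid.partition("|")
    if not sep or not family:
        raise ValueError(f"subject id {sseqid!r} is not in VIRUS|FAMILY form")
    return virus, family


def filter_hits(hits: list[TabularHit], e_max: float = DEFAULT_E_MAX) -> list[TabularHit]:
    """Keep hits with e-value <= e_max (inclusive boundary), preserving order."""
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    return [h for h in hits if h.evalue <= e_max]


def species_of_scaffold(scaffold_id: str) -> str:
    """Species encoded in a ``species|scaffold`` identifier."""
    species, sep, _ = scaffold_id.partition("|")
    if not sep:
        raise ValueError(f"scaffold id {scaffold_id!r} does not carry a species prefix")
    return species


def call_loci(hits: list[TabularHit], species: str | None = None) -> list[EveLocus]:
    """Merge filtered hits into EVE loci.

    Overlapping (or book-ended) same-strand hits on the same scaffold are
    unioned into one locus.  The locus family and source virus come from
    the highest-bitscore constituent hit; ties are broken by lower
    e-value, then lexicographic subject id.  Output is sorted by
    (scaffold, start) with pairwise non-overlapping intervals per
    scaffold and strand.
    """
    loci: list[EveLocus] = []
    keyed = sorted(hits, key=lambda h: (h.qseqid, h.strand, h.start, h.end))
    for (scaffold, strand), group in groupby(keyed, key=lambda h: (h.qseqid, h.strand)):
        sp = species if species is not None else species_of_scaffold(scaffold)
        cluster: list[TabularHit] = []
        cluster_end = -1
        for hit in group:
            if cluster and hit.start <= cluster_end:  # overlap or book-ended
                cluster.append(hit)
                cluster_end = max(cluster_end, hit.end)
            else:
                if cluster:
                    loci.append(_locus_from_cluster(cluster, sp, scaffold, strand))
                cluster = [hit]
                cluster_end = hit.end
        if cluster:
            loci.append(_locus_from_cluster(cluster, sp, scaffold, strand))
    loci.sort(key=lambda l: (l.scaffold, l.start))
    return loci


def _locus_from_cluster(cluster: list[TabularHit], species: str, scaffold: str, strand: str) -> EveLocus:
    start = min(h.start for h in cluster)
    end = max(h.end for h in cluster)
    best = min(cluster, key=lambda h: (-h.bitscore, h.evalue, h.sseqid))
    virus, family = split_subject(best.sseqid)
    return EveLocus(
        locus_id=f"{scaffold}:{start}-{end}({strand})",
        species=species,
        scaffold=scaffold,
        start=start,
        end=end,
        strand=strand,
        family=family,
        best_virus=virus,
    )


def orf_integrity(
    sequence: str,
    strand: str = "+",
    hit_span: int | None = None,
) -> tuple[str, str | None]:
    """Call ORF integrity for a locus nucleotide sequence.

    The sequence is the forward-strand scaffold slice of the locus; minus
    strand loci are reverse-complemented first.  All three frames are
    scanned for readings from a recognized start codon (ATG or the
    alternative starts TTG/CTG/GTG) to the next in-frame stop.  Status:

    * ``complete`` — a start-to-stop reading covers >= 80% of the
      hit-supported span (no internal stop truncates the gene);
    * ``premature_stop`` — the best reading terminates at a stop codon
      but truncates more than 20% of the span;
    * ``incomplete`` — no recognized start, or no stop within the locus.

    Returns (status, start_codon); start_codon is None when no start was
    found.
    """
    if len(sequence) < 6:
        raise ValueError("locus sequence shorter than 6 nt")
    seq = str(Seq(sequence).reverse_complement()).upper() if strand == "-" else sequence.upper()
    span = hit_span if hit_span is not None else len(seq)

    best: tuple[int, int, str] | None = None  # (orf_len, has_stop, start_codon)
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        i = 0
        while i < len(codons):
            if codons[i] in START_CODONS:
                j = i
                while j < len(codons) and codons[j] not in STOP_CODONS:
                    j += 1
                has_stop = j < len(codons)
                orf_len = (j - i + (1 if has_stop else 0)) * 3
                cand = (orf_len, int(has_stop), codons[i])
                if best is None or cand[:2] > best[:2]:
                    best = cand
                i = j + 1
            else:
                i += 1

    if best is None:
        return "incomplete", None
    orf_len, has_stop, start_codon = best
    if has_stop and orf_len >= MIN_COMPLETE_FRACTION * span:
        return "complete", start_codon
    if has_stop:
        return "premature_stop", start_codon
    return "incomplete", start_codon


def annotate_orf_status(loci: list[EveLocus], scaffold_seqs: dict[str, str]) -> list[EveLocus]:
    """Fill orf_status/start_codon for each locus from its scaffold sequence."""
    out = []
    for locus in loci:
        seq = scaffold_seqs[locus.scaffold][locus.start : locus.end]
        status, start_codon = orf_integrity(seq, locus.strand, hit_span=locus.span)
        out.append(replace(locus, orf_status=status, start_codon=start_codon))
    return out
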