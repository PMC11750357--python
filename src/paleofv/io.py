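"""Readers and writers for the pipeline's tabular interchange formats.

Homology and transposable-element hits travel in the 12-column tabular
format emitted by BLAST/MMseqs2 (``outfmt 6``):

    qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore

Query coordinates in files are 1-based inclusive, with ``qstart > qend``
marking a minus-strand hit, as the search tools write them.  Internally
every interval is 0-based half-open on the forward strand; normalization
happens here, at parse time, and nowhere else.
"""

from __future__ import annotations

import csv
import json
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable


class ParseError(ValueError):
    """Malformed row in a tabular input; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True)
class TabularHit:
    """One homology hit with strand-normalized 0-based half-open coordinates."""

    qseqid: str
    sseqid: str
    pident: float
    length: int          # alignment length in subject units (aa for protein subjects)
    mismatch: int
    gapopen: int
    start: int           # 0-based inclusive, forward strand
    end: int             # 0-based exclusive, forward strand
    strand: str          # '+' or '-'
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.start}..{self.end} for {self.qseqid}")
        if self.evalue < 0:
            raise ValueError("negative e-value")


def read_hits(path) -> list[TabularHit]:
    """Read a 12-column tabular hit file, tolerating ``#`` comment lines."""
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(path, lineno, f"expected 12 columns, got {len(fields)}")
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                if qstart <= qend:
                    start, end, strand = qstart - 1, qend, "+"
                else:
                    start, end, strand = qend - 1, qstart, "-"
                hits.append(
                    TabularHit(
                        qseqid=fields[0],
                        sseqid=fields[1],
                        pident=float(fields[2]),
                        length=int(fields[3]),
                        mismatch=int(fields[4]),
                        gapopen=int(fields[5]),
                        start=start,
                        end=end,
                        strand=strand,
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return hits


def write_hits(path, hits: Iterable[TabularHit]) -> None:
    """Write hits back to the 1-based inclusive tabular convention."""
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                qstart, qend = h.start + 1, h.end
            else:
                qstart, qend = h.end, h.start + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.qseqid, h.sseqid, f"{h.pident:.1f}", h.length, h.mismatch,
                        h.gapopen, qstart, qend, h.sstart, h.send,
                        f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


def read_two_column_tsv(path, value_type=float) -> dict[str, object]:
    """Read a key\\tvalue TSV (e.g. per-scaffold mean coverage)."""
    out: dict[str, object] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
            try:
                out[fields[0]] = value_type(fields[1])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return out


def read_taxonomy_tsv(path) -> dict[str, list[tuple[str, str]]]:
    """Read per-protein taxonomy labels: scaffold_id, protein_id, taxon."""
    out: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(path, lineno, f"expected 3 columns, got {len(fields)}")
            out.setdefault(fields[0], []).append((fields[1], fields[2]))
    return out


@dataclass(frozen=True)
class TipMetadata:
    """Metadata for one gene-tree tip."""

    tip: str
    kind: str      # 'wasp' or 'virus'
    species: str
    lineage: str   # viral lineage tag; for wasps the species' clade tag or '-'


def read_tip_metadata(path) -> dict[str, TipMetadata]:
    out: dict[str, TipMetadata] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
            tip, kind, species, lineage = fields
            if kind not in ("wasp", "virus"):
                raise ParseError(path, lineno, f"kind must be wasp|virus, got {kind!r}")
            out[tip] = TipMetadata(tip, kind, species, lineage)
    return out


def write_tip_metadata(path, records: Iterable[TipMetadata]) -> None:
    with open(path, "w") as fh:
        fh.write("#tip\tkind\tspecies\tlineage\n")
        for r in records:
            fh.write(f"{r.tip}\t{r.kind}\t{r.species}\t{r.lineage}\n")


def write_tsv(path, header: list[str], rows: Iterable[Iterable[object]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def read_tsv(path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [row for row in reader if row]
    if not rows:
        return [], []
    header = rows[0]
    if header and header[0].startswith("#"):
        header[0] = header[0].lstrip("#")
    return header, rows[1:]


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
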