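"""Readers and writers for the standard formats the pipeline touches.

All downstream modules consume only the domain types defined here:
:class:`SequenceRecord`, :class:`SequenceMetadata` and :class:`SimilarityHit`.
Coordinates are 1-based inclusive throughout (BLAST convention); any half-open
conversion is internal and never serialized.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

#: Baltimore classes: dsDNA (I), ssDNA (II), dsRNA (III), +ssRNA (IV),
#: -ssRNA (V), +ssRNA with DNA intermediate (VI), dsDNA with RNA
#: intermediate (VII).
BALTIMORE_CLASSES = ("I", "II", "III", "IV", "V", "VI", "VII")
MONOPHYLETIC_CLASSES = ("1", "2", "3", "4", "5")
NUCLEIC_ACIDS = ("DNA", "RNA")
UNKNOWN = "unknown"
NA = "NA"

#: The 25 one-letter COG/KOG functional categories (information storage and
#: processing, cellular processes and signaling, metabolism, poorly
#: characterized).
CATEGORY_ALPHABET = frozenset("JAKLBDYVTMNZWUOCGEFHIPQRS")

METADATA_COLUMNS = (
    "seq_id",
    "genome_id",
    "baltimore",
    "monophyletic",
    "nucleic_acid",
    "categories",
)


class FormatError(ValueError):
    """Raised on malformed input files; message names the offending line."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence; ``residues`` may be omitted when only lengths
    matter (e.g. when consuming a precomputed hit table)."""

    seq_id: str
    length: int
    genome_id: str = ""
    residues: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"sequence {self.seq_id!r}: length must be positive")
        if self.residues is not None and len(self.residues) != self.length:
            raise ValueError(
                f"sequence {self.seq_id!r}: length {self.length} != "
                f"{len(self.residues)} residues"
            )


@dataclass(frozen=True)
class SequenceMetadata:
    """Per-sequence classification labels and functional-category letters."""

    seq_id: str
    genome_id: str = ""
    baltimore: str = UNKNOWN
    monophyletic: str = NA
    nucleic_acid: str = UNKNOWN
    categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.baltimore not in BALTIMORE_CLASSES and self.baltimore != UNKNOWN:
            raise ValueError(f"undeclared Baltimore class {self.baltimore!r}")
        if self.monophyletic not in MONOPHYLETIC_CLASSES and self.monophyletic != NA:
            raise ValueError(f"undeclared monophyletic class {self.monophyletic!r}")
        if self.nucleic_acid not in NUCLEIC_ACIDS and self.nucleic_acid != UNKNOWN:
            raise ValueError(f"undeclared nucleic acid type {self.nucleic_acid!r}")
        bad = self.categories - CATEGORY_ALPHABET
        if bad:
            raise ValueError(f"undeclared category letters {sorted(bad)!r}")


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise local-alignment record (an HSP) with its E-value,
    bitscore and 1-based inclusive coordinates on both sequences."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aln_length: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: unordered coordinates"
            )
        if self.aln_length <= 0:
            raise ValueError("alignment length must be positive")

    @property
    def is_self(self) -> bool:
        """Self-hits are parsed but never become network edges."""
        return self.query_id == self.subject_id


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

def read_blast_tab(path: str | Path) -> Iterator[SimilarityHit]:
    """Stream hits from a 12-column BLAST tabular file.

    Columns: qid, sid, pident, length, mismatch, gapopen, qstart, qend,
    sstart, send, evalue, bitscore. Extra trailing columns are tolerated;
    blank lines and ``#`` comment lines are skipped. An empty file yields an
    empty stream.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate whitespace-delimited dialect
                fields = line.split()
            if len(fields) < 12:
                raise FormatError(
                    f"{path}, line {lineno}: expected >=12 columns, got {len(fields)}"
                )
            try:
                hit = SimilarityHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    aln_length=int(fields[3]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
            yield hit


def write_blast_tab(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits in the 12-column tabular layout (pident/mismatch/gapopen
    are not modeled and written as 0)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        0.0,
                        h.aln_length,
                        0,
                        0,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein FASTA; the header token up to the first whitespace is the
    seq_id. Duplicate ids and empty sequences are errors."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate seq_id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(seq_id=rec.id, length=len(seq), residues=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = []
    for r in records:
        if r.residues is None:
            raise ValueError(f"record {r.seq_id!r} has no residues to write")
        bio.append(BioSeqRecord(Seq(r.residues), id=r.seq_id, description=""))
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Metadata TSV
# ---------------------------------------------------------------------------

def read_metadata_table(path: str | Path) -> dict[str, SequenceMetadata]:
    """Read the tab-separated metadata table with header
    ``seq_id genome_id baltimore monophyletic nucleic_acid categories``.

    Empty class fields map to the unknown/NA tokens; any other undeclared
    class value is an error naming the value. Duplicated seq_ids are errors.
    """
    out: dict[str, SequenceMetadata] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != METADATA_COLUMNS:
            raise FormatError(
                f"{path}: expected header {' '.join(METADATA_COLUMNS)!r}, "
                f"got {reader.fieldnames!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            sid = row["seq_id"]
            if sid in out:
                raise FormatError(f"{path}, line {lineno}: duplicate seq_id {sid!r}")
            try:
                out[sid] = SequenceMetadata(
                    seq_id=sid,
                    genome_id=row["genome_id"] or "",
                    baltimore=row["baltimore"] or UNKNOWN,
                    monophyletic=row["monophyletic"] or NA,
                    nucleic_acid=row["nucleic_acid"] or UNKNOWN,
                    categories=frozenset(row["categories"] or ""),
                )
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
    return out


def write_metadata_table(
    metadata: Mapping[str, SequenceMetadata], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(METADATA_COLUMNS) + "\n")
        for m in metadata.values():
            fh.write(
                "\t".join(
                    (
                        m.seq_id,
                        m.genome_id,
                        m.baltimore,
                        m.monophyletic,
                        m.nucleic_acid,
                        "".join(sorted(m.categories)),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Network export (Cytoscape/Gephi-compatible)
# ---------------------------------------------------------------------------

def export_network(
    network,
    node_attributes: Mapping[str, Mapping[str, object]] | None,
    path: str | Path,
    format: str = "edge-list",
) -> None:
    """Export a similarity network as a 3-column edge list
    (id1, id2, evalue) or as GraphML carrying node attributes (class labels,
    composite status, community id, ...) and edge attributes (evalue,
    bitscore)."""
    graph = getattr(network, "graph", network)
    if format == "edge-list":
        with open(path, "w") as fh:
            for u, v, data in graph.edges(data=True):
                fh.write(f"{u}\t{v}\t{data.get('evalue', ''):.6g}\n")
    elif format == "graphml":
        g = nx.Graph()
        for node, data in graph.nodes(data=True):
            attrs = {k: v for k, v in data.items() if _graphml_ok(v)}
            if node_attributes and node in node_attributes:
                attrs.update(
                    {k: v for k, v in node_attributes[node].items() if _graphml_ok(v)}
                )
            g.add_node(node, **attrs)
        for u, v, data in graph.edges(data=True):
            g.add_edge(u, v, **{k: v2 for k, v2 in data.items() if _graphml_ok(v2)})
        nx.write_graphml(g, str(path))
    else:
        raise ValueError(f"unknown export format {format!r}")


def _graphml_ok(value: object) -> bool:
    return isinstance(value, (str, int, float, bool))


def read_edge_list(path: str | Path) -> nx.Graph:
    """Re-import an exported 3-column edge list (adjacency + evalue only)."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}, line {lineno}: expected 3 columns")
            g.add_edge(parts[0], parts[1], evalue=float(parts[2]))
    return g
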