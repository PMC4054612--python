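"""Readers and writers for the external formats the pipeline touches.

FASTQ (optionally gzipped), genome FASTA, feature annotation as GFF3 or
BED6, TSV tables with headers, and network export as SIF / GraphML / TSV.

Coordinate convention: everything in memory is 0-based half-open
``[start, end)``.  GFF3 is 1-based closed on disk and converted at the
boundary; BED6 already matches the internal convention.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import networkx as nx
import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
FEATURE_CLASSES = (
    "miRNA",
    "snoRNA",
    "tRNA_fragment",
    "other_ncRNA",
    "coding_exon",
    "intergenic_label",
)
NCRNA_CLASSES = ("miRNA", "snoRNA", "tRNA_fragment", "other_ncRNA")

#: Mapping from annotation type/name tokens to internal feature classes.
#: GFF3 uses column 3 (type); BED6 uses a ``class:`` prefix on the name or,
#: failing that, the token before the first ``-`` in the name.
CLASS_ALIASES = {
    "mirna": "miRNA",
    "mir": "miRNA",
    "mirna_primary_transcript": "miRNA",
    "snorna": "snoRNA",
    "sno": "snoRNA",
    "trna_fragment": "tRNA_fragment",
    "trf": "tRNA_fragment",
    "trna": "tRNA_fragment",
    "ncrna": "other_ncRNA",
    "other_ncrna": "other_ncRNA",
    "exon": "coding_exon",
    "cds": "coding_exon",
    "coding_exon": "coding_exon",
    "intergenic": "intergenic_label",
}


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records, naming the offending record."""


@dataclass
class ReadRecord:
    """A single sequencing read with SANGER (offset-33) Phred qualities."""

    read_id: str
    sequence: str
    quality: np.ndarray  # int Phred scores, len == len(sequence)

    def __post_init__(self) -> None:
        self.quality = np.asarray(self.quality, dtype=np.int16)
        if len(self.sequence) != len(self.quality):
            raise FastqParseError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def quality_string(self) -> str:
        return "".join(chr(int(q) + PHRED_OFFSET) for q in self.quality)


@dataclass
class FeatureAnnotation:
    """A genomic feature interval (0-based half-open)."""

    feature_id: str
    feature_class: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature {self.feature_id!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature {self.feature_id!r}: unknown class {self.feature_class!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord`s from a (gzipped) 4-line FASTQ file.

    Malformed records abort with a :class:`FastqParseError` naming the
    1-based record index.
    """
    with _open_text(path) as fh:
        index = 0
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                index += 1
                if len(seq) != len(qual):
                    raise FastqParseError(
                        f"record {index} ({title.split()[0]!r}): sequence length "
                        f"{len(seq)} != quality length {len(qual)}"
                    )
                quality = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
                    np.int16
                ) - PHRED_OFFSET
                if quality.size and (quality.min() < 0 or quality.max() > 93):
                    raise FastqParseError(
                        f"record {index}: Phred score outside [0, 93]"
                    )
                yield ReadRecord(title.split()[0], seq.upper(), quality)
        except ValueError as exc:
            if isinstance(exc, FastqParseError):
                raise
            raise FastqParseError(f"record {index + 1}: {exc}") from exc


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write records as 4-line FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality_string()}\n")
            n += 1
    return n


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into ``{chromosome: sequence}`` (uppercase)."""
    genome: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in genome:
                raise ValueError(f"duplicate chromosome name {rec.id!r}")
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"empty sequence for chromosome {rec.id!r}")
            genome[rec.id] = seq
    return genome


def write_genome_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _resolve_class(token: str) -> str:
    key = token.strip().lower()
    if key in CLASS_ALIASES:
        return CLASS_ALIASES[key]
    raise ValueError(f"cannot map annotation type {token!r} to a feature class")


def read_annotation(path: str | Path, dialect: str) -> list[FeatureAnnotation]:
    """Read feature annotation from GFF3 (1-based closed) or BED6.

    The feature class is taken from the GFF3 type column, or from a
    ``class:`` prefix / leading name token for BED6 (see ``CLASS_ALIASES``).
    GFF3 attributes must contain ``ID=``.
    """
    if dialect not in ("gff3", "bed6"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    features: list[FeatureAnnotation] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if dialect == "gff3":
                    if len(cols) < 9:
                        raise ValueError(f"expected 9 GFF3 columns, got {len(cols)}")
                    chrom, _src, ftype, start1, end1, _score, strand, _phase, attrs = cols[:9]
                    start = int(start1) - 1  # 1-based closed -> 0-based half-open
                    end = int(end1)
                    attr_map = dict(
                        kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                    )
                    fid = attr_map.get("ID")
                    if fid is None:
                        raise ValueError("missing ID attribute")
                    fclass = _resolve_class(ftype)
                else:
                    if len(cols) < 6:
                        raise ValueError(f"expected 6 BED columns, got {len(cols)}")
                    chrom, start_s, end_s, name, _score, strand = cols[:6]
                    start, end = int(start_s), int(end_s)
                    if ":" in name:
                        token, fid = name.split(":", 1)
                    else:
                        token, fid = name.split("-", 1)[0], name
                    fclass = _resolve_class(token)
                features.append(
                    FeatureAnnotation(fid, fclass, chrom, start, end, strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return features


def write_annotation_gff3(features: Iterable[FeatureAnnotation], path: str | Path) -> None:
    """Write features as GFF3 (converting back to 1-based closed)."""
    inverse = {
        "miRNA": "miRNA",
        "snoRNA": "snoRNA",
        "tRNA_fragment": "tRNA_fragment",
        "other_ncRNA": "ncRNA",
        "coding_exon": "exon",
        "intergenic_label": "intergenic",
    }
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.chrom}\tsrnakit\t{inverse[f.feature_class]}\t{f.start + 1}\t"
                f"{f.end}\t.\t{f.strand}\t.\tID={f.feature_id}\n"
            )


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def write_network(edges, path: str | Path, fmt: str) -> None:
    """Export network edges as SIF, GraphML or TSV.

    ``edges`` is an iterable of objects with attributes ``mirna``, ``gene``,
    ``support``, ``mirna_direction``, ``gene_direction`` (miRNA->gene
    targeting edges) or 2-tuples ``(geneA, geneB)`` (PPI edges).  SIF uses
    relation ``targets`` for miRNA->gene and ``interacts`` for PPI.  Node
    and edge ordering is lexicographic, so identical input yields
    byte-identical files.
    """
    if fmt not in ("sif", "graphml", "tsv"):
        raise ValueError(f"unknown network format {fmt!r}")
    targeting, ppi = [], []
    for e in edges:
        if isinstance(e, tuple):
            ppi.append(tuple(sorted(e[:2])))
        else:
            targeting.append(e)
    targeting.sort(key=lambda e: (e.mirna, e.gene))
    ppi = sorted(set(ppi))

    if fmt == "sif":
        with _open_text(path, "wt") as fh:
            for e in targeting:
                fh.write(f"{e.mirna}\ttargets\t{e.gene}\n")
            for a, b in ppi:
                fh.write(f"{a}\tinteracts\t{b}\n")
        return

    if fmt == "tsv":
        with _open_text(path, "wt") as fh:
            fh.write("source\trelation\ttarget\tsupport\tsource_direction\ttarget_direction\n")
            for e in targeting:
                fh.write(
                    f"{e.mirna}\ttargets\t{e.gene}\t{e.support}\t"
                    f"{e.mirna_direction}\t{e.gene_direction}\n"
                )
            for a, b in ppi:
                fh.write(f"{a}\tinteracts\t{b}\t\t\t\n")
        return

    g = nx.DiGraph()
    for e in targeting:
        g.add_node(e.mirna, node_type="miRNA", direction=e.mirna_direction)
        g.add_node(e.gene, node_type="gene", direction=e.gene_direction)
        g.add_edge(e.mirna, e.gene, relation="targets", support=int(e.support))
    for a, b in ppi:
        for n in (a, b):
            if n not in g:
                g.add_node(n, node_type="gene", direction="")
        g.add_edge(a, b, relation="interacts", support=0)
    # deterministic node/edge order
    h = nx.DiGraph()
    h.add_nodes_from(sorted(g.nodes(data=True)))
    h.add_edges_from(sorted(g.edges(data=True)))
    data = "\n".join(nx.generate_graphml(h)) + "\n"
    with _open_text(path, "wt") as fh:
        fh.write(data)
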