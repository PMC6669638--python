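"""Circular-genome container, sequence I/O, and annotation serialization.

Baculovirus genomes are covalently closed circles, so every coordinate-
bearing operation in this package has to survive an arbitrary choice of
sequence origin.  Internally all coordinates are 0-based half-open on the
forward strand; a feature that crosses the origin is encoded with
``end > len(genome)`` and interpreted modulo the genome length.  Serialized
output (GFF3, TSV) uses 1-based inclusive coordinates, the GenBank/GFF3
convention, with origin-spanning features split into two location lines
that share an ``ID`` attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TYPE_CHECKING

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .annotate import OrfRecord

logger = logging.getLogger(__name__)

_DNA_ALPHABET = frozenset("ACGTN")

__all__ = [
    "CircularGenome",
    "GenomeStats",
    "read_sequence",
    "rotate",
    "reverse_complement",
    "compute_stats",
    "write_annotations",
    "read_annotations",
]


@dataclass(frozen=True)
class CircularGenome:
    """A named DNA sequence with explicit topology.

    Parameters
    ----------
    id : str
        Sequence identifier (e.g. a GenBank accession).
    sequence : str
        Uppercase DNA over ``{A, C, G, T, N}``.
    topology : {"circular", "linear"}
        Whether coordinate arithmetic wraps at the origin.
    """

    id: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology: {self.topology!r}")
        seq = self.sequence.upper()
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"non-DNA characters in sequence {self.id!r}: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, end: int) -> str:
        """Subsequence on the forward strand; wraps the origin when circular.

        ``start`` must lie in ``[0, len)``; ``end >= start`` and may exceed
        the genome length (interpreted mod length) on circular genomes.
        """
        n = len(self.sequence)
        if not 0 <= start < n:
            raise IndexError(f"start {start} outside [0, {n})")
        if end < start:
            raise IndexError("end < start")
        if end <= n:
            return self.sequence[start:end]
        if not self.is_circular:
            raise IndexError("coordinates beyond the end of a linear genome")
        if end - start > n:
            raise IndexError("requested span exceeds genome length")
        return self.sequence[start:] + self.sequence[: end - n]


@dataclass(frozen=True)
class GenomeStats:
    """Basic composition statistics.

    ``gc_percent`` is (#G + #C) / (length − #N) × 100: ambiguous bases do
    not dilute the composition of the known ones.
    """

    length_bp: int
    gc_percent: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if not 0.0 <= self.gc_percent <= 100.0:
            raise ValueError("gc_percent outside [0, 100]")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_sequence(
    path: str | Path, format: str = "fasta", topology: str | None = None
) -> CircularGenome:
    """Read the first record of a FASTA or GenBank file as a genome.

    For GenBank input the topology comes from the LOCUS line; for FASTA it
    defaults to circular unless ``topology`` says otherwise.  Multi-record
    files trigger a logged warning and only the first record is used.
    """
    path = Path(path)
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format: {format!r}")
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise ValueError(f"no records found in {path}")
    if len(records) > 1:
        logger.warning(
            "%s contains %d records; using the first (%s)",
            path, len(records), records[0].id,
        )
    rec = records[0]
    if format == "genbank":
        topo = rec.annotations.get("topology", "linear")
    else:
        topo = topology or "circular"
    return CircularGenome(id=rec.id, sequence=str(rec.seq), topology=topo)


def rotate(genome: CircularGenome, offset: int) -> CircularGenome:
    """Cyclically shift the origin of a circular genome by ``offset``."""
    if not genome.is_circular:
        raise ValueError("cannot rotate a linear genome")
    n = len(genome)
    if not 0 <= offset < n:
        raise ValueError(f"offset {offset} outside [0, {n})")
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    return CircularGenome(id=genome.id, sequence=seq, topology="circular")


def compute_stats(genome: CircularGenome) -> GenomeStats:
    seq = genome.sequence
    n_n = seq.count("N")
    denom = len(seq) - n_n
    if denom == 0:
        gc = 0.0
    else:
        gc = (seq.count("G") + seq.count("C")) / denom * 100.0
    return GenomeStats(length_bp=len(seq), gc_percent=gc)


def _gff3_lines(orf: "OrfRecord", genome_id: str, genome_length: int) -> list[str]:
    attrs = f"ID={orf.id};n_codons={orf.n_codons};category={orf.category}"
    base = [genome_id, "bacuchar", "ORF"]
    if orf.end <= genome_length:
        return [
            "\t".join(base + [str(orf.start + 1), str(orf.end), ".", orf.strand,
                              ".", attrs])
        ]
    # origin-spanning: split at the origin, shared ID
    return [
        "\t".join(base + [str(orf.start + 1), str(genome_length), ".",
                          orf.strand, ".", attrs]),
        "\t".join(base + ["1", str(orf.end - genome_length), ".",
                          orf.strand, ".", attrs]),
    ]


def write_annotations(
    orfs: Iterable["OrfRecord"],
    path: str | Path,
    genome: CircularGenome,
    format: str = "gff3",
) -> None:
    """Serialize ORF records as GFF3 or TSV (1-based inclusive coordinates)."""
    path = Path(path)
    n = len(genome)
    orfs = list(orfs)
    for orf in orfs:
        if not (0 <= orf.start < n) or orf.end - orf.start > n:
            raise ValueError(f"ORF {orf.id} coordinates out of range for {genome.id}")
    if format == "gff3":
        lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {n}"]
        for orf in orfs:
            lines.extend(_gff3_lines(orf, genome.id, n))
    elif format == "tsv":
        lines = ["id\tstart\tend\tstrand\tn_codons\tcategory"]
        for orf in orfs:
            lines.append(
                f"{orf.id}\t{orf.start + 1}\t{orf.end}\t{orf.strand}"
                f"\t{orf.n_codons}\t{orf.category}"
            )
    else:
        raise ValueError(f"unsupported annotation format: {format!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_annotations(path: str | Path, genome_length: int) -> list["OrfRecord"]:
    """Read back a GFF3 file written by :func:`write_annotations`.

    Split (origin-spanning) features sharing an ID are re-joined into a
    single record with ``end > genome_length``.
    """
    from .annotate import OrfRecord

    pieces: dict[str, list[tuple[int, int, str, int, str]]] = {}
    order: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        start1, end1, strand = int(cols[3]), int(cols[4]), cols[6]
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
        fid = attrs["ID"]
        if fid not in pieces:
            order.append(fid)
        pieces.setdefault(fid, []).append(
            (start1 - 1, end1, strand, int(attrs.get("n_codons", 0)),
             attrs.get("category", "candidate"))
        )
    out = []
    for fid in order:
        parts = pieces[fid]
        if len(parts) == 1:
            s, e, strand, nc, cat = parts[0]
        elif len(parts) == 2:
            # origin-spanning: one part ends at genome_length, the other starts at 0
            (s, e_hi, strand, nc, cat), (s_lo, e_lo, *_rest) = sorted(
                parts, key=lambda p: p[0], reverse=True
            )
            if e_hi != genome_length or s_lo != 0:
                raise ValueError(f"inconsistent split feature {fid}")
            s, e = s, genome_length + e_lo
        else:
            raise ValueError(f"feature {fid} split into {len(parts)} parts")
        out.append(OrfRecord(id=fid, start=s, end=e, strand=strand,
                             n_codons=nc, category=cat))
    return out
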