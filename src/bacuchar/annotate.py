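"""ORF identification and annotation on circular genomes.

The annotation rules follow standard practice for baculovirus genome
reports: every ORF of at least ``min_codons`` sense codons (ATG to the
first in-frame stop) in all six reading frames is a candidate; candidates
with recognizable homologs in labelled reference proteomes are always
annotated, while anonymous candidates are kept only if they do not overlap
a larger ORF by ``max_overlap_bp`` or more *and* carry support from both
external gene-prediction programs (supplied as boolean evidence, not
recomputed here).  Promoter motifs — an initiator CAKT and a TATA box
TATAWAW by default — are scanned within a window upstream of each start
codon on the coding strand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .genome import CircularGenome, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "IUPAC_DNA",
    "MotifSpec",
    "AnnotationConfig",
    "OrfRecord",
    "VariantRecord",
    "find_orfs",
    "filter_candidate_orfs",
    "assign_homology",
    "scan_promoter_motifs",
    "filter_variant_frequencies",
    "iupac_regex",
]

#: IUPAC nucleotide ambiguity codes -> the set of bases each matches.
IUPAC_DNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_STOPS = ("TAA", "TAG", "TGA")


def iupac_regex(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC degenerate DNA string to a regex."""
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC_DNA:
            raise ValueError(f"invalid IUPAC nucleotide code: {ch!r}")
        bases = IUPAC_DNA[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


@dataclass(frozen=True)
class MotifSpec:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        iupac_regex(self.pattern)  # validates


def _default_motifs() -> list[MotifSpec]:
    return [MotifSpec("initiator", "CAKT"), MotifSpec("tata_box", "TATAWAW")]


@dataclass
class AnnotationConfig:
    """Thresholds for ORF calling, filtering and promoter scanning."""

    min_codons: int = 50
    max_overlap_bp: int = 75
    promoter_window_bp: int = 250
    motif_set: list[MotifSpec] = field(default_factory=_default_motifs)
    homology_min_identity: float = 0.25
    homology_min_coverage: float = 0.5
    start_codons: tuple[str, ...] = ("ATG",)

    def __post_init__(self) -> None:
        if min(self.min_codons, self.max_overlap_bp, self.promoter_window_bp) <= 0:
            raise ValueError("thresholds must be positive")
        for frac in (self.homology_min_identity, self.homology_min_coverage):
            if not 0.0 < frac <= 1.0:
                raise ValueError("identity/coverage thresholds must be in (0, 1]")


@dataclass(frozen=True)
class OrfRecord:
    """A candidate or annotated ORF.

    Coordinates are 0-based half-open on the forward strand and include the
    stop codon, so ``end - start == 3 * (n_codons + 1)``.  ``end`` may
    exceed the genome length for origin-spanning ORFs on circular genomes.
    """

    id: str
    start: int
    end: int
    strand: str
    n_codons: int
    category: str = "candidate"
    best_hit: tuple[str, float, float] | None = None  # (ref id, identity, coverage)
    predictor_support: tuple[bool, bool] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VariantRecord:
    """A putative sub-consensus variant with its read frequency."""

    position: int  # 1-based
    ref: str
    alt: str
    frequency: float

    def __post_init__(self) -> None:
        if not 0.0 < self.frequency < 1.0:
            raise ValueError("variant frequency must be in (0, 1)")


def _scan_strand(seq: str, n: int, circular: bool, starts: tuple[str, ...]
                 ) -> list[tuple[int, int]]:
    """All maximal ORFs (per stop/frame, longest start) on one strand.

    Returns (start, end) 0-based half-open on the scanned sequence, with
    end possibly > n when the ORF crosses the origin.  The scan runs on the
    doubled sequence for circular input and deduplicates by start mod n.
    """
    s = seq + seq if circular else seq
    limit = len(s)
    # collapse nested ORFs to the longest per circular stop codon:
    # key = stop position mod n (the stop codon is unique on the circle)
    orfs: dict[int, tuple[int, int]] = {}
    for frame in range(3):
        pending: int | None = None  # leftmost open start in this frame
        i = frame
        while i + 3 <= limit:
            codon = s[i:i + 3]
            if pending is None and i < n and codon in starts:
                pending = i
            elif pending is not None and codon in _STOPS:
                start, end = pending, i + 3
                if end - start <= n:  # cannot wrap the whole circle
                    key = end % n if circular else end
                    prev = orfs.get(key)
                    if prev is None or end - start > prev[1] - prev[0]:
                        orfs[key] = (start, end)
                pending = None
                # re-scan after the stop for the next start
            i += 3
        # ORFs with no stop before the scan limit are dropped: on a linear
        # molecule they are not complete ORFs, on a circular one they would
        # wrap more than once.
    out = []
    for start, end in orfs.values():
        if circular:
            start_m = start % n
            out.append((start_m, start_m + (end - start)))
        else:
            out.append((start, end))
    return sorted(set(out))


def find_orfs(genome: CircularGenome, config: AnnotationConfig | None = None
              ) -> list[OrfRecord]:
    """Scan all six reading frames for ORFs of >= ``min_codons`` sense codons.

    Nested same-strand ORFs sharing a stop codon are collapsed to the
    longest.  Origin-spanning ORFs on circular genomes are reported with
    ``end > len(genome)``.  Output is sorted by forward-strand start.
    """
    config = config or AnnotationConfig()
    n = len(genome)
    min_len = 3 * (config.min_codons + 1)
    records: list[OrfRecord] = []
    fwd = _scan_strand(genome.sequence, n, genome.is_circular, config.start_codons)
    for start, end in fwd:
        if end - start >= min_len:
            records.append(OrfRecord(id="", start=start, end=end, strand="+",
                                     n_codons=(end - start) // 3 - 1))
    rc = reverse_complement(genome.sequence)
    for s, e in _scan_strand(rc, n, genome.is_circular, config.start_codons):
        if e - s < min_len:
            continue
        # map reverse-complement coordinates back to the forward strand
        f_start = (n - e) % n
        records.append(OrfRecord(id="", start=f_start, end=f_start + (e - s),
                                 strand="-", n_codons=(e - s) // 3 - 1))
    records.sort(key=lambda o: (o.start, o.end, o.strand))
    return [replace(o, id=f"orf{i + 1:03d}") for i, o in enumerate(records)]


def _circular_overlap(a: OrfRecord, b: OrfRecord, n: int) -> int:
    """Nucleotide overlap of two (possibly origin-spanning) intervals mod n."""
    def segments(o: OrfRecord) -> list[tuple[int, int]]:
        if o.end <= n:
            return [(o.start, o.end)]
        return [(o.start, n), (0, o.end - n)]

    total = 0
    for sa, ea in segments(a):
        for sb, eb in segments(b):
            total += max(0, min(ea, eb) - max(sa, sb))
    return total


def filter_candidate_orfs(orfs: Sequence[OrfRecord],
                          config: AnnotationConfig | None = None,
                          genome_length: int | None = None) -> list[OrfRecord]:
    """Apply the annotation retention rule.

    ORFs with a homology hit are always retained.  An anonymous ORF is
    retained only if (a) its overlap with every larger ORF is strictly less
    than ``max_overlap_bp`` and (b) both gene-predictor support flags are
    true.  "Larger" means longer; between equal-length ORFs the one with a
    homology hit counts as larger (ties broken toward evidence).  Overlap
    is computed on circular coordinates irrespective of strand.
    """
    config = config or AnnotationConfig()
    if genome_length is None:
        genome_length = max(o.end for o in orfs) if orfs else 0
    n = genome_length

    def larger_than(b: OrfRecord, a: OrfRecord) -> bool:
        if len(b) != len(a):
            return len(b) > len(a)
        return b.best_hit is not None and a.best_hit is None

    kept = []
    for orf in orfs:
        if orf.best_hit is not None:
            kept.append(orf)
            continue
        support = orf.predictor_support
        if support is None:
            logger.warning("ORF %s lacks predictor evidence; treated as "
                           "unsupported", orf.id)
            continue
        if not (support[0] and support[1]):
            continue
        clash = any(
            larger_than(other, orf)
            and _circular_overlap(orf, other, n) >= config.max_overlap_bp
            for other in orfs
            if other is not orf
        )
        if not clash:
            kept.append(orf)
    return kept


_CATEGORY_RANK = {"core": 0, "alpha_conserved": 1, "shared": 2}


def translate_orf(genome: CircularGenome, orf: OrfRecord) -> str:
    """Translate an ORF (standard code); the stop codon is not included."""
    nt = genome.fetch(orf.start, orf.end)
    if orf.strand == "-":
        nt = reverse_complement(nt)
    aa = str(Seq(nt).translate(table=1))
    if not aa.endswith("*"):
        raise ValueError(f"ORF {orf.id} does not end in a stop codon")
    body = aa[:-1]
    if "*" in body:
        raise ValueError(f"internal stop codon in ORF {orf.id}")
    return body


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def assign_homology(
    genome: CircularGenome,
    orfs: Sequence[OrfRecord],
    reference_proteomes: Mapping[str, Mapping[str, str]],
    config: AnnotationConfig | None = None,
    prescreen_k: int = 4,
) -> list[OrfRecord]:
    """Label ORFs by similarity to labelled reference proteomes.

    ``reference_proteomes`` maps a category label (``core``,
    ``alpha_conserved``, ``shared``) to ``{protein_id: sequence}``.  Each
    translated ORF is globally aligned (k-mer prescreened) against the
    references; the best hit above the identity/coverage thresholds sets
    ``best_hit`` and ``category``, with ties between categories resolved
    core > alpha_conserved > shared.  ORFs without a qualifying hit are
    labelled ``unique``.
    """
    from .comparative import global_align  # local import to avoid a cycle

    config = config or AnnotationConfig()
    if not any(reference_proteomes.values()):
        raise ValueError("reference proteomes are empty")
    refs = []
    for label, proteins in reference_proteomes.items():
        for pid, pseq in proteins.items():
            refs.append((label, pid, pseq, _kmer_set(pseq, prescreen_k)))

    out = []
    for orf in orfs:
        aa = translate_orf(genome, orf)
        kmers = _kmer_set(aa, prescreen_k)
        best: tuple[float, int, str, str, float] | None = None
        for label, pid, pseq, ref_kmers in refs:
            if not (kmers & ref_kmers):
                continue
            aln = global_align(aa, pseq, alphabet="protein")
            cov = aln.n_aligned_columns / len(pseq)
            if (aln.identity >= config.homology_min_identity
                    and cov >= config.homology_min_coverage):
                key = (aln.identity, -_CATEGORY_RANK.get(label, 3))
                if best is None or key > (best[0], -best[1]):
                    best = (aln.identity, _CATEGORY_RANK.get(label, 3),
                            label, pid, cov)
        if best is None:
            out.append(replace(orf, category="unique", best_hit=None))
        else:
            identity, _rank, label, pid, cov = best
            out.append(replace(orf, category=label,
                               best_hit=(pid, identity, cov)))
    return out


def scan_promoter_motifs(
    genome: CircularGenome,
    orf: OrfRecord,
    config: AnnotationConfig | None = None,
) -> list[tuple[str, int]]:
    """Scan the upstream promoter window of an ORF for IUPAC motifs.

    The window is the ``promoter_window_bp`` positions immediately 5' of
    the start codon on the ORF's coding strand; it crosses the origin on a
    circular genome and is clipped (with a warning) on a linear one.
    Matches are reported as ``(motif name, offset)`` with the offset the
    coding-strand position of the match start relative to the A of ATG
    (always negative).
    """
    config = config or AnnotationConfig()
    n = len(genome)
    window = config.promoter_window_bp
    if window >= n:
        logger.warning("promoter window %d clipped to genome length %d",
                       window, n - 1)
        window = n - 1
    if orf.strand == "+":
        if genome.is_circular:
            lo = (orf.start - window) % n
            up = genome.fetch(lo, lo + window)
        else:
            lo = max(0, orf.start - window)
            if lo == 0 and orf.start < window:
                logger.warning("promoter window clipped at the start of a "
                               "linear genome")
            up = genome.sequence[lo:orf.start]
    else:
        # coding-strand upstream lies at forward coordinates [end, end+window)
        anchor = orf.end % n if genome.is_circular else orf.end
        if genome.is_circular:
            up = reverse_complement(genome.fetch(anchor, anchor + window))
        else:
            hi = min(n, anchor + window)
            if hi - anchor < window:
                logger.warning("promoter window clipped at the end of a "
                               "linear genome")
            up = reverse_complement(genome.sequence[anchor:hi])
    w = len(up)
    hits = []
    for motif in config.motif_set:
        rx = iupac_regex(motif.pattern)
        for m in rx.finditer(up):
            hits.append((motif.name, m.start() - w))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def filter_variant_frequencies(
    variants: Iterable[VariantRecord], min_freq: float = 0.05
) -> tuple[int, int]:
    """Count variants, and variants at frequency strictly above ``min_freq``."""
    total = above = 0
    for v in variants:
        total += 1
        if v.frequency > min_freq:
            above += 1
    return total, above
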