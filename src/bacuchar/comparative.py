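"""Pairwise comparison: global alignment, K2P distances, species
demarcation, gene parity maps, and diagnostic alignment columns.

The Kimura two-parameter (K2P) model separates substitutions into
transitions (A<->G, C<->T, proportion P) and transversions (proportion Q)
and estimates the expected number of substitutions per site as

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

K2P distances at the lef-8, lef-9 and polh loci are the standard metric
for baculovirus species demarcation: pairs below ~0.015 substitutions/site
at all loci are conspecific, pairs above ~0.072 at all loci are distinct
species, and anything between is inconclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "PairwiseAlignment",
    "K2PResult",
    "SaturatedDistanceError",
    "SpeciesDecision",
    "ParityPoint",
    "SignatureColumn",
    "global_align",
    "k2p_distance",
    "species_demarcation",
    "parity_map",
    "signature_columns",
]


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment as two equal-length gapped strings."""

    seq_a: str
    seq_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("gapped sequences differ in length")

    @property
    def n_aligned_columns(self) -> int:
        return sum(a != "-" and b != "-"
                   for a, b in zip(self.seq_a, self.seq_b))

    @property
    def identity(self) -> float:
        """Fraction of identical residues over aligned (non-gap) columns."""
        aligned = matches = 0
        for a, b in zip(self.seq_a, self.seq_b):
            if a != "-" and b != "-":
                aligned += 1
                matches += a == b
        return matches / aligned if aligned else 0.0


_DNA_CHARS = set("ACGTNRYSWKMBDHV")


def _looks_like_dna(seq: str) -> bool:
    return bool(seq) and set(seq.upper()) <= _DNA_CHARS


def global_align(
    a: str,
    b: str,
    alphabet: str | None = None,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -2.0,
) -> PairwiseAlignment:
    """Optimal Needleman–Wunsch global alignment with affine gaps.

    ``alphabet`` is "dna" or "protein"; when omitted it is inferred, and a
    mismatch between the two sequences' alphabets is an error.  Protein
    alignments use BLOSUM62 with gap open -11 / extend -1; DNA alignments
    use the simple match/mismatch/gap scores given.  Ties between
    co-optimal alignments are broken deterministically (first alignment in
    the aligner's canonical order).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    a, b = a.upper(), b.upper()
    if alphabet is None:
        a_dna, b_dna = _looks_like_dna(a), _looks_like_dna(b)
        if a_dna != b_dna:
            raise ValueError("sequences appear to use different alphabets")
        alphabet = "dna" if a_dna else "protein"
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        # tolerate residues outside the matrix alphabet (X, *, ...)
        aligner.wildcard = "X"
    elif alphabet == "dna":
        aligner.match_score = match
        aligner.mismatch_score = mismatch
        aligner.open_gap_score = gap_open
        aligner.extend_gap_score = gap_extend
        aligner.wildcard = "N"
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(seq_a=str(aln[0]), seq_b=str(aln[1]),
                             score=float(aln.score))


class SaturatedDistanceError(ValueError):
    """The K2P log arguments are non-positive: the distance is undefined."""


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class K2PResult:
    """Transition/transversion proportions and the K2P distance."""

    P: float
    Q: float
    L: int
    d: float


def k2p_distance(a_gapped: str, b_gapped: str) -> K2PResult:
    """Kimura two-parameter distance between two aligned DNA sequences.

    Sites where either sequence carries a gap or a non-ACGT symbol are
    excluded (pairwise deletion).  Raises :class:`SaturatedDistanceError`
    when the observed divergence exceeds the model's admissible region.
    """
    if len(a_gapped) != len(b_gapped):
        raise ValueError("aligned sequences differ in length")
    ts = tv = L = 0
    for x, y in zip(a_gapped.upper(), b_gapped.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        L += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if L == 0:
        raise ValueError("no pairwise-complete sites")
    P, Q = ts / L, tv / L
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedDistanceError(
            f"K2P distance saturated (P={P:.4f}, Q={Q:.4f})"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P=P, Q=Q, L=L, d=d)


@dataclass(frozen=True)
class SpeciesDecision:
    """Per-locus K2P distances and the demarcation verdict.

    ``distances`` maps locus name to a :class:`K2PResult` or the string
    ``"saturated"`` (treated as exceeding the distinct-species threshold).
    """

    distances: Mapping[str, K2PResult | str]
    threshold_same: float = 0.015
    threshold_diff: float = 0.072
    verdict: str = field(init=False, default="")

    def __post_init__(self) -> None:
        usable = [v for v in self.distances.values()]
        if not usable:
            raise ValueError("no usable locus distances")
        if all(isinstance(v, K2PResult) and v.d < self.threshold_same
               for v in usable):
            verdict = "same_species"
        elif all(v == "saturated" or
                 (isinstance(v, K2PResult) and v.d > self.threshold_diff)
                 for v in usable):
            verdict = "different_species"
        else:
            verdict = "inconclusive"
        object.__setattr__(self, "verdict", verdict)


def species_demarcation(
    distances: Mapping[str, K2PResult | str],
    threshold_same: float = 0.015,
    threshold_diff: float = 0.072,
) -> SpeciesDecision:
    """Apply the K2P species-demarcation rule to per-locus distances."""
    return SpeciesDecision(distances=dict(distances),
                           threshold_same=threshold_same,
                           threshold_diff=threshold_diff)


@dataclass(frozen=True)
class ParityPoint:
    """Ordinal positions of one homolog pair; 0 marks an absent partner."""

    orf_index_a: int
    orf_index_b: int
    label_a: str = ""
    label_b: str = ""

    @property
    def shared(self) -> bool:
        return self.orf_index_a > 0 and self.orf_index_b > 0


def parity_map(
    orfs_a: Sequence[str],
    orfs_b: Sequence[str],
    homology: Mapping[str, str] | None = None,
) -> list[ParityPoint]:
    """Gene parity points from two position-ordered ORF label lists.

    ``homology`` maps labels in genome A to their homolog's label in
    genome B; ``None`` means labels are directly comparable (identity
    mapping).  Both lists must be ordered by genomic position from a
    shared anchor (conventionally polyhedrin as ORF 1).  ORFs present in
    only one genome get index 0 on the other axis, which puts them on the
    axis line of a parity plot.
    """
    for name, labels in (("A", orfs_a), ("B", orfs_b)):
        dupes = {x for x in labels if list(labels).count(x) > 1}
        if dupes:
            raise ValueError(
                f"duplicate ORF labels in genome {name}: {sorted(dupes)}; "
                "disambiguate paralogs explicitly"
            )
    if homology is None:
        mapping = {x: x for x in orfs_a}
    else:
        mapping = dict(homology)
    index_b = {label: i + 1 for i, label in enumerate(orfs_b)}
    points = []
    matched_b: set[str] = set()
    for i, label in enumerate(orfs_a, start=1):
        partner = mapping.get(label)
        if partner is not None and partner in index_b:
            points.append(ParityPoint(i, index_b[partner], label, partner))
            matched_b.add(partner)
        else:
            points.append(ParityPoint(i, 0, label, ""))
    for j, label in enumerate(orfs_b, start=1):
        if label not in matched_b:
            points.append(ParityPoint(0, j, "", label))
    return points


@dataclass(frozen=True)
class SignatureColumn:
    """An alignment column diagnostic for the in-group phenotype."""

    alignment_column: int  # 1-based
    reference_residue_number: int | None  # reference ungapped position, 1-based
    in_group_residue: str
    out_group_residues: tuple[str, ...]
    n_out_group_differing: int


def signature_columns(
    alignment: Mapping[str, str],
    group_labels: Mapping[str, str],
    in_group: str,
    min_out_differing: int,
    reference: str,
) -> list[SignatureColumn]:
    """Columns where the in-group residue is invariant and differs in at
    least ``min_out_differing`` out-group sequences.

    ``alignment`` maps sequence id to its gapped row; ``group_labels``
    assigns every id a phenotype label, and rows labelled ``in_group``
    form the in-group.  Residue numbers are reported in the ungapped
    coordinates of the ``reference`` sequence (1-based); columns gapped in
    the reference get ``None``.
    """
    ids = list(alignment)
    missing = [i for i in ids if i not in group_labels]
    if missing:
        raise ValueError(f"sequences without a group label: {missing}")
    in_ids = [i for i in ids if group_labels[i] == in_group]
    out_ids = [i for i in ids if group_labels[i] != in_group]
    if len(in_ids) < 2 or len(out_ids) < 2:
        raise ValueError("need at least two sequences per group")
    if reference not in alignment:
        raise ValueError(f"reference {reference!r} not in alignment")
    ncol = {len(row) for row in alignment.values()}
    if len(ncol) != 1:
        raise ValueError("alignment rows differ in length")
    ref_row = alignment[reference]
    out = []
    ref_pos = 0
    for col in range(ncol.pop()):
        ref_char = ref_row[col]
        if ref_char != "-":
            ref_pos += 1
        in_res = {alignment[i][col] for i in in_ids}
        if len(in_res) != 1:
            continue
        residue = in_res.pop()
        if residue == "-":
            continue
        out_res = tuple(alignment[i][col] for i in out_ids)
        differing = sum(r != residue for r in out_res)
        if differing >= min_out_differing:
            out.append(SignatureColumn(
                alignment_column=col + 1,
                reference_residue_number=ref_pos if ref_char != "-" else None,
                in_group_residue=residue,
                out_group_residues=out_res,
                n_out_group_differing=differing,
            ))
    return out
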