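"""Direct-repeat discovery, motif counting, and hr-region detection.

Baculovirus genomes typically carry *hr* (homologous repeat) regions:
clusters of conserved direct repeats and/or palindromes dispersed around
the circle that act as replication origins and transcriptional enhancers.
This module finds tandem direct-repeat arrays, builds IUPAC degenerate
consensus units for them, counts complete/partial copies of a given motif,
and decides whether repeat units recur at dispersed loci with an embedded
imperfect palindrome — the operational definition of an hr used here.  An
empty result from :func:`detect_hr_regions` is a meaningful output: the
certified absence of hr-like structure under the stated parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotate import IUPAC_DNA, iupac_regex
from .genome import CircularGenome, reverse_complement

__all__ = [
    "MotifCount",
    "RepeatRegion",
    "HrRegion",
    "count_motif_occurrences",
    "find_direct_repeats",
    "detect_hr_regions",
    "search_repeat_in_genomes",
]

# base-set -> IUPAC code, inverse of annotate.IUPAC_DNA
_SET_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_DNA.items()}


@dataclass(frozen=True)
class MotifCount:
    motif: str
    complete_hits: int
    complete_positions: tuple[int, ...]
    partial_hits: int
    partial_positions: tuple[int, ...]
    min_partial_fraction: float = 0.5


@dataclass(frozen=True)
class RepeatRegion:
    """A tandem array of direct repeats.

    ``unit_consensus`` is the majority-rule consensus over the complete
    copies, with IUPAC degenerate codes at positions where bases tie or
    where the minority fraction exceeds the mismatch tolerance.
    """

    start: int
    end: int
    unit_consensus: str
    unit_len: int
    complete_copies: int
    partial_copies: int
    copy_identities: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.complete_copies < 2:
            raise ValueError("a repeat region needs >= 2 complete copies")
        if len(self.unit_consensus) != self.unit_len:
            raise ValueError("consensus length != unit_len")
        if self.end - self.start < self.complete_copies * self.unit_len:
            raise ValueError("region shorter than its complete copies")


@dataclass(frozen=True)
class HrRegion:
    loci: tuple[tuple[int, int], ...]
    shared_consensus: str
    palindrome_arm_len: int

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def _iupac_match(base: str, code: str) -> bool:
    return base in IUPAC_DNA.get(code, "")


def count_motif_occurrences(
    genome: CircularGenome, motif: str, min_partial_fraction: float = 0.5
) -> MotifCount:
    """Count non-overlapping complete and flanking partial motif copies.

    Complete hits are leftmost-greedy non-overlapping IUPAC matches on the
    forward strand.  A partial hit is a prefix or suffix of the motif, of
    length at least ``min_partial_fraction`` times the motif length, lying
    immediately adjacent to a complete hit (the way truncated terminal
    copies flank a tandem array).  On circular genomes an array split by
    the origin is re-joined before counting.
    """
    if len(motif) < 8:
        raise ValueError("motif must be at least 8 nt")
    rx = iupac_regex(motif)
    seq = genome.sequence
    n = len(seq)
    m = len(motif)
    circular = genome.is_circular

    def circ(i: int, j: int) -> str | None:
        """Substring at circular positions [i, j); None if out of range."""
        if circular:
            if j - i > n:
                return None
            d = seq + seq
            return d[i % n: i % n + (j - i)]
        if i < 0 or j > n:
            return None
        return seq[i:j]

    scan = seq + seq[: min(n, 2 * m)] if circular else seq
    comp: list[int] = []
    covered: set[int] = set()
    pos = 0
    while True:
        match = rx.search(scan, pos)
        if match is None or match.start() >= n:
            break
        st = match.start()
        span = {x % n for x in range(st, st + m)}
        if span & covered:  # wrap duplicate at the origin junction
            pos = st + 1
            continue
        comp.append(st)
        covered |= span
        pos = match.end()

    min_len = int(np.ceil(min_partial_fraction * m))
    partial: list[int] = []

    def matches(region: str, template: str) -> bool:
        return all(_iupac_match(b, c) for b, c in zip(region, template))

    for p in comp:
        # motif suffix ending right where a complete copy begins
        for k in range(m - 1, min_len - 1, -1):
            region = circ(p - k, p)
            if region is None:
                continue
            if matches(region, motif[-k:]):
                span = {x % n for x in range(p - k, p)}
                if not span & covered:
                    partial.append((p - k) % n)
                    covered |= span
                break
        # motif prefix starting right after a complete copy ends
        e = p + m
        for k in range(m - 1, min_len - 1, -1):
            region = circ(e, e + k)
            if region is None:
                continue
            if matches(region, motif[:k]):
                span = {x % n for x in range(e, e + k)}
                if not span & covered:
                    partial.append(e % n)
                    covered |= span
                break
    return MotifCount(
        motif=motif,
        complete_hits=len(comp),
        complete_positions=tuple(sorted(comp)),
        partial_hits=len(partial),
        partial_positions=tuple(sorted(set(partial))),
        min_partial_fraction=min_partial_fraction,
    )


def _consensus(copies: Sequence[str], max_mismatch_frac: float) -> str:
    """Majority-rule consensus with IUPAC codes at ambiguous columns."""
    unit_len = len(copies[0])
    cols = []
    for j in range(unit_len):
        bases = [c[j] for c in copies if c[j] in "ACGT"]
        if not bases:
            cols.append("N")
            continue
        counts: dict[str, int] = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        top = max(counts.values())
        majority = {b for b, c in counts.items() if c == top}
        # minority bases beyond the mismatch tolerance join the code
        keep = set(majority)
        for b, c in counts.items():
            if b not in majority and c / len(bases) > max_mismatch_frac:
                keep.add(b)
        cols.append(_SET_TO_IUPAC[frozenset(keep)])
    return "".join(cols)


def _match_runs(mism: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Runs of consecutive matches (False in ``mism``) of length >= min_run."""
    match = ~mism
    if not match.any():
        return []
    padded = np.concatenate(([False], match, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    keep = (ends - starts) >= min_run
    return list(zip(starts[keep].tolist(), ends[keep].tolist()))


def _grow_segment(cs: np.ndarray, a: int, b: int, n: int, max_frac: float,
                  window: int = 10, max_window_mm: int = 5
                  ) -> tuple[int, int]:
    """Extend a clean seed run [a, b) while every trailing ``window`` of
    positions keeps at most ``max_window_mm`` mismatches; endpoints settle
    on match positions.  ``cs`` is the prefix-sum of the mismatch track."""

    def mm(i: int, j: int) -> int:
        return int(cs[j] - cs[i])

    end = b
    j = b
    while j < n:
        w0 = max(a, j + 1 - window)
        if mm(w0, j + 1) > max_window_mm:
            break
        # endpoints settle on matches whose trailing 5 positions are clean
        if mm(j, j + 1) == 0 and mm(max(a, j + 1 - 5), j + 1) <= 1:
            end = j + 1
        j += 1
    start = a
    i = a - 1
    while i >= 0:
        w1 = min(end, i + window)
        if mm(i, w1) > max_window_mm:
            break
        if mm(i, i + 1) == 0 and mm(i, min(end, i + 5)) <= 1:
            start = i
        i -= 1
    # global mismatch budget: shrink the dirtier end until satisfied
    while end - start > 0 and mm(start, end) > max_frac * (end - start):
        head = mm(start, min(end, start + 5))
        tail = mm(max(start, end - 5), end)
        if head >= tail:
            start += 1
            while start < end and mm(start, start + 1):
                start += 1
        else:
            end -= 1
            while end > start and mm(end - 1, end):
                end -= 1
    return start, end


def find_direct_repeats(
    genome: CircularGenome,
    min_unit: int = 15,
    max_unit: int = 80,
    min_copies: int = 2,
    max_mismatch_frac: float = 0.12,
    min_partial_fraction: float = 0.5,
    detect_mismatch_frac: float = 0.3,
) -> list[RepeatRegion]:
    """Detect tandem direct-repeat arrays.

    For every candidate period ``p`` the sequence is compared against
    itself shifted by ``p``; stretches where the shifted self-match holds
    (adjacent-copy mismatch fraction <= ``detect_mismatch_frac``) mark
    tandem arrays of period ``p``, with a short bounded extension across
    copy-boundary mutations.  Overlapping calls at harmonic periods are
    reduced to the period spanning the longest region.  The consensus unit
    is majority-rule over complete copies; columns where bases tie, or
    where a minority base exceeds ``max_mismatch_frac`` of copies, get
    IUPAC degenerate codes.  A terminal remnant of at least
    ``min_partial_fraction`` of the unit counts as a partial copy.
    """
    seq = genome.sequence
    n = len(seq)
    if n < 2 * min_unit:
        raise ValueError("genome shorter than two repeat units")
    # work on an extended sequence so arrays crossing the origin are seen
    ext = seq + seq[: min(n, 2 * max_unit)] if genome.is_circular else seq
    arr = np.frombuffer(ext.encode(), dtype=np.uint8)
    min_seed = 6
    candidates: list[tuple[int, int, int]] = []  # (start, end, period)
    for p in range(min_unit, min(max_unit, n - 1) + 1):
        mism = arr[:-p] != arr[p:]
        cs = np.concatenate(([0], np.cumsum(mism, dtype=np.int64)))
        m = len(mism)
        claimed_to = -1
        for a, b in _match_runs(mism, min_seed):
            if a <= claimed_to:
                continue
            i, j = _grow_segment(cs, a, b, m, detect_mismatch_frac)
            claimed_to = j
            start, end = i, j + p  # region includes the final copy
            if start >= n:
                continue
            if end - start >= p * min_copies - 2:  # boundary-loss tolerance
                candidates.append((start, end, p))
    if not candidates:
        return []
    # cluster overlapping candidates; within a cluster keep the longest
    # span, preferring the smaller (primitive) period when spans are close
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[2], c[0]))
    chosen: list[tuple[int, int, int]] = []
    for start, end, p in candidates:
        merged = False
        for idx, (s2, e2, p2) in enumerate(chosen):
            ov = min(end, e2) - max(start, s2)
            if ov > 0 and ov >= 0.5 * min(end - start, e2 - s2):
                if (end - start) >= (e2 - s2) - 6 and p < p2:
                    chosen[idx] = (start, end, p)
                merged = True
                break
        if not merged:
            chosen.append((start, end, p))
    regions = []
    for start, end, p in chosen:
        total = end - start
        # tolerate +-2 bp of boundary loss from mutated terminal positions
        c_round = int(round(total / p))
        if abs(total - c_round * p) <= 2 and c_round >= 2:
            n_complete, partial = c_round, 0
            end = start + n_complete * p
        else:
            n_complete = total // p
            remainder = total - n_complete * p
            partial = 1 if remainder >= min_partial_fraction * p else 0
            if partial == 0:
                end = start + n_complete * p
        if n_complete < min_copies:
            continue
        copies = [ext[start + k * p: start + (k + 1) * p]
                  for k in range(n_complete)]
        consensus = _consensus(copies, max_mismatch_frac)
        idents = tuple(
            sum(_iupac_match(b, c) for b, c in zip(copy, consensus)) / p
            for copy in copies
        )
        regions.append(RepeatRegion(
            start=start, end=end, unit_consensus=consensus, unit_len=p,
            complete_copies=n_complete, partial_copies=partial,
            copy_identities=idents,
        ))
    regions.sort(key=lambda r: r.start)
    return regions


def _has_imperfect_palindrome(unit: str, arm: int, max_mismatch: int,
                              max_spacer: int = 10) -> bool:
    """True if the unit contains an inverted repeat with arms >= ``arm``
    and at most ``max_mismatch`` mismatches between the arms."""
    m = len(unit)
    for i in range(m - 2 * arm + 1):
        left = unit[i:i + arm]
        for sp in range(0, max_spacer + 1):
            j = i + arm + sp
            if j + arm > m:
                break
            right = reverse_complement(unit[j:j + arm])
            mism = sum(a != b or a not in "ACGT"
                       for a, b in zip(left, right))
            if mism <= max_mismatch:
                return True
    return False


def _dispersed_units(genome: CircularGenome, min_unit: int,
                     min_separation: int, k: int = 16) -> list[str]:
    """Candidate repeat units found at >= 2 loci >= ``min_separation`` apart,
    by exact k-mer anchoring and ungapped extension."""
    seq = genome.sequence
    n = len(seq)
    anchors: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        anchors.setdefault(seq[i:i + k], []).append(i)
    units = []
    seen_spans: set[tuple[int, int]] = set()
    for kmer, positions in anchors.items():
        if len(positions) < 2:
            continue
        far = [(a, b) for ai, a in enumerate(positions)
               for b in positions[ai + 1:] if b - a >= min_separation]
        for a, b in far:
            # extend the exact match outwards
            lo = 0
            while a - lo - 1 >= 0 and b - lo - 1 >= 0 and \
                    seq[a - lo - 1] == seq[b - lo - 1]:
                lo += 1
            hi = k
            while a + hi < n and b + hi < n and seq[a + hi] == seq[b + hi]:
                hi += 1
            if lo + hi >= min_unit:
                span = (a - lo, a + hi)
                if span not in seen_spans:
                    seen_spans.add(span)
                    units.append(seq[a - lo:a + hi])
    return units


def detect_hr_regions(
    genome: CircularGenome,
    min_loci: int = 2,
    min_unit: int = 30,
    palindrome_arm: int = 6,
    max_arm_mismatch: int = 1,
    min_separation: int = 2000,
    min_locus_identity: float = 0.8,
) -> list[HrRegion]:
    """Find hr-like regions: a repeat unit recurring at dispersed loci that
    contains an imperfect palindrome.

    Candidate units come from tandem arrays (:func:`find_direct_repeats`)
    and from a dispersed exact-anchor search.  A unit qualifies as hr-like
    only if it occurs at >= ``min_loci`` loci separated by at least
    ``min_separation`` bp and embeds an inverted repeat with arms of
    ``palindrome_arm`` nt and at most ``max_arm_mismatch`` mismatches.
    An empty list certifies the absence of hr-like structure at these
    parameters.
    """
    units: list[str] = []
    try:
        for region in find_direct_repeats(genome, min_unit=min_unit):
            units.append(region.unit_consensus)
    except ValueError:
        pass
    units.extend(_dispersed_units(genome, min_unit, min_separation))
    out: list[HrRegion] = []
    claimed: list[tuple[int, int]] = []

    def is_claimed(s: int, e: int) -> bool:
        return any(min(e, ce) - max(s, cs) > 0.5 * (e - s)
                   for cs, ce in claimed)

    for unit in sorted(set(units), key=lambda u: (-len(u), u)):
        if not _has_imperfect_palindrome(unit, palindrome_arm,
                                         max_arm_mismatch):
            continue
        hits = search_repeat_in_genomes(unit, [genome],
                                        min_identity=min_locus_identity)
        loci = []
        for hit in hits[genome.id]:
            if not hit.present:
                continue
            s = hit.position
            if any(abs(s - t) < min_separation for t in
                   (l[0] for l in loci)):
                continue
            loci.append((s, s + len(unit)))
        loci = [l for l in loci if not is_claimed(*l)]
        if len(loci) >= min_loci:
            claimed.extend(loci)
            out.append(HrRegion(
                loci=tuple(sorted(loci)),
                shared_consensus=unit,
                palindrome_arm_len=palindrome_arm,
            ))
    out.sort(key=lambda h: h.loci[0][0])
    return out


@dataclass(frozen=True)
class RepeatHit:
    position: int
    strand: str
    identity: float
    present: bool


def _iupac_identity_profile(window_len: int, seq: str, motif: str
                            ) -> np.ndarray:
    """Identity of the motif against every window of ``seq`` (ungapped)."""
    n = len(seq)
    m = len(motif)
    if n < m:
        return np.zeros(0)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    scores = np.zeros(n - m + 1)
    for j, code in enumerate(motif):
        allowed = np.frombuffer(IUPAC_DNA[code].encode(), dtype=np.uint8)
        scores += np.isin(arr[j:j + n - m + 1], allowed)
    return scores / m


def search_repeat_in_genomes(
    motif: str,
    genomes: Sequence[CircularGenome],
    min_identity: float = 0.8,
) -> dict[str, list[RepeatHit]]:
    """Best ungapped matches of a repeat motif in each genome, both strands.

    Returns, per genome, all non-overlapping hits at identity >=
    ``min_identity``; when none qualify, the single best sub-threshold hit
    is returned with ``present=False`` so absence is still quantified.
    """
    if len(motif) < 15:
        raise ValueError("repeat motif must be at least 15 nt")
    results: dict[str, list[RepeatHit]] = {}
    m = len(motif)
    for genome in genomes:
        seq = genome.sequence
        if genome.is_circular:
            seq = seq + genome.sequence[: m - 1]
        best: list[RepeatHit] = []
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            prof = _iupac_identity_profile(m, s, motif)
            if prof.size == 0:
                continue
            order = np.argsort(prof)[::-1]
            taken: list[int] = []
            for idx in order:
                if prof[idx] < min_identity:
                    break
                if any(abs(int(idx) - t) < m for t in taken):
                    continue
                taken.append(int(idx))
                pos = int(idx)
                if strand == "-":
                    pos = len(s) - pos - m
                best.append(RepeatHit(position=pos % len(genome),
                                      strand=strand,
                                      identity=float(prof[idx]),
                                      present=True))
        if not best:
            # report the best sub-threshold match as evidence of absence
            top = None
            for strand, s in (("+", seq), ("-", reverse_complement(seq))):
                prof = _iupac_identity_profile(m, s, motif)
                if prof.size == 0:
                    continue
                idx = int(np.argmax(prof))
                pos = idx if strand == "+" else len(s) - idx - m
                cand = RepeatHit(position=pos % len(genome), strand=strand,
                                 identity=float(prof[idx]), present=False)
                if top is None or cand.identity > top.identity:
                    top = cand
            best = [top] if top is not None else []
        results[genome.id] = sorted(best, key=lambda h: (-h.identity,
                                                         h.position))
    return results
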