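"""Seeded synthetic-data generators with known ground truth.

Every pipeline stage can be exercised without downloads: circular genomes
with planted ORFs, promoter motifs, tandem repeats and hr-like loci at
known coordinates; aligned sequence pairs with controlled transition/
transversion divergence; binomial dose-mortality tables from a probit
model; and death times from a known survival distribution observed on a
12-hour check grid.  The generator defaults mirror the study conditions
this package models: a ~37.3% GC circular alphabaculovirus genome, a
five-dose design of 1e4-1e8 OBs/mL with 30 larvae per dose, and an 8-day
(192 h) observation window with twice-daily checks.

Identical seed + specification gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bioassay import DoseResponseData
from .genome import CircularGenome, reverse_complement

__all__ = [
    "PlantedOrf",
    "PlantedRepeat",
    "PlantedHr",
    "PlantedMotif",
    "GenomeManifest",
    "GenomeTruth",
    "DivergencePairSpec",
    "AssayTruth",
    "gen_genome",
    "gen_divergent_pair",
    "gen_bioassay",
    "gen_survival",
    "chinnpv_like_manifest",
    "random_background",
    "REPEAT_UNIT_22",
    "REPEAT_UNIT_25A",
    "REPEAT_UNIT_25G",
    "REPEAT_UNIT_33",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

# printed repeat units of the characterized genome, reused as the default
# planted truths for the repeat detectors
REPEAT_UNIT_22 = "TGTATTAGCTTTAATCTATTAT"
REPEAT_UNIT_25A = "AAAAAATATTATAAACATTTCAAAG"   # variant with A at pos 6
REPEAT_UNIT_25G = "AAAAAGTATTATAAACATTTCAAAG"   # variant with G at pos 6
REPEAT_UNIT_33 = "TACAGTTAACAAAAAACCCAATCACCATTAGAA"


@dataclass(frozen=True)
class PlantedOrf:
    start: int
    strand: str
    n_codons: int
    source_protein: str | None = None  # amino acid sequence to encode
    target_identity: float = 1.0

    @property
    def span(self) -> int:
        return 3 * (self.n_codons + 1)


@dataclass(frozen=True)
class PlantedRepeat:
    position: int
    unit: str
    copies: int
    mutations_per_copy: tuple[int, ...] = ()
    explicit_copies: tuple[str, ...] = ()  # verbatim copies, overrides unit
    partial_len: int = 0  # truncated leading/trailing copy, 0 = none
    partial_side: str = "after"  # "before" or "after"

    @property
    def span(self) -> int:
        return len(self.unit) * self.copies + self.partial_len


@dataclass(frozen=True)
class PlantedHr:
    unit: str  # must contain a palindrome to be hr-like
    loci: tuple[int, ...]


@dataclass(frozen=True)
class PlantedMotif:
    motif: str  # literal sequence planted (IUPAC already resolved)
    orf_index: int
    offset: int  # negative, relative to the ORF start codon


@dataclass(frozen=True)
class GenomeManifest:
    """Complete recipe for a synthetic circular genome."""

    seed: int
    length: int = 20_000
    gc_target: float = 0.3728
    orfs: tuple[PlantedOrf, ...] = ()
    repeats: tuple[PlantedRepeat, ...] = ()
    hrs: tuple[PlantedHr, ...] = ()
    motifs: tuple[PlantedMotif, ...] = ()
    id: str = "synthetic"


@dataclass(frozen=True)
class GenomeTruth:
    """Ground-truth coordinates of everything planted in a genome."""

    orfs: tuple[PlantedOrf, ...]
    repeats: tuple[PlantedRepeat, ...]
    hrs: tuple[PlantedHr, ...]
    motifs: tuple[tuple[str, int, int], ...]  # (motif, orf_index, offset)


def random_background(rng: np.random.Generator, length: int,
                      gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    """n sense codons (no stops) drawn from the background composition."""
    out = []
    while len(out) < n:
        codon = random_background(rng, 3, gc).tobytes().decode()
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


_CODON_BY_AA: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODON_BY_AA:
        from Bio.Data.CodonTable import standard_dna_table
        for codon, aa in standard_dna_table.forward_table.items():
            _CODON_BY_AA.setdefault(aa, []).append(codon)
    return _CODON_BY_AA


def _encode_protein(rng: np.random.Generator, protein: str,
                    identity: float) -> str:
    """Reverse-translate, substituting residues to hit ~``identity``."""
    table = _codon_table()
    aas = list(table)
    seq = []
    for aa in protein:
        res = aa
        if rng.random() > identity:
            choices = [x for x in aas if x != aa]
            res = choices[rng.integers(len(choices))]
        codons = table[res]
        seq.append(codons[rng.integers(len(codons))])
    return "".join(seq)


def _orf_sequence(rng: np.random.Generator, orf: PlantedOrf,
                  gc: float) -> str:
    if orf.source_protein is not None:
        if len(orf.source_protein) != orf.n_codons:
            raise ValueError("source protein length != n_codons")
        coding = _encode_protein(rng, orf.source_protein,
                                 orf.target_identity)
        coding = "ATG" + coding[3:]  # the first residue is always Met
    else:
        coding = "ATG" + _random_codons(rng, orf.n_codons - 1, gc)
    return coding + "TAA"


def _repeat_sequence(rng: np.random.Generator, rep: PlantedRepeat) -> str:
    unit = rep.unit.upper()
    p = len(unit)
    if rep.explicit_copies:
        if len(rep.explicit_copies) != rep.copies or any(
                len(c) != p for c in rep.explicit_copies):
            raise ValueError("explicit copies must match copies and unit "
                             "length")
        copies = [c.upper() for c in rep.explicit_copies]
    else:
        muts = rep.mutations_per_copy or (0,) * rep.copies
        if len(muts) != rep.copies:
            raise ValueError("mutations_per_copy length != copies")
        copies = []
        for k in range(rep.copies):
            copy = list(unit)
            sites = (rng.choice(p, size=muts[k], replace=False)
                     if muts[k] else [])
            for s in sites:
                alt = [b for b in "ACGT" if b != copy[s]]
                copy[s] = alt[rng.integers(3)]
            copies.append("".join(copy))
    body = "".join(copies)
    if rep.partial_len:
        if rep.partial_side == "after":
            body = body + unit[: rep.partial_len]
        else:
            body = unit[-rep.partial_len:] + body
    return body


def gen_genome(manifest: GenomeManifest
               ) -> tuple[CircularGenome, GenomeTruth]:
    """Build a synthetic circular genome from its manifest.

    Background sequence is i.i.d. at ``gc_target``; planted features are
    spliced in at their stated coordinates.  Overlapping planted features
    are an error.  The same manifest (same seed) is byte-identical across
    runs.
    """
    rng = np.random.default_rng(manifest.seed)
    n = manifest.length
    seq = random_background(rng, n, manifest.gc_target)

    spans: list[tuple[int, int, str]] = []

    def claim(start: int, length: int, what: str) -> None:
        end = start + length
        if end > n:
            raise ValueError(f"{what} runs past the genome end")
        for s, e, w in spans:
            if start < e and s < end:
                raise ValueError(f"planted {what} overlaps planted {w}")
        spans.append((start, end, what))

    def splice(start: int, payload: str) -> None:
        seq[start:start + len(payload)] = np.frombuffer(
            payload.encode(), dtype=np.uint8)

    orf_payloads: list[tuple[PlantedOrf, str]] = []
    for orf in manifest.orfs:
        payload = _orf_sequence(rng, orf, manifest.gc_target)
        claim(orf.start, len(payload), f"ORF@{orf.start}")
        if orf.strand == "-":
            payload = reverse_complement(payload)
        orf_payloads.append((orf, payload))
    for rep in manifest.repeats:
        payload = _repeat_sequence(rng, rep)
        claim(rep.position, len(payload), f"repeat@{rep.position}")
        splice(rep.position, payload)
    for hr in manifest.hrs:
        for locus in hr.loci:
            claim(locus, len(hr.unit), f"hr@{locus}")
            splice(locus, hr.unit.upper())
    motif_truth = []
    for pm in manifest.motifs:
        orf = manifest.orfs[pm.orf_index]
        if pm.offset >= 0:
            raise ValueError("promoter motif offsets must be negative")
        if orf.strand == "+":
            start = orf.start + pm.offset
            payload = pm.motif
        else:
            start = orf.start + orf.span - pm.offset - len(pm.motif)
            payload = reverse_complement(pm.motif)
        start %= n
        claim(start, len(pm.motif), f"motif@{start}")
        splice(start, payload)
        motif_truth.append((pm.motif, pm.orf_index, pm.offset))
    # splice ORFs last and sterilize their frames is not needed: ORFs are
    # placed on fresh background, and chance ORFs are the caller's problem
    for orf, payload in orf_payloads:
        splice(orf.start, payload)

    genome = CircularGenome(id=manifest.id, sequence=seq.tobytes().decode(),
                            topology="circular")
    truth = GenomeTruth(orfs=manifest.orfs, repeats=manifest.repeats,
                        hrs=manifest.hrs, motifs=tuple(motif_truth))
    return genome, truth


def chinnpv_like_manifest(seed: int, length: int = 20_000) -> GenomeManifest:
    """A genome emulating the characterized isolate's repeat landscape:
    three tandem direct-repeat regions (one partial + five complete copies
    of a 22-mer; four copies of a 25-mer consensus mixing A/G at one site;
    two perfect copies of a 33-mer) and no hr-like dispersed palindromic
    repeats."""
    third = length // 4
    rep22 = PlantedRepeat(position=third, unit=REPEAT_UNIT_22, copies=5,
                          partial_len=14, partial_side="after")
    # two copies carry A and two carry G at the degenerate site -> R
    rep25 = PlantedRepeat(position=2 * third, unit=REPEAT_UNIT_25A, copies=4,
                          explicit_copies=(REPEAT_UNIT_25A, REPEAT_UNIT_25G,
                                           REPEAT_UNIT_25A, REPEAT_UNIT_25G))
    rep33 = PlantedRepeat(position=3 * third, unit=REPEAT_UNIT_33, copies=2)
    return GenomeManifest(seed=seed, length=length, gc_target=0.3728,
                          repeats=(rep22, rep25, rep33),
                          id="ChinNPV-like-synthetic")


@dataclass(frozen=True)
class DivergencePairSpec:
    """Controlled transition/transversion divergence between two sequences."""

    seed: int
    length: int = 10_000
    p_target: float = 0.0  # per-site transition probability
    q_target: float = 0.0  # per-site transversion probability
    gc: float = 0.5

    def __post_init__(self) -> None:
        if self.length < 100:
            raise ValueError("pair length must be >= 100")
        if self.p_target + self.q_target >= 0.75:
            raise ValueError("P + Q must be < 0.75")


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def gen_divergent_pair(spec: DivergencePairSpec
                       ) -> tuple[str, str, float, float]:
    """An aligned pair with per-site transition probability ``p_target``
    and transversion probability ``q_target``.

    Returns (seq_a, seq_b, realized_P, realized_Q) where the realized
    proportions are the observed difference counts over the length.
    """
    rng = np.random.default_rng(spec.seed)
    anc = random_background(rng, spec.length, spec.gc).tobytes().decode()
    u = rng.random(spec.length)
    pick = rng.random(spec.length)
    out = []
    n_ts = n_tv = 0
    for i, base in enumerate(anc):
        if u[i] < spec.p_target:
            out.append(_TRANSITION[base])
            n_ts += 1
        elif u[i] < spec.p_target + spec.q_target:
            tv = _TRANSVERSIONS[base]
            out.append(tv[0] if pick[i] < 0.5 else tv[1])
            n_tv += 1
        else:
            out.append(base)
    return anc, "".join(out), n_ts / spec.length, n_tv / spec.length


@dataclass(frozen=True)
class AssayTruth:
    """True dose-mortality and time-mortality parameters for simulation."""

    seed: int
    lc50: float = 1.71e5
    slope: float = 1.8
    doses: tuple[float, ...] = (1e4, 1e5, 1e6, 1e7, 1e8)
    n_per_dose: int = 30
    median_h: float = 166.9
    log_sd: float = 0.2
    check_interval_h: float = 12.0
    window_h: float = 192.0

    def __post_init__(self) -> None:
        if self.lc50 <= 0 or self.slope <= 0 or self.median_h <= 0:
            raise ValueError("lc50, slope and median must be positive")


def gen_bioassay(truth: AssayTruth, label: str = "") -> DoseResponseData:
    """Binomial dose-mortality data under the probit model of ``truth``."""
    rng = np.random.default_rng(truth.seed)
    alpha = -truth.slope * np.log10(truth.lc50)
    x = np.log10(np.asarray(truth.doses))
    p = stats.norm.cdf(alpha + truth.slope * x)
    dead = tuple(int(rng.binomial(truth.n_per_dose, pi)) for pi in p)
    return DoseResponseData(dose=truth.doses,
                            n=(truth.n_per_dose,) * len(truth.doses),
                            dead=dead, label=label)


def gen_survival(truth: AssayTruth, n: int = 30
                 ) -> tuple[list[float], int]:
    """Death times on the 12-h check grid, survivors excluded.

    Times are drawn log-normal with the given median and log-scale sd,
    rounded up to the next check (the grid is anchored at 12 h post
    infection), and truncated at the observation window: subjects dying
    beyond ``window_h`` are excluded survivors.  Returns
    (death_times, n_excluded_survivors).
    """
    rng = np.random.default_rng(truth.seed)
    raw = rng.lognormal(mean=np.log(truth.median_h), sigma=truth.log_sd,
                        size=n)
    step = truth.check_interval_h
    checked = np.ceil(raw / step) * step
    checked = np.maximum(checked, step)
    deaths = [float(t) for t in checked if t <= truth.window_h]
    return deaths, int(n - len(deaths))
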