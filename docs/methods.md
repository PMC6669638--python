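# Methods

This note documents the models, rules and numerical choices behind
`bacuchar`, in the order a genome characterization proceeds: ORF
annotation, repeat and hr discovery, comparative analyses, and bioassay
statistics, followed by the synthetic-data generators that every test and
the acceptance script run on.

## Circular coordinates

All coordinates are 0-based half-open on the forward strand internally;
serialized output (GFF3, TSV, BED) is 1-based inclusive. A feature that
crosses the sequence origin of a circular genome is encoded with
`end > length` and interpreted modulo the length; in GFF3 it is written as
two location lines sharing an `ID`. GC content is computed as
(#G + #C) / (length − #N) × 100, so ambiguous bases do not dilute the
composition of the known ones.

## ORF annotation

An ORF runs from an ATG to the first in-frame stop (TAA/TAG/TGA), stop
codon included in its coordinates; `n_codons` counts sense codons only, so
a retained ORF satisfies `end − start = 3(n_codons + 1)` and the default
threshold of ≥ 50 codons means ≥ 50 sense codons excluding the stop.
Whether published ≥ 50-codon conventions include the stop is ambiguous;
this package's choice is the conventional one and the boundary is covered
by tests. Only ATG initiation is considered (the start-codon set is
configurable). All six frames are scanned on the doubled sequence for
circular genomes and deduplicated modulo the length; nested same-strand
ORFs sharing a stop codon are collapsed to the longest, keyed by the stop
position on the circle. ORFs longer than the genome (no stop in a full
revolution) are not reported.

Retention mirrors standard baculovirus annotation practice: an ORF with a
homology hit is always kept; an anonymous ORF is kept only if (a) its
overlap with every larger ORF — computed on circular coordinates,
irrespective of strand — is strictly below 75 bp, and (b) both external
gene-predictor flags are true. Those flags are *inputs* (an optional
evidence table); the external predictors themselves are not re-implemented,
and an ORF with missing flags is treated as unsupported. Between two
equal-length overlapping ORFs, the one carrying a homology hit counts as
the larger (ties break toward evidence).

Homology assignment replaces an external BLASTx round trip with a built-in
search: each translated ORF is compared against user-supplied labelled
proteomes by global alignment (BLOSUM62, gap open −11 / extend −1) after a
shared 4-mer prescreen. A hit requires identity ≥ 0.25 over coverage
(aligned columns / reference length) ≥ 0.5, both configurable; categories
rank core > alpha-conserved > shared, else unique. This is deterministic
and dependency-free, but it is a similarity search, not BLASTx: its
thresholds are not E-values, and annotations of real genomes will differ
from database-driven ones.

Promoter scanning examines the `promoter_window_bp` (default 250)
positions 5′ of the start codon on the coding strand for IUPAC patterns —
by default the early initiator CAKT and TATA box TATAWAW. Offsets are
reported negative, relative to the A of ATG; windows wrap the origin on
circular genomes and clip (with a warning) on linear ones.

## Repeat discovery

Tandem arrays are found by exhaustive shifted self-comparison: for every
candidate period p (15–80 by default) the sequence is compared with itself
shifted by p, and stretches where adjacent copies agree mark arrays. This
is strictly more sensitive than exact k-mer seeding for short, mutated
units and is still fast (numpy, O(L × p-range)). A segment grows from a
clean seed run (≥ 6 consecutive matches) while every trailing window of 10
positions holds ≤ 5 mismatches; endpoints settle on match positions whose
terminal 5 positions contain ≤ 1 mismatch, and the whole segment must keep
its mismatch fraction ≤ 0.3 (`detect_mismatch_frac`). Copy number
tolerates ±2 bp of boundary loss from mutated terminal positions (counts
are rounded when the span is within 2 bp of a whole number of units); a
terminal remnant of ≥ 50% of the unit is a partial copy. Overlapping calls
at harmonic periods collapse to the longest span, preferring the smaller
(primitive) period when spans are within 6 bp. The consensus is
majority-rule across complete copies; columns where bases tie, or where a
minority base exceeds `max_mismatch_frac` (default 0.12) of copies, are
written as IUPAC degenerate codes — four copies with a single A→G
disagreement therefore show an R, matching how degenerate repeat consensi
are reported. The detector trades some specificity for this sensitivity:
two-copy arrays of short units near the 30% divergence ceiling can arise
by chance in background sequence (a handful per 20 kb), which is why
downstream checks key on planted/expected coordinates rather than on the
total number of calls.

Motif counting is leftmost-greedy and non-overlapping on the forward
strand, with IUPAC-aware matching; a flanking partial copy is a motif
prefix or suffix of ≥ 50% of the motif length immediately adjacent to a
complete hit. Arrays split by the origin are re-joined before counting.

hr (homologous repeat) regions are operationalized as *dispersed +
palindromic*, following the standard description of baculovirus hrs as
conserved direct repeats and/or palindromes dispersed through the genome:
a candidate unit (from tandem arrays or from an exact-anchor dispersed
search with ungapped extension) qualifies only if it occurs at ≥ 2 loci
separated by ≥ 2 kb (at ≥ 80% identity) and contains an inverted repeat
with arms ≥ 6 nt, ≤ 1 mismatch, spacer ≤ 10 nt. No quantitative hr
definition is universal; every threshold is exposed in the function
signature, and an empty result is the certified-absence verdict at those
parameters.

## Comparative analyses

Pairwise global alignment uses the exact Needleman–Wunsch/Gotoh machinery
of Biopython's `PairwiseAligner` (affine gaps; DNA defaults match +1,
mismatch −1, gap −2). Co-optimal alignments are resolved deterministically
by taking the aligner's first alignment; the optimal *score* is unique, and
identity is reported over aligned non-gap columns.

The Kimura two-parameter distance separates transitions (A↔G, C↔T;
proportion P) and transversions (Q) over pairwise-complete sites (columns
with a gap or non-ACGT symbol in either sequence are dropped — pairwise
deletion, including ambiguity codes):

    d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)   [substitutions/site]

When 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 the distance is *saturated* and a
dedicated error is raised rather than substituting infinity. Species
demarcation applies the standard baculovirus K2P rule at lef-8, lef-9 and
polh: all loci < 0.015 → same species; all loci > 0.072 (saturated loci
count as exceeding) → different species; anything else inconclusive. Both
thresholds are configurable, since they come from the demarcation
method's published scheme rather than from any single study's text.
Distances here assume nucleotide (not codon-aware) alignments, which is
also what the package's aligned-FASTA inputs are expected to be.

Gene parity maps take two ORF label lists ordered from a shared anchor
(conventionally polyhedrin as ORF 1) and an optional homology mapping;
unpaired ORFs get ordinal 0 on the partner axis so they land on the axis
line of a parity plot. Duplicate labels are an error listing the
offenders, since paralogs must be disambiguated explicitly.

Signature-column analysis scans a labelled protein MSA for columns where
the in-group residue is invariant and ≥ `min_out_differing` out-group
sequences differ; residue numbers are reported in the ungapped coordinates
of a named reference row. This is how morphology-correlated residues
(e.g. polyhedrin positions in tetrahedral-occlusion-body viruses) are
identified; note that with `min_out_differing` equal to the full out-group
size, a single out-group sequence identical to the in-group removes the
column — the imperfect-correlate case.

## Bioassay statistics

Dose–mortality data are fitted by maximum-likelihood probit regression on
x = log10(dose): p(x) = C + (1 − C)Φ(α + βx), with natural response C
fixed at 0 by default (an Abbott-style C is available but off, as no
control-mortality correction is part of the modelled design). The fit is
Fisher-scoring (Newton with expected information) with step-halving, to a
relative tolerance of 1e-10; it agrees with a probit GLM to numerical
precision, which a test verifies as an independent route. Complete
separation (all-or-nothing mortality at every dose) and quasi-separation
(a single informative dose driving the slope to infinity) have no finite
MLE and raise an explicit error; Monte-Carlo summaries are therefore
computed over the fits that exist, with the count reported. Grossly
non-monotone data fit with a warning.

LC50 = 10^(−α/β). Its 95% fiducial limits come from Fieller's theorem on
the ratio −α/β in log10-dose space, back-transformed through 10^x, with
g = t²·var(β)/β²; g ≥ 1 is reported as an unbounded interval, never
truncated. Heterogeneity follows the classic Finney/PoloPlus convention:
h = Pearson χ²/(k − 2), and when χ² exceeds its 5% critical value the
covariance is inflated by h and the normal quantile is replaced by a
t on k − 2 degrees of freedom. The exact internal algorithms of
commercial probit software are unpublished; this implementation is
standard ML probit + Fieller with heterogeneity inflation, documented as
such.

Parallelism (common slope, free intercepts) and equality (one line) are
likelihood-ratio tests against the free model, with df = k − 1 and
2(k − 1); the constrained models are fitted exactly as probit GLMs with
group dummies. Letter groups come from pairwise equality tests at
p < 0.05, assigned greedily in descending-LC50 order (compact letter
display); the greedy rule is stated because published tables rarely
specify theirs.

Median lethal times use death times of responders only ("survivors
excluded"). With no censoring the Kaplan–Meier curve equals the empirical
survival function; LT50 is the first observed time with S(t) ≤ 0.5 (so
for deaths {1,2,3,4} h the estimate is 2), and the 95% CI inverts the
log-log Greenwood band at 0.5 — the Brookmeyer–Crowley construction, as
implemented in lifelines. Group comparisons use the log-rank test
(lifelines), with letters from pairwise tests ranked by median death time.

## Synthetic data: what it emulates, and what it does not

The generators produce every input with known truth, at the modelled
study's design sizes: a circular genome at 37.28% GC; planted ORFs
(optionally reverse-translated from a source protein at a target
identity), tandem repeats with per-copy mutation counts or explicit copy
sequences, hr-like dispersed palindromic units, and promoter motifs at
stated offsets; sequence pairs with per-site transition/transversion
probabilities; binomial dose–mortality tables over five log-spaced doses
(1e4–1e8 OBs/mL, 30 larvae/dose); and log-normal death times observed on
a 12-h check grid anchored at t = 12 h, truncated at 192 h (8 days) with
later deaths becoming excluded survivors. The default assay truths are
the published point estimates (LC50 1.71e5 OBs/mL, slope 1.8, LT50s
166.9/91.3/77.6 h), used purely as *simulation truths*: the underlying
raw mortality counts were never published, so the printed LC50/LT50
values themselves are **not reproducible** from available information and
the package does not attempt to reproduce them. The log-scale SD of the
death-time distribution defaults to 0.2, chosen so the distribution
spreads over several 12-h checks as real monitoring data do.

Background sequence is i.i.d., which real genomes are not: it contains no
codon structure, no gene-length distribution, no compositional skew.
Passing tests on planted genomes therefore demonstrate the correctness of
the coordinate arithmetic, detectors and statistics — not that a real
genome's annotation would match a database-driven published one (that
also depends on external evidence this package deliberately takes as
input). The 12-h rounding and 192-h truncation bias the simulated LT50
slightly relative to the continuous truth (up by discretization, down by
tail truncation); tests budget for both.

## Problem sizes and reproducibility

Simulation studies use 100 random-genome ORF-oracle comparisons (1–6 kb),
200 planted-repeat manifests (5 kb), divergent pairs of L = 10,000, 200
probit replicates for coverage and power, 500–1000 replicates for the
null calibration of the equality test, and 200 replicates per survival
scenario — sizes at which every Monte-Carlo check is stable across
seeds while the whole suite stays desk-scale. All randomness flows from
explicit integer seeds; `scripts/acceptance.py` derives independent
sub-streams from its `--seed` so different seeds give genuinely
independent replicates.

## Known limitations

- The homology search is a similarity screen, not BLASTx; category calls
  on real genomes depend on the supplied reference proteomes.
- The repeat detector favours sensitivity for short mutated units; expect
  occasional two-copy background calls near the divergence ceiling.
- Quasi-separated dose–mortality datasets (common at steep slopes with
  few intermediate doses) have no finite probit MLE and are reported as
  errors rather than numbers.
- hr detection is an operational definition; published hr annotations
  rest on curated homology, not only on dispersal + palindromicity.
- MSA construction is out of scope: K2P and signature analyses consume
  alignments produced elsewhere.
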