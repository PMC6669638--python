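import numpy as np
import pytest

from bacuchar import (
    AnnotationConfig,
    CircularGenome,
    OrfRecord,
    VariantRecord,
    assign_homology,
    filter_candidate_orfs,
    filter_variant_frequencies,
    find_orfs,
    rotate,
    scan_promoter_motifs,
)
from bacuchar.genome import reverse_complement

from conftest import random_genome

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orfs(genome, min_codons):
    """Independent oracle: scan the doubled sequence codon-by-codon per
    strand, keep the longest ORF per circular stop, report as
    (forward start mod n, length, strand)."""
    n = len(genome)
    found = set()
    for strand in "+-":
        s = genome.sequence if strand == "+" else \
            reverse_complement(genome.sequence)
        d = s + s if genome.is_circular else s
        best = {}
        for start in range(len(s) if genome.is_circular else len(s) - 2):
            if d[start:start + 3] != "ATG":
                continue
            j = start + 3
            while j + 3 <= len(d) and j + 3 - start <= n:
                if d[j:j + 3] in STOPS:
                    if j + 3 - start >= 3 * (min_codons + 1):
                        key = (j + 3) % n if genome.is_circular else j + 3
                        if key not in best or \
                                j + 3 - start > best[key][1] - best[key][0]:
                            best[key] = (start, j + 3)
                    break
                j += 3
        for start, end in best.values():
            if strand == "+":
                found.add((start % n, end - start, "+"))
            else:
                found.add(((n - end) % n, end - start, "-"))
    return found


def as_keyset(orfs, n):
    return {(o.start % n, o.end - o.start, o.strand) for o in orfs}


class TestFindOrfs:
    def test_exactly_fifty_codons_retained(self):
        seq = "A" * 10 + "ATG" + "GCT" * 49 + "TAA" + "T" * 10
        g = CircularGenome("t", seq, topology="linear")
        orfs = find_orfs(g)
        assert len(orfs) == 1
        o = orfs[0]
        assert (o.start, o.end, o.n_codons, o.strand) == (10, 163, 50, "+")

    def test_forty_nine_codons_rejected(self):
        seq = "A" * 10 + "ATG" + "GCT" * 48 + "TAA" + "T" * 10
        g = CircularGenome("t", seq, topology="linear")
        assert find_orfs(g) == []

    def test_orf_length_counts_stop_codon(self):
        seq = "ATG" + "GCT" * 60 + "TAG"
        g = CircularGenome("t", seq, topology="linear")
        o = find_orfs(g)[0]
        assert o.end - o.start == 3 * (o.n_codons + 1)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_brute_force_oracle(self, seed):
        g = random_genome(seed + 100, 2000 + 137 * seed)
        cfg = AnnotationConfig(min_codons=25)
        assert as_keyset(find_orfs(g, cfg), len(g)) == \
            brute_force_orfs(g, 25)

    def test_rotation_equivariance(self):
        g = random_genome(55, 3000)
        cfg = AnnotationConfig(min_codons=20)
        n = len(g)
        base = {((o.start) % n, o.end - o.start, o.strand)
                for o in find_orfs(g, cfg)}
        for k in (1, 137, 1500, 2999):
            shifted = {((o.start + k) % n, o.end - o.start, o.strand)
                       for o in find_orfs(rotate(g, k), cfg)}
            assert shifted == base

    def test_reverse_complement_equivariance(self):
        g = random_genome(56, 3000)
        cfg = AnnotationConfig(min_codons=20)
        n = len(g)
        rc = CircularGenome("rc", reverse_complement(g.sequence))
        flip = {"+": "-", "-": "+"}
        base = as_keyset(find_orfs(g, cfg), n)
        mapped = {((n - (o.start + (o.end - o.start))) % n,
                   o.end - o.start, flip[o.strand])
                  for o in find_orfs(rc, cfg)}
        assert mapped == base

    def test_origin_spanning_orf_detected(self):
        insert = "ATG" + "GCT" * 60 + "TAA"
        bg = random_genome(77, 2000).sequence
        seq = insert[100:] + bg + insert[:100]
        g = CircularGenome("w", seq)
        n = len(g)
        wrapped = [o for o in find_orfs(g) if o.end > n]
        # the planted stop sits at circular position 86; the reported ORF
        # may start further upstream at an in-frame chance ATG
        planted = [o for o in wrapped
                   if o.end % n == 86 and o.end - o.start >= len(insert)]
        assert planted and planted[0].strand == "+"


class TestFilterCandidates:
    def _orf(self, start, length, oid="x", hit=None, support=(True, True)):
        return OrfRecord(id=oid, start=start, end=start + length,
                         strand="+", n_codons=length // 3 - 1,
                         best_hit=hit, predictor_support=support)

    def test_seventy_five_bp_overlap_removed(self):
        big = self._orf(0, 300, "big", hit=("r", 1.0, 1.0))
        small = self._orf(225, 150, "small")  # 75 bp overlap
        kept = filter_candidate_orfs([big, small], genome_length=1000)
        assert [o.id for o in kept] == ["big"]

    def test_seventy_four_bp_overlap_retained(self):
        big = self._orf(0, 300, "big", hit=("r", 1.0, 1.0))
        small = self._orf(226, 150, "small")  # 74 bp overlap
        kept = filter_candidate_orfs([big, small], genome_length=1000)
        assert {o.id for o in kept} == {"big", "small"}

    def test_homology_hit_always_retained(self):
        big = self._orf(0, 300, "big", hit=("r", 1.0, 1.0))
        nested = self._orf(0, 150, "nested", hit=("r2", 0.5, 0.9))
        kept = filter_candidate_orfs([big, nested], genome_length=1000)
        assert {o.id for o in kept} == {"big", "nested"}

    def test_missing_predictor_support_treated_unsupported(self):
        lone = self._orf(0, 300, "lone", support=None)
        assert filter_candidate_orfs([lone], genome_length=1000) == []

    def test_single_false_flag_removes_anonymous_orf(self):
        lone = self._orf(0, 300, "lone", support=(True, False))
        assert filter_candidate_orfs([lone], genome_length=1000) == []

    def test_equal_length_tie_broken_toward_evidence(self):
        with_hit = self._orf(0, 300, "hit", hit=("r", 1.0, 1.0))
        no_hit = self._orf(150, 300, "anon")  # 150 bp overlap, same length
        kept = filter_candidate_orfs([with_hit, no_hit], genome_length=1000)
        assert [o.id for o in kept] == ["hit"]

    def test_overlap_computed_across_origin(self):
        big = self._orf(900, 300, "big", hit=("r", 1.0, 1.0))  # wraps to 200
        small = self._orf(100, 150, "small")  # overlap 100 via origin
        kept = filter_candidate_orfs([big, small], genome_length=1000)
        assert [o.id for o in kept] == ["big"]


class TestHomology:
    def test_planted_orfs_recover_source_and_category(self,
                                                      planted_orf_genome):
        genome, truth, manifest, proteomes = planted_orf_genome
        annotated = assign_homology(genome, find_orfs(genome), proteomes)
        hits = {o.best_hit[0]: o for o in annotated if o.best_hit}
        assert set(hits) == {"ref0", "ref1", "ref2"}
        assert hits["ref0"].category == "core"
        assert hits["ref1"].category == "alpha_conserved"
        assert hits["ref2"].category == "shared"
        # identities should sit near the planted 80% target
        for o in hits.values():
            assert 0.65 <= o.best_hit[1] <= 0.95

    def test_exact_match_is_identity_one(self):
        prot = "MSTKLVNDEQRAFGHWYCPI" * 4
        coding = "ATG"
        from Bio.Data.CodonTable import standard_dna_table
        by_aa = {}
        for codon, aa in standard_dna_table.forward_table.items():
            by_aa.setdefault(aa, codon)
        coding = "".join(by_aa[aa] for aa in prot) + "TAA"
        g = CircularGenome("g", "A" * 50 + coding + "C" * 50,
                           topology="linear")
        orfs = find_orfs(g)
        annotated = assign_homology(g, orfs, {"core": {"p": prot}})
        best = [o for o in annotated if o.best_hit]
        assert best and best[0].best_hit[1] == 1.0
        assert best[0].category == "core"

    def test_no_hit_labelled_unique(self, planted_orf_genome):
        genome, *_ , proteomes = planted_orf_genome
        annotated = assign_homology(genome, find_orfs(genome), proteomes)
        anon = [o for o in annotated if o.best_hit is None]
        assert anon and all(o.category == "unique" for o in anon)


class TestPromoterScan:
    def test_tata_box_w_expansion(self):
        up = "C" * 150 + "TATAAAA" + "C" * 93
        seq = up + "ATG" + "GCT" * 60 + "TAA"
        g = CircularGenome("g", seq)
        orf = [o for o in find_orfs(g) if o.start == 250][0]
        hits = scan_promoter_motifs(g, orf)
        assert ("tata_box", -100) in hits

    def test_initiator_k_expansion(self):
        for mid, expected in (("CAGT", True), ("CATT", True),
                              ("CACT", False)):
            up = "C" * 100 + mid + "C" * 146
            seq = up + "ATG" + "GCT" * 60 + "TAA"
            g = CircularGenome("g", seq)
            orf = [o for o in find_orfs(g) if o.start == 250][0]
            hits = scan_promoter_motifs(g, orf)
            assert (("initiator", -150) in hits) is expected

    def test_planted_motif_on_minus_strand(self, planted_orf_genome):
        genome, truth, manifest, _ = planted_orf_genome
        planted = manifest.orfs[1]  # '-' strand ORF with CAGT at -60
        orfs = [o for o in find_orfs(genome)
                if o.strand == "-" and o.start <= planted.start
                and o.start + 20 > planted.start - 20]
        target = [o for o in find_orfs(genome)
                  if o.strand == "-"
                  and (o.end % len(genome)) == planted.start + planted.span]
        assert target
        hits = scan_promoter_motifs(genome, target[0])
        assert ("initiator", -60) in hits

    def test_window_crosses_origin(self):
        core = "ATG" + "GCT" * 60 + "TAA"
        # a stop codon at the very end of the circle blocks upstream
        # extension, pinning the ORF start to position 0
        up = "G" * 146 + "TATATAT" + "G" * 94 + "TAA"
        bg = random_genome(9, 500).sequence
        seq = core + bg + up
        assert len(seq) % 3 == 0
        g = CircularGenome("g", seq)
        orf = [o for o in find_orfs(g) if o.start == 0 and o.strand == "+"]
        assert orf
        hits = scan_promoter_motifs(g, orf[0])
        assert ("tata_box", -104) in hits


class TestVariantFilter:
    def test_empty(self):
        assert filter_variant_frequencies([]) == (0, 0)

    def test_strict_inequality_at_threshold(self):
        variants = [VariantRecord(i + 1, "A", "G", f)
                    for i, f in enumerate([0.0095, 0.05, 0.0501, 0.1363])]
        assert filter_variant_frequencies(variants) == (4, 2)

    def test_binomial_simulation_rate(self):
        rng = np.random.default_rng(1234)
        freqs = np.where(rng.random(1000) < 0.03,
                         rng.uniform(0.051, 0.14, 1000),
                         rng.uniform(0.005, 0.05, 1000))
        variants = [VariantRecord(i + 1, "A", "G", float(f))
                    for i, f in enumerate(freqs)]
        total, above = filter_variant_frequencies(variants)
        assert total == 1000
        expected = int((freqs > 0.05).sum())
        assert above == expected
        assert 10 <= above <= 60  # ~30 expected under the 3% planting rate

    def test_frequency_bounds_enforced(self):
        with pytest.raises(ValueError):
            VariantRecord(1, "A", "G", 1.0)
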