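import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_revcomp, random_dna
from sbpmarker.markerdesign import (
    DesignConfig,
    GelModel,
    InSilicoPcrError,
    PrimerPair,
    Rejection,
    SbpMarker,
    design_marker,
    design_primers,
    gel_resolvable,
    haplotype_windows,
    insilico_pcr,
    name_marker,
    primer_tm,
)
from sbpmarker.restriction import digest, scan_sites
from sbpmarker.seqio import SequenceRecord
from sbpmarker.snpcall import SnpCandidate


def snp(chrom, pos, ref, alt):
    return SnpCandidate(chrom, pos, ref, alt, 3, 1.0, 30, 1.0, True)


class TestHaplotypeWindows:
    def test_single_substitution_at_offset(self):
        rng = random.Random(73)
        seq = random_dna(rng, 1_000)
        genome = [SequenceRecord("chr1", seq)]
        s = snp("chr1", 500, seq[499], "A" if seq[499] != "A" else "C")
        wa, wb, off = haplotype_windows(genome, s, 100)
        assert wa == seq[399:600] and off == 101
        assert wb[off - 1] == s.cons_base
        assert sum(a != b for a, b in zip(wa, wb)) == 1

    def test_left_truncation_is_error(self):
        genome = [SequenceRecord("chr1", "ACGT" * 100)]
        with pytest.raises(ValueError, match="truncated"):
            haplotype_windows(genome, snp("chr1", 30, "G", "A"), 50)

    def test_n_in_window_is_error(self):
        genome = [SequenceRecord("chr1", "A" * 100 + "N" + "A" * 100)]
        with pytest.raises(ValueError, match="contains N"):
            haplotype_windows(genome, snp("chr1", 95, "A", "G"), 20)

    def test_reference_base_mismatch_is_error(self):
        genome = [SequenceRecord("chr1", "A" * 200)]
        with pytest.raises(ValueError, match="mismatch"):
            haplotype_windows(genome, snp("chr1", 100, "C", "G"), 20)


class TestPrimerTm:
    @pytest.mark.parametrize(
        "seq,tm",
        [
            ("CACAAACCCTTCACCTCCAT", 60.0),  # 10 AT + 10 GC
            ("A" * 10, 20.0),
            ("G" * 10, 40.0),
        ],
    )
    def test_wallace_rule_values(self, seq, tm):
        assert primer_tm(seq) == tm

    def test_non_acgt_is_error(self):
        with pytest.raises(ValueError):
            primer_tm("ACGTACGTNN")

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            primer_tm("ACGTACGT")


class TestNameMarker:
    @pytest.mark.parametrize(
        "chrom,pos,name",
        [(1, 950_000, "SBP1_0.95"), (5, 25_000_000, "SBP5_25.00"), (3, 1, "SBP3_0.00"),
         (2, 14_065_000, "SBP2_14.07")],  # half-up at the third decimal
    )
    def test_naming_rule(self, chrom, pos, name):
        assert name_marker(chrom, pos) == name

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            name_marker(0, 100)


class TestGelResolvable:
    def test_canonical_cut_vs_uncut(self, gel):
        assert gel_resolvable([233], [150, 83], gel) is True

    def test_identical_patterns_unresolvable(self, gel):
        assert gel_resolvable([200], [200], gel) is False

    def test_small_shifts_unresolvable(self, gel):
        assert gel_resolvable([120, 80], [110, 90], gel) is False

    def test_invisible_fragment_ignored(self, gel):
        # the 30 nt band is below min_fragment; remaining bands are too close
        assert gel_resolvable([200], [190, 30], gel) is False

    def test_empty_fragments_rejected(self, gel):
        with pytest.raises(ValueError):
            gel_resolvable([], [100], gel)

    @given(
        st.lists(st.integers(41, 600), min_size=1, max_size=4),
        st.lists(st.integers(41, 600), min_size=1, max_size=4),
        st.integers(5, 14),
    )
    @settings(max_examples=150, deadline=None)
    def test_shrinking_min_diff_is_monotone(self, fa, fb, smaller):
        """Lowering the resolution threshold can only reveal differences."""
        strict = GelModel(min_diff=15)
        lax = GelModel(min_diff=smaller)
        if gel_resolvable(fa, fb, strict):
            assert gel_resolvable(fa, fb, lax)

    def test_gel_model_validation(self):
        with pytest.raises(ValueError):
            GelModel(min_rel_diff=1.5)
        with pytest.raises(ValueError):
            GelModel(min_fragment=0)


def _window_pair(rng, n=240, snp_at=None):
    seq = random_dna(rng, n)
    snp_at = snp_at if snp_at is not None else n // 2  # 0-based
    alt = rng.choice([c for c in "ACGT" if c != seq[snp_at]])
    return seq, seq[:snp_at] + alt + seq[snp_at + 1 :], snp_at + 1


def brute_force_pairs(window_a, window_b, snp_offset, poly, target_len, len_range, cfg=None):
    """Exhaustive enumeration of every primer placement under the published
    constraints; independent of the ranked generator."""
    cfg = cfg or DesignConfig()
    snp0 = snp_offset - 1
    forbidden = {snp0, *(p - 1 for p in poly)}
    n = len(window_a)

    def ok(i, L):
        seg = window_a[i : i + L]
        if window_b[i : i + L] != seg or set(range(i, i + L)) & forbidden:
            return None
        gc = (seg.count("G") + seg.count("C")) / L
        if not cfg.gc_range[0] <= gc <= cfg.gc_range[1]:
            return None
        tm = 2.0 * (seg.count("A") + seg.count("T")) + 4.0 * gc * L
        if not cfg.tm_range[0] <= tm <= cfg.tm_range[1]:
            return None
        return seg, tm

    def unique_in(win, seg):
        rc = oracle_revcomp(seg)
        count = sum(
            1
            for i in range(len(win) - len(seg) + 1)
            for q in ({seg, rc} if rc != seg else {seg})
            if win[i : i + len(seg)] == q
        )
        return count == 1

    out = set()
    for i in range(0, snp0):
        for Lf in range(cfg.primer_len[0], cfg.primer_len[1] + 1):
            if i + Lf > snp0:
                break
            f = ok(i, Lf)
            if not f:
                continue
            for j in range(snp0 + 1, n):
                for Lr in range(cfg.primer_len[0], cfg.primer_len[1] + 1):
                    if j + Lr > n:
                        break
                    r = ok(j, Lr)
                    if not r:
                        continue
                    product = j + Lr - i
                    if not len_range[0] <= product <= len_range[1]:
                        continue
                    if abs(f[1] - r[1]) > cfg.max_tm_diff:
                        continue
                    rev = oracle_revcomp(r[0])
                    if not all(
                        unique_in(w, s) for w in (window_a, window_b) for s in (f[0], rev)
                    ):
                        continue
                    out.add((f[0], rev, product))
    return out


class TestDesignPrimers:
    def test_constructive_window_yields_pairs_containing_snp(self):
        rng = random.Random(79)
        wa, wb, off = _window_pair(rng, 400, snp_at=200)
        pairs = design_primers(wa, wb, off, target_len=150, len_range=(80, 380))
        assert pairs
        for p in pairs[:20]:
            assert p.product_start <= off <= p.product_end
            i0 = p.product_start - 1
            assert wa[i0 : i0 + len(p.fwd)] == p.fwd
            assert oracle_revcomp(p.rev) == wa[p.product_end - len(p.rev) : p.product_end]
            # footprints strictly flank the SNP
            assert i0 + len(p.fwd) < off and p.product_end - len(p.rev) + 1 > off

    def test_ranked_by_distance_to_target_length(self):
        rng = random.Random(83)
        wa, wb, off = _window_pair(rng, 400, snp_at=200)
        pairs = design_primers(wa, wb, off, target_len=150, len_range=(80, 380))
        dists = [abs(p.product_length - 150) for p in pairs]
        assert dists == sorted(dists)

    def test_polymorphic_flanks_give_empty_list_with_reason(self):
        rng = random.Random(89)
        wa, wb, off = _window_pair(rng, 120, snp_at=60)
        poly = [p for p in range(1, 121) if p != off]  # every other position polymorphic
        reasons = Counter()
        pairs = design_primers(wa, wb, off, poly, target_len=100, len_range=(40, 120),
                               reasons=reasons)
        assert pairs == []
        assert reasons["primer over polymorphic site"] > 0

    def test_matches_exhaustive_validator(self):
        rng = random.Random(97)
        wa, wb, off = _window_pair(rng, 220, snp_at=110)
        got = {
            (p.fwd, p.rev, p.product_length)
            for p in design_primers(wa, wb, off, target_len=160, len_range=(60, 220))
        }
        expected = brute_force_pairs(wa, wb, off, [], 160, (60, 220))
        assert got == expected and got


class TestInsilicoPcr:
    def _primers(self, rng):
        fwd = random_dna(rng, 20)
        rev = list(fwd)
        rng.shuffle(rev)  # same base composition -> identical Wallace Tm
        return fwd, "".join(rev)

    def _genome_with_product(self, rng, fwd, rev, insert_len=160):
        product = fwd + random_dna(rng, insert_len) + oracle_revcomp(rev)
        seq = random_dna(rng, 3_000) + product + random_dna(rng, 3_000)
        return [SequenceRecord("chr1", seq)], product

    def test_roundtrip_unique_product(self):
        rng = random.Random(101)
        fwd, rev = self._primers(rng)
        genome, product = self._genome_with_product(rng, fwd, rev)
        pair = PrimerPair(fwd, rev, primer_tm(fwd), primer_tm(rev), 1, len(product))
        assert insilico_pcr(genome, pair) == product

    def test_multiple_products_rejected_with_count(self):
        rng = random.Random(103)
        fwd, rev = self._primers(rng)
        genome, product = self._genome_with_product(rng, fwd, rev)
        doubled = [SequenceRecord("chr1", genome[0].sequence + product)]
        pair = PrimerPair(fwd, rev, primer_tm(fwd), primer_tm(rev), 1, len(product))
        with pytest.raises(InSilicoPcrError, match="products"):
            insilico_pcr(doubled, pair)

    def test_no_product_rejected(self):
        rng = random.Random(107)
        genome = [SequenceRecord("chr1", random_dna(rng, 500))]
        fwd, rev = "ACGTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA"
        pair = PrimerPair(fwd, rev, primer_tm(fwd), primer_tm(rev), 1, 100)
        with pytest.raises(InSilicoPcrError, match="0 products"):
            insilico_pcr(genome, pair)


def _planted_genome(rng, enz_site="CCGG", break_at=1, L=8_000, pos=4_000):
    """Reference genome with the enzyme site at `pos`; SNP breaks it."""
    seq = list(random_dna(rng, L))
    for k, ch in enumerate(enz_site):
        seq[pos - 1 + k] = ch
    seq = "".join(seq)
    ref = enz_site[break_at]
    genome = [SequenceRecord("chr1", seq)]
    return genome, pos + break_at  # SNP position (1-based)


class TestDesignMarker:
    def test_site_destroying_snp_yields_marker(self, enzyme_db, gel):
        rng = random.Random(109)
        genome, pos = _planted_genome(rng)
        s = snp("chr1", pos, "C", "A")  # CCGG -> CAGG kills MspI in haplotype B
        m = design_marker(genome, s, enzyme_db, gel)
        assert isinstance(m, SbpMarker), m
        assert m.resolvable and m.snp_position == pos
        assert sum(m.fragments_a) == m.amplicon_len_a
        assert sum(m.fragments_b) == m.amplicon_len_b
        # haplotype A is cut at the SNP site, B is not (or vice versa)
        assert len(m.fragments_a) != len(m.fragments_b)
        # SNP strictly inside the product, between the primer footprints
        p = m.primers
        assert p.product_start + len(p.fwd) - 1 < pos < p.product_end - len(p.rev) + 1

    def test_snp_touching_no_site_is_rejected(self, enzyme_db, gel):
        rng = random.Random(113)
        while True:
            seq = random_dna(rng, 4_000)
            pos = 2_000
            s = snp("chr1", pos, seq[pos - 1], rng.choice([c for c in "ACGT" if c != seq[pos - 1]]))
            genome = [SequenceRecord("chr1", seq)]
            wa = seq[pos - 301 : pos + 300]
            wb = wa[:300] + s.cons_base + wa[301:]
            if all(scan_sites(wa, e) == scan_sites(wb, e) for e in enzyme_db):
                break
        r = design_marker(genome, s, enzyme_db, gel)
        assert isinstance(r, Rejection)
        assert r.stage == "enzyme" and "no differential enzyme" in r.reason

    def test_window_truncation_is_rejection_not_error(self, enzyme_db, gel):
        genome = [SequenceRecord("chr1", "ACGT" * 200)]
        r = design_marker(genome, snp("chr1", 50, "C", "A"), enzyme_db, gel)
        assert isinstance(r, Rejection) and r.stage == "window"

    def test_emitted_marker_survives_pcr_roundtrip(self, enzyme_db, enzymes_by_name, gel):
        """Re-derive both amplicons and digests from the genomes alone."""
        rng = random.Random(127)
        genome, pos = _planted_genome(rng, enz_site="TCGA", break_at=1)
        s = snp("chr1", pos, "C", "G")
        m = design_marker(genome, s, enzyme_db, gel)
        assert isinstance(m, SbpMarker)
        alt_seq = genome[0].sequence
        alt_genome = [SequenceRecord("chr1", alt_seq[: pos - 1] + "G" + alt_seq[pos:])]
        amp_a = insilico_pcr(genome, m.primers)
        amp_b = insilico_pcr(alt_genome, m.primers)
        enz = enzymes_by_name[m.enzyme]
        assert digest(amp_a, enz).fragment_lengths == m.fragments_a
        assert digest(amp_b, enz).fragment_lengths == m.fragments_b
        assert (len(amp_a), len(amp_b)) == (m.amplicon_len_a, m.amplicon_len_b)

    def test_wider_length_range_never_loses_markers(self, enzyme_db, gel):
        """Enlarging the allowed amplicon range can only help."""
        rng = random.Random(131)
        outcomes = []
        for _ in range(6):
            genome, pos = _planted_genome(rng, L=6_000, pos=3_000)
            s = snp("chr1", pos, "C", "T")
            narrow = design_marker(genome, s, enzyme_db, gel,
                                   DesignConfig(len_range=(150, 250)))
            wide = design_marker(genome, s, enzyme_db, gel,
                                 DesignConfig(len_range=(80, 600)))
            outcomes.append((isinstance(narrow, SbpMarker), isinstance(wide, SbpMarker)))
        assert all(wide for n, wide in outcomes if n)
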