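"""Turn a validated SNP into a co-dominant, gel-scored restriction marker.

The design path: slice matched haplotype windows around the SNP, enumerate
primer pairs whose product contains the SNP, digest both haplotypes' amplicons
with every candidate enzyme, keep the first combination whose band patterns a
4% agarose gel can separate, and verify it by an in-silico PCR round trip on
both haplotype genomes.  Failures are returned as data (a rejection record
naming the stage), never raised.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import TYPE_CHECKING, Iterator, Mapping, Sequence

from . import restriction
from .filters import genome_occurrences
from .restriction import Enzyme, reverse_complement

if TYPE_CHECKING:  # pragma: no cover
    from .seqio import SequenceRecord
    from .snpcall import SnpCandidate

log = logging.getLogger(__name__)


class InSilicoPcrError(RuntimeError):
    """Zero or multiple PCR products for a primer pair."""


@dataclass(frozen=True)
class GelModel:
    """What a 4% (w/v) agarose gel can tell apart.

    ``min_fragment`` — bands shorter than this run off / stain too weakly to
    score.  Two bands count as separated when their lengths differ by at least
    ``min_diff`` nucleotides or ``min_rel_diff`` of the larger band, whichever
    is greater.
    """

    agarose_pct: float = 4.0
    min_fragment: int = 40
    min_diff: int = 15
    min_rel_diff: float = 0.08

    def __post_init__(self) -> None:
        if min(self.agarose_pct, self.min_fragment, self.min_diff) <= 0:
            raise ValueError("gel parameters must be positive")
        if not 0.0 < self.min_rel_diff < 1.0:
            raise ValueError("min_rel_diff must be in (0, 1)")

    def _separable(self, f: int, g: int) -> bool:
        return abs(f - g) >= max(self.min_diff, self.min_rel_diff * max(f, g))

    def resolvable(self, fragments_a: Sequence[int], fragments_b: Sequence[int]) -> bool:
        """True iff the two band patterns are visibly different on this gel."""
        va = sorted(f for f in fragments_a if f >= self.min_fragment)
        vb = sorted(f for f in fragments_b if f >= self.min_fragment)
        if va == vb:
            return False
        for one, other in ((va, vb), (vb, va)):
            for f in one:
                if not any(not self._separable(f, g) for g in other):
                    return True
        return False


def gel_resolvable(fragments_a: Sequence[int], fragments_b: Sequence[int], gel: GelModel) -> bool:
    if not fragments_a or not fragments_b:
        raise ValueError("fragment lists must be non-empty")
    return gel.resolvable(fragments_a, fragments_b)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair; both written 5'->3'."""

    fwd: str
    rev: str
    fwd_tm: float
    rev_tm: float
    product_start: int  # 1-based inclusive, reference chromosome
    product_end: int

    def __post_init__(self) -> None:
        for p in (self.fwd, self.rev):
            if not 18 <= len(p) <= 27:
                raise ValueError(f"primer length {len(p)} outside 18..27")
        if abs(self.fwd_tm - self.rev_tm) > 5:
            raise ValueError("primer Tm difference exceeds 5 degrees")

    @property
    def product_length(self) -> int:
        return self.product_end - self.product_start + 1


@dataclass(frozen=True)
class SbpMarker:
    """A designed marker: one Table-row-shaped assay definition."""

    name: str
    chrom: str
    snp_position: int
    primers: PrimerPair
    enzyme: str
    amplicon_len_a: int
    amplicon_len_b: int
    fragments_a: tuple[int, ...]
    fragments_b: tuple[int, ...]
    resolvable: bool

    def __post_init__(self) -> None:
        assert sum(self.fragments_a) == self.amplicon_len_a
        assert sum(self.fragments_b) == self.amplicon_len_b


@dataclass(frozen=True)
class Rejection:
    """Why a SNP did not become a marker; failures are data, not exceptions."""

    chrom: str
    position: int
    stage: str
    reason: str


@dataclass(frozen=True)
class DesignConfig:
    half_width: int = 300
    target_len: int = 200
    len_range: tuple[int, int] = (80, 600)
    primer_len: tuple[int, int] = (18, 27)
    gc_range: tuple[float, float] = (0.30, 0.70)
    tm_range: tuple[float, float] = (48.0, 64.0)
    max_tm_diff: float = 5.0
    max_pairs_tried: int = 500
    max_pcr_product: int = 5000


def haplotype_windows(
    genome: Sequence["SequenceRecord"],
    snp: "SnpCandidate",
    half_width: int,
) -> tuple[str, str, int]:
    """Reference window and its SNP-substituted twin around ``snp``.

    Returns ``(window_a, window_b, snp_offset)`` with the SNP's 1-based offset
    inside the windows.  Windows truncated by a chromosome end or containing N
    are errors: they cannot anchor a clean amplicon.
    """
    seqs = {r.id: r.sequence for r in genome}
    if snp.chrom not in seqs:
        raise ValueError(f"unknown chromosome {snp.chrom!r}")
    ref = seqs[snp.chrom]
    lo, hi = snp.position - half_width, snp.position + half_width
    if lo < 1 or hi > len(ref):
        raise ValueError(f"window {snp.chrom}:{lo}-{hi} truncated by the chromosome end")
    window_a = ref[lo - 1 : hi]
    if "N" in window_a:
        raise ValueError(f"window {snp.chrom}:{lo}-{hi} contains N")
    offset = snp.position - lo + 1
    if window_a[offset - 1] != snp.ref_base:
        raise ValueError(
            f"reference base mismatch at {snp.chrom}:{snp.position}: "
            f"genome has {window_a[offset - 1]}, SNP record says {snp.ref_base}"
        )
    window_b = window_a[: offset - 1] + snp.cons_base + window_a[offset:]
    return window_a, window_b, offset


def primer_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degrees C."""
    if len(seq) < 10:
        raise ValueError("primer too short for the Wallace rule (need >= 10 nt)")
    counts = Counter(seq)
    bad = set(counts) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT character(s) in primer: {sorted(bad)}")
    at = counts["A"] + counts["T"]
    gc = counts["G"] + counts["C"]
    return 2.0 * at + 4.0 * gc


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _occurrences(strings: Sequence[str], query: str) -> int:
    rc = reverse_complement(query)
    total = 0
    for s in strings:
        i = 0
        while (i := s.find(query, i)) >= 0:
            total += 1
            i += 1
        if rc != query:
            i = 0
            while (i := s.find(rc, i)) >= 0:
                total += 1
                i += 1
    return total


@dataclass
class _Candidate:
    start: int  # 0-based within window
    length: int
    seq: str
    tm: float


def _enumerate_half(
    window_a: str,
    window_b: str,
    lo: int,
    hi: int,  # candidate start range, 0-based half-open
    poly: frozenset[int],
    cfg: DesignConfig,
    reasons: Counter,
    limit_end: int | None = None,
) -> list[_Candidate]:
    out = []
    lmin, lmax = cfg.primer_len
    for i in range(lo, hi):
        for L in range(lmin, lmax + 1):
            end = i + L
            if limit_end is not None and end > limit_end:
                break
            if end > len(window_a):
                break
            if any(p in poly for p in range(i, end)):
                reasons["primer over polymorphic site"] += 1
                continue
            seq = window_a[i:end]
            if seq != window_b[i:end]:
                reasons["primer over polymorphic site"] += 1
                continue
            if "N" in seq:
                reasons["primer contains N"] += 1
                continue
            gc = _gc_fraction(seq)
            if not cfg.gc_range[0] <= gc <= cfg.gc_range[1]:
                reasons["GC content out of range"] += 1
                continue
            tm = primer_tm(seq)
            if not cfg.tm_range[0] <= tm <= cfg.tm_range[1]:
                reasons["Tm out of range"] += 1
                continue
            out.append(_Candidate(i, L, seq, tm))
    return out


def iter_primer_pairs(
    window_a: str,
    window_b: str,
    snp_offset: int,
    known_polymorphisms: Sequence[int] = (),
    target_len: int = 200,
    len_range: tuple[int, int] = (80, 600),
    *,
    genomes: tuple[Sequence["SequenceRecord"], Sequence["SequenceRecord"]] | None = None,
    window_start: int = 1,
    config: DesignConfig | None = None,
    reasons: Counter | None = None,
) -> Iterator[PrimerPair]:
    """Lazily yield valid primer pairs, best product length first.

    The SNP lies strictly between the primer footprints; primers are identical
    in both windows, avoid every listed polymorphism, satisfy length 18-27,
    GC 30-70%, Tm 48-64 and pair dTm <= 5, and occur exactly once (both
    strands) in each haplotype genome when ``genomes`` is given, else once in
    each window.  Pairs are ordered by |product - target_len| with a
    deterministic positional tie-break.
    """
    cfg = config or DesignConfig(target_len=target_len, len_range=len_range)
    cfg = replace(cfg, target_len=target_len, len_range=len_range)
    reasons = reasons if reasons is not None else Counter()
    snp0 = snp_offset - 1  # 0-based
    poly = frozenset([snp0, *(p - 1 for p in known_polymorphisms)])

    fwd = _enumerate_half(window_a, window_b, 0, snp0, poly, cfg, reasons, limit_end=snp0)
    rev = _enumerate_half(window_a, window_b, snp0 + 1, len(window_a), poly, cfg, reasons)
    if not fwd or not rev:
        reasons["no candidate primer on one side"] += 1
        return

    if genomes is not None:
        hap_a = [r.sequence for r in genomes[0]]
        hap_b = [r.sequence for r in genomes[1]]
    else:
        hap_a, hap_b = [window_a], [window_b]
    unique_cache: dict[str, bool] = {}

    def unique(seq: str) -> bool:
        hit = unique_cache.get(seq)
        if hit is None:
            hit = _occurrences(hap_a, seq) == 1 and _occurrences(hap_b, seq) == 1
            unique_cache[seq] = hit
        return hit

    fwd_by_start: dict[int, list[_Candidate]] = {}
    for c in fwd:
        fwd_by_start.setdefault(c.start, []).append(c)
    rev_by_end: dict[int, list[_Candidate]] = {}
    for c in rev:
        rev_by_end.setdefault(c.start + c.length, []).append(c)
    rev_ends = sorted(rev_by_end)

    lmin, lmax = cfg.len_range
    for d in sorted(range(lmin, lmax + 1), key=lambda d: (abs(d - cfg.target_len), d)):
        for e in rev_ends:
            fwds = fwd_by_start.get(e - d)
            if not fwds:
                continue
            for fc in fwds:
                for rc in rev_by_end[e]:
                    if abs(fc.tm - rc.tm) > cfg.max_tm_diff:
                        reasons["pair Tm mismatch"] += 1
                        continue
                    rev_seq = reverse_complement(rc.seq)
                    if not (unique(fc.seq) and unique(rev_seq)):
                        reasons["primer not unique in genome"] += 1
                        continue
                    yield PrimerPair(
                        fwd=fc.seq,
                        rev=rev_seq,
                        fwd_tm=fc.tm,
                        rev_tm=rc.tm,
                        product_start=window_start + fc.start,
                        product_end=window_start + e - 1,
                    )


def design_primers(
    window_a: str,
    window_b: str,
    snp_offset: int,
    known_polymorphisms: Sequence[int] = (),
    target_len: int = 200,
    len_range: tuple[int, int] = (80, 600),
    **kwargs,
) -> list[PrimerPair]:
    """All valid primer pairs for the window, ranked (see iter_primer_pairs).

    Returns an empty list when no placement satisfies the constraints; the
    failure histogram is logged.
    """
    reasons: Counter = kwargs.pop("reasons", Counter())
    pairs = list(
        iter_primer_pairs(
            window_a, window_b, snp_offset, known_polymorphisms,
            target_len, len_range, reasons=reasons, **kwargs,
        )
    )
    if not pairs and reasons:
        log.info("design_primers: no valid pair; failures: %s", dict(reasons.most_common()))
    return pairs


def insilico_pcr(
    genome_hap: Sequence["SequenceRecord"],
    primers: PrimerPair | tuple[str, str],
    max_product: int = 5000,
) -> str:
    """Exact-match PCR: the unique product primed by fwd and rev.

    Locates exact occurrences of the forward primer and of the reverse
    complement of the reverse primer; exactly one pairing within
    ``max_product`` must exist, otherwise the reaction is rejected with the
    product count in the error.  ``primers`` may be a designed
    :class:`PrimerPair` or a plain ``(fwd, rev)`` tuple — externally published
    pairs need not satisfy the designer's pair-Tm constraint.
    """
    if isinstance(primers, tuple):
        fwd, rev = primers
    else:
        fwd, rev = primers.fwd, primers.rev
    if not fwd or not rev:
        raise ValueError("primers must be non-empty")
    rc_rev = reverse_complement(rev)
    products: list[tuple[str, int, int]] = []
    for rec in genome_hap:
        seq = rec.sequence
        f = 0
        fwd_starts = []
        while (f := seq.find(fwd, f)) >= 0:
            fwd_starts.append(f)
            f += 1
        r = 0
        rc_starts = []
        while (r := seq.find(rc_rev, r)) >= 0:
            rc_starts.append(r)
            r += 1
        for f0 in fwd_starts:
            for r0 in rc_starts:
                length = r0 + len(rc_rev) - f0
                if r0 >= f0 and length <= max_product and length >= max(len(fwd), len(rc_rev)):
                    products.append((rec.id, f0, r0 + len(rc_rev)))
    if len(products) != 1:
        raise InSilicoPcrError(f"{len(products)} products")
    rec_id, s, e = products[0]
    seqs = {r.id: r.sequence for r in genome_hap}
    return seqs[rec_id][s:e]


def name_marker(chrom_number: int, snp_position: int) -> str:
    """Marker name: SBP<chromosome>_<megabase position to 2 dp, half-up>."""
    if chrom_number < 1 or snp_position < 1:
        raise ValueError("chromosome number and position must be >= 1")
    mb = (Decimal(snp_position) / Decimal(1_000_000)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return f"SBP{chrom_number}_{mb}"


def _chrom_number(chrom: str, genome: Sequence["SequenceRecord"]) -> int:
    m = re.search(r"(\d+)\s*$", chrom)
    if m:
        return int(m.group(1))
    for i, rec in enumerate(genome, 1):
        if rec.id == chrom:
            return i
    return 1


def design_marker(
    genome: Sequence["SequenceRecord"],
    snp: "SnpCandidate",
    enzyme_db: Sequence[Enzyme] | None = None,
    gel: GelModel | None = None,
    config: DesignConfig | None = None,
    known_polymorphisms: Mapping[str, Sequence[int]] | None = None,
) -> SbpMarker | Rejection:
    """Full design of one SNP: windows -> primers -> differential digest ->
    gel verdict -> in-silico PCR verification.

    Returns the best-ranked passing :class:`SbpMarker`, or a
    :class:`Rejection` naming the first stage with no viable candidate.
    """
    db = enzyme_db if enzyme_db is not None else restriction.load_default_enzymes()
    gel = gel or GelModel()
    cfg = config or DesignConfig()

    try:
        window_a, window_b, snp_offset = haplotype_windows(genome, snp, cfg.half_width)
    except ValueError as exc:
        return Rejection(snp.chrom, snp.position, "window", str(exc))

    # an amplicon digest can only differ where the windows' site sets differ
    diff_db = [
        e for e in db
        if restriction.scan_sites(window_a, e) != restriction.scan_sites(window_b, e)
    ]
    if not diff_db:
        return Rejection(snp.chrom, snp.position, "enzyme", "no differential enzyme")

    # haplotype B genome: reference with the consensus base substituted
    alt_genome = []
    for rec in genome:
        if rec.id == snp.chrom:
            s = rec.sequence
            alt_genome.append(
                type(rec)(rec.id, s[: snp.position - 1] + snp.cons_base + s[snp.position :])
            )
        else:
            alt_genome.append(rec)

    window_lo = snp.position - cfg.half_width  # genomic coord of window start
    poly = [
        p - window_lo + 1
        for p in (known_polymorphisms or {}).get(snp.chrom, ())
        if window_lo <= p <= snp.position + cfg.half_width and p != snp.position
    ]
    reasons: Counter = Counter()
    pairs = iter_primer_pairs(
        window_a, window_b, snp_offset, poly,
        cfg.target_len, cfg.len_range,
        genomes=(genome, alt_genome), window_start=window_lo,
        config=cfg, reasons=reasons,
    )

    tried = 0
    saw_pair = False
    for pair in pairs:
        saw_pair = True
        tried += 1
        if tried > cfg.max_pairs_tried:
            break
        i0 = pair.product_start - window_lo
        i1 = pair.product_end - window_lo + 1
        amp_a, amp_b = window_a[i0:i1], window_b[i0:i1]
        hits = restriction.differential_enzymes(amp_a, amp_b, diff_db, gel)
        if not hits:
            reasons["no gel-resolvable digest in amplicon"] += 1
            continue
        enz, dig_a, dig_b = hits[0]
        try:
            prod_a = insilico_pcr(genome, pair, cfg.max_pcr_product)
            prod_b = insilico_pcr(alt_genome, pair, cfg.max_pcr_product)
        except InSilicoPcrError as exc:
            reasons[f"in-silico PCR failed ({exc})"] += 1
            continue
        if prod_a != amp_a or prod_b != amp_b:
            reasons["in-silico PCR product mismatch"] += 1
            continue
        assert restriction.digest(prod_a, enz).fragment_lengths == dig_a.fragment_lengths
        assert restriction.digest(prod_b, enz).fragment_lengths == dig_b.fragment_lengths
        return SbpMarker(
            name=name_marker(_chrom_number(snp.chrom, genome), snp.position),
            chrom=snp.chrom,
            snp_position=snp.position,
            primers=pair,
            enzyme=enz.name,
            amplicon_len_a=len(amp_a),
            amplicon_len_b=len(amp_b),
            fragments_a=dig_a.fragment_lengths,
            fragments_b=dig_b.fragment_lengths,
            resolvable=True,
        )

    if not saw_pair:
        top = reasons.most_common(1)
        reason = top[0][0] if top else "no candidate primer pair"
        return Rejection(snp.chrom, snp.position, "primers", reason)
    return Rejection(
        snp.chrom, snp.position, "digest",
        "no primer pair yields a gel-resolvable differential digest",
    )


def virtual_gel(
    lanes: Mapping[str, Sequence[int]],
    width: int = 40,
    min_len: int = 20,
    max_len: int = 700,
) -> str:
    """Text rendering of band patterns: one lane per haplotype, log-scaled
    mobility (short fragments run far)."""
    import math

    rows: dict[int, dict[str, list[int]]] = {}
    names = list(lanes)
    for name, frags in lanes.items():
        for f in frags:
            f_clamped = min(max(f, min_len), max_len)
            y = int(
                (math.log(max_len) - math.log(f_clamped))
                / (math.log(max_len) - math.log(min_len))
                * (width - 1)
            )
            rows.setdefault(y, {}).setdefault(name, []).append(f)
    out = ["mobility " + "  ".join(f"{n:>12}" for n in names)]
    for y in range(width):
        cells = []
        for n in names:
            frags = rows.get(y, {}).get(n)
            cells.append(f"{','.join(map(str, sorted(frags, reverse=True))):>12}" if frags else " " * 12)
        if any(c.strip() for c in cells):
            out.append(f"{y:>8} " + "  ".join(cells))
    return "\n".join(out)
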