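"""Reference-guided pileup and SNP qualification.

Each covered position becomes a :class:`PileupColumn`; a SNP candidate is
emitted where the most frequent non-reference base clears the support,
concordance and base-quality thresholds.  The candidate carries the evidence
fields a reviewer needs to judge it: supporting-read count, concordance
(support / total coverage), the best supporting base quality, the mean number
of genome-wide alignment hits over covering reads, and whether every
supporting read was uniquely mapped.
"""

from __future__ import annotations

import heapq
from collections import defaultdict
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Iterator, NamedTuple, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .seqio import AlignedRead, SequenceRecord


class SupportRead(NamedTuple):
    """Per-read evidence at one pileup position."""

    start: int
    end: int
    strand: str
    n_hits: int
    base_quality: int


@dataclass
class PileupColumn:
    chrom: str
    position: int  # 1-based
    ref_base: str
    coverage: int
    base_counts: dict[str, int]
    supporting_reads: dict[str, list[SupportRead]]

    def __post_init__(self) -> None:
        assert sum(self.base_counts.values()) == self.coverage


@dataclass(frozen=True)
class SnpCandidate:
    """A putative substitution with its pileup evidence fields."""

    chrom: str
    position: int
    ref_base: str
    cons_base: str
    support: int
    concordance: float
    max_quality: int
    avg_hits: float
    read_type: bool  # True iff every supporting read mapped uniquely

    def __post_init__(self) -> None:
        if self.cons_base == self.ref_base:
            raise ValueError("consensus base must differ from the reference base")
        if not 0.0 < self.concordance <= 1.0:
            raise ValueError(f"concordance must be in (0, 1], got {self.concordance}")
        if self.support < 1:
            raise ValueError("support must be positive")
        if self.avg_hits < 1:
            raise ValueError("avg_hits must be >= 1")


def build_pileup(
    reads: Iterable["AlignedRead"],
    genome: Sequence["SequenceRecord"],
) -> Iterator[PileupColumn]:
    """One column per covered position, zero-coverage positions omitted.

    Reads may arrive in any order; they are grouped per chromosome and swept
    by coordinate.  Reverse-strand reads contribute their stored bases, which
    are already reference-oriented.
    """
    seqs = {r.id: r.sequence for r in genome}
    by_chrom: dict[str, list] = defaultdict(list)
    for r in reads:
        if r.chrom not in seqs:
            raise ValueError(f"read {r.read_id!r} mapped to unknown chromosome {r.chrom!r}")
        by_chrom[r.chrom].append(r)
    for chrom in sorted(by_chrom):
        ref = seqs[chrom]
        reads_c = sorted(by_chrom[chrom], key=lambda r: r.start)
        active: list[tuple[int, int, object]] = []  # (end, tiebreak, read) min-heap
        idx, n = 0, len(reads_c)
        pos = reads_c[0].start
        while idx < n or active:
            if not active and idx < n:
                pos = max(pos, reads_c[idx].start)
            while idx < n and reads_c[idx].start <= pos:
                r = reads_c[idx]
                heapq.heappush(active, (r.end, idx, r))
                idx += 1
            while active and active[0][0] < pos:
                heapq.heappop(active)
            if not active:
                continue
            counts: dict[str, int] = {}
            support: dict[str, list[SupportRead]] = {}
            for _end, _i, r in active:
                off = pos - r.start
                base = r.bases[off]
                counts[base] = counts.get(base, 0) + 1
                support.setdefault(base, []).append(
                    SupportRead(r.start, r.end, r.strand, r.n_hits, r.quals[off])
                )
            yield PileupColumn(
                chrom=chrom,
                position=pos,
                ref_base=ref[pos - 1],
                coverage=len(active),
                base_counts=counts,
                supporting_reads=support,
            )
            pos += 1


def _call_column(
    col: PileupColumn,
    min_support: int,
    min_concordance: float,
    min_quality: int,
) -> SnpCandidate | None:
    nonref = {b: c for b, c in col.base_counts.items() if b != col.ref_base and b != "N"}
    if not nonref:
        return None
    best = max(nonref.values())
    top = [b for b, c in nonref.items() if c == best]
    if len(top) > 1:  # ambiguous: refuse to call
        return None
    cons = top[0]
    support = nonref[cons]
    concordance = support / col.coverage
    sup_reads = col.supporting_reads[cons]
    max_q = max(sr.base_quality for sr in sup_reads)
    if support < min_support or concordance < min_concordance or max_q < min_quality:
        return None
    all_reads = [sr for srs in col.supporting_reads.values() for sr in srs]
    return SnpCandidate(
        chrom=col.chrom,
        position=col.position,
        ref_base=col.ref_base,
        cons_base=cons,
        support=support,
        concordance=concordance,
        max_quality=max_q,
        avg_hits=sum(sr.n_hits for sr in all_reads) / len(all_reads),
        read_type=all(sr.n_hits == 1 for sr in sup_reads),
    )


def call_snps(
    pileup: Iterable[PileupColumn],
    min_support: int = 2,
    min_concordance: float = 0.8,
    min_quality: int = 20,
) -> list[SnpCandidate]:
    """Qualify substitution candidates from a pileup stream.

    A call requires the most frequent non-reference base to reach
    ``min_support`` reads, ``support / coverage >= min_concordance`` and a best
    supporting base quality of at least ``min_quality``.  Ties between
    non-reference bases are refused rather than broken arbitrarily.
    """
    if min_support < 0 or min_quality < 0:
        raise ValueError("thresholds must be non-negative")
    if not 0.0 < min_concordance <= 1.0:
        raise ValueError("min_concordance must be in (0, 1]")
    out = []
    for col in pileup:
        snp = _call_column(col, min_support, min_concordance, min_quality)
        if snp is not None:
            out.append(snp)
    return out


def call_snps_with_support(
    pileup: Iterable[PileupColumn],
    min_support: int = 2,
    min_concordance: float = 0.8,
    min_quality: int = 20,
) -> list[tuple[SnpCandidate, list[SupportRead]]]:
    """Like :func:`call_snps` but keeps the supporting reads of each call,
    as needed by the independent-molecule filter downstream."""
    out = []
    for col in pileup:
        snp = _call_column(col, min_support, min_concordance, min_quality)
        if snp is not None:
            out.append((snp, list(col.supporting_reads[snp.cons_base])))
    return out
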