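"""Reliability screens applied between SNP calling and marker design.

Two independent screens:

* the *staggered-read* filter on the resequenced haplotype's evidence —
  reads sharing identical (start, end, strand) are presumed PCR duplicates of
  one template molecule, so a SNP seen only in such reads may be a PCR-born
  mutation and is rejected unless at least two independent molecules show it;

* reference-side validation — the window around the SNP must be single-copy
  in the reference genome (counting both strands), and may additionally be
  required to match supporting evidence sequences exactly (one transcript, or
  genomic sequence from at least two distinct BAC clones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .restriction import reverse_complement

if TYPE_CHECKING:  # pragma: no cover
    from .seqio import SequenceRecord
    from .snpcall import SnpCandidate

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvidenceBundle:
    """Supporting-evidence sequences: transcripts (cDNA/EST role) and BAC
    genomic sequences with distinct source ids."""

    transcripts: tuple = ()
    bac_sequences: tuple = ()

    def __post_init__(self) -> None:
        for group, label in ((self.transcripts, "transcript"), (self.bac_sequences, "BAC")):
            ids = [r.id for r in group]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate {label} ids in evidence bundle")


def distinct_molecule_count(snp: "SnpCandidate", reads: Sequence) -> int:
    """Number of distinct template molecules among the supporting reads.

    Reads sharing (start, end, strand) are collapsed: identical coordinates
    on the same strand are what PCR duplicates of a single fragment look like,
    while staggered ends demonstrate independent molecules.  ``reads`` may be
    full aligned reads or the per-position support tuples from the pileup.
    """
    keys = set()
    for r in reads:
        if not (r.start <= snp.position <= r.end):
            raise ValueError(
                f"read ({r.start},{r.end},{r.strand}) does not cover SNP position {snp.position}"
            )
        keys.add((r.start, r.end, r.strand))
    return len(keys)


def staggered_filter(
    snps: Sequence["SnpCandidate"],
    reads_by_snp: Mapping,
    min_molecules: int = 2,
) -> tuple[list["SnpCandidate"], list["SnpCandidate"]]:
    """Partition SNPs into (kept, rejected) by independent-molecule count.

    ``reads_by_snp`` maps each SNP (or its ``(chrom, position)``) to its
    supporting reads.  A SNP is kept iff its supporting reads span at least
    ``min_molecules`` distinct (start, end, strand) coordinates.
    """
    if min_molecules < 1:
        raise ValueError("min_molecules must be >= 1")
    kept, rejected = [], []
    for snp in snps:
        reads = reads_by_snp.get(snp)
        if reads is None:
            reads = reads_by_snp.get((snp.chrom, snp.position), [])
        n = distinct_molecule_count(snp, reads)
        (kept if n >= min_molecules else rejected).append(snp)
    return kept, rejected


def _count_overlapping(text: str, pattern: str) -> int:
    count = start = 0
    while True:
        i = text.find(pattern, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def genome_occurrences(genome: Sequence["SequenceRecord"], query: str) -> int:
    """Occurrences of ``query`` in the genome counting both strands
    (overlapping matches included)."""
    rc = reverse_complement(query)
    total = 0
    for rec in genome:
        total += _count_overlapping(rec.sequence, query)
        if rc != query:
            total += _count_overlapping(rec.sequence, rc)
    return total


def single_copy_check(
    genome: Sequence["SequenceRecord"],
    chrom: str,
    position: int,
    window_half: int = 50,
) -> bool:
    """True iff the window ``position +/- window_half`` occurs exactly once in
    the genome counting both strands.  The window must lie fully inside the
    chromosome and contain no N."""
    seqs = {r.id: r.sequence for r in genome}
    if chrom not in seqs:
        raise ValueError(f"unknown chromosome {chrom!r}")
    ref = seqs[chrom]
    lo, hi = position - window_half, position + window_half  # 1-based inclusive
    if lo < 1 or hi > len(ref):
        raise ValueError(
            f"window {chrom}:{lo}-{hi} extends outside the chromosome (length {len(ref)})"
        )
    window = ref[lo - 1 : hi]
    if "N" in window:
        raise ValueError(f"window {chrom}:{lo}-{hi} contains N")
    return genome_occurrences(genome, window) == 1


def evidence_validation(window_seq: str, evidence: EvidenceBundle) -> bool:
    """True iff ``window_seq`` matches supporting evidence exactly.

    The rule: a 100% match (either strand) inside at least one transcript, or
    inside the genomic sequences of at least two distinct BAC clones.
    """
    if not window_seq:
        raise ValueError("window sequence must be non-empty")
    rc = reverse_complement(window_seq)

    def hit(rec) -> bool:
        return window_seq in rec.sequence or rc in rec.sequence

    if any(hit(t) for t in evidence.transcripts):
        return True
    bac_ids = {b.id for b in evidence.bac_sequences if hit(b)}
    return len(bac_ids) >= 2
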