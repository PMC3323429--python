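"""File formats for the marker pipeline.

Everything external is plain text: multi-record FASTA, a SAM subset (75 bp
ungapped matches), TSV variant tables with the pileup evidence columns, the
enzyme table, and the marker report.  All genomic coordinates are 1-based
inclusive throughout the package, matching SAM.

Readers and writers are exact inverses on valid data; malformed input raises
:class:`ParseError` naming the offending line or field.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO as _BioSeqIO

from .restriction import Enzyme

if TYPE_CHECKING:  # pragma: no cover
    from .markerdesign import SbpMarker
    from .snpcall import SnpCandidate

log = logging.getLogger(__name__)

_ALPHABET = set("ACGTN")

VARIANT_COLUMNS = [
    "Name", "Chromosome", "Position", "RefBase", "ConsBase",
    "ReadType", "Support", "Concordance", "MaxQuality", "AvgHits",
]

MARKER_COLUMNS = [
    "Chromosome", "Name", "ForwardPrimer", "ReversePrimer", "Enzyme",
    "AmpliconSizeHapA", "AmpliconSizeHapB", "FragmentsHapA", "FragmentsHapB",
    "Resolvable",
]


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}, uppercased on read."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedRead:
    """A mapped short read; ``bases`` are reference-oriented.

    ``n_hits`` is the number of alignment locations genome-wide (the NH tag),
    used downstream for the repetitiveness evidence fields.
    """

    read_id: str
    chrom: str
    start: int  # 1-based inclusive
    strand: str  # '+' or '-'
    bases: str
    quals: tuple[int, ...]
    n_hits: int = 1

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError(f"{self.read_id}: quals/bases length mismatch")
        if self.start < 1:
            raise ValueError(f"{self.read_id}: start must be >= 1")

    @property
    def end(self) -> int:
        """1-based inclusive end coordinate."""
        return self.start + len(self.bases) - 1


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA; sequences uppercased and alphabet-checked."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} contains illegal character(s) "
                f"{sorted(bad)} (alphabet is A,C,G,T,N)"
            )
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM subset

_CIGAR_MATCH = re.compile(r"^(\d+)[M=]$")
_NH_TAG = re.compile(r"\bNH:i:(\d+)\b")


def read_alignments(
    path: str | Path,
    genome: Sequence[SequenceRecord],
    stats: dict | None = None,
) -> Iterator[AlignedRead]:
    """Stream reads from a SAM text file (header optional).

    Only simple ungapped records (single ``M``/``=`` CIGAR run) are accepted;
    unmapped and indel/clipped records are skipped with a logged count.  A read
    mapped to a chromosome absent from ``genome``, or extending past its
    chromosome end, is an error.
    """
    chrom_len = {r.id: len(r.sequence) for r in genome}
    counters = stats if stats is not None else {}
    counters.setdefault("accepted", 0)
    counters.setdefault("unmapped_skipped", 0)
    counters.setdefault("cigar_skipped", 0)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ParseError(f"{path}:{lineno}: SAM record has {len(fields)} fields (need 11)")
            qname, flag_s, rname, pos_s, _mapq, cigar = fields[:6]
            seq, qual = fields[9], fields[10]
            try:
                flag, pos = int(flag_s), int(pos_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric FLAG/POS") from None
            if flag & 0x4 or rname == "*":
                counters["unmapped_skipped"] += 1
                continue
            m = _CIGAR_MATCH.match(cigar)
            if m is None or int(m.group(1)) != len(seq):
                counters["cigar_skipped"] += 1
                continue
            if rname not in chrom_len:
                raise ParseError(f"{path}:{lineno}: read {qname!r} mapped to unknown chromosome {rname!r}")
            seq = seq.upper()
            if pos + len(seq) - 1 > chrom_len[rname]:
                raise ParseError(f"{path}:{lineno}: read {qname!r} extends past the end of {rname!r}")
            quals = tuple(ord(c) - 33 for c in qual) if qual != "*" else (30,) * len(seq)
            nh = _NH_TAG.search("\t".join(fields[11:]))
            counters["accepted"] += 1
            yield AlignedRead(
                read_id=qname,
                chrom=rname,
                start=pos,
                strand="-" if flag & 0x10 else "+",
                bases=seq,
                quals=quals,
                n_hits=int(nh.group(1)) if nh else 1,
            )
    log.info(
        "read_alignments(%s): %d accepted, %d unmapped skipped, %d non-simple CIGAR skipped",
        path, counters["accepted"], counters["unmapped_skipped"], counters["cigar_skipped"],
    )


def write_sam(
    reads: Iterable[AlignedRead],
    genome: Sequence[SequenceRecord],
    path: str | Path,
) -> None:
    """Write reads as a minimal SAM file with an @SQ header."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rec in genome:
            fh.write(f"@SQ\tSN:{rec.id}\tLN:{len(rec.sequence)}\n")
        for r in reads:
            flag = 16 if r.strand == "-" else 0
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(
                f"{r.read_id}\t{flag}\t{r.chrom}\t{r.start}\t60\t{len(r.bases)}M"
                f"\t*\t0\t0\t{r.bases}\t{qual}\tNH:i:{r.n_hits}\n"
            )


# ---------------------------------------------------------------------------
# Variant table (pileup-evidence columns)


def write_variant_table(snps: Sequence["SnpCandidate"], path: str | Path, name: str = "sbp") -> None:
    """TSV with the evidence columns; ``name`` labels the project column."""
    rows = [
        {
            "Name": name,
            "Chromosome": s.chrom,
            "Position": s.position,
            "RefBase": s.ref_base,
            "ConsBase": s.cons_base,
            "ReadType": int(s.read_type),
            "Support": s.support,
            "Concordance": repr(s.concordance),
            "MaxQuality": s.max_quality,
            "AvgHits": repr(s.avg_hits),
        }
        for s in snps
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> list["SnpCandidate"]:
    from .snpcall import SnpCandidate

    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty variant table") from None
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    out: list[SnpCandidate] = []
    for i, row in enumerate(df.itertuples(index=False), 2):  # 2 = first data line
        try:
            snp = SnpCandidate(
                chrom=row.Chromosome,
                position=int(row.Position),
                ref_base=row.RefBase,
                cons_base=row.ConsBase,
                support=int(row.Support),
                concordance=float(row.Concordance),
                max_quality=int(row.MaxQuality),
                avg_hits=float(row.AvgHits),
                read_type=bool(int(row.ReadType)),
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from None
        out.append(snp)
    return out


def write_vcf(snps: Sequence["SnpCandidate"], path: str | Path) -> None:
    """Minimal 8-column VCF rendering of the variant table."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SUP,Number=1,Type=Integer,Description="Supporting reads">\n')
        fh.write('##INFO=<ID=CONC,Number=1,Type=Float,Description="Concordance">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps:
            fh.write(
                f"{s.chrom}\t{s.position}\t.\t{s.ref_base}\t{s.cons_base}"
                f"\t{s.max_quality}\t.\tSUP={s.support};CONC={s.concordance:g}\n"
            )


# ---------------------------------------------------------------------------
# Enzyme table


def read_enzyme_table(path: str | Path) -> list[Enzyme]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("name", "site", "cut_top", "cut_bottom"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing enzyme-table column {col!r}")
    enzymes = []
    for i, row in enumerate(df.itertuples(index=False), 2):
        try:
            enzymes.append(
                Enzyme(
                    name=row.name,
                    site=row.site.upper(),
                    cut_top=int(row.cut_top),
                    cut_bottom=int(row.cut_bottom),
                    warning=getattr(row, "warning", ""),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from None
    return enzymes


def write_enzyme_table(enzymes: Sequence[Enzyme], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"name": e.name, "site": e.site, "cut_top": e.cut_top,
             "cut_bottom": e.cut_bottom, "warning": e.warning}
            for e in enzymes
        ],
        columns=["name", "site", "cut_top", "cut_bottom", "warning"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Marker report


def _fmt_fragments(fragments: Sequence[int]) -> str:
    return ",".join(str(f) for f in sorted(fragments, reverse=True))


def write_marker_report(markers: Sequence["SbpMarker"], path: str | Path) -> None:
    rows = [
        {
            "Chromosome": m.chrom,
            "Name": m.name,
            "ForwardPrimer": m.primers.fwd,
            "ReversePrimer": m.primers.rev,
            "Enzyme": m.enzyme,
            "AmpliconSizeHapA": m.amplicon_len_a,
            "AmpliconSizeHapB": m.amplicon_len_b,
            "FragmentsHapA": _fmt_fragments(m.fragments_a),
            "FragmentsHapB": _fmt_fragments(m.fragments_b),
            "Resolvable": int(m.resolvable),
        }
        for m in markers
    ]
    pd.DataFrame(rows, columns=MARKER_COLUMNS).to_csv(path, sep="\t", index=False)


def read_marker_report(path: str | Path) -> pd.DataFrame:
    """Marker report as a DataFrame (used by the ``verify`` stage)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df
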