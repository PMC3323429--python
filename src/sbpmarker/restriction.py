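"""Restriction-enzyme modelling: IUPAC site scanning and virtual digestion.

A recognition site is written 5'->3' on the top strand using the 15-letter
IUPAC alphabet.  Cut offsets are *gap indices relative to the site start in
top-strand coordinates*: an enzyme like TaqI (T^CGA) has ``cut_top=1``; an
outside cutter like BtsCI (GGATG with a 2 nt spacer past the site) has
``cut_top=7``.  ``cut_bottom`` is the bottom-strand nick expressed in the same
top-strand gap coordinate, which is what a site matched on the reverse strand
cleaves the top strand at (mirrored).

Only top-strand cleavage positions define fragment boundaries: agarose gels
measure fragment length, and nick-level stagger is invisible at that
resolution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC codes allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(site_char: str, base: str) -> bool:
    """True iff ``base`` (one of ACGT) is in the expansion of ``site_char``."""
    try:
        expansion = IUPAC[site_char]
    except KeyError:
        raise ValueError(f"unknown IUPAC code {site_char!r}") from None
    if base not in "ACGT":
        raise ValueError(f"base must be one of ACGT, got {base!r}")
    return base in expansion


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease.

    Attributes
    ----------
    name : str
        Enzyme name as used on gels and in marker reports (e.g. ``MspI``).
    site : str
        Recognition sequence, top strand 5'->3', IUPAC alphabet, length >= 4.
    cut_top, cut_bottom : int
        Cleavage gap indices relative to the site start (see module docstring).
    warning : str
        Free-text caveat carried through the enzyme table (e.g. methylation
        sensitivity that the in-silico digest ignores).
    """

    name: str
    site: str
    cut_top: int
    cut_bottom: int
    warning: str = ""

    def __post_init__(self) -> None:
        if len(self.site) < 4:
            raise ValueError(f"{self.name}: recognition site shorter than 4 nt")
        bad = set(self.site) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC site characters {sorted(bad)}")

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.site) == self.site


@dataclass(frozen=True)
class CutSite:
    position: int  # 1-based start of the matched site on the scanned sequence
    strand: str  # '+' or '-'
    enzyme: str
    cleavage_pos: int  # 0-based gap index where the top strand is severed


@dataclass(frozen=True)
class DigestResult:
    """Ordered fragment lengths of a complete single-enzyme digest."""

    fragment_lengths: tuple[int, ...]
    enzyme: str

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fragment_lengths):
            raise ValueError("digest fragments must be positive")


def _site_regex(site: str) -> re.Pattern[str]:
    # lookahead so overlapping occurrences are all reported
    body = "".join("[" + "".join(sorted(IUPAC[c])) + "]" for c in site)
    return re.compile(f"(?=({body}))")


def scan_sites(sequence: str, enzyme: Enzyme) -> list[CutSite]:
    """All recognition-site matches of ``enzyme`` on either strand.

    Positions are 1-based starts on the scanned (top) sequence.  Palindromic
    sites are reported once per position, as '+'.  Matches whose cleavage gap
    falls outside ``[0, len(sequence)]`` are discarded: the physical cut would
    miss the molecule.
    """
    n = len(sequence)
    sites: list[CutSite] = []
    for m in _site_regex(enzyme.site).finditer(sequence):
        p0 = m.start()
        gap = p0 + enzyme.cut_top
        if 0 <= gap <= n:
            sites.append(CutSite(p0 + 1, "+", enzyme.name, gap))
    if not enzyme.is_palindromic:
        rc = reverse_complement(enzyme.site)
        length = len(enzyme.site)
        for m in _site_regex(rc).finditer(sequence):
            p0 = m.start()
            # a reverse-strand match cleaves the top strand at the mirrored
            # bottom-strand offset
            gap = p0 + length - enzyme.cut_bottom
            if 0 <= gap <= n:
                sites.append(CutSite(p0 + 1, "-", enzyme.name, gap))
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def digest(sequence: str, enzyme: Enzyme) -> DigestResult:
    """Complete digest: fragment lengths between deduplicated cleavage gaps.

    Cleavage gaps at the very ends of the molecule do not shorten it and are
    ignored; a sequence with no internal cleavage yields one full-length
    fragment.
    """
    n = len(sequence)
    gaps = sorted({s.cleavage_pos for s in scan_sites(sequence, enzyme) if 0 < s.cleavage_pos < n})
    bounds = [0, *gaps, n]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    assert sum(fragments) == n, "digest fragments must sum to parent length"
    return DigestResult(fragments, enzyme.name)


def differential_enzymes(
    amplicon_a: str,
    amplicon_b: str,
    db: Sequence[Enzyme],
    gel,
) -> list[tuple[Enzyme, DigestResult, DigestResult]]:
    """Enzymes whose digests of the two haplotype amplicons are gel-separable.

    ``gel`` is any object with a ``resolvable(fragments_a, fragments_b)``
    method (see :class:`sbpmarker.markerdesign.GelModel`).  Results are sorted
    by total band count then enzyme name, so the simplest assay ranks first.
    """
    if not amplicon_a or not amplicon_b:
        raise ValueError("amplicons must be non-empty")
    hits = []
    for enz in db:
        da = digest(amplicon_a, enz)
        db_ = digest(amplicon_b, enz)
        if gel.resolvable(da.fragment_lengths, db_.fragment_lengths):
            hits.append((enz, da, db_))
    hits.sort(key=lambda t: (len(t[1].fragment_lengths) + len(t[2].fragment_lengths), t[0].name))
    return hits


def load_default_enzymes() -> list[Enzyme]:
    """The bundled enzyme table (user-replaceable TSV, see seqio)."""
    from . import seqio

    with resources.as_file(resources.files("sbpmarker").joinpath("data/enzymes.tsv")) as p:
        return seqio.read_enzyme_table(p)
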