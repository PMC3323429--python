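"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive expected behaviour from first
principles (per-character comparisons, exhaustive enumeration) and share no
code with the implementation paths they check.
"""

from __future__ import annotations

import random

import pytest

from sbpmarker import load_default_enzymes
from sbpmarker.markerdesign import GelModel

# Independent IUPAC expansion table (typed out, not imported from the package)
ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
ORACLE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq: str) -> str:
    return "".join(ORACLE_COMP[b] for b in reversed(seq))


def oracle_scan(sequence: str, enzyme) -> list[tuple[int, str, int]]:
    """Every (1-based position, strand, top-strand cleavage gap) by testing
    every offset on both strands with per-character IUPAC comparison."""
    n, L = len(sequence), len(enzyme.site)
    hits = []
    site = enzyme.site
    # reverse complement of an IUPAC site, built from the oracle's own table
    comp_iupac = {}
    for code, bases in ORACLE_IUPAC.items():
        comp = frozenset(ORACLE_COMP[b] for b in bases)
        comp_iupac[code] = next(k for k, v in ORACLE_IUPAC.items() if frozenset(v) == comp)
    rc_site = "".join(comp_iupac[c] for c in reversed(site))
    palindromic = rc_site == site
    for p in range(n - L + 1):
        if all(sequence[p + k] in ORACLE_IUPAC[site[k]] for k in range(L)):
            gap = p + enzyme.cut_top
            if 0 <= gap <= n:
                hits.append((p + 1, "+", gap))
        if not palindromic and all(
            sequence[p + k] in ORACLE_IUPAC[rc_site[k]] for k in range(L)
        ):
            gap = p + L - enzyme.cut_bottom
            if 0 <= gap <= n:
                hits.append((p + 1, "-", gap))
    return sorted(hits)


def oracle_digest(sequence: str, enzyme) -> list[int]:
    n = len(sequence)
    gaps = sorted({g for _, _, g in oracle_scan(sequence, enzyme) if 0 < g < n})
    bounds = [0, *gaps, n]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def oracle_count_occurrences(genome_seqs: list[str], query: str) -> int:
    """Overlapping occurrence count on both strands by naive scan."""
    total = 0
    queries = {query, oracle_revcomp(query)}
    for seq in genome_seqs:
        for q in queries:
            total += sum(1 for i in range(len(seq) - len(q) + 1) if seq[i : i + len(q)] == q)
    return total


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def enzyme_db():
    return load_default_enzymes()


@pytest.fixture(scope="session")
def enzymes_by_name(enzyme_db):
    return {e.name: e for e in enzyme_db}


@pytest.fixture
def gel():
    return GelModel()
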