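"""Seeded generator of two-haplotype study fixtures.

Emulates the study design the pipeline assumes: a reference haplotype
(ecotype A), a resequenced haplotype (ecotype B) differing only at planted
SNPs, and 75 nt reads of B carrying PCR-duplicate structure (a fraction of
template molecules re-sequenced at identical coordinates).  Reads carry their
true coordinates, so alignment — not the contribution under test — is
bypassed.

A fraction of the planted SNPs is placed inside a concretized recognition site
of a bundled enzyme so that one haplotype is cut and the other is not; the
truth table records every planting decision together with whether the SNP is
actually convertible into a gel-resolvable marker (decided by running the
designer with perfect knowledge of the SNP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import markerdesign, restriction
from .restriction import IUPAC, Enzyme
from .seqio import AlignedRead, SequenceRecord

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# planted SNPs are kept at least this far apart and from chromosome ends, so
# every design window (+/- 300 nt) sees exactly one polymorphism
MIN_SNP_SPACING = 701


@dataclass(frozen=True)
class SimConfig:
    genome_len: int = 200_000
    n_chroms: int = 1
    n_snps: int = 100
    frac_site_breaking: float = 0.5
    read_len: int = 75
    coverage: float = 3.0  # the study's ~3X genome depth
    pcr_dup_rate: float = 0.3
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_site_breaking", "pcr_dup_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_len <= 10 * self.read_len:
            raise ValueError("genome_len must exceed 10x read_len")
        if self.n_chroms < 1 or self.n_snps < 0:
            raise ValueError("n_chroms >= 1 and n_snps >= 0 required")


@dataclass(frozen=True)
class TruthRow:
    chrom: str
    position: int
    ref_base: str
    alt_base: str
    planted_enzyme: str  # empty when the SNP was placed without site intent
    expected_convertible: bool


def _plant_positions(rng, chrom_lens: dict[str, int], n_snps: int) -> list[tuple[str, int]]:
    total = sum(chrom_lens.values())
    chosen: list[tuple[str, int]] = []
    remaining = n_snps
    items = list(chrom_lens.items())
    for k, (chrom, L) in enumerate(items):
        n_here = remaining if k == len(items) - 1 else int(round(n_snps * L / total))
        n_here = min(n_here, remaining)
        usable = L - 2 * MIN_SNP_SPACING
        if n_here > 0:
            span = usable // n_here if n_here else usable
            if usable <= 0 or span < MIN_SNP_SPACING + 1:
                raise ValueError(
                    f"{n_here} SNPs too dense for chromosome {chrom!r} of length {L}: "
                    f"need >= {MIN_SNP_SPACING + 1} nt per SNP window"
                )
            for i in range(n_here):
                seg_start = MIN_SNP_SPACING + i * span
                offset = int(rng.integers(0, span - MIN_SNP_SPACING))
                chosen.append((chrom, seg_start + offset + 1))  # 1-based
        remaining -= n_here
    return chosen


def make_haplotype_pair(
    config: SimConfig,
    enzyme_db: Sequence[Enzyme] | None = None,
    gel: markerdesign.GelModel | None = None,
    design_config: markerdesign.DesignConfig | None = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[TruthRow]]:
    """Reference genome, SNP-substituted twin, and the truth table."""
    db = enzyme_db if enzyme_db is not None else restriction.load_default_enzymes()
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    base_arrays = {
        c: rng.integers(0, 4, config.genome_len) for c in chrom_names
    }
    seq_a = {c: list(_BASES[a]) for c, a in base_arrays.items()}

    positions = _plant_positions(rng, {c: config.genome_len for c in chrom_names}, config.n_snps)
    n_break = int(round(config.frac_site_breaking * len(positions)))
    breaking = set(rng.choice(len(positions), size=n_break, replace=False).tolist()) if n_break else set()

    subs: dict[tuple[str, int], tuple[str, str, str]] = {}  # (chrom,pos) -> ref, alt, enzyme
    for idx, (chrom, pos) in enumerate(positions):
        if idx in breaking:
            enz = db[int(rng.integers(0, len(db)))]
            site = "".join(
                sorted(IUPAC[c])[int(rng.integers(0, len(IUPAC[c])))] for c in enz.site
            )
            mutable = [m for m, c in enumerate(enz.site) if len(IUPAC[c]) < 4]
            m = mutable[int(rng.integers(0, len(mutable)))]
            outside = sorted(set("ACGT") - IUPAC[enz.site[m]])
            breaker = outside[int(rng.integers(0, len(outside)))]
            start0 = pos - 1 - m  # 0-based site start so the SNP sits at site[m]
            for k, ch in enumerate(site):
                seq_a[chrom][start0 + k] = ch
            if rng.random() < 0.5:  # site intact in A, broken in B
                ref, alt = site[m], breaker
            else:  # site intact in B, broken in A
                ref, alt = breaker, site[m]
                seq_a[chrom][pos - 1] = ref
            subs[(chrom, pos)] = (ref, alt, enz.name)
        else:
            ref = seq_a[chrom][pos - 1]
            others = [b for b in "ACGT" if b != ref]
            subs[(chrom, pos)] = (ref, others[int(rng.integers(0, 3))], "")

    genome_a = [SequenceRecord(c, "".join(seq_a[c])) for c in chrom_names]
    seq_b = {c: list(s) for c, s in seq_a.items()}
    for (chrom, pos), (_ref, alt, _e) in subs.items():
        seq_b[chrom][pos - 1] = alt
    genome_b = [SequenceRecord(c, "".join(seq_b[c])) for c in chrom_names]

    truth: list[TruthRow] = []
    for chrom, pos in sorted(positions):
        ref, alt, enz_name = subs[(chrom, pos)]
        truth.append(
            TruthRow(
                chrom=chrom,
                position=pos,
                ref_base=ref,
                alt_base=alt,
                planted_enzyme=enz_name,
                expected_convertible=_convertible(genome_a, chrom, pos, ref, alt, db, gel, design_config),
            )
        )
    return genome_a, genome_b, truth


def _convertible(genome_a, chrom, pos, ref, alt, db, gel, design_config) -> bool:
    from .snpcall import SnpCandidate

    snp = SnpCandidate(
        chrom=chrom, position=pos, ref_base=ref, cons_base=alt,
        support=2, concordance=1.0, max_quality=30, avg_hits=1.0, read_type=True,
    )
    result = markerdesign.design_marker(genome_a, snp, db, gel, design_config)
    return isinstance(result, markerdesign.SbpMarker)


def simulate_reads(
    genome_b: Sequence[SequenceRecord],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[AlignedRead]:
    """Uniformly placed reads of haplotype B with PCR-duplicate structure.

    Each template molecule is emitted once; with probability ``pcr_dup_rate``
    an exact-coordinate duplicate is added (same start/end/strand — what a
    PCR copy of the same fragment end looks like).  Sequencing errors are
    drawn independently per emitted read at ``error_rate`` per base; qualities
    are Phred 30, errored bases 10.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    reads: list[AlignedRead] = []
    rl = config.read_len
    base_q, err_q = 30, 10
    for rec in genome_b:
        L = len(rec.sequence)
        n_frags = int(round(config.coverage * L / rl))
        starts = rng.integers(1, L - rl + 2, n_frags)
        strands = rng.integers(0, 2, n_frags)
        dup_flags = rng.random(n_frags) < config.pcr_dup_rate
        for i in range(n_frags):
            start = int(starts[i])
            strand = "-" if strands[i] else "+"
            template = rec.sequence[start - 1 : start - 1 + rl]
            n_copies = 2 if dup_flags[i] else 1
            for copy in range(n_copies):
                if config.error_rate > 0.0:
                    errs = np.flatnonzero(rng.random(rl) < config.error_rate)
                else:
                    errs = ()
                bases = list(template)
                quals = [base_q] * rl
                for e in errs:
                    wrong = [b for b in "ACGT" if b != bases[e]]
                    bases[e] = wrong[int(rng.integers(0, 3))]
                    quals[e] = err_q
                suffix = "" if copy == 0 else f".dup{copy}"
                reads.append(
                    AlignedRead(
                        read_id=f"sim:{rec.id}:{i}{suffix}",
                        chrom=rec.id,
                        start=start,
                        strand=strand,
                        bases="".join(bases),
                        quals=tuple(quals),
                        n_hits=1,
                    )
                )
    return reads


# ---------------------------------------------------------------------------
# Truth table TSV

_TRUTH_COLUMNS = ["Chromosome", "Position", "RefBase", "AltBase", "PlantedEnzyme", "ExpectedConvertible"]


def write_truth(truth: Sequence[TruthRow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "Chromosome": t.chrom,
                "Position": t.position,
                "RefBase": t.ref_base,
                "AltBase": t.alt_base,
                "PlantedEnzyme": t.planted_enzyme,
                "ExpectedConvertible": int(t.expected_convertible),
            }
            for t in truth
        ],
        columns=_TRUTH_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[TruthRow]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        TruthRow(
            chrom=r.Chromosome,
            position=int(r.Position),
            ref_base=r.RefBase,
            alt_base=r.AltBase,
            planted_enzyme=r.PlantedEnzyme,
            expected_convertible=bool(int(r.ExpectedConvertible)),
        )
        for r in df.itertuples(index=False)
    ]
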