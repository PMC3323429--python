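# Methods

## Scope and data model

The package converts single-nucleotide differences between two haplotypes of
the same species into gel-scorable restriction assays.  All coordinates are
1-based inclusive (the SAM convention) throughout.  Reads enter already
aligned — re-implementing a short-read aligner is out of scope — as a SAM
text subset restricted to ungapped single match-run records; indel or clipped
alignments are skipped with a logged count, because the marker model is a
point substitution and 75 nt ungapped matches are the evidence it consumes.
Genomes may contain N, but no designed amplicon, window or primer may.

## SNP qualification

A pileup column carries the reference base, per-base read counts and, per
base, the supporting reads' (start, end, strand, hits, base quality).  A SNP
candidate is the most frequent non-reference base when it reaches
`min_support` reads (default 2), concordance `support/coverage ≥ 0.8`, and a
best supporting base quality of ≥ 20 Phred.  Ties between two non-reference
bases refuse to call: reproducible and conservative beats arbitrary.  The
thresholds are defaults of this implementation, chosen where the upstream
tooling's exact settings are not public; they are all CLI-configurable.
`avg_hits` averages genome-wide alignment hit counts over *all* covering
reads; the concordance denominator is total coverage (repetitive reads
included), and the `read_type` flag records whether every supporting read was
uniquely mapped.

## Reliability screens

**Independent molecules.**  Sequencing libraries amplified by PCR can present
one template molecule many times; a polymerase error in an early cycle then
masquerades as a SNP.  Overlapping reads with *staggered* ends demonstrate
distinct template molecules, so the filter counts distinct
(start, end, strand) tuples among supporting reads and requires ≥ 2.  Strand
is part of the key because opposite-strand reads cannot be PCR copies of the
same sequenced fragment end.  Adding an exact duplicate of any read never
changes a decision (tested as an invariant).

**Reference-side validation.**  The window around the SNP (default ± 50 nt,
configurable) must occur exactly once in the reference genome counting both
strands — repeat-borne false SNPs and unmappable assays are excluded
together.  Optionally the window must also match supporting evidence at 100%
identity: one transcript suffices (independent molecule type), while genomic
evidence needs at least two BAC clones with distinct ids (two independent
clones guard against a single-clone sequencing error).  Whether the full
window or only the SNP locus must match is a genuinely open choice; the
window length is a parameter, and the full window is required here because a
marker needs correct flanking sequence, not just a correct SNP base.

## Restriction model

Enzymes are rows of a replaceable TSV: name, IUPAC recognition site, and two
cut offsets expressed as *gap indices from the site start in top-strand
coordinates* (TaqI `T^CGA` → `cut_top=1, cut_bottom=3`; the outside cutter
BtsCI `GGATG(2/0)` → `7, 5`).  Scanning matches the site and its reverse
complement at every offset (overlaps included; palindromic sites reported
once); a reverse-strand match cleaves the top strand at the mirrored bottom
offset `p + |site| − cut_bottom`.  Digestion keeps only top-strand cleavage
points — agarose gels measure length, not nick stagger — deduplicates them,
and returns the inter-cut fragment lengths, which always sum to the parent
length (asserted).  Cleavage points falling outside the molecule are
discarded: the physical digest would not shorten the fragment.  DpnI's
methylation requirement is ignored (flagged in the table's warning column);
in-silico methylation state is unknowable here.

## Gel model

A 4% (w/v) agarose gel resolves roughly the 40–600 nt range.  The verdict
drops fragments below `min_fragment` (40 nt) from both patterns, then calls
the pair resolvable iff the surviving multisets differ *and* some band in one
pattern has no counterpart in the other within
`max(min_diff, min_rel_diff × length)` (defaults 15 nt and 8%).  The
absolute floor models band thickness, the relative term models resolution
decay with size; both are configurable and deliberately conservative so that
an emitted marker is easy to score by eye.

## Primer and amplicon design

Candidate primers are exhaustively enumerated on each side of the SNP under:
length 18–27 nt, GC 30–70%, Wallace-rule Tm (2(A+T) + 4(G+C)) within
48–64 °C, pair ΔTm ≤ 5 °C, identical sequence in both haplotypes (no overlap
with the SNP or any listed polymorphism), and exact-match uniqueness, both
strands, in both haplotype genomes — stricter than strictly necessary, but it
provably prevents multi-product PCR.  The Wallace rule was chosen over
nearest-neighbor thermodynamics because the primers are short, the rule is
the bench convention at these lengths, and it is exactly testable; annealing
temperatures in the reported range correspond to standard 50–55 °C cycling.
Pairs are ranked by |product − 200 nt| with deterministic positional
tie-breaks; the accepted product range is 80–600 nt, reflecting what a 4% gel
and the target-size intent jointly allow.

`design_marker` composes the stages lazily: haplotype windows (default
± 300 nt) → a pre-filter keeping only enzymes whose site sets differ between
the two windows (an amplicon digest can only differ where the windows do) →
ranked primer pairs → differential digest under the gel model (candidates
sorted by total band count then enzyme name, so the simplest assay wins) →
in-silico PCR on both haplotype genomes, requiring exactly one product each
that equals the window slice and reproduces the reported fragments.  The
first fully verified combination is returned; otherwise a rejection record
names the first stage with no viable candidate.  In-silico PCR pairs exact
forward-primer matches with exact reverse-complemented reverse-primer matches
and fails on zero or multiple products.  Published primer pairs from the
field's marker tables may violate the designer's ΔTm constraint, so the PCR
routine also accepts a plain `(fwd, rev)` tuple.

Marker names follow `SBP<chromosome>_<megabases>` with the position rounded
half-up to two decimals.

## Synthetic data

The simulator emulates the study design the pipeline assumes: a uniform
i.i.d. ACGT reference, a twin genome differing at planted SNPs, and 75 nt
reads at a chosen mean depth (default 3×, the depth regime the method was
built for) with PCR-duplicate structure (default rate 0.3) and per-base
errors (default 0.005, a typical early-Illumina figure; errored bases get
Phred 10 against a constant 30).  Half the SNPs (configurable) are planted
inside a concretized recognition site of a bundled enzyme, broken in one
haplotype.  Planted SNPs keep ≥ 701 nt spacing and margin, so every design
window contains exactly one polymorphism; reads carry true coordinates, so
alignment is bypassed.

`expected_convertible` in the truth table is decided by running the designer
with perfect knowledge of the planted SNP, not from the planting intent
alone: a SNP planted without site intent can still create or destroy a site
of one of the 13 enzymes by chance, and a planted site can fail primer
constraints.  This keeps the truth consistent with the designability
definition; the design stage itself is validated independently against
brute-force oracles (exhaustive primer enumeration, per-character site
scanning), so the end-to-end comparison measures the read-evidence path, not
the designer against itself.

What the simulator does **not** model: indels and structural variants, repeat
families (uniqueness failures are exercised with explicitly planted
duplications instead), GC-biased coverage, realistic quality-score profiles,
and methylation.  Passing tests therefore demonstrate the logic of the
pipeline under its own assumptions, not performance on real libraries, where
repetitive sequence and coverage bias will lower yield.

## Problem sizes and determinism

The acceptance script runs, per seed: the restriction oracle on 1,000 random
500-mers × 13 enzymes; the staggered filter on 40 kb genomes at duplication
rates 0/0.5/1; marker recovery on one 200 kb genome with 100 SNPs at 20×
clean coverage; and depth response on ten replicate 50 kb genomes at 3/10/20×.
These sizes give stable statistics (recovery fractions separated by far more
than sampling noise) while a full run stays around a minute.  Every random
draw descends from the `--seed` argument; identical seeds give byte-identical
outputs.

## Known limitations

Substitutions only — length polymorphisms show up as differing amplicon sizes
when present in the input variant table but are not designed for, and
mismatch-primer (dCAPS) rescue of SNPs with no natural site differential is
deliberately out of scope.  Primer uniqueness is exact-match, so a primer
differing from a second locus by one base still passes; thermodynamic dimer
and hairpin screening is not performed.  Single-enzyme digests only: rows
listing several enzymes are alternatives, never combined digests.
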