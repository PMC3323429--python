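# sbpmarker

Design **co-dominant CAPS-style markers from two known haplotype sequences**
("sequence based polymorphic" markers).  Given a reference genome (haplotype A)
and short-read evidence for a second haplotype (B), the package:

1. builds per-position pileups from 75 nt aligned reads and qualifies SNP
   candidates with their evidence fields (support, concordance, best base
   quality, mean alignment hits, repetitiveness flag);
2. screens candidates for reliability — a SNP must be seen in **at least two
   staggered reads** (reads sharing identical start/end/strand are presumed
   PCR duplicates of one template molecule, so PCR-born mutations are
   excluded), and its reference window must be **single-copy** in the genome
   and, optionally, match transcript or multi-BAC evidence at 100% identity;
3. converts each surviving SNP into a **restriction-site differential**: an
   enzyme whose recognition site is created or destroyed by the substitution;
4. designs a small PCR amplicon (~200 bp) around the SNP whose single-enzyme
   digests of the two haplotypes a **4% agarose gel** can tell apart, verifies
   it by in-silico PCR on both haplotypes, and emits a marker report row
   (name, primer pair, enzyme, amplicon sizes, fragment sizes per haplotype).

Because both digest patterns are visible simultaneously, the assays are
co-dominant: heterozygotes show both haplotypes' bands.  The intended users
are mapping and breeding labs that have an assembled reference plus cheap
resequencing of a second accession and want gel-scorable markers for chosen
genomic regions.

## The model in brief

A SNP at position *p* with reference base *r* and consensus base *c* is
reported when the pileup satisfies

    support(c) ≥ s_min,   support(c) / coverage ≥ k_min,   maxQ(c) ≥ q_min

(defaults 2, 0.8, Phred 20; ties between non-reference bases are refused).
Independent-molecule support is the number of distinct (start, end, strand)
tuples among reads carrying *c* — the staggered-read count — and must be ≥ 2.
Restriction sites are scanned on both strands with full IUPAC ambiguity
(e.g. DdeI `CTNAG`, AccI `GTMKAC`), including outside cutters (BtsCI
`GGATG(2/0)`, MboII/HphI `(8/7)`); a digest is the set of top-strand cleavage
points, and two band patterns count as resolvable when, after dropping bands
< 40 nt, one pattern has a band with no counterpart within
max(15 nt, 8% of length) in the other.  Primers follow the Wallace rule
Tm = 2(A+T) + 4(G+C) with length 18–27, GC 30–70%, Tm 48–64 °C, pair
ΔTm ≤ 5 °C, exact single-copy placement on both haplotypes, and the SNP
strictly between the primer footprints.

## Worked example

A fully seeded run on simulated data (no external files needed):

```sh
sbpmarker simulate --genome-len 30000 --n-snps 6 --coverage 15 \
    --frac-site-breaking 0.8 --error-rate 0 --seed 9 --outdir demo
sbpmarker callsnps demo/reads.sam demo/hapA.fasta -o demo/variants.tsv
sbpmarker filter demo/variants.tsv demo/reads.sam demo/hapA.fasta -o demo/filtered.tsv
sbpmarker design demo/filtered.tsv demo/hapA.fasta -o demo/markers.tsv
sbpmarker verify demo/markers.tsv demo/hapA.fasta demo/filtered.tsv
```

which logs

```
simulate: 1 chrom(s), 6 SNPs (5 convertible), 7808 reads -> demo
callsnps: 7808 reads in, 6 SNP candidates out
filter: 6 in, 6 out
design: 6 SNPs in, 5 markers out, 1 rejected
verified 5 marker(s): all amplicons and digests match
```

and writes `demo/markers.tsv`, e.g.

```
Chromosome  Name       ForwardPrimer       ReversePrimer          Enzyme  AmpliconSizeHapA  AmpliconSizeHapB  FragmentsHapA  FragmentsHapB  Resolvable
chr1        SBP1_0.01  TTCTTTCCACAGCTGATGC  CTCTGTGCCTATTCGCCG    MspI    200               200               102,80,18      102,98         1
chr1        SBP1_0.02  ATCTGGGAACGCAACCCT   TCAGGAGATGGTCATTTG    BamHI   200               200               200            177,23         1
```

Reading the MspI row: the same primer pair amplifies 200 bp from both
haplotypes; haplotype A is cut into 102 + 80 + 18, haplotype B into 102 + 98 —
on a 4% gel the 80 nt band versus the 98 nt band scores the genotype, and a
heterozygote shows both.  Marker names encode chromosome and megabase position
(`SBP<chr>_<Mb>`).  The one rejected SNP touched no recognition site in the
enzyme table (`design --rejections` writes the per-SNP failing stage).

Library use mirrors the CLI: `make_haplotype_pair` / `simulate_reads`
(fixtures), `build_pileup` + `call_snps`, `staggered_filter` +
`single_copy_check`, and `design_marker`, which returns either an `SbpMarker`
or a `Rejection` naming the failed stage.

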