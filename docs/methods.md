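# Methods

## Genome model and coordinates

A `MitoGenome` is a circular nucleotide sequence over {A,C,G,T,N} with an
ordered list of typed, stranded features (CDS, tRNA, rRNA, control region,
pseudogene, intergenic). Coordinates are 1-based inclusive everywhere —
the convention of printed mitogenome tables, where a repeat at
10,168–10,185 spans 18 bp. A feature may wrap the origin only on a
circular genome. Ambiguity codes other than N are rejected at parse time;
N is accepted but excluded from every composition denominator.

Incomplete stop codons are common in mitogenomes (the stop is completed by
polyadenylation). The policy here: composition statistics use the full
annotated span; codon-level analyses drop the trailing partial codon
(`drop_incomplete_stop`), and `start_stop_summary` can report the recorded
partial stop padded with dashes ("TA-"). Pseudogenes (e.g. a duplicated
*nad5* fragment) stay in the model but never enter PCG partitions or codon
statistics. Duplicated Leu/Ser tRNAs are kept distinct; bare `trnL`/`trnS`
labels are resolved by anticodon/codon-family notes when present, else by
order of appearance.

## Composition and skews

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C), computed on raw counts of
the sense (deposited) strand for the full genome and on reading-direction
sequences for gene partitions; this is what makes the PCG partition's AT
skew go negative when the *nad* genes sit on the minus strand. Skews with
a zero denominator are reported as missing, with a warning, never as 0.
Reporting rounds half-up (1 decimal for percentages, 3 for skews) because
Python's built-in banker's rounding would disagree with printed tables at
ties; full precision is kept on the objects. `skews_from_percentages`
exists because skews are ratio statistics: a published table of per-base
percentages is a sufficient input, and the worked-value tests exploit
that.

## Codon usage

The genetic code defaults to translation table 5 (invertebrate
mitochondrial: AGA/AGG = Ser, ATA = Met, TGA = Trp); tables 1, 2 and 4 are
selectable. RSCU families split leucine and serine into their two codon
families (Leu1 = CTN, Leu2 = TTR, Ser1 = AGN, Ser2 = TCN), matching how
mitochondrial codon-usage figures are drawn. Stop codons are tallied
separately and excluded from families; a codon in an unused family has
RSCU 0 by definition, and within any used family the RSCU mean is exactly
1. The amino-acid frequency denominator is all translated non-stop codons.
Start-codon tallies group ATA/ATT/ATG under the conventional "ATD" label.

## Nei–Gojobori ka/ks

The NG86 estimator is implemented from first principles rather than
wrapped from an external GUI tool, so that it is scriptable and testable:

* per-codon site counts s = (number of synonymous one-step changes)/3,
  n = 3 − s; mutational changes into stop codons are counted as
  nonsynonymous (the standard convention — MEGA-style implementations may
  differ at the third decimal on short genes);
* pathway averaging for codon pairs differing at k positions enumerates
  all k! orders and averages Sd/Nd over orders avoiding intermediate stop
  codons; if every order crosses a stop, the unrestricted average is used
  with a logged note (rare; keeps Sd+Nd = k exactly);
* Jukes–Cantor correction d = −(3/4)ln(1 − (4/3)p), undefined (reported
  missing) at p ≥ 3/4.

Alignment is an input: the module consumes codon-aligned sequences and
skips codon columns containing gaps, N or in-frame stops pairwise.

Gene-level ω aggregates all unordered taxon pairs as a **ratio of means**
(mean ka / mean ks), which stays defined when individual pairs have
ks ≈ 0 and matches the single-per-gene-value structure of published
bar plots. Because published per-gene ω values rarely state their
aggregation, the mean-of-ratios alternative is always emitted alongside
(`omega_mean_of_ratios`) for comparison.

## Microsatellite scanning

The scanner reports all maximal perfect tandem repeats of primitive 1–6 bp
motifs meeting the minimum-unit thresholds (defaults 12/6/4/3/3/3,
interruption 0 — i.e. only directly adjacent repeats merge into compound
records). Design choices:

* forward-strand scanning, motifs reported as they occur, no canonical
  collapsing (AAAT, TAAA and TTAT are distinct types, as in MISA output);
* only complete units count toward `n_units` and `size`; a trailing
  partial unit is ignored;
* every repeat surfaces once, at its shortest true period: a run whose
  array has a smaller period (ATATAT → AT) is left to the smaller-period
  scan and threshold-tested there;
* N breaks any run; the sequence is treated as linear, so a repeat
  spanning the origin of the circle is not detected (a documented
  limitation shared with standard scanners).

RA = repeats/kb and RD = repeat bp/kb (RA interprets "repeats" as record
count, which is the definition that reproduces the published 0.17/kb for
3 repeats in 17,197 bp). Note that the published relative density for the
same genome (0.64 bp/kb) is inconsistent with the definitional value
(12+18+12 = 42 bp over 17.197 kb = 2.44 bp/kb); this package reports the
definitional value. Location classes are the gene containing the repeat
start (CDS/rRNA/tRNA by name), the control region, or intergenic. The
cross-species summary adds pooled motif-class percentages, the A/T-only
motif fraction, and the Pearson r² (with two-sided p) of repeat count
against genome size, omitted below 3 genomes or under zero variance.

## Supermatrix

`build_supermatrix` concatenates pre-aligned per-gene blocks in a
configurable order (default: nad1, nad4, nad3, cox3, cox1, nad4l, cytb,
atp8, nad6, nad2, cox2, atp6, nad5), records 1-based block coordinates,
and writes FASTA, relaxed PHYLIP and NEXUS with charsets plus RAxML-style
partition files (optionally by codon position). A taxon missing from a
gene is a hard error by default; `allow_missing` gap-fills with a warning.
Amino-acid mode translates each nucleotide block with table 5 before
concatenation. Alignment, trimming, model selection and tree inference are
out of scope — those remain external tools.

## Synthetic data

The generator emulates the study conditions a comparative pentatomid
mitogenomics paper describes: a circular ~15–17 kb molecule, ~74% AT
(default target A 42.5 / T 31.5 / C 15.0 / G 11.0, the composition of the
larger of the two newly sequenced genomes), 13 CDS + 22 tRNA + 2 rRNA in
the ancestral insect gene order with 23 genes on the sense and 14 on the
antisense strand, a 300 bp intergenic spacer and a control region filling
the genome to length. CDS are valid table-5 ORFs (start from
{ATA, ATT, ATG, TTG}, TAA stop, no internal stops); minus-strand genes are
generated in reading orientation and reverse-complemented into the genome
so strand handling is exercised end-to-end. Composition is hit by filling
all non-CDS positions with an exact compensating base multiset computed
after the CDS are realized, so realized global composition lands within
±1% of target (full-genome skews typically within ±0.005 of the implied
values).

Embedded microsatellites are written at recorded coordinates; a scrub loop
then rescans the genome and locally resamples any incidental repeat
meeting the thresholds (codon-aware inside CDS, never touching embedded
spans; iteration cap 1,000), guaranteeing the scanner's output equals the
truth record exactly. Motif/strand feasibility matters: some AT-rich
motifs (TAAA on a plus-strand gene) contain a stop codon in every reading
frame and can only be hosted on minus-strand genes; `cds_motif_compatible`
encodes this and the panel generator respects it.

`mutate_cds_pair` plants exactly n synonymous and m nonsynonymous
single-nucleotide changes, one per codon (keeping pathway counting exact,
k = 1), never creating stops and never touching start/stop codons, with a
per-change truth record. `make_gene_alignment` builds star-shaped
multi-taxon alignments from one base ORF.

`generate_panel` draws genome sizes uniformly (default 14.8–18 kb, n = 56)
and repeat counts from a linear model count ≈ 5.3·size_kb − 75 +
N(0, 2.2²), clipped at zero — parameters chosen so a 56-genome panel
spans roughly 3–20 repeats per genome with r² ≈ 0.83 between count and
size, the regime reported for real pentatomid panels. Motif classes
default to the observed pooled frequencies (tetra 43.1%, tri 40.4%, the
rest minor), motifs are A/T-only with probability 0.988, and 70% of
repeats are placed in genes (host-gene weights follow the reported
gene-wise repeat distribution, nad6 > nad4 > rrnL > nad2).

What the generator does **not** emulate: phylogenetically correlated
sequence evolution (taxa are star-shaped, not tree-shaped), indels,
heteroplasmy, imperfect repeats, tRNA secondary structure, and realistic
inter-gene overlap patterns. Passing tests therefore demonstrate
correctness of the statistics and scanners on known ground truth, not
performance on the quirks of real annotation (overlapping genes,
frameshifts, ambiguous boundaries).

Determinism: all randomness flows from one integer seed through a single
`numpy.random.Generator`; fixed seed ⇒ bit-identical genomes, truth
records and reports on a given NumPy version.

## Problem sizes and numerical choices

The test suite runs the scanner-vs-enumerator check on 200 random 500 bp
sequences, the pathway enumerator on 1,000 random codon pairs, ω recovery
on a 10-taxon, 400-codon star gene, and panel summaries on a 56-genome
panel — sizes chosen to exercise every code path while keeping the default
suite fast. Floating-point comparisons in reports use half-up decimal
rounding; internal math is double precision throughout. Degenerate inputs
(empty partitions, zero-denominator skews, saturated distances, all-gap
columns, zero-variance panels) are reported as explicit missing values or
errors, never silently coerced to zero.
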