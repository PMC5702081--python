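# Methods

## The problem

In a pooled CRISPR/Cas9 knockout screen, a Cas9-expressing cell population
is infected at low multiplicity with a lentiviral library carrying several
single-guide RNAs (sgRNAs) per gene. After phenotypic selection, the guide
cassettes integrated in the surviving cells are PCR-amplified and deep
sequenced. The relative frequency of each guide in the selected
(experimental) library versus an unselected control library is a proxy for
the fitness effect of knocking out its target gene. `guidescreen` covers the
informatic half of this workflow: turning raw amplicon FASTQ files into
per-guide counts, and per-guide counts into ranked, multiplicity-corrected
gene-level statistics.

## Guide-tag extraction

Each amplicon read has the structure `[prefix][anchor][guide][suffix]`,
where the anchor is a fixed vector-derived sequence (default `GAAACACCG`,
the U6-promoter/scaffold junction) that immediately precedes the 19-bp
variable guide. The filter pipeline locates the **first** occurrence of the
anchor (exact match, case-insensitive — the amplicon design places the
anchor once, before the guide) and keeps exactly the next 19 bases with
their qualities; reads lacking the anchor, or with fewer than 19 trailing
bases, are discarded and tallied. No mismatches are tolerated in the anchor
and no fuzzy guide matching is performed downstream: exact string equality
keeps the counting deterministic and auditable, at the cost of losing reads
with sequencing errors inside the anchor or guide (these land in the
discard/unmapped tallies rather than being silently misassigned).

Additional composable steps — crop, head/tail cut, pattern replace, mean
Phred-quality filter (offset 33 by default, 64 selectable), length filter,
and barcode demultiplexing — can be arranged in any order; the pipeline
applies exactly the declared order, which matters (crop-then-search and
search-then-crop differ). Workflows serialize to versioned YAML and
round-trip losslessly. Processing is single-pass streaming, so memory does
not grow with file size, and the implementation is deliberately sequential:
output order equals input order and runs are byte-reproducible.

Two choices the underlying method description leaves open, made here once:

- `replace` with a length-changing replacement splices the quality string
  position-wise; bases inserted beyond the original span receive the
  maximum neighbouring quality, keeping sequence and quality aligned.
- `demultiplex` is primarily a multi-stream operation (one output per
  barcode label plus an unassigned stream); used *inside* a single-output
  workflow it takes a `keep_label` parameter and keeps one sample's reads.
- Reads with `N` in the retained guide window are kept by the filter;
  validity is decided by matching (reference guides are ACGT-only, so such
  reads simply count as unmapped).

## Counting and aggregation

The reference library is any headered delimited file; the caller declares
the sequence column and one or more identifier columns (gene, guide ID,
position), so libraries from different vendors work unchanged. Duplicate
guide sequences are rejected at parse time — a tag matching two rows would
be ambiguous to count. Counting is a single hash lookup per read; the
invariant `mapped + unmapped = reads` is maintained and checked. Counts can
be aggregated by any identifier column, and ranked composition summaries
break ties lexicographically so output is reproducible.

## Gene-level statistics

Given per-guide counts for paired experimental/control libraries (replicate
pairs are matched by declared order), the score for each gene is computed
in six steps:

1. **Matrix assembly.** Genes are rows; each library contributes a column
   of per-guide counts. A guide with zero observed reads in a library is a
   missing value.
2. **Median imputation.** Missing values are set to 1. Then, in a single
   pass, every count equal to 1 — originally observed or just imputed — is
   replaced by the median of that gene's guide counts in the same library,
   computed from the pre-replacement values (the substitution is not
   iterated; a gene whose guides are all 1 is a fixed point). The median is
   per gene and per library, not library-global; the even-count median is
   the mean of the two central values. The library-global reading of
   "median of all counts" is a defensible alternative; the per-gene reading
   is implemented because the imputation is meant to stabilize a *gene's*
   fold change against its own dropout guides.
3. **Total normalization.** Each imputed count is divided by its library's
   post-imputation sum, giving frequencies x that sum to 1 per library and
   make libraries of different sequencing depth comparable. All downstream
   statistics are scale-invariant: multiplying a library's counts by a
   constant changes nothing (verified as an acceptance property; the
   invariance is exact only when no count equals 0 or 1, since imputation
   reacts to count magnitude).
4. **Log-ratios.** For each gene, r_i = log2(x_exp,i / x_ctrl,i) over its
   guides, pooled across replicate pairs (5 guides x 1 pair = 5 ratios).
5. **z-test.** m = mean(r), s = sample SD (ddof = 1),
   t = m / (s / sqrt(n)), and the p-value refers t to the **standard
   normal**: p = 1 − Φ(t) for enrichment (the default — positive-selection
   screens look for enriched guides), Φ(t) for depletion, 2(1 − Φ(|t|))
   two-sided. The statistic is identical to the paired t-test statistic on
   (log2 x_exp, log2 x_ctrl); only the reference distribution differs.
6. **Multiple testing.** Benjamini–Hochberg step-up FDR and Bonferroni
   min(1, m·p), with m = the number of genes actually tested.

### The normal-vs-t approximation

Referencing t to the normal instead of Student's t_{n−1} makes the test
anti-conservative for small guide numbers. Under an exact null (i.i.d.
normal ratios) the one-sided rejection rate at nominal α = 0.05 with n = 5
guides is P(T₄ > z₀.₉₅) ≈ 0.0876, not 0.05. The test suite and acceptance
script *verify* this closed form empirically (20,000 simulated null genes,
±0.01 Monte-Carlo band) rather than asserting nominal type-I control: it
characterizes the method. Rankings are unaffected (the map t → p is
monotone), which is why spike-in recovery is unimpaired.

### Degenerate cases

- s = 0, m ≠ 0: t = ±∞ by the sign of m, p = 0 or 1, flagged `degenerate`.
- s = 0, m = 0: t = 0, p = 0.5 (enrichment tail) — the null identity.
- n = 1 ratio: the SD is undefined; the gene is reported with its log2FC
  and no p-value, and excluded from the multiple-testing family m.
- p = 0 in the volcano table: −log(p) is clamped at the smallest positive
  double and flagged.

### Significance display

The volcano table/plot uses y = −log2(p) by default (−log10 selectable)
and marks genes red when raw p falls below the Bonferroni threshold α/m;
the helper `bonferroni_threshold(0.05, 20000) = 2.5e−6` reproduces the
conventional genome-wide cutoff, while the adjusted p-values in the output
use the number of genes actually tested.

## Synthetic screens

The generator emulates the screen structure end to end with exact,
recorded ground truth:

- **Library:** `n_genes` x `guides_per_gene` (default 5, matching
  genome-wide knockout libraries) distinct random 19-mers.
- **Abundance:** per-guide expected abundance ~ log-normal(0, σ = 1),
  modelling uneven library representation; enriched genes multiply their
  guides' expected abundance by a fold change f (depleted by 1/f).
- **Counts:** one multinomial draw per library over the normalized
  expectations, so the library size is exact and the per-guide tallies are
  the oracle for counting tests.
- **Reads:** 75 bp, anchor at a uniform random offset with the guide always
  fitting, constant Q40 qualities (optionally a fraction at Q2 for quality-
  filter tests), and a configurable fraction of anchor-free junk reads.
  Flanks are re-drawn in the rare event they create an earlier anchor
  occurrence, so anchor trimming recovers the intended guide for every
  read and the truth table is exact, not approximate.

All outputs are fully determined by the seed. What the generator does *not*
model — sequencing errors inside reads, PCR duplicates, chimeras,
infection-multiplicity effects, guide-efficiency variation — bounds what
passing tests show: they validate the arithmetic and bookkeeping of the
pipeline on structurally faithful data, not robustness to real-world read
noise (which exact matching, by design, converts into unmapped-read loss).

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` run at sizes chosen to make the
checks sharp while keeping a full run interactive: spike-in recovery at
1,000 genes x 5 guides, 500,000 reads/library, 10 genes enriched 8-fold,
5 seeds (count-level simulation — the identical count stage the FASTQ
generator uses); end-to-end FASTQ fidelity at 200 genes x 5 guides,
200,000 reads/library with 10% anchor-free reads; null calibration at
20,000 genes x 5 guides; BH oracle comparison on 1,000 random vectors of
length up to 500.

## Known limitations

- Exact anchor and guide matching: no mismatch tolerance anywhere.
- Single-end reads only; no adapter discovery.
- The z-test inherits the normal approximation's anti-conservatism at
  small n (quantified above); no negative-binomial modelling, dispersion
  estimation, RRA ranking, copy-number correction or guide-efficiency
  weighting.
- Imputation assumes several guides per gene; with 1–2 guides the per-gene
  median is nearly meaningless (single-ratio genes are excluded from
  testing for this reason).
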