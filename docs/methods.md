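# Methods

This note documents the models, statistics, and numerical choices behind
`editscope`, in the order the pipeline runs them. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate model

All internal coordinates are 0-based half-open; GTF (1-based inclusive) and
bedGraph (0-based) are converted at the I/O boundary. A transcript is an
ordered list of non-overlapping exons plus an optional CDS span (genomic
min/max of the CDS). On the minus strand, mRNA position 0 is the 3′-most
genomic exon end, so `genomic_to_mrna` and `mrna_to_genomic` are exact
inverses on every exonic position (property-tested over randomized
transcripts). 5′UTR/CDS/3′UTR lengths are counted in exonic nucleotides, so
introns inside a CDS do not distort segment lengths.

Where a gene has several isoforms, one *representative transcript* carries
region assignment: the longest mRNA, ties broken by the lexicographically
smallest transcript id. This rule is arbitrary but deterministic; the ARE
scorer is the one analysis that deliberately looks at *all* isoforms (it
keeps the best-scoring 3′UTR per gene). Non-coding transcripts are kept and
labelled `noncoding_exon` rather than dropped, so edit accounting stays
conservative.

## Edit calling

At each position whose sense-strand reference base is A (genomic A under +
genes, genomic T under − genes), the caller compares experiment and control
tallies. A site is reported iff

* experiment coverage ≥ 20 reads and edited fraction ≥ 15% (both
  inclusive — the thresholds are stated as "at least", and the boundary is
  tested exactly),
* control coverage ≥ 20 reads and control edited fraction ≤ 2%.

The control tolerance deserves a note. A literal "zero edited reads in the
control" rule rejects true sites at rate 1 − (1 − e/3)^cov, where e is the
per-base sequencing error: ~5% of sites at 150× control coverage and
e = 0.1%, and a 1% tolerance degenerates to the same zero-read rule
whenever control coverage is below 100× (one error read is already > 1%).
The 2% default is ~60× the expected error-driven alt fraction (e/3 ≈
0.03%) yet 7.5× below the 15% calling threshold, so it keeps the
"unedited control" requirement while being robust to sequencing error.
`ctrl_max_alt_frac=0.0` remains available for genomic-DNA controls.

Sites whose control is absent or under-covered are excluded (conservative)
and tallied in a `no-control` diagnostic, never silently called. Replicates
are intersected by (contig, position, strand); only sites passing all
thresholds in *every* replicate are reported, each keeping its
per-replicate edit percentage for heatmap-style output.

The BAM pileup path excludes bases below Q20 and reads below MAPQ 10; the
MAPQ filter approximates a unique-mapping requirement. Pileups (per-position
tallies) rather than reads are the pipeline's native substrate — alignment
is treated as upstream.

## Metagene coordinates

An exonic edit in a coding gene gets `metagene_x = region_index +
within-region fraction`, with 5′UTR → [0,1), CDS → [1,2), 3′UTR → [2,3).
Each region is rescaled to unit length per transcript (the usual metaplot
convention); raw fractional positions are emitted and binned only at plot
time. `metagene_x` is strictly increasing in mRNA position, which is
asserted as a property test. Region percentages are reported over the three
mRNA regions; intronic/intergenic/non-coding counts are reported separately.

## Motif enrichment (k-mer z-scores)

±100 nt windows around each edit are taken in mRNA coordinates — hence
intronless — and truncated at transcript ends. Enrichment of each observed
k-mer (default k = 8) is measured against a null of per-window
dinucleotide-preserving shuffles (Altschul–Erikson; the shuffle provably
preserves the exact dinucleotide multiset and both end bases, which is
property-tested). Three numerical details matter:

* **Variance floor.** A k-mer the shuffle never regenerates has null sd 0;
  a literal z-score would be infinite and one-off k-mers would outrank
  abundant motifs. The variance is floored at (null mean + 1)/n_shuffles,
  a Poisson-style guard.
* **Ranking.** K-mers rank by add-one empirical p, ties broken by observed
  count then lexicographically. The empirical p is floor-limited at
  1/(n_shuffles+1), so among clear hits the observed count decides — this
  is what lets a motif present in dozens of windows beat a coincidental
  repeat.
* **Family-wise p.** Because thousands of k-mers are scored, the minimum
  per-k-mer p is small under any null. The returned table therefore carries
  `attrs["top_fwer_p"]`: the observed maximum z compared against per-round
  maxima over the *full* k-mer universe (including k-mers only the shuffles
  produce), with a leave-one-out correction so each round is scored
  exchangeably with the observed data (Westfall–Young style). This is the
  number to consult before trusting the top hit; under i.i.d.-sequence
  nulls it is approximately uniform, slightly conservative.

Windows from nearby edits in the same gene overlap and share sequence;
the per-window shuffle null does not model that pseudo-replication, which
is one reason the family-wise p, not the per-k-mer p, guards the headline
call.

## ARE scoring

The AU-rich-element score of a 3′UTR is a pentamer-based measure:

* +1.0 per AUUUA occurrence (positional scan; overlaps counted),
* +1.5 per consecutive pentamer pair with starts ≤ 10 nt apart,
* +0.75 per pair 11–20 nt apart,
* +0.5 per pentamer whose immediate neighbors on both sides exist and are
  A or U.

The weights and distance bins are this package's parameterization of
pentamer + clustering + context scoring (`AREScoreParams`, all
configurable); every comparison in the pipeline uses the same
parameterization on both sides, so downstream statistics are
self-consistent. Only 3′UTRs longer than 10 nt are scored; per gene, the
highest-scoring isoform is kept and genes with no qualifying 3′UTR are
absent (not zero). The scorer is T/U-agnostic and is tested for exact
equality against an independently written brute-force implementation on
10⁴ random sequences, plus a monotonicity property (appending a disjoint,
non-A/U-flanked AUUUA raises the score by exactly one pentamer point).

## Normalization and differential classification

Size factors are DESeq-style median-of-ratios: the reference is the
per-gene geometric mean over samples (genes with any zero count excluded
from the reference, but still normalized), and each sample's factor is the
median ratio to the reference. The worked two-sample example (10,20,30 vs
20,40,60 → factors 1/√2, √2) is asserted to four decimals, and the
construction identity — per-sample median log-ratio of normalized counts to
the reference is exactly zero — is asserted on every call.

Per-gene classification uses a permutation test with a **pooled null**:

* statistic: group mean difference of log2(normalized counts + 0.5). The
  log transform is variance-stabilizing for overdispersed counts (variance
  ≈ dispersion for moderate-to-high means), which is what makes the
  statistic comparable across genes;
* null: all group-label assignments when C(n, n₁) ≤ 1000, else ≥ 10⁴
  Monte-Carlo draws, *excluding* the observed assignment and its mirror
  (they do not break the group structure), pooled across genes;
* p: add-one empirical tail probability of |statistic| in the pooled null.

Pooling is what makes small designs testable at all: a per-gene exhaustive
two-sided permutation p at 3v3 replicates can never fall below
2/C(6,3) = 0.1, so no per-gene scheme can call anything at α = 0.05 with
three replicates per arm. The pooled scheme assumes genes are roughly
exchangeable after the log transform; genes with true effects contaminate
the null slightly, making the test conservative in proportion to the
fraction of affected genes. Calibration is verified by simulation in the
acceptance suite: the null false-positive rate at α = 0.05 is measured on a
2000-gene null (5v5), and the downstream chi-square p-value is checked for
uniformity over null runs.

Classes: `down` iff padj ≤ α and log2fc < −lfc_floor, `up` symmetric, else
`unchanged`. The inclusive ≤ is the calibrated convention for discrete
permutation p-values. Default `padj_mode="raw"` (padj = p) mirrors a plain
p < 0.05 report; Benjamini–Hochberg is available via `padj_mode="bh"`. The
default `lfc_floor` is 0 (no fold-change floor is imposed on the
"unchanged" class, but one is configurable). log2fc is the log-ratio of
mean normalized counts with a 0.5 pseudocount.

## Target stratification, bootstrap, Fisher combination

The 3 (class) × 2 (target/background) contingency table is tested with a
Pearson chi-square (df = 2, no continuity correction); all-zero class rows
are dropped (the statistic is unchanged; df adjusts) and cells with
expected counts < 5 set a `low_expected` flag on the report. Target and
background gene sets are then resampled with replacement (default 1000
bootstraps) at their observed sizes; per-class fraction CIs are the
2.5/97.5 percentiles, and the per-bootstrap chi-square p-values are
combined globally with Fisher's method, X = −2Σln pᵢ against χ² with 2k
df, using the exact survival function (for k = 1 this reduces to the
identity, which is tested). Bootstrap resamples are not independent, so
the combined p is a summary of the bootstrap evidence, not a calibrated
single-test p-value — the primary inferential quantity remains the
point chi-square p.

## Intron-read (nascent transcription) analysis

Intron intervals are each gene's span (over all its transcripts) minus the
exon union of *all* transcripts of *all* genes; zero overlap with any
annotated exon is asserted on every build, and intronless genes are absent.
Reads count toward a gene's intron signal only when every aligned block
lies inside a single intron interval — junction-spanning or exon-touching
reads are excluded. The intron count matrix then goes through the *same*
median-of-ratios + permutation classifier as the exonic arm (size factors
from the full intron matrix; class fractions reported among targets), so
the exonic and intronic verdicts are methodologically comparable: an
exonic `down` with an intronic `unchanged` is the posttranscriptional
signature.

## Synthetic data: what it emulates and what it does not

The generator builds a single-contig transcriptome (default 60 genes;
5′UTR 50–150 nt, CDS 300–900 nt, 3′UTR 100–300 nt; half the genes carry
one intron of 60–200 nt inside the CDS; random strand). Twelve target
genes receive three planted edits each, placed across 5′UTR/CDS/3′UTR with
weights 0.04/0.267/0.693 — the positional profile of a 3′UTR-biased RBP —
at true edit fractions drawn uniformly from 0.3–0.7. 80% of target 3′UTRs
carry a planted UAUAUAUA element, and 3′UTR edits concentrate within
±40 nt of it, modelling editing near the binding element; edits otherwise
fall uniformly on sense-strand adenosines.

Pileups: per-site coverage is negative-binomial with mean 150 and size 10
(RNA-seq-like overdispersion; the size-10 NB is a documented, configurable
choice). The 150× default mean is typical of expressed transcripts in a
poly(A) library at standard depth and puts the probability of a sub-20-read
site at ~6×10⁻⁶ per site and sample (straight from the NB CDF), so
coverage drop-out is a negligible failure mode at default settings. At a
planted site with fraction f, the edited-base count is Binomial(cov, f);
all remaining reads then acquire errors at 0.1% per base (a post-Q20-filter
figure), split over the three non-reference bases in alphabetical order.
The control is an error-only RNA sample with no planted edits — both a
non-fusion RNA control and a genomic-DNA control reduce to this. Every
random stream derives from `default_rng([seed, stream_id])` with documented
stream ids, so equal seeds give byte-identical outputs.

Count matrices: per-gene means are lognormal around 300 (σ = 0.8), counts
negative-binomial with dispersion 0.05, three samples per condition. The
knockdown effect (default log2FC −1) multiplies target genes' *exonic*
means only; the intronic matrix (means 25% of exonic) takes an independent
transcriptional effect, default 0 — that asymmetry is the planted
posttranscriptional signature the pipeline must recover.

What the simulation does **not** model: read-level error profiles, PCR
duplicates, splice-aware read placement, ADAR nearest-neighbor sequence
preference around edited adenosines, SNP contamination of the control,
isoform diversity (one transcript per gene), and 3′UTR length regulation.
Passing tests therefore demonstrate correctness of the statistical
machinery and recovery under the stated noise model, not robustness to
alignment artifacts or population variation in real libraries.

## Problem sizes used in tests

The test and acceptance suites run the pipeline at the generator's default
scale (60 genes, 36 planted edits, duplicate replicates) over 20 seeds for
the recovery, motif, and end-to-end-signature properties; statistical
calibration uses 2000-gene null matrices (5v5) for the type-I rate, 200
targets in 2000 genes for detection power, and 150–200 null runs of 500
genes for chi-square uniformity. These sizes were chosen so that binomial
sampling noise in each measured rate is small against the asserted bound
(e.g. a ~93% detection rate measured over 200 targets has a standard error
under 2%, so a ≥ 90% assertion tests the method rather than the draw).

## Known limitations

* The edit caller has no SNP masking beyond the control comparison; on real
  data an edited-looking homozygous variant in the experiment strain but
  not the control would be called.
* The pooled permutation null is conservative when a large fraction of the
  transcriptome truly changes.
* The k-mer statistic detects exact-match enrichment only; degenerate
  motifs spread across variants dilute rank.
* The ARE parameterization is internally consistent but not numerically
  comparable to external ARE-scoring tools.
* Bootstrap chi-square p-values are dependent across resamples; see above.
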