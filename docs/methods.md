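# Methods

This note documents the models, rules and numerical choices behind
`hypolnc`, and what the synthetic-data experiments do and do not show.

## Stepwise lncRNA identification

A transcript is called a candidate lncRNA iff it survives an ordered
cascade: length > 200 nt (strict: 201 keeps, 200 removes); longest ORF
≤ 300 nt; the external-evidence stages; and the expression-noise filter.

The ORF convention: an ORF is ATG…{TAA,TAG,TGA} in one frame with no
internal stop, its length counted from the first base of ATG through the
last base of the stop codon (so 300 nt ≈ 99 codons + stop). Both strands
are scanned by default because de novo assembled contigs are unoriented;
`strands="forward"` restricts to the given strand. Codons containing N
never act as start or stop. Ties between equally long ORFs break toward
the smaller start, then the forward strand, then the lower frame.

External tools (BLASTx against protein databases, Pfam/HMMER,
CPC/CPAT coding-potential scores, Rfam families) are not reimplemented;
their outputs enter as id blacklists via `make_blacklist_predicate`, and
their customary E-value thresholds are recorded in `FilterConfig` for
provenance only. The mRNA set is likewise an input (ids with protein
homology plus functional annotation).

The expression filter keeps transcripts with FPKM ≥ `fpkm_min` (default
1) in at least `min_expressed_samples` (default 2) samples. The
source wording for this step ("low abundance and expressed in only one
sample were screened") is ambiguous between a conjunction and two
separate filters; the keep-rule above removes the union, which is the
conservative reading, and both thresholds are configurable.

## Duplex scanning and the target / mimic rules

Sites are found by windowed global alignment of the reverse complement
of the miRNA against the transcript: windows of length len(miRNA) ± 4 nt,
unit cost per mismatch and per bulged base, Watson–Crick and G–U wobble
columns free. A window whose optimal cost is at most `max_edits`
(default 9 = the loosest rule-compatible bound: 5 central + 4 other)
emits its co-optimal alignments; flanking bulged transcript bases are
trimmed and duplicate column sets are merged. Alignments are enumerated
by deterministic depth-first traceback (diagonal, then miRNA-gap, then
transcript-gap), capped at 24 co-optimal paths per window — alignments
near the rule boundaries have few co-optimal paths, so the cap only
truncates high-cost junk.

Classification uses 1-based positions from the miRNA 5′ end; the
central region is the closed interval [9, 12] and the seed is [2, 8].

* **Target**: ≤ 1 nt of mismatch/indel in the central region, ≤ 4 nt of
  mismatches/bulges elsewhere, and no two consecutive mismatch columns
  anywhere (the continuity rule applies to targets only, and to
  mismatches only — a mismatch adjacent to a bulge is allowed).
* **Mimic**: 2–5 nt of mismatch/indel in the central region, every seed
  column paired (WC or G–U) with no bulge interleaved, and ≤ 4 nt of
  mismatches/indels elsewhere.

Accounting conventions where the rules are silent: an unpaired miRNA
base counts toward the region containing its position; a bulged
transcript base between miRNA positions i and i+1 is central iff
9 ≤ i ≤ 11 (the 8|9 boundary bulge is non-central); terminal unpaired
miRNA bases are charged like any other bulge, which keeps every miRNA
position covered exactly once in the column list and keeps the rules no
weaker at the ends than in the middle. Target and mimic are mutually
exclusive for a single alignment (central edits cannot be both ≤ 1 and
≥ 2); among co-optimal alignments the more consequential role wins
(target > mimic > none).

**Pruning.** An alignment with more than 5 edits cannot satisfy the
target rule, and cannot satisfy the mimic rule either unless its seed is
perfectly paired. The scanner therefore skips, by default, high-cost
windows with no contiguously pairing seed block and discards high-cost
alignments that do not classify as mimics. This is lossless for role
discovery up to redundant variants that are strictly worse than another
emitted alignment at the same locus; `exhaustive=True` restores the full
emission. The practical effect is large: random 1 kb of sequence emits
tens of thousands of rule-violating co-optimal alignments at the default
edit budget, and none of them can carry a role.

**Chance hits are real.** Rule sets of this kind, applied over every
window and every co-optimal alignment with wobble pairing free, admit
rule-satisfying alignments on unrelated sequence (measured here at
roughly 0.5–1 sites per miRNA per kilobase). Consequently the package
evaluates role recovery *at a locus*: among the alignments overlapping a
site, those with the fewest edits are the predicted duplex structures,
and the most favorable of their roles is the site's role. Pair-level
tables (any-site precedence) are also emitted, but on long transcripts
they inevitably include chance interactions, exactly as such rule
pipelines do on real transcriptomes.

MFE annotation of duplexes (e.g. via an external folding tool) is a
deliberate non-feature of classification: the rules are purely
combinatorial, and no MFE threshold is applied anywhere.

## Synthetic data

The generator is the constructive inverse of the pipeline's assumptions.

* **Transcripts.** mRNA-like sequences embed an in-frame ORF ≥ 400 nt
  (about 45 % of the transcript) inside UTRs; lncRNA-like sequences are
  rejection-sampled until the longest ORF is < 300 nt. Default lengths
  are lognormal with medians ≈ 2100 nt (mRNA) and ≈ 700 nt (lncRNA), and
  default GC targets are 0.50 vs 0.43 — the contrast reported for rodent
  transcriptomes of this kind. Analyses in the test-suite use shorter
  length medians (stated per run) to keep alignment corpora small; the
  distributional shape is unchanged.
* **miRNAs.** `gen_mirnas` emits one record per species per sequence, as
  in a per-species mature-sequence dump; exactly round(n·f) sequences are
  shared by two species, so the conservation filter has an exact truth.
* **Planted sites.** `plant_site` writes the reverse complement of the
  miRNA into the transcript and injects edits by role. In strict mode,
  targets get ≤ 1 central and ≤ 2 other mismatches, pairwise
  non-adjacent; mimics get a central bulge of 2–3 inserted bases pinned
  between positions 10 and 11 plus ≤ 1 tail mismatch — the classic
  sponge pattern, chosen because an insert must be bulged by *every*
  alignment of the locus, so no register of a planted mimic can read as
  a cleavable target; "none" sites combine a central 2-nt bulge with one
  seed mismatch (3 edits violating both rule sets in every register).
  Mismatch and insert bases are chosen not to pair the surrounding miRNA
  positions, so planted edits cannot be rescued by one-step register
  shifts. Because miRNAs with repetitive central context can still allow
  a bulge to float across a region boundary, each planted site is
  verified locally with the classifier at plant time and re-drawn if
  ambiguous — the same rejection-sampling pattern used for lncRNA ORFs.
  Sites never overlap within a transcript, and a (miRNA, transcript)
  pair carries at most one planted site.
* **Counts.** Negative-binomial with gene-wise lognormal base means and
  one shared dispersion (default 0.1) — deliberately simpler than
  trend-fitted gene-wise dispersion models, and sufficient to exercise a
  Wald caller. Differential expression is planted per contrast by
  multiplying the first group's mean by 2^±log2fc; co-expression blocks
  share a latent per-sample profile on the log2 scale (default amplitude
  2.0, gene-level noise 0.15, giving within-block correlations ≈ 0.95
  after count noise). Block members and DE genes are disjoint. FPKM =
  counts / (length_kb × library_size_millions) with library size equal
  to the column sum.

What the generator does not emulate: splice isoforms, sequencing error,
positional coverage bias, gene-wise dispersion trends, and correlated
library composition beyond what finite library sums induce. Passing
tests therefore demonstrate correctness of the algorithms under their
own generative assumptions, not performance on real RNA-seq.

## Differential expression

Size factors are median-of-ratios over genes with nonzero geometric
mean. For a contrast A vs B the caller computes normalized group means,
log2fc = log2((m_A+0.5)/(m_B+0.5)) (0.5 pseudo-mean on the normalized
scale), and a Wald z with SE from the NB delta method,
Var(m̂) = (m + αm²)/n. Dispersion α comes from method-of-moments
residuals pooled across the two groups; by default the per-gene
estimates are additionally pooled across genes by their mean, matching
the shared-dispersion generative model. The per-gene mode is exposed but
is strongly anticonservative at 2–3 replicates (measured null
p<0.05 rate ≈ 0.12 vs ≈ 0.055 pooled); the mean rather than the median
is used for pooling because the few-degrees-of-freedom per-gene
estimates are right-skewed and their median under-estimates α (measured
rate 0.077). A fixed numeric dispersion can be supplied, under which the
caller reduces exactly to a Poisson Wald test as dispersion → 0.

Calls use the raw p < 0.05 with fold change > 2 (up) or < 0.5 (down), no
multiple-testing correction by default; `fdr=True` gates on
Benjamini–Hochberg adjusted p instead.

## Topology metrics

Betweenness is the literal count of shortest paths through a node:
σ_st(i) summed over unordered pairs s < t with both endpoints distinct
from i, not the Brandes fraction σ_st(i)/σ_st (available via
`betweenness="fraction"`). Average shortest path length averages over
nodes reachable from i only; disconnected pairs contribute nothing.
Closeness is the reciprocal of that average, 0 for isolated nodes. All
computed from per-source BFS with path counting; verified against
exhaustive simple-path enumeration on graphs of ≤ 8 nodes.

## Co-expression

Correlations are computed on log2(FPKM+1) by default (`--no-log` for raw
FPKM), after keeping the top 75 % of transcripts by sample variance
(ties broken by id). Fisher's asymptotic p uses z = atanh(r)·√(n−3),
with atanh clamped at |r| = 1 − 1e−15; underflow is reported as 0
(below 1e−300). Bonferroni multiplies by the number of successfully
tested pairs (constant transcripts are skipped with a warning). The
top/bottom-5 % correlation cutoffs are quantiles over all tested pairs,
not per partition. An edge needs both the adjusted-p gate and a tail
membership. Enrichment is an upper-tail hypergeometric test per term
over a user-supplied transcript→term map, BH-adjusted; the background
defaults to annotated mRNAs surviving the variance filter.

The block-recovery experiment uses 1000 genes so that the two planted
blocks do not dominate library size; with few hundred genes the FPKM
denominator couples all genes to the block profiles and induces spurious
compositional correlations — itself a useful reminder that FPKM-level
correlation networks are composition-sensitive.

## Problem sizes

The shipped experiments use: 1e5 random column lists for classifier
equivalence; a 50 miRNA × 200 transcript corpus (~500 nt median) with
300 planted sites for role recovery; 1000 random sequences ≤ 2 kb for
the ORF oracle; 2000 genes at 3 vs 3 for DE calibration; 1000 genes ×
18 samples for the co-expression gate; and a 120-transcript, 20-miRNA
study for the end-to-end run. These sizes were chosen to exercise each
stage at a scale where the measured rates are stable.
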