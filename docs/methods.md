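# Methods

This note records the models and procedures implemented by `ecdysocomp`,
the parameters that matter, the choices made where the design was open,
and what the synthetic-data tests do and do not establish.

## Coordinate and identifier conventions

All genomic coordinates are 1-based inclusive (the GFF3 convention, the
only coordinate-bearing format in scope): a single-exon gene on (10, 19)
has length 10. Each gene is represented by its longest-CDS transcript
everywhere. Exons are stored in ascending genomic order; strand is carried
but affects no statistic computed here. Subject→taxon mapping for hit
tables tries an exact identifier match first, then the longest matching
prefix; unmapped subjects are dropped and counted, never silently. TSV
outputs are tab-delimited UTF-8 with one commented header line and rows
sorted by primary key, so reruns are byte-identical.

## HGT-index screen

For each gene, hits with E-value ≥ the cutoff (default 10⁻⁵, strict `<`
for survivors) and hits whose subject species equals the query's own are
discarded; then B_o is the maximum surviving non-metazoan bit score
(prokaryote ∪ virus ∪ non-metazoan eukaryote) and B_m the maximum metazoan
bit score. The index is h_U = B_o − B_m; a gene with no metazoan hit has
B_m = 0 so h_U = B_o — the index measures metazoan deficit, and
single-sided genes stay in scope. Candidates satisfy h_U ≥ τ (default
30 bits) *and* B_o > 0. Ties at a maximum keep the lexicographically
smallest subject for reporting only.

A note on monotonicity: the candidate set shrinks monotonically as τ
rises, but *not* necessarily as the E-value cutoff tightens — a stricter
cutoff can remove a gene's best metazoan hit, driving B_m to 0 and h_U up.
The property tests assert the conditional form (metazoan hits surviving
the cutoff).

### Tree-of-origin classification

Per-candidate gene trees carry no guaranteed outgroup, so trees with
branch lengths are midpoint-rooted; trees without lengths keep their given
rooting. From the query leaf the classifier walks rootward, enlarging the
clade while all non-query leaves share one taxon group; the group of the
largest such clade is the category. If even the first informative clade is
mixed, the candidate is `complex_non_hgt` when metazoan leaves form a
strict majority of that clade (the query sits inside a metazoan
radiation), else `complex_hgt` (transfer affirmed, source unclear). The
majority rule is a design choice; the underlying distinction is
qualitative. Trees with fewer than 4 leaves are `insufficient`. A test
checks the walk against exhaustive enumeration of every clade containing
the query on random tagged trees up to 12 leaves.

### Validation tiers

Tiers are nested sets: `high` ⊆ `supported` ⊆ `candidate`.

* `rejected`: gene-tree category `metazoan` or `complex_non_hgt`.
* `supported`: tree-confirmed transfer (prokaryote, virus, non-metazoan
  eukaryote, or complex-HGT).
* `high`: tree-confirmed AND expressed AND conserved in the designated
  sister species. A flag whose data are missing is recorded as unknown and
  blocks the high tier.
* `candidate_only`: index candidates whose tree was too small or absent.

Intron presence is reported but never gates a tier: gene finders are
biased toward predicting introns, making it a weak validation criterion.
The expression criterion defaults to "maximum TPM over any library > 1";
the alternative mean-based reading is available as
`ScreenConfig.expression_rule="mean"` — the two phrasings coexist in the
literature and neither is asserted as canonical. Tier counts are reported
cumulatively with percentages of the gene total rounded half-up to one
decimal.

### Genomic clustering

Two HGT genes join a cluster iff they share a scaffold with at most
`cluster_max_gap` (default 1) intervening non-HGT genes; clusters need ≥ 2
members. Per-gene distances to the nearest candidate on each side use the
sentinel ±1,000,000 at scaffold ends, matching the established
neighbourhood-table convention.

## Dollo parsimony and synapomorphies

Presence is member count ≥ 1 — Dollo parsimony operates on
presence/absence, not abundance. The birth node is the MRCA of the
carrying leaves; the loss set is the roots of the maximal all-absent
clades below the birth, which is the unique minimum. An acceptance test
verifies this against brute-force enumeration of every (birth, loss-set)
assignment for all 255 presence rows on an 8-leaf tree.

A family is a synapomorphy of an internal node iff it is absent outside
the node's descendants and every child clade (every child of a polytomy)
contributes ≥ 1 carrier; coverage is carriers / descendants. Coverage
histograms use half-open bins of width 0.1 plus a closed bin at exactly
1.0; half-openness is a stated choice. Any node whose descendant leaf set
is identical under two competing trees must receive the identical
synapomorphy set — asserted as set equality on 1,000 simulated families.

Clade enrichment uses a two-sided rank-sum test with midranks of
per-species member counts (focal clade vs the rest), skipping families
with fewer than two non-zero taxa. For total n ≤ 12 the p-value is exact
by enumerating all group assignments (correct under ties, where standard
exact tables fail); larger samples use the tie-corrected normal
approximation with continuity correction, matching R's `wilcox.test`.
Bonferroni correction divides by the number of families actually tested.
Fold overrepresentation flags families whose focal mean strictly exceeds
`fold` (default 4) times the mean over all other species, zeros included.

Co-occurrence networks weight each species pair by the number of families
containing both; weights are normalized by the maximum weight among the
reported edges, and never-co-clustered pairs get no edge. Where
group-to-group averages are needed, normalization precedes averaging (the
alternative order is not distinguishable from published descriptions;
this one is fixed and documented). Bipartition support takes the split as
four leaf groups (the subtrees adjacent to the tested edge); a gene tree
is informative iff it holds ≥ 1 leaf of each group, and supports the split
iff an edge of the unrooted tree separates its two sides. Denominators
therefore vary per bipartition.

## Synteny and gene structure

RBH pairs are mutual best hits by bit score, ties to the lowest subject
identifier. Neighbourhood conservation assesses scaffolds with strictly
more than `min_genes` genes (10 and 20 are the standard settings); the
fraction's denominator is orthologued genes only — scaffolds dominated by
lineage-specific genes would otherwise be penalized for missing partners
rather than for rearrangement.

Gene length is the genomic span from first to last CDS base (start codon
to stop codon); exon span (= CDS length) is the summed exon length; intron
span is their difference. CDS outliers are pairs whose genome-A CDS is
strictly more than 1.2× or strictly less than 0.8× the genome-B CDS —
likely misannotations, excluded on request from summary tables. The log₂
intron-span ratio adds a 1 bp pseudo-count on both sides so intronless
orthologues remain finite; the pseudo-count never enters summary
statistics. Ratio tables round half-up to two decimals. Collapsed-copy
estimation is local/global read depth rounded to the nearest integer.

## Expression statistics

Fold change is mean-tun TPM / (mean-active TPM + 0.1); the 0.1
pseudo-count keeps silent-in-active genes finite, and both condition means
are plain arithmetic means over replicates. DEGs require FDR < 0.05 from
an external caller (no negative-binomial test is re-implemented; genes the
caller did not test are never DEGs), a TPM gate, and FC > 2 or < 0.5, with
directions always reported separately. The TPM gate defaults to "max of
the two condition means > 1" so silent-to-induced genes (e.g. 0 → 27.5
TPM) remain callable; the overall-mean reading is a switch. Distribution
comparisons use the same rank-sum machinery as the enrichment test;
summary SDs use the n−1 denominator. Cross-species DEG overlap counts
families holding ≥ 1 DEG from each species, and screens families DE in one
species only for partner-species members constitutively high (> 100 TPM).
Expression classes are high (> 100), silent (< 1), else expressed — all
boundaries strict.

The miRNA seed filter passes a hit iff full-alignment identity exceeds
70 % and at least one seed window (query bases 1–7, 2–8, 3–9) aligns with
no mismatch and no gap over consecutive columns. Identity is taken over
the full alignment (the matched-region alternative is not implemented).

## Synthetic data

Each generator draws from its own fixed stream derived from the single run
seed (`default_rng([seed, offset])`): adding a generator never perturbs
another's output, and identical configurations are byte-identical.

* **Gene families**: one gain at a sampled node, survival of each
  descendant branch with probability 1 − loss_prob, member counts
  1 + Poisson(0.5) at surviving leaves; all-extinct draws are resampled,
  so expected per-leaf presence is the branch-survival product conditioned
  on non-extinction (the calibration test uses the conditional closed
  form).
* **HGT hits**: each gene gets a metazoan anchor score ~ U(100, 300) and a
  non-metazoan score offset by a margin, constant or normal; planted
  transfers have positive location, natives negative. E-values are
  log-uniform below 10⁻⁶. A configurable fraction is single-sided.
* **Genome pairs**: genome B copies genome A's gene order, then applies
  within-scaffold inversions (order broken, linkage kept) and
  translocations (linkage broken); genome-A introns are genome-B's scaled
  by a ratio, so the median log₂ intron ratio of recovered pairs equals
  log₂(ratio) by construction.
* **Expression**: log-normal baseline means (log-mean 4, log-sd 1.5 —
  a realistic TPM-like dynamic range), negative-binomial counts
  parameterized by (mean, dispersion) with dispersion the inverse size
  parameter (variance = μ + d·μ²; d → 0 recovers Poisson), TPM by
  library-size normalization with all gene lengths 1 (keeping the
  TPM/count distinction visible without re-implementing quantification).
  The FDR column comes from a per-gene pooled two-sample t-test on
  log₂(count+1) with Benjamini–Hochberg correction — a deliberately simple
  stand-in for an external caller; pooling the variance recovers some of
  the degrees of freedom real callers gain by sharing dispersion across
  genes.
* **miRNA hits**: random mature sequences with one planted mismatch at a
  known position; truth lists the surviving windows.

What passing these tests shows: the statistics are implemented correctly
and calibrated under their own model assumptions. What they do not show:
robustness to features of real data the generators omit — paralogy
confounding RBH orthology, annotation errors beyond the ±20 % CDS screen,
count overdispersion varying per gene, contaminant-driven HGT signal,
alignment uncertainty in gene trees. Those remain the responsibility of
the upstream tools whose outputs this package consumes.

## Problem sizes and numerics

Default verification sizes — 255 exhaustive Dollo rows, 1,000 simulated
families for hypothesis invariance, 5,000 genes for planted-HGT recovery,
2,000 genes for null DE calibration, exact rank-sum enumeration up to
n = 12 — are chosen so each check completes in seconds while leaving
3-sigma binomial envelopes tight enough to detect real miscalibration.
Percentages round half-up at one decimal, ratios at two, matching the
precision at which such tables are conventionally printed. Degenerate
inputs (empty hit tables, all-absent presence rows, empty pair sets,
zero-member conditions) raise typed errors or return empty results as
documented per function, never silent NaNs.
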