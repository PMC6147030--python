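# Methods

## Compositional screen for horizontal gene transfer

Foreign genes tend to carry the base composition of their donor genome.
The screen summarises each gene by four statistics — the GC fraction at
codon positions 1, 2 and 3 (GC1, GC2, GC3) and over the whole gene (GCT) —
and models the recipient genome's "native" composition by the mean and
standard deviation δ of each statistic across genes. Genes shorter than
300 bp are excluded from the background fit, because short genes are
disproportionately foreign and would inflate δ; they remain eligible for
flagging. δ is the sample (n−1) standard deviation, the conventional choice
for an estimated background.

A gene is flagged when |GCT − mean| > 1.5 δ_T, or when its GC1 and GC3
deviations share a sign and at least one exceeds 1.5 δ of its statistic.
The same-sign requirement captures directional drift of silent and
non-silent positions together, which is what a recent transfer from a
compositionally distinct donor produces; GC2 is computed and reported but
takes part in no rule. All threshold comparisons are strict, so with a
degenerate δ = 0 background any nonzero deviation flags. A deviation of
exactly zero at position 1 or 3 carries no sign and never satisfies the
same-sign rule. Ambiguous bases (N) drop out of numerator and denominator
position-wise; a trailing partial codon is truncated with a warning.

Note the estimator is deliberately contaminated: the background is fitted
over *all* qualifying genes, aliens included. With an alien fraction f and
shift s·δ the fitted δ inflates by roughly √(1 + f(1−f)s²), which is why
sensitivity at small shifts is modest and why the false-positive rate sits
below the naive two-sided 1.5σ tail mass (~13%) in mixed genomes.

## Taxonomic screen, donors, age

Hits are filtered with inclusive cutoffs (identity ≥ 50%, e-value ≤ 1e−5,
query coverage ≥ 70%), after removing hits whose subject belongs to an
excluded sister genome; ordering is bitscore desc, then e-value asc,
identity desc, subject id. A gene is a candidate when it has at least one
qualified hit and none of the top min(10, available) hits contains the
self group (default "Bacteroidetes") anywhere in its lineage. Genes with
no qualified hits are *not* candidates — absence of similarity is not
evidence of foreign origin. The HGT call requires both screens.

Donor assignment takes the leaf minimising the number of nodes on the path
to the query in a per-gene tree (ties broken lexicographically); age is
"ancient" when the gene has an ortholog in at least one sister genome and
"recent" otherwise, so ancient + recent always equals the candidate count.
Donor-group fractions are reported over non-transposase candidates only
(transposase labels are an annotation input, never inferred), and nested
donor groups (e.g. *Wolbachia* within Proteobacteria) are reported
separately rather than forced to sum to 100%.

## Genome statistics

* **Coding density** is Σ gene length / genome length × 100; overlapping
  genes count twice, matching the CDS-count × mean-length arithmetic used
  in genome tables.
* **Redundancy** is the merged query-side coverage of self-alignments with
  identity strictly over 95% and e-value ≤ 1e−20, after discarding the
  trivial full-diagonal hit, divided by genome length. Both copies of a
  repeat contribute coverage (the "both copies" convention; the alternative
  — counting only extra copies — would give half the value for a two-copy
  repeat). Alignments can be supplied as a TSV or produced by the internal
  self-aligner, an exact-repeat finder that chains co-diagonal k-mer
  matches (k = 32, minimum reported length 100 bp, k-mers occurring > 50
  times skipped). The finder reports only exact repeats; diverged repeat
  pairs below 100% identity require externally supplied alignments.
* **ANI** follows the fragment convention: consecutive 1020-bp fragments of
  one genome are aligned against the other (16-mer diagonal voting selects
  a candidate window, then a semi-global edit-distance alignment scores
  it); fragments with ≥ 30% identity and ≥ 70% alignable coverage
  contribute their identity, and ANI is the mean over accepted fragments,
  averaged over both directions. Unrelated genomes yield no accepted
  fragments and an explicit undefined-result error rather than a number.

## Pan-genome partition

Protein pairs are aligned locally (BLOSUM62, gap open −11, extend −1);
identity is identities / alignment columns and coverage is alignment
columns / shorter sequence length. Clusters are single-linkage connected
components over edges with identity ≥ 50% and coverage ≥ 70%, mirroring
BLASTClust semantics — greedy centroid clustering was rejected because it
disagrees on chained similarities. Categories depend only on the set of
genomes represented: core (all), shared (more than one but not all),
specific (one). Per-genome percentages divide by the number of clusters
containing that genome, so a genome's core + shared + specific percentages
sum to 100.

## COG profiles and the exact rank-sum test

Cluster-to-COG assignments may carry several letters; each letter receives
1/m of the cluster's mass, and percentages are per genome over total
assigned mass across the 22 categories (J K L B C G E F H I P Q D V T M N
Z U O R S). Profiles are compared between groups with an exact two-sided
Wilcoxon rank-sum test: mid-ranks are assigned to the pooled sample and all
C(n₁+n₂, n₁) assignments enumerated when that count is ≤ 10⁶ (group sizes
4 vs 13 give 2380 assignments); otherwise a seeded Monte-Carlo permutation
with ≥ 10⁵ draws, including the observed assignment, estimates the tails.
The two-sided p is twice the smaller tail, capped at 1. The exact path was
chosen over the normal approximation because at sizes 4 vs 13 complete
separation yields p = 2/2380 = 8.40E-04, a floor the approximation cannot
represent. No multiple-testing correction is applied; the comparison table
reports raw p-values with a 0.05 significance flag. Profile clustering is
average-linkage on Euclidean distances of per-category z-scored columns
(constant categories map to 0), with genomes pre-sorted by label so tied
merges resolve deterministically.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical structure the screens consume, at
the scale of a reduced endosymbiont genome:

* 755 native + 40 alien genes (795 CDS, ~5% alien), lengths uniform on
  300–1800 bp (mean ≈ 1050 bp) in multiples of 3;
* codon-position GC targets (0.47, 0.37, 0.33), giving ≈ 39% genomic GC;
* intergenic spacers of 150–520 bp, giving ≈ 76% coding density;
* alien genes shifted on GC1 and GC3 equally (default +3 δ on the gene
  total, where δ = √(p(1−p)/L̄) is the analytic per-gene standard deviation
  at the background GC p and mean gene length L̄) — equal shifts produce
  the same-sign pattern the screen's second rule tests;
* donor mix ≈ 64% Proteobacteria (half *Wolbachia*, a quarter
  *Rickettsia*), with 37.5% of aliens labelled transposases and 47.5%
  ancient;
* hit tables in which native genes draw Bacteroidetes top hits (sometimes
  outranked by a sister-strain hit the filter must remove), alien genes
  draw their donor lineage, and every gene gets sub-cutoff junk hits;
* optional exact segmental duplications (with padding to an exact target
  length, so coverage fractions are round numbers) and substitution-only
  diverged genome copies with iid changes to a different base.

Bases are iid within codon positions: there is no codon-usage table, amino
acid coherence, indel process, or phylogeny-aware evolution, and hit
e-values/bitscores are sampled rather than derived from alignments. Passing
tests therefore demonstrate that the statistics and decision rules behave
as specified under their own model assumptions — not that real genomes meet
those assumptions; on real data, amelioration of anciently transferred
genes, strand-specific skew, and within-genome composition heterogeneity
all blur the separation the simulator plants.

## Numerical and design choices

* Coordinates are GFF3-style 1-based inclusive everywhere; half-open
  conversion happens only inside functions.
* All report percentages pass through one helper (`pipeline.pct`, two
  decimals), so printed percentages always equal their count ratios.
* Background fitting sorts genes by id before summing, making the fit
  exactly permutation-invariant despite floating-point addition.
* One RNG stream (`numpy.random.default_rng(seed)`) drives a full
  simulation run; rerunning with the same configuration is byte-identical,
  and the pipeline's TSV/JSON outputs are byte-stable across reruns.
* Hit-table dialect is fixed (12 tabular columns + coverage + lineage); no
  auto-detection, by design.
* Problem sizes in the shipped analyses and tests — ~1.1-Mb simulated
  chromosomes for the end-to-end screen, 100-kb genomes for redundancy and
  ANI, 60–120 random instances per brute-force oracle comparison — were
  chosen so every result is stable at the stated tolerances while the whole
  suite stays quick to iterate on.

## Known limitations

* The composition screen has no length normalisation beyond the 300-bp fit
  exclusion: very short genes have noisy GC statistics and flag more often.
* The internal self-aligner detects exact repeats only; redundancy of
  diverged repeat families needs externally supplied alignments.
* The ANI aligner assumes substitution-dominated divergence; heavy indel
  divergence would reduce fragment coverage below the acceptance threshold
  and bias ANI toward well-conserved regions, as fragment methods do.
* `pairwise_similarity` is all-vs-all without a k-mer prefilter and is
  intended for the cluster-scale inputs used here, not whole proteomes of
  free-living bacteria.
* Reproducing published strain-level numbers (e.g. a specific core-genome
  size or an ANI between two deposited assemblies) requires those
  assemblies as inputs; the package validates the machinery on synthetic
  data with known truth instead.
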