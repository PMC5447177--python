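# Methods

This note documents the models, decision rules, numerical choices and known
limitations of the package. Units and defaults are stated with each
parameter; every default is also the value used by the pipeline
(`halotrans.pipeline.RunConfig`) unless overridden.

## Units of analysis

The input is a catalogue of predicted ORFs (nucleotide CDS plus protein)
with per-ORF read counts for two conditions (low vs high salt, ≥ 2
replicates each). ORFs are collapsed into genes; expression is tested at the
ORF level and reduced to genes; duplication, enrichment and LGT screening
operate on genes through their longest-isoform representative.

## Isoform collapsing

Two ORFs belong to one gene iff they share an exact nucleotide stretch of at
least `min_shared` = 50 nt, closed transitively. Sharing a stretch of length
≥ L is logically equivalent to sharing an exact L-mer, so the partition is
computed from a k-mer index with union-find — an exact algorithm, not a
heuristic — and is verified in the tests against the all-pairs
longest-common-substring dynamic program on small catalogues. Matching is
forward-strand only: assembled transcripts are oriented by ORF prediction.
The representative isoform is the longest ORF, ties broken by smallest id,
which makes gene labelling deterministic. The rule tolerates no mismatches;
a near-identical-stretch variant was considered and rejected because the
exact rule is the one whose boundary (49 vs 50 nt) can be pinned in tests.

## Contamination screening

Each ORF is compared with every prokaryotic reference sequence that shares
at least two exact 11-mers with it (two-hit seeding; a single shared word is
almost always a random collision, while any region long and identical enough
to matter carries many words). Seeded pairs are aligned locally with
BLASTN-like scoring (match +2, mismatch −3, gap open −5, extend −2). The ORF
is discarded iff some window of the aligned columns longer than 100 bp has
identity strictly above 90% — sub-windows are scanned because the rule asks
whether *some* region qualifies, and the score-maximal alignment may embed a
short near-identical core in a longer mediocre context. Gap columns count as
mismatches. Decisions are independent of database order. The screen is
validated against an exhaustive ungapped window oracle on substitution-only
constructions; with indels the seeded/scored search is an approximation, as
any seeded local aligner is.

Prokaryote-affiliated genes that survive (or that only show protein-level
affinity) are re-examined with expression and intron evidence:

- abundance ≤ 10 TPM without an intron → contaminant (the ceiling observed
  for confirmed food-source carry-over),
- an intron, or abundance > 600 TPM → eukaryotic,
- otherwise → uncertain.

TPM here is the replicate-averaged, per-condition value (`condition_mean_tpm`):
abundance statements refer to condition means, which are robust to single
stray reads — on a ~1,500-ORF catalogue one read on a short transcript
already exceeds 10 TPM in a single replicate.

## Expression and differential expression

TPM normalises counts by length within sample and scales columns to 10⁶.
ORFs whose 75th percentile of counts across all samples (linear
interpolation between order statistics, the "type 7" rule) is below 10 reads
are removed before testing. The quantile is taken across all samples jointly
rather than per sample; the alternative reading ("in all samples" as a
per-sample criterion) is stricter and was not adopted.

The DE caller models counts as negative binomial with a log link and
library-size offsets (median-of-ratios size factors). Dispersion is
estimated by moments per gene, (pooled within-condition variance − mean)/mean²,
and moderated toward the dataset-wide mean of raw estimates with prior
weight 20 pseudo-degrees of freedom against the residual degrees (samples
minus two). The plain mean is used for the common value because sample
variances are unbiased, whereas medians or positive-only summaries
under-estimate a shared dispersion and make the test anticonservative. The
condition effect is tested by a likelihood-ratio test against χ²(1); type-I
error at α = 0.05 sits in the 0.04–0.07 range at 2 × 3 replicates on a null
simulation, and power at |log2FC| = 3, mean 200, dispersion 0.1 is ≈ 1.

Fold changes for thresholding are computed on size-factor-normalised counts,
not TPM: TPM is a within-sample composition measure, so a few very highly
expressed responsive transcripts (the LGT-like genes in the simulation, for
example) would bias the TPM ratio of every other gene, while median-of-ratios
normalisation is robust to such shifts. The shrunken fold change
(m₂ + c)/(m₁ + c) with pseudocount c = 1 normalised count is a transparent
bounded estimator standing in for empirical-Bayes posterior fold changes,
which are out of scope; external caller outputs (adjusted p or posterior
probability, with their own fold changes) can be ingested and thresholded on
the same path via the posterior-mode switch (> 0.95). A call requires both
significance (adj. p < 0.05, strict) and fold change < 0.5 or > 2 (strict).

Gene-level reduction: a gene is DE if any isoform is DE; its direction comes
from the DE isoform with the smallest adjusted p. This is configurable and
deliberately simple — isoform-level discordance is reported, not resolved.

## Duplicate detection

Protein comparisons use local alignment with BLOSUM62 and affine gaps
(−11/−1). Identity is matches over aligned columns (internal gaps included);
coverage is the aligned span over the length of the shorter sequence.
Homologs require identity > 30% and coverage > 2/3, both strict. The
candidate rule ranks hits by alignment score (the self-contained search has
no database-size-dependent E-value): a gene is a candidate duplicate iff its
best hit is conspecific and strictly outscores every non-focal hit; ties go
against candidacy. All-against-all search uses an exact shared-5-mer
prefilter with the two-hit rule; at the identities that matter (paralogs at
~95%, panel homologs at ~50–60%) the expected shared-word count is far above
two, while unrelated pairs almost never reach it.

Clusters are connected components of mutual passing conspecific hits (the
construction is otherwise under-determined). Per cluster, the members plus
all their non-focal homologs enter a tree: reference-anchored alignment
(longest sequence anchors the columns; insertions relative to the anchor are
dropped; columns with > 50% gaps trimmed), p-distance, neighbour-joining,
and bootstrap supports as the percentage of 100 column-resampled replicates
containing each bipartition of the full-data tree. External Newick trees
(e.g. from a maximum-likelihood tool) are accepted instead and preferred
when provided; ML inference itself is not reimplemented. The
reference-anchored alignment is exact for indel-free families (as simulated)
and approximate otherwise — another reason external alignments/trees are
ingestible.

Exclusivity is tested on unrooted bipartitions, hence rooting-invariant: a
cluster is accepted iff some internal edge splits exactly its members from
all other leaves with support strictly above 50%. With a single non-focal
leaf the split is topologically forced and counts as a pass (support
reported as none); whether such 3-taxon cases should count is genuinely
open, and the forced-pass choice is the permissive reading, documented here.
On an ingested tree whose relevant edge carries no support value the cluster
is not accepted — exclusivity without quantified support is not evidence.

Copy-number surveys collapse sequences with pairwise identity > 90% by
single linkage before counting.

## Association statistics

Class enrichment uses the hypergeometric distribution; both tails are
computed and the reported p is the tail matching the observed direction.
BH correction runs across retained classes only; six uninformative classes
("Cell motility", "Defense mechanisms", "Unknown function", "General
predictions only", "Nuclear structures", "No hits found") are excluded
before the family is formed. Genes with several classes count once per
class (classes tested marginally).

The duplication × DE association is tested two ways. First, the overlap
test: the fraction of duplicated genes that are DE, with an upper-tail
hypergeometric p against the universe of genes surviving the low-abundance
exclusion (the universe is an explicit parameter — on real data the choice
of gene vs ORF universe materially changes the numbers). Second, the
mixed-direction statistic: the fraction of accepted duplicate clusters
containing at least one up- and one down-regulated member. Its null is
generated by drawing the clustered gene count from the universe's
up/down/none labels without replacement and re-partitioning into the
observed cluster sizes, 1,000 replicates by default; the reported spread is
the sample SD across replicates, and the empirical p uses the (r+1)/(n+1)
convention so it is never exactly zero. The closed form
1 − H(no up) − H(no down) + H(neither), averaged over clusters, serves as an
independent oracle; Monte-Carlo means agree with it within three standard
errors on a fixture grid and at the study scale (11,280 genes, 435 genes in
153 clusters). The cluster-size distribution is an explicit input: in the
integrated pipeline it comes from the detected clusters, and at the study
scale — where the true distribution is unpublished — sizes start at 2 and
the remaining genes are spread uniformly, which makes the study-scale null
value conditional on that choice.

## LGT screening and motifs

The verdict table composes the two published evidence rules literally:
prokaryotic best hits + (intron or > 600 TPM) → candidate; prokaryotic best
hits + ≤ 10 TPM without intron → probable contaminant; other
prokaryote-affiliated genes → uncertain; everything else → not LGT. Clade
exclusivity with prokaryotes (when a tree is supplied) raises a confidence
flag but is not required — on real data it is supporting, not defining,
evidence. The ">600 TPM" figure describes the observed candidates rather
than a designed threshold; it is a parameter with that default. Absence in
a sister lineage is an optional input flag, never computed (it needs
external data).

Motif patterns use `x`/`X` as single-residue wildcards and bracketed
alternation in both spellings (`[KR]`, `[K/R]`); matches are reported
1-based and may overlap. ER-retention checks are positional: KDEL/HDEL as
the last four residues, KK as the last two, KxK as K at −3 and −1, RR as the
first two.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
defaults chosen as the study conditions at desk scale:

| parameter | default | meaning |
|---|---|---|
| n_genes | 1,000 | catalogue size (desk scale; the study's is ~12,000) |
| n_families / sizes | 20, sizes 2–4 (weights .7/.2/.1) | recent duplicate families |
| divergence_per_copy | 0.05 subst./site | pairwise protein divergence within a family |
| panel_divergence | 0.5 | divergence of other-eukaryote homologs |
| species_only_family_fraction | 0.64 | families with no non-focal homolog (mirrors 317/494) |
| n_isoforms_max / shared_stretch_len | 3 / 60 nt | isoforms share a central exact block |
| n_contaminants / contaminant_identity | 20 / 0.95 | prokaryote copies mutated per site |
| n_replicates | 3 per condition | two conditions, fixed |
| de_fraction / de_up_share | 0.20 / 0.62 | DE genes and their direction split |
| de_log2fc_magnitude | 2 | true effect size |
| nb_mean / nb_dispersion | 100 / 0.1 | NB(μ, var = μ + 0.1 μ²) counts |
| low_abundance_fraction | 0.10 | ORFs at near-zero counts |
| contaminant_mean | 0.15 counts | trace carry-over, < 10 TPM at this scale |
| intron_fraction | 0.30 | genes with an intron flag |
| n_lgt | 2 | prokaryote-derived, intron-bearing, ~40× expressed genes |

Protein lengths are uniform on 120–400 aa; per-gene expression factors are
lognormal with σ = 0.8 (mean-preserving), so baseline means straddle
nb_mean realistically. Family members are created by mutating a common
ancestor protein at divergence_per_copy/2 per copy and back-translating each
copy with independently drawn codons: paralogs are therefore close at the
protein level while sharing no long exact nucleotide stretch, so recent
duplicates do not collapse as isoforms — the two rules are kept separable by
construction. Isoforms are codon-aligned truncations (optionally with a
novel 3′ extension) all containing a central exact block of
shared_stretch_len, exercising the 50-nt rule from both sides. Each
contaminant derives from a distinct prokaryote panel sequence, because two
95%-identity copies of the same source would share long exact stretches and
wrongly merge as isoforms. The two LGT-like genes are mutated prokaryote
panel proteins (10% divergence), forced intron-positive, up-regulated and
highly expressed, mirroring the two reported LGT cases.

What the simulation does **not** emulate: indels and codon-usage structure
(substitution-only, uniform codons), splice-graph realism (isoforms are
nested substrings), expression-dependent dispersion trends, batch effects,
and annotation noise. Passing the recovery tests therefore demonstrates the
correctness of the decision rules under their stated assumptions, not
robustness to assembly artefacts or alignment error on real data.

## Determinism and problem sizes

All randomness flows from explicit integer seeds (NumPy `default_rng`); the
pipeline expands one seed per stage and echoes it in `report.json`; the same
configuration yields byte-identical output files. The shipped analyses and
the acceptance script run at the default desk scale (1,000 genes ≈ 1,500
ORFs), a 2,000-gene null for calibration, 200–300 seed replicates for power,
and the study-scale randomization (11,280 genes, 1,000 replicates) — sizes
chosen so the full suite completes in a few minutes on one CPU while leaving
every statistical check adequately powered.

## Known limitations

- The seeded screens can in principle miss adversarial mismatch spacings
  (as can any word-seeded search); thresholds are pinned by construction
  tests, not by exhaustive search.
- The NB likelihood-ratio test is mildly anticonservative at very small
  replicate counts; the moderated dispersion keeps it within the calibrated
  band but a quasi-likelihood F-test would be the next refinement.
- The reference-anchored alignment underestimates divergence when indels are
  common; supply external alignments/trees for real gappy families.
- The study-scale randomization null is conditional on an assumed
  cluster-size distribution; only the dataset-derived null is free of that
  assumption.
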