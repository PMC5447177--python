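# halotrans

Post-assembly transcriptome analysis for a halophilic protist grown at two
salinities. The package implements the computational stages that follow read
assembly and quantification: collapsing ORFs into genes, removing prokaryotic
contaminants, calling differential expression (DE), detecting recently
duplicated gene families by phylogenetic exclusivity, testing the association
between duplication and salt-responsiveness, and screening lateral-gene-
transfer (LGT) candidates. Every stage is exercisable end to end on synthetic
data with known ground truth, so the whole pipeline is testable without any
external database.

## Who this is for

Researchers analysing a de novo two-condition transcriptome of a non-model
eukaryote who need the classic post-assembly decision rules as tested,
reusable code — and a simulator that generates datasets with known gene
families, contaminants and DE structure to validate those rules.

## The rules and statistics implemented

- **Isoform collapsing.** Two ORFs are isoforms of one gene iff they share an
  exact nucleotide stretch of ≥ 50 nt (transitively closed); the longest
  isoform represents the gene.
- **Decontamination.** An ORF is discarded iff it carries a > 100 bp region
  > 90% identical to a prokaryotic reference (both bounds strict). Borderline
  prokaryote-affiliated genes are rescued by eukaryotic evidence: an intron,
  or replicate-averaged abundance > 600 TPM; genes at ≤ 10 TPM (the ceiling
  observed for food-source carry-over) are called contaminants.
- **Differential expression.** TPM_i = 10⁶ · (c_i/l_i) / Σ_j (c_j/l_j);
  ORFs with a 75th count percentile < 10 reads are removed; a
  negative-binomial likelihood-ratio test (log link, median-of-ratios size
  factors, moment-based dispersion moderated toward the common value) gives
  p-values, BH-adjusted; an ORF is DE iff adj. p < 0.05 (or posterior
  probability > 0.95 for ingested empirical-Bayes callers) **and** the
  shrunken fold change FC = (m₂+1)/(m₁+1) is < 0.5 or > 2.
- **Recent duplicates.** A gene is a candidate duplicate when its best
  protein hit is conspecific and strictly outscores every other-organism
  homolog (homologs = identity > 30% over > 2/3 of the shorter sequence).
  Candidates cluster by mutual hits; a cluster is accepted when its members
  form an exclusive clade with bootstrap support > 50% on a neighbour-joining
  tree (100 column-resampled pseudoreplicates). Clusters with no non-focal
  homolog at all are "species-only". A > 90%-identity dedup supports
  copy-number surveys.
- **Association statistics.** Hypergeometric COG-class enrichment with BH
  correction (six uninformative classes excluded from the family); the
  duplication × DE overlap test P(X ≥ k) under Hypergeom(N, K, n); and the
  mixed-direction cluster statistic — the fraction of duplicate clusters
  containing both an up- and a down-regulated member — against a
  cluster-randomization null (genes drawn without replacement and
  re-partitioned into the observed cluster sizes, 1,000 replicates) with a
  closed-form expectation 1 − P(no up) − P(no down) + P(neither) as an
  independent check.
- **LGT screening.** Prokaryotic best hits + (intron or > 600 TPM) →
  candidate; prokaryotic best hits + ≤ 10 TPM without intron → probable
  contaminant. Wildcard motif scans (e.g. `PxLXHGDLWSxN`, `Tx[K/R]`) and
  ER-retention signals (KDEL/HDEL/KK/KxK C-terminal, RR N-terminal) support
  the case-level evidence.

## Worked example

```python
from halotrans.synthetic_data import SimConfig, simulate_dataset, write_dataset
from halotrans.pipeline import RunConfig, run_all

write_dataset(simulate_dataset(SimConfig(seed=5)), "scratch/demo")
report = run_all(RunConfig(input_dir="scratch/demo", out_dir="scratch/demo_out", seed=5))
for key in ("n_orfs_in", "n_orfs_discarded_contaminant", "n_genes_after_collapse",
            "n_de_genes", "n_de_up", "n_de_down", "clusters_by_category",
            "mixed_direction_null_mean", "lgt_verdict_counts"):
    print(key, report[key])
```

prints (seed 5):

```
n_orfs_in 1504
n_orfs_discarded_contaminant 20
n_genes_after_collapse 1000
n_de_genes 198
n_de_up 118
n_de_down 80
clusters_by_category {'species_only': 13, 'exclusive_clade': 7, 'rejected': 0}
mixed_direction_null_mean 0.043
lgt_verdict_counts {'lgt_candidate': 2}
```

Reading: all 20 planted contaminants were discarded and none of the 1,484
eukaryotic ORFs was lost; the 1,484 ORFs collapse back into exactly the
1,000 true genes; 198 genes are called DE (sensitivity 0.945 against the 200
truly DE genes, empirical FDR 0.045) with a ~60/40 up/down split matching
the configured 62/38 within sampling error; all 20 planted
duplicate families are found, 7 of them as bootstrap-supported exclusive
clades (the others have no non-focal homolog, hence species-only); and both
planted LGT-like genes are flagged as candidates. The randomization null for
mixed-direction clusters (4.3%) matches the closed-form expectation.

The same stages are available as numbered drivers under `analysis/`
(`01_simulate.py` … `06_lgt_motifs.py`, writing tables to `results/`) and as
a CLI (`halotrans simulate|collapse|decontam|tpm|de|consensus|dupfind|enrich|
randtest|lgt|motif|run-all`).

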