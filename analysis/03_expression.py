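#!/usr/bin/env python
"""Quantify expression and call differential expression.

Computes TPM, removes ORFs with low counts (75th quantile < 10 reads), runs
the negative-binomial likelihood-ratio test with BH correction, and calls
DE at adjusted p < 0.05 with shrunken fold change < 0.5 or > 2. Also shows
the consensus operation by intersecting the NB caller with a more lenient
and a more stringent variant of itself. Writes expression.tsv and
gene_de.tsv under results/expression/.
"""

from pathlib import Path

import pandas as pd

from halotrans.expression_de import (
    consensus_de,
    gene_level_de,
    low_expression_filter,
    summarize_expression,
)
from halotrans.synthetic_data import load_dataset

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = load_dataset(ROOT / "dataset")
    out = ROOT / "expression"
    out.mkdir(parents=True, exist_ok=True)
    genes = pd.read_csv(ROOT / "catalog" / "genes.tsv", sep="\t")
    gene_of_orf = {
        oid: row.gene_id for row in genes.itertuples() for oid in row.orf_ids.split(",")
    }

    counts = data["counts"].subset(sorted(gene_of_orf))
    kept = low_expression_filter(counts)
    print(f"{len(counts.counts)} retained ORFs; {len(counts.counts) - len(kept)} removed by the low-count filter")

    summary = summarize_expression(counts.subset(kept))
    summary.to_csv(out / "expression.tsv", sep="\t")
    n_de = int(summary["de_flag"].sum())
    n_up = int((summary["direction"] == "up").sum())
    print(f"DE ORFs: {n_de} ({n_up} up, {n_de - n_up} down; "
          f"{100 * n_up / max(1, n_de):.0f}% up-regulated at high salt)")

    gene_de = gene_level_de(summary, gene_of_orf)
    gene_de.to_csv(out / "gene_de.tsv", sep="\t")
    print(f"DE genes after isoform reduction: {int(gene_de['de_flag'].sum())}")

    # consensus across three thresholds of the same caller (strict/default/lenient)
    callers = {}
    for name, alpha in (("strict", 0.01), ("default", 0.05), ("lenient", 0.10)):
        called = summarize_expression(counts.subset(kept), alpha=alpha)
        callers[name] = called[["de_flag", "direction"]]
    cons = consensus_de(callers)
    print(f"consensus: flagged by all three = {cons['n_all']}, by any = {cons['n_any']}")

    truth = data["truth"]
    if truth:
        true_de = {g for g, s in truth.de_status.items() if s != "none"}
        rec = {gene_of_orf_to_truth(gene_of_orf, truth, g) for g in gene_de.index[gene_de["de_flag"]]}
        tp = len(rec & true_de)
        print(f"  sensitivity {tp / len(true_de):.3f}, empirical FDR {1 - tp / max(1, len(rec)):.3f}")


def gene_of_orf_to_truth(gene_of_orf, truth, gene_id):
    for oid, g in gene_of_orf.items():
        if g == gene_id:
            return truth.gene_of_orf[oid]
    raise KeyError(gene_id)


if __name__ == "__main__":
    main()
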