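#!/usr/bin/env python
"""Association statistics: enrichment, duplication x DE, mixed-direction null.

Tests COG-class enrichment of DE genes (hypergeometric + BH, six
uninformative classes excluded), the overlap between duplicated and DE
genes, and the fraction of duplicate clusters holding both up- and
down-regulated members against a cluster-randomization null (1,000
replicates) plus its closed-form expectation. Repeats the randomization at
the study scale: 11,280 genes, 435 assigned to 153 clusters. Writes
enrichment.tsv and randomization.json under results/association/.
"""

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from halotrans.association import (
    analytic_mixed_expectation,
    class_enrichment,
    dup_de_overlap_test,
    mixed_direction_fraction,
    randomization_null,
)
from halotrans.synthetic_data import load_dataset

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 5) -> None:
    data = load_dataset(ROOT / "dataset")
    out = ROOT / "association"
    out.mkdir(parents=True, exist_ok=True)

    gene_de = pd.read_csv(ROOT / "expression" / "gene_de.tsv", sep="\t", index_col=0)
    clusters = pd.read_csv(ROOT / "duplication" / "clusters.tsv", sep="\t")
    genes = pd.read_csv(ROOT / "catalog" / "genes.tsv", sep="\t")
    cog_of_orf = data["cog_of_orf"]

    universe = sorted(gene_de.index)
    de_genes = sorted(gene_de.index[gene_de["de_flag"]])
    direction = {g: gene_de.loc[g, "direction"] for g in universe}

    annotations = {}
    for row in genes.itertuples():
        classes = {cog_of_orf.get(o, "") for o in row.orf_ids.split(",")} - {""}
        annotations[row.gene_id] = classes
    enrichment = class_enrichment(annotations, de_genes, universe)
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    sig = enrichment[enrichment["adj_p"] < 0.05]
    print(f"enrichment: {len(enrichment)} classes tested, {len(sig)} significant at adj p < 0.05")

    accepted = clusters[clusters["category"].isin(["exclusive_clade", "species_only"])]
    dup_genes = sorted(
        {m for row in accepted.itertuples() for m in row.members.split(",")} & set(universe)
    )
    frac, p = dup_de_overlap_test(dup_genes, de_genes, universe)
    print(f"duplicated genes in universe: {len(dup_genes)}; "
          f"{100 * frac:.0f}% are DE (hypergeometric p = {p:.3g})")

    exclusive = clusters[clusters["category"] == "exclusive_clade"]
    member_sets = [row.members.split(",") for row in exclusive.itertuples()]
    full_dir = dict(direction)
    for ms in member_sets:
        for m in ms:
            full_dir.setdefault(m, "none")
    observed = mixed_direction_fraction(member_sets, full_dir) if member_sets else None
    results = {}
    if observed is not None:
        sizes = [len(m) for m in member_sets]
        labels = [direction[g] for g in universe]
        res = randomization_null(labels, sum(sizes), sizes, n_reps=1000, seed=seed, observed=observed)
        analytic = analytic_mixed_expectation(
            len(labels), labels.count("up"), labels.count("down"), sizes
        )
        print(f"mixed-direction clusters: observed {100 * observed:.1f}% vs null "
              f"{100 * res.null_mean:.1f} ± {100 * res.null_sd:.1f}% "
              f"(analytic {100 * analytic:.1f}%, empirical p = {res.empirical_p:.3f})")
        results["dataset"] = {**asdict(res), "analytic_expectation": analytic}

    # study-scale configuration with the printed DE direction counts
    N, n_genes, n_clusters = 11280, 435, 153
    n_up = int(round(2871 * 0.62))
    n_down = 2871 - n_up
    labels = ["up"] * n_up + ["down"] * n_down + ["none"] * (N - n_up - n_down)
    sizes = [2] * n_clusters
    import numpy as np

    rng = np.random.default_rng(seed)
    for _ in range(n_genes - 2 * n_clusters):
        sizes[int(rng.integers(0, n_clusters))] += 1
    res = randomization_null(labels, n_genes, sizes, n_reps=1000, seed=seed + 1)
    analytic = analytic_mixed_expectation(N, n_up, n_down, sizes)
    print(f"study scale: null mean {100 * res.null_mean:.1f} ± {100 * res.null_sd:.1f}% "
          f"(analytic {100 * analytic:.1f}%)")
    results["study_scale"] = {**asdict(res), "analytic_expectation": analytic}
    (out / "randomization.json").write_text(json.dumps(results, indent=1))


if __name__ == "__main__":
    main()
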