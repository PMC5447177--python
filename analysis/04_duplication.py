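#!/usr/bin/env python
"""Detect recently duplicated gene clusters.

Ranks each gene's conspecific hits against the other-eukaryote and
prokaryote panels, clusters mutual hits (identity > 30%, coverage of the
shorter sequence > 2/3), builds 100-replicate bootstrap NJ trees and keeps
clusters whose members form an exclusive clade with support > 50%. Writes
clusters.tsv and affinity.tsv (per-gene prokaryotic best-hit flag) under
results/duplication/.
"""

from pathlib import Path

import pandas as pd

from halotrans.duplication import detect_duplicate_clusters
from halotrans.synthetic_data import load_dataset

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 5) -> None:
    data = load_dataset(ROOT / "dataset")
    out = ROOT / "duplication"
    out.mkdir(parents=True, exist_ok=True)
    genes = pd.read_csv(ROOT / "catalog" / "genes.tsv", sep="\t")
    aa = {o.orf_id: o.aa_seq for o in data["orfs"]}
    focal = {
        row.gene_id: aa[row.representative]
        for row in genes.itertuples()
        if aa.get(row.representative)
    }
    panel = list(data["eukaryote_panel_aa"]) + list(data["prokaryote_panel_aa"])

    clusters, summary = detect_duplicate_clusters(focal, panel, seed=seed)
    pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "members": ",".join(sorted(c.member_gene_ids)),
                "category": c.category,
                "support": "" if c.clade_support is None else c.clade_support,
            }
            for c in clusters
        ]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)

    affinity_rows = []
    for gid, hits in summary["hits"].items():
        best_prok = False
        if hits:
            best = max(h.score for h in hits)
            best_prok = {h.subject_origin for h in hits if h.score == best} == {"prokaryote"}
        affinity_rows.append({"gene_id": gid, "best_hits_prokaryotic": int(best_prok)})
    pd.DataFrame(affinity_rows).to_csv(out / "affinity.tsv", sep="\t", index=False)

    print(f"{summary['n_clusters']} clusters holding {summary['n_genes_clustered']} genes")
    for cat, n in summary["by_category"].items():
        print(f"  {cat}: {n} clusters, {summary['n_genes_by_category'][cat]} genes")
    truth = data["truth"]
    if truth:
        fams = truth.family_members()
        print(f"  true families: {len(fams)}")


if __name__ == "__main__":
    main()
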