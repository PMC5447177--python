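#!/usr/bin/env python
"""Screen lateral-gene-transfer candidates and scan diagnostic motifs.

Genes whose best protein hits are prokaryotic are screened with the
combined evidence rules (intron presence, abundance >600 TPM vs the <=10
TPM contamination ceiling). All proteins are additionally scanned for the
aminoglycoside-kinase motif PxLXHGDLWSxN, the protein-kinase-C consensus
site Tx[K/R] and ER-retention signals. Writes lgt.tsv and motifs.tsv under
results/lgt/.
"""

from pathlib import Path

import pandas as pd

from halotrans.duplication import HomologHit
from halotrans.expression_de import condition_mean_tpm
from halotrans.lgt_motifs import check_er_retention, scan_motif, screen_lgt_candidate
from halotrans.synthetic_data import load_dataset

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = load_dataset(ROOT / "dataset")
    out = ROOT / "lgt"
    out.mkdir(parents=True, exist_ok=True)
    genes = pd.read_csv(ROOT / "catalog" / "genes.tsv", sep="\t")
    affinity = pd.read_csv(ROOT / "duplication" / "affinity.tsv", sep="\t", index_col=0)
    tpm = condition_mean_tpm(data["counts"])
    intron_of_orf = data["intron_of_orf"]

    rows = []
    for row in genes.itertuples():
        if not affinity.loc[row.gene_id, "best_hits_prokaryotic"]:
            continue
        orf_ids = row.orf_ids.split(",")
        max_tpm = float(tpm.loc[[o for o in orf_ids if o in tpm.index]].values.max())
        has_intron = any(intron_of_orf.get(o, False) for o in orf_ids)
        hits = [HomologHit(row.gene_id, "prok_best", "prokaryote", 500.0, 0.9, 1.0)]
        cand = screen_lgt_candidate(row.gene_id, hits, max_tpm, has_intron)
        rows.append(vars(cand))
    lgt_table = pd.DataFrame(rows)
    lgt_table.to_csv(out / "lgt.tsv", sep="\t", index=False)
    if len(lgt_table):
        print("LGT screening of prokaryote-affiliated genes:")
        print(lgt_table["verdict"].value_counts().to_string())
    else:
        print("no prokaryote-affiliated genes found")

    aa = {o.orf_id: o.aa_seq for o in data["orfs"] if o.aa_seq}
    motif_rows = []
    for pattern, name in (("PxLXHGDLWSxN", "aminoglycoside_kinase"), ("Tx[K/R]", "pkc_site")):
        for oid, seq in aa.items():
            for hit in scan_motif(seq, pattern, oid, name):
                motif_rows.append(vars(hit))
    er_count = sum(1 for seq in aa.values() if any(check_er_retention(seq).values()))
    pd.DataFrame(motif_rows).to_csv(out / "motifs.tsv", sep="\t", index=False)
    by_motif = pd.DataFrame(motif_rows)["motif_name"].value_counts() if motif_rows else {}
    print(f"motif hits: {dict(by_motif)}")
    print(f"proteins with an ER-retention signal: {er_count}/{len(aa)}")


if __name__ == "__main__":
    main()
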