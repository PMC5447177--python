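#!/usr/bin/env python
"""Generate the default synthetic study dataset.

Writes the full input layout (ORF FASTA, panels, counts, annotations, truth)
to results/dataset/ under the default study conditions: 1,000 genes, 20
duplicate families, 2 x 3 replicates with 20% DE split 62/38, 20
contaminants at 95% identity and two LGT-like genes.
"""

from pathlib import Path

from halotrans.synthetic_data import SimConfig, simulate_dataset, write_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "dataset"


def main(seed: int = 5) -> None:
    cfg = SimConfig(seed=seed)
    ds = simulate_dataset(cfg)
    write_dataset(ds, OUT)
    truth = ds.truth
    n_de = sum(1 for s in truth.de_status.values() if s != "none")
    n_up = sum(1 for s in truth.de_status.values() if s == "up")
    print(f"wrote {OUT}")
    print(f"  ORFs: {len(ds.orfs)} ({len(truth.contaminant_orfs)} contaminants)")
    print(f"  genes: {cfg.n_genes}; families: {len(truth.family_members())}")
    print(f"  DE genes: {n_de} ({n_up} up / {n_de - n_up} down); LGT-like: {len(truth.lgt_genes)}")


if __name__ == "__main__":
    main()
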