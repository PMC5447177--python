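"""End-to-end orchestration of the analysis stages.

Stage order follows the methodology: decontaminate, collapse isoforms,
quantify and call differential expression, detect duplicate clusters, run
the association statistics (which need DE directions and cluster sizes),
then screen lateral-transfer candidates. Every stage's thresholds default to
the published values; all randomness flows from a single seed expanded per
stage and echoed in the report.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import duplication as dup
from . import expression_de as expr
from . import lgt_motifs as lgt
from . import transcript_catalog as catalog
from .synthetic_data import load_dataset

__all__ = ["RunConfig", "PipelineError", "run_all"]


@dataclass
class RunConfig:
    """All stage thresholds; defaults are the published values."""

    input_dir: str
    out_dir: str
    min_shared: int = 50  # nt, shared-stretch isoform rule (non-strict)
    contam_min_len: int = 100  # bp, strict
    contam_min_identity: float = 0.90  # strict
    contaminant_tpm_ceiling: float = 10.0
    confident_eukaryotic_tpm: float = 600.0
    low_quantile: float = 0.75
    low_threshold: float = 10.0
    alpha: float = 0.05
    posterior_cutoff: float = 0.95
    fc_low: float = 0.5
    fc_high: float = 2.0
    min_identity: float = 0.30  # strict
    min_coverage: float = 2.0 / 3.0  # strict
    min_support: float = 50.0  # strict
    n_bootstrap: int = 100
    rand_reps: int = 1000
    seed: int = 0
    tree_dir: str | None = None


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, fn, timings: dict):
    start = time.perf_counter()
    try:
        out = fn()
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap with stage context
        raise PipelineError(name, exc) from exc
    timings[name] = round(time.perf_counter() - start, 3)
    return out


def run_all(config: RunConfig) -> dict:
    """Run every stage on an input directory; returns the run report.

    Writes contamination.tsv, genes.tsv, expression.tsv, clusters.tsv,
    enrichment.tsv, randomization.json, lgt.tsv and report.json under
    ``config.out_dir``. The returned dict carries the report plus in-memory
    tables under the ``tables`` key.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(rng.integers(0, 2**31 - 1)) for name in ("duplication", "randomization")}

    data = _stage("load", lambda: load_dataset(config.input_dir), timings)
    orfs = data["orfs"]

    # ---- decontamination -------------------------------------------------
    def do_decontam():
        hits = catalog.screen_orfs(
            orfs, data["prokaryote_panel_nt"], config.contam_min_len, config.contam_min_identity
        )
        pd.DataFrame([vars(h) for h in hits]).to_csv(out / "contamination.tsv", sep="\t", index=False)
        discarded = {h.orf_id for h in hits if h.decision == "discard"}
        return hits, discarded

    contamination_hits, discarded = _stage("decontam", do_decontam, timings)
    retained_orfs = [o for o in orfs if o.orf_id not in discarded]

    # ---- isoform collapsing ---------------------------------------------
    genes = _stage(
        "collapse",
        lambda: catalog.collapse_orfs_to_genes(retained_orfs, config.min_shared),
        timings,
    )
    orf_by_id = {o.orf_id: o for o in retained_orfs}
    gene_of_orf = {oid: g.gene_id for g in genes for oid in g.orf_ids}
    for g in genes:
        g.cog_classes = {
            c for oid in g.orf_ids for c in [data["cog_of_orf"].get(oid, "")] if c
        }
        g.has_intron = any(data["intron_of_orf"].get(oid, False) for oid in g.orf_ids)

    # ---- expression ------------------------------------------------------
    def do_expression():
        counts = data["counts"].subset([o.orf_id for o in retained_orfs])
        tpm = expr.condition_mean_tpm(counts)
        kept = expr.low_expression_filter(counts, config.low_quantile, config.low_threshold)
        summary = expr.summarize_expression(
            counts.subset(kept), config.alpha, config.fc_low, config.fc_high
        )
        summary.to_csv(out / "expression.tsv", sep="\t")
        gene_table = expr.gene_level_de(summary, gene_of_orf)
        return counts, tpm, kept, summary, gene_table

    counts, tpm, kept_orfs, summary, gene_de = _stage("expression", do_expression, timings)
    max_tpm_of_gene = {
        g.gene_id: float(tpm.loc[[o for o in g.orf_ids], :].values.max()) for g in genes
    }

    # ---- duplication -----------------------------------------------------
    def do_duplication():
        focal = {
            g.gene_id: orf_by_id[g.representative_orf].aa_seq
            for g in genes
            if orf_by_id[g.representative_orf].aa_seq
        }
        panel = list(data["eukaryote_panel_aa"]) + list(data["prokaryote_panel_aa"])
        external = None
        source = "internal"
        if config.tree_dir:
            source = "external"
            external = {}
            for path in sorted(Path(config.tree_dir).glob("*.nwk")):
                external[path.stem] = dup.PhyloTree.from_newick(path.read_text())
        clusters, dsummary = dup.detect_duplicate_clusters(
            focal,
            panel,
            tree_source=source,
            external_trees=external,
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
            min_support=config.min_support,
            n_bootstrap=config.n_bootstrap,
            seed=stage_seeds["duplication"],
        )
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
        return clusters, dsummary

    clusters, dup_summary = _stage("duplication", do_duplication, timings)

    # gene origin labels from similarity affinity + abundance/intron evidence
    hits_of_gene = dup_summary["hits"]
    affinity = {}
    for g in genes:
        hits = hits_of_gene.get(g.gene_id, [])
        if hits:
            best = max(h.score for h in hits)
            affinity[g.gene_id] = {h.subject_origin for h in hits if h.score == best} == {"prokaryote"}
        else:
            affinity[g.gene_id] = False
    for g in genes:
        g.origin_label = catalog.classify_origin_by_abundance(
            g,
            max_tpm_of_gene[g.gene_id],
            affinity[g.gene_id],
            config.contaminant_tpm_ceiling,
            config.confident_eukaryotic_tpm,
        )
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "orf_ids": ",".join(sorted(g.orf_ids)),
                "representative": g.representative_orf,
                "n_isoforms": len(g.orf_ids),
                "has_intron": int(g.has_intron),
                "origin_label": g.origin_label,
            }
            for g in genes
        ]
    ).to_csv(out / "genes.tsv", sep="\t", index=False)

    # ---- association -----------------------------------------------------
    def do_association():
        kept_set = set(kept_orfs)
        universe = sorted({g.gene_id for g in genes if set(g.orf_ids) & kept_set})
        de_genes = sorted(g for g in universe if g in gene_de.index and gene_de.loc[g, "de_flag"])
        direction = {
            g: (str(gene_de.loc[g, "direction"]) if g in gene_de.index else "none")
            for g in universe
        }
        accepted = [c for c in clusters if c.category in ("species_only", "exclusive_clade")]
        dup_genes = sorted({m for c in accepted for m in c.member_gene_ids} & set(universe))
        overlap_fraction = overlap_p = None
        if dup_genes:
            overlap_fraction, overlap_p = assoc.dup_de_overlap_test(dup_genes, de_genes, universe)
        annotations = {g.gene_id: sorted(g.cog_classes) for g in genes}
        enrichment = assoc.class_enrichment(annotations, de_genes, universe)
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)

        exclusive = [c for c in clusters if c.category == "exclusive_clade"]
        randomization = None
        observed_mixed = None
        analytic = None
        if exclusive:
            cluster_sets = [sorted(c.member_gene_ids) for c in exclusive]
            full_direction = dict(direction)
            for c in exclusive:
                for m in c.member_gene_ids:
                    full_direction.setdefault(m, "none")
            observed_mixed = assoc.mixed_direction_fraction(cluster_sets, full_direction)
            sizes = [len(c.member_gene_ids) for c in exclusive]
            labels = [direction[g] for g in universe]
            randomization = assoc.randomization_null(
                labels,
                sum(sizes),
                sizes,
                n_reps=config.rand_reps,
                seed=stage_seeds["randomization"],
                observed=observed_mixed,
            )
            analytic = assoc.analytic_mixed_expectation(
                len(labels),
                sum(1 for l in labels if l == "up"),
                sum(1 for l in labels if l == "down"),
                sizes,
            )
            (out / "randomization.json").write_text(
                json.dumps({**asdict(randomization), "analytic_expectation": analytic}, indent=1)
            )
        return {
            "universe": universe,
            "de_genes": de_genes,
            "dup_genes": dup_genes,
            "overlap_fraction": overlap_fraction,
            "overlap_p": overlap_p,
            "enrichment": enrichment,
            "observed_mixed": observed_mixed,
            "randomization": randomization,
            "analytic": analytic,
        }

    assoc_out = _stage("association", do_association, timings)

    # ---- LGT screening ---------------------------------------------------
    def do_lgt():
        rows = []
        for g in genes:
            if not affinity[g.gene_id]:
                continue
            cand = lgt.screen_lgt_candidate(
                g.gene_id,
                hits_of_gene.get(g.gene_id, []),
                max_tpm_of_gene[g.gene_id],
                g.has_intron,
                high_tpm=config.confident_eukaryotic_tpm,
                contaminant_tpm=config.contaminant_tpm_ceiling,
            )
            rows.append(vars(cand))
        table = pd.DataFrame(rows)
        table.to_csv(out / "lgt.tsv", sep="\t", index=False)
        return table

    lgt_table = _stage("lgt", do_lgt, timings)
    verdict_counts = (
        lgt_table["verdict"].value_counts().to_dict() if len(lgt_table) else {}
    )

    de_flags = gene_de[gene_de["de_flag"]]
    rand = assoc_out["randomization"]
    report = {
        "seed": config.seed,
        "config": asdict(config),
        "n_orfs_in": len(orfs),
        "n_orfs_discarded_contaminant": len(discarded),
        "n_orfs_retained": len(retained_orfs),
        "n_genes_after_collapse": len(genes),
        "n_orfs_after_low_count_filter": len(kept_orfs),
        "n_genes_in_universe": len(assoc_out["universe"]),
        "n_de_genes": len(assoc_out["de_genes"]),
        "n_de_up": int((de_flags["direction"] == "up").sum()),
        "n_de_down": int((de_flags["direction"] == "down").sum()),
        "clusters_by_category": dup_summary["by_category"],
        "genes_in_clusters_by_category": dup_summary["n_genes_by_category"],
        "n_duplicated_genes_in_universe": len(assoc_out["dup_genes"]),
        "dup_de_overlap_fraction": assoc_out["overlap_fraction"],
        "dup_de_overlap_p": assoc_out["overlap_p"],
        "mixed_direction_observed": assoc_out["observed_mixed"],
        "mixed_direction_null_mean": rand.null_mean if rand else None,
        "mixed_direction_null_sd": rand.null_sd if rand else None,
        "mixed_direction_empirical_p": rand.empirical_p if rand else None,
        "mixed_direction_analytic": assoc_out["analytic"],
        "lgt_verdict_counts": verdict_counts,
        "wall_clock_s": timings,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    report["tables"] = {
        "genes": genes,
        "gene_of_orf": gene_of_orf,
        "contamination": contamination_hits,
        "expression": summary,
        "gene_de": gene_de,
        "clusters": clusters,
        "enrichment": assoc_out["enrichment"],
        "lgt": lgt_table,
        "universe": assoc_out["universe"],
    }
    return report
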