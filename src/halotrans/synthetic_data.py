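"""Synthetic two-condition transcriptome datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: gene families created by recent duplication with tunable protein
divergence, alternative isoforms sharing an exact central nucleotide block,
prokaryotic contaminant transcripts at tunable identity, a three-way
conspecific / other-eukaryote / prokaryote protein panel, lateral-transfer
-like genes (prokaryote-derived, intron-bearing, highly expressed), and
negative-binomial counts for two conditions with a designated
up/down-regulated gene set (62/38 direction split by default).

Family members are re-back-translated independently codon by codon, so
paralogs are close at the protein level while sharing no long exact
nucleotide stretch — recent duplicates must not collapse as isoforms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .duplication import PanelSeq
from .expression_de import CountMatrix
from .transcript_catalog import OrfRecord

__all__ = [
    "SimConfig",
    "TruthTables",
    "SimulatedDataset",
    "ConfigError",
    "simulate_dataset",
    "simulate_counts",
    "write_dataset",
    "load_dataset",
]

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_TABLE = unambiguous_dna_by_id[1]
_CODONS_OF: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _CODONS_OF.setdefault(aa, []).append(codon)


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


_DEFAULT_COG = (
    ("Translation, ribosomal structure and biogenesis", 2.0),
    ("Replication, recombination and repair", 1.5),
    ("Posttranslational modification, protein turnover, chaperones", 1.5),
    ("Signal transduction mechanisms", 1.5),
    ("Inorganic ion transport and metabolism", 1.0),
    ("Amino acid transport and metabolism", 1.0),
    ("Carbohydrate transport and metabolism", 1.0),
    ("Lipid transport and metabolism", 1.0),
    ("Intracellular trafficking, secretion, and vesicular transport", 1.0),
    ("Energy production and conversion", 1.0),
    ("Cytoskeleton", 0.8),
    ("Cell motility", 0.1),
    ("Defense mechanisms", 0.1),
    ("Unknown function", 0.5),
)


@dataclass
class SimConfig:
    """Dataset-level simulation parameters.

    Defaults are the desk-scale study conditions: 1,000 genes, 20 duplicate
    families at 5% per-copy protein divergence, 20% DE genes split 62/38
    up/down with |log2FC| = 2, NB counts (mean 100, dispersion 0.1) over
    2 x 3 replicates, 2% contaminants at 95% identity, and two
    lateral-transfer-like genes mirroring the two reported LGT cases.
    """

    n_genes: int = 1000
    n_families: int = 20
    family_size_distribution: Sequence[tuple[int, float]] = ((2, 0.7), (3, 0.2), (4, 0.1))
    divergence_per_copy: float = 0.05
    n_isoforms_max: int = 3
    shared_stretch_len: int = 60
    n_contaminants: int = 20
    contaminant_identity: float = 0.95
    n_conditions: int = 2
    n_replicates: int = 3
    de_fraction: float = 0.2
    de_up_share: float = 0.62
    de_log2fc_magnitude: float = 2.0
    nb_mean: float = 100.0
    nb_dispersion: float = 0.1
    low_abundance_fraction: float = 0.1
    intron_fraction: float = 0.3
    cog_classes: Sequence[tuple[str, float]] = _DEFAULT_COG
    seed: int = 0
    # panel structure
    panel_divergence: float = 0.5
    species_only_family_fraction: float = 0.64
    ortholog_distractor_fraction: float = 0.05
    n_lgt: int = 2
    lgt_divergence: float = 0.10
    n_prokaryote_panel: int = 12
    n_random_eukaryote_panel: int = 10
    # sequence / expression shape
    protein_length_range: tuple[int, int] = (120, 400)
    expression_sigma: float = 0.8
    lgt_expression_boost: float = 40.0
    low_abundance_mean: float = 0.3
    # trace abundance of food-source carry-over: stays below the 10-TPM
    # contamination ceiling at the default catalogue size
    contaminant_mean: float = 0.15

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_families < 0:
            raise ConfigError("n_families must be >= 0")
        sizes = [s for s, _ in self.family_size_distribution]
        weights = [w for _, w in self.family_size_distribution]
        if any(s < 2 for s in sizes):
            raise ConfigError("family_size_distribution sizes must be >= 2")
        if sum(weights) <= 0 or any(w < 0 for w in weights):
            raise ConfigError("family_size_distribution weights must be non-negative and sum > 0")
        if not 0 <= self.divergence_per_copy < 1:
            raise ConfigError("divergence_per_copy must lie in [0, 1)")
        if self.n_isoforms_max < 1:
            raise ConfigError("n_isoforms_max must be >= 1")
        if self.shared_stretch_len < 3:
            raise ConfigError("shared_stretch_len must be >= 3")
        if not 0.9 < self.contaminant_identity <= 1:
            raise ConfigError("contaminant_identity must lie in (0.9, 1]")
        if self.n_conditions != 2:
            raise ConfigError("n_conditions is fixed at 2")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        for name in (
            "de_fraction",
            "de_up_share",
            "low_abundance_fraction",
            "intron_fraction",
            "species_only_family_fraction",
            "ortholog_distractor_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.de_log2fc_magnitude <= 0:
            raise ConfigError("de_log2fc_magnitude must be > 0")
        if self.nb_mean <= 0:
            raise ConfigError("nb_mean must be > 0")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        cw = [w for _, w in self.cog_classes]
        if not cw or sum(cw) <= 0:
            raise ConfigError("cog_classes weights must sum to a positive value")
        total_family = sum(sizes) * self.n_families  # upper bound check
        if self.n_families and max(sizes) * self.n_families > self.n_genes:
            raise ConfigError("n_families too large for n_genes")
        if self.protein_length_range[0] < 30:
            raise ConfigError("protein_length_range minimum must be >= 30")


@dataclass
class TruthTables:
    gene_of_orf: dict[str, str]
    family_of_gene: dict[str, str | None]
    de_status: dict[str, str]  # up | down | none
    origin: dict[str, str]  # per sequence id: focal | other_eukaryote | prokaryote | contaminant
    intron: dict[str, bool]
    lgt_genes: list[str] = field(default_factory=list)
    contaminant_orfs: list[str] = field(default_factory=list)

    def family_members(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for gene, fam in self.family_of_gene.items():
            if fam is not None:
                fams.setdefault(fam, []).append(gene)
        return {f: sorted(m) for f, m in fams.items()}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthTables":
        return cls(**json.loads(text))


@dataclass
class SimulatedDataset:
    config: SimConfig
    orfs: list[OrfRecord]
    counts: CountMatrix
    cog_of_gene: dict[str, str]
    intron_of_gene: dict[str, bool]
    prokaryote_panel_nt: dict[str, str]
    prokaryote_panel_aa: list[PanelSeq]
    eukaryote_panel_aa: list[PanelSeq]
    truth: TruthTables


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA20, size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in _AA20 if a != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _back_translate(rng: np.random.Generator, aa: str) -> str:
    parts = []
    for residue in aa:
        codons = _CODONS_OF[residue]
        parts.append(codons[rng.integers(0, len(codons))])
    return "".join(parts)


def _mutate_nt(rng: np.random.Generator, seq: str, rate: float) -> str:
    bases = "ACGT"
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [b for b in bases if b != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _translate(nt: str) -> str:
    return str(Seq(nt[: len(nt) // 3 * 3]).translate()).replace("*", "X")


def simulate_counts(
    design: Mapping[str, str],
    de_truth: Mapping[str, str],
    nb_mean: float,
    nb_dispersion: float,
    de_log2fc_magnitude: float,
    lengths: Mapping[str, int],
    seed: int = 0,
    expression_factors: Mapping[str, float] | None = None,
) -> CountMatrix:
    """Negative-binomial counts for a two-condition replicate layout.

    Per-feature baseline means are proportional to feature length (so that
    downstream TPM is length-corrected) around ``nb_mean``; features marked
    ``up`` in ``de_truth`` have their second-condition mean multiplied by
    2**de_log2fc_magnitude, features marked ``down`` divided by it. Variance
    follows mu + dispersion * mu^2 (dispersion 0 gives the Poisson limit).
    ``expression_factors`` scales per-feature baselines (default 1).
    """
    if nb_dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    ids = sorted(lengths)
    for fid in ids:
        if lengths[fid] <= 0:
            raise ValueError(f"zero-length feature {fid!r}")
    missing = [g for g in de_truth if g not in lengths]
    if missing:
        raise ValueError(f"de_truth features without a length: {missing[:5]}")
    conditions = sorted(set(design.values()))
    if len(conditions) != 2:
        raise ValueError("design must have exactly 2 conditions")
    samples = sorted(design)
    rng = np.random.default_rng(seed)
    mean_len = float(np.mean([lengths[i] for i in ids]))
    fc = 2.0**de_log2fc_magnitude
    base = np.array(
        [
            nb_mean
            * (lengths[i] / mean_len)
            * (expression_factors.get(i, 1.0) if expression_factors else 1.0)
            for i in ids
        ]
    )
    cond2_factor = np.array(
        [fc if de_truth.get(i) == "up" else (1 / fc if de_truth.get(i) == "down" else 1.0) for i in ids]
    )
    mat = np.zeros((len(ids), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mu = base * (cond2_factor if design[s] == conditions[1] else 1.0)
        if nb_dispersion < 1e-12:
            mat[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / nb_dispersion
            p = r / (r + mu)
            mat[:, j] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(mat, index=ids, columns=samples)
    return CountMatrix(counts, dict(design), {i: int(lengths[i]) for i in ids})


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a full dataset (sequences, panels, counts, truth).

    Deterministic given ``config.seed``: the same configuration always yields
    byte-identical output files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length_range

    # --- gene ids, families, special genes -------------------------------
    n = config.n_genes
    width = max(4, len(str(n)))
    genes = [f"gene{i:0{width}d}" for i in range(1, n + 1)]
    sizes = np.array([s for s, _ in config.family_size_distribution])
    weights = np.array([w for _, w in config.family_size_distribution], dtype=float)
    weights /= weights.sum()
    family_sizes = [int(rng.choice(sizes, p=weights)) for _ in range(config.n_families)]
    if sum(family_sizes) > n:
        raise ConfigError("n_families: drawn family sizes exceed n_genes")
    family_of_gene: dict[str, str | None] = {g: None for g in genes}
    families: dict[str, list[str]] = {}
    cursor = 0
    for f, size in enumerate(family_sizes, start=1):
        fam_id = f"fam{f:03d}"
        members = genes[cursor : cursor + size]
        cursor += size
        families[fam_id] = members
        for g in members:
            family_of_gene[g] = fam_id
    singletons = genes[cursor:]
    n_lgt = min(config.n_lgt, len(singletons))
    lgt_genes = singletons[len(singletons) - n_lgt :] if n_lgt else []
    plain_singletons = singletons[: len(singletons) - n_lgt]

    species_only_cut = int(round(config.species_only_family_fraction * len(families)))
    fam_ids = sorted(families)
    species_only_fams = set(fam_ids[:species_only_cut])

    # --- DE truth ---------------------------------------------------------
    n_de = int(round(config.de_fraction * n))
    n_up = int(round(n_de * config.de_up_share))
    de_status = {g: "none" for g in genes}
    forced_up = lgt_genes if n_up >= len(lgt_genes) and n_de >= len(lgt_genes) else []
    pool = [g for g in genes if g not in forced_up]
    chosen = list(rng.choice(pool, size=n_de - len(forced_up), replace=False)) if n_de > len(forced_up) else []
    de_genes = forced_up + chosen
    for i, g in enumerate(de_genes):
        de_status[g] = "up" if i < n_up else "down"

    # --- prokaryote panel -------------------------------------------------
    n_prok = max(config.n_prokaryote_panel, config.n_contaminants, n_lgt)
    prok_aa: dict[str, str] = {}
    prok_nt: dict[str, str] = {}
    for i in range(1, n_prok + 1):
        pid = f"prok{i:03d}"
        protein = _random_protein(rng, int(rng.integers(lo, hi + 1)))
        prok_aa[pid] = protein
        prok_nt[pid] = _back_translate(rng, protein)

    # --- focal proteins ---------------------------------------------------
    protein_of_gene: dict[str, str] = {}
    euk_panel: list[PanelSeq] = []
    for fam_id in fam_ids:
        members = families[fam_id]
        ancestor = _random_protein(rng, int(rng.integers(lo, hi + 1)))
        for g in members:
            protein_of_gene[g] = _mutate_protein(rng, ancestor, config.divergence_per_copy / 2)
        if fam_id not in species_only_fams:
            homolog = _mutate_protein(rng, ancestor, config.panel_divergence)
            euk_panel.append(PanelSeq(f"euk_{fam_id}", homolog, "other_eukaryote"))
    for g in plain_singletons:
        protein_of_gene[g] = _random_protein(rng, int(rng.integers(lo, hi + 1)))
    n_distract = int(round(config.ortholog_distractor_fraction * len(plain_singletons)))
    for g in plain_singletons[:n_distract]:
        ortho = _mutate_protein(rng, protein_of_gene[g], 0.15)
        euk_panel.append(PanelSeq(f"euk_ortho_{g}", ortho, "other_eukaryote"))
    for i, g in enumerate(lgt_genes):
        source = sorted(prok_aa)[i]
        protein_of_gene[g] = _mutate_protein(rng, prok_aa[source], config.lgt_divergence)
    for i in range(1, config.n_random_eukaryote_panel + 1):
        euk_panel.append(
            PanelSeq(f"euk_rand{i:03d}", _random_protein(rng, int(rng.integers(lo, hi + 1))), "other_eukaryote")
        )

    # --- isoforms ---------------------------------------------------------
    iso_weights = np.array([0.6, 0.3, 0.1][: config.n_isoforms_max])
    iso_weights = iso_weights / iso_weights.sum()
    orfs: list[OrfRecord] = []
    gene_of_orf: dict[str, str] = {}
    orf_counter = 0

    def next_orf_id() -> str:
        nonlocal orf_counter
        orf_counter += 1
        return f"orf{orf_counter:06d}"

    for g in genes:
        nt = _back_translate(rng, protein_of_gene[g])
        n_iso = int(rng.choice(np.arange(1, config.n_isoforms_max + 1), p=iso_weights))
        L = len(nt)
        block_nt = 3 * -(-config.shared_stretch_len // 3)  # codon-aligned, >= stretch
        block_start = ((L - block_nt) // 2 // 3) * 3
        block_end = block_start + block_nt
        oid = next_orf_id()
        orfs.append(OrfRecord(oid, nt, protein_of_gene[g]))
        gene_of_orf[oid] = g
        for _ in range(n_iso - 1):
            start = int(rng.integers(0, block_start // 3 + 1)) * 3
            end = int(rng.integers(block_end // 3, L // 3 + 1)) * 3
            iso_nt = nt[start:end]
            if rng.random() < 0.3:  # 3' extension with novel sequence
                iso_nt += _back_translate(rng, _random_protein(rng, int(rng.integers(10, 41))))
            oid = next_orf_id()
            orfs.append(OrfRecord(oid, iso_nt, _translate(iso_nt)))
            gene_of_orf[oid] = g

    # --- contaminants (each from a distinct prokaryote source) -----------
    contaminant_orfs: list[str] = []
    contam_gene_ids: list[str] = []
    prok_ids_sorted = sorted(prok_nt)
    for i in range(config.n_contaminants):
        source = prok_ids_sorted[i]
        nt = _mutate_nt(rng, prok_nt[source], 1.0 - config.contaminant_identity)
        oid = next_orf_id()
        orfs.append(OrfRecord(oid, nt, _translate(nt)))
        cg = f"contam{i + 1:03d}"
        gene_of_orf[oid] = cg
        contam_gene_ids.append(cg)
        contaminant_orfs.append(oid)

    # --- annotations ------------------------------------------------------
    cog_labels = [c for c, _ in config.cog_classes]
    cog_weights = np.array([w for _, w in config.cog_classes], dtype=float)
    cog_weights /= cog_weights.sum()
    cog_of_gene = {g: str(rng.choice(cog_labels, p=cog_weights)) for g in genes}
    intron_of_gene = {g: bool(rng.random() < config.intron_fraction) for g in genes}
    for g in lgt_genes:
        intron_of_gene[g] = True
    for cg in contam_gene_ids:
        intron_of_gene[cg] = False

    # --- expression -------------------------------------------------------
    sigma = config.expression_sigma
    expr_of_gene = {
        g: float(rng.lognormal(-0.5 * sigma**2, sigma)) for g in genes
    }
    for g in lgt_genes:
        expr_of_gene[g] *= config.lgt_expression_boost
    lengths = {o.orf_id: o.nt_length for o in orfs}
    expr_factors: dict[str, float] = {}
    de_truth_orf: dict[str, str] = {}
    low_mask = rng.random(len(orfs)) < config.low_abundance_fraction
    for o, is_low in zip(orfs, low_mask):
        g = gene_of_orf[o.orf_id]
        if g.startswith("contam"):
            expr_factors[o.orf_id] = config.contaminant_mean / config.nb_mean
            de_truth_orf[o.orf_id] = "none"
            continue
        expr_factors[o.orf_id] = (
            config.low_abundance_mean / config.nb_mean if is_low else expr_of_gene[g]
        )
        de_truth_orf[o.orf_id] = de_status[g]
    design = {
        f"salt{salt}_r{r}": cond
        for salt, cond in (("15", "salt15"), ("30", "salt30"))
        for r in range(1, config.n_replicates + 1)
    }
    counts = simulate_counts(
        design,
        de_truth_orf,
        config.nb_mean,
        config.nb_dispersion,
        config.de_log2fc_magnitude,
        lengths,
        seed=int(rng.integers(0, 2**31 - 1)),
        expression_factors=expr_factors,
    )

    origin: dict[str, str] = {}
    for o in orfs:
        origin[o.orf_id] = "contaminant" if o.orf_id in set(contaminant_orfs) else "focal"
    for p in euk_panel:
        origin[p.seq_id] = "other_eukaryote"
    for pid in prok_aa:
        origin[pid] = "prokaryote"

    truth = TruthTables(
        gene_of_orf=gene_of_orf,
        family_of_gene=family_of_gene,
        de_status=de_status,
        origin=origin,
        intron=dict(intron_of_gene),
        lgt_genes=list(lgt_genes),
        contaminant_orfs=contaminant_orfs,
    )
    return SimulatedDataset(
        config=config,
        orfs=orfs,
        counts=counts,
        cog_of_gene=cog_of_gene,
        intron_of_gene=intron_of_gene,
        prokaryote_panel_nt=prok_nt,
        prokaryote_panel_aa=[PanelSeq(pid, prok_aa[pid], "prokaryote") for pid in sorted(prok_aa)],
        eukaryote_panel_aa=sorted(euk_panel, key=lambda p: p.seq_id),
        truth=truth,
    )


def _write_fasta(records: Sequence[tuple[str, str]], path: Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records],
        str(path),
        "fasta",
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Emit the dataset as plain-text files (FASTA / TSV / JSON).

    Layout: orfs.fna, orfs.faa, panel_prokaryote.{fna,faa},
    panel_eukaryote.faa, counts.tsv, samples.tsv, lengths.tsv, cog.tsv
    (per-ORF), introns.tsv (per-ORF 0/1), truth.json.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_fasta([(o.orf_id, o.nt_seq) for o in ds.orfs], out / "orfs.fna")
    _write_fasta([(o.orf_id, o.aa_seq) for o in ds.orfs], out / "orfs.faa")
    _write_fasta(sorted(ds.prokaryote_panel_nt.items()), out / "panel_prokaryote.fna")
    _write_fasta([(p.seq_id, p.seq) for p in ds.prokaryote_panel_aa], out / "panel_prokaryote.faa")
    _write_fasta([(p.seq_id, p.seq) for p in ds.eukaryote_panel_aa], out / "panel_eukaryote.faa")
    ds.counts.counts.to_csv(out / "counts.tsv", sep="\t", index_label="orf_id")
    pd.DataFrame(
        {"sample_id": list(ds.counts.counts.columns),
         "condition": [ds.counts.condition_of_sample[s] for s in ds.counts.counts.columns]}
    ).to_csv(out / "samples.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"orf_id": [o.orf_id for o in ds.orfs], "length": [o.nt_length for o in ds.orfs]}
    ).to_csv(out / "lengths.tsv", sep="\t", index=False)
    gene_of = ds.truth.gene_of_orf
    pd.DataFrame(
        [
            {"orf_id": o.orf_id, "cog_class": ds.cog_of_gene.get(gene_of[o.orf_id], "")}
            for o in ds.orfs
        ]
    ).to_csv(out / "cog.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"orf_id": o.orf_id, "intron": int(ds.intron_of_gene.get(gene_of[o.orf_id], False))}
            for o in ds.orfs
        ]
    ).to_csv(out / "introns.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(ds.truth.to_json())


def load_dataset(indir: str | Path):
    """Read back the file layout written by :func:`write_dataset`.

    Returns a dict of the parsed pieces (ORFs, panels, counts, annotations,
    truth when present) for pipeline consumption.
    """
    indir = Path(indir)
    nt = {r.id: str(r.seq) for r in SeqIO.parse(str(indir / "orfs.fna"), "fasta")}
    aa = {r.id: str(r.seq) for r in SeqIO.parse(str(indir / "orfs.faa"), "fasta")}
    orfs = [OrfRecord(oid, nt[oid], aa.get(oid, "")) for oid in nt]
    counts = CountMatrix.from_tsv(indir / "counts.tsv", indir / "samples.tsv", indir / "lengths.tsv")
    prok_nt = {
        r.id: str(r.seq) for r in SeqIO.parse(str(indir / "panel_prokaryote.fna"), "fasta")
    }
    prok_aa = [
        PanelSeq(r.id, str(r.seq), "prokaryote")
        for r in SeqIO.parse(str(indir / "panel_prokaryote.faa"), "fasta")
    ]
    euk_aa = [
        PanelSeq(r.id, str(r.seq), "other_eukaryote")
        for r in SeqIO.parse(str(indir / "panel_eukaryote.faa"), "fasta")
    ]
    cog = pd.read_csv(indir / "cog.tsv", sep="\t").fillna("")
    introns = pd.read_csv(indir / "introns.tsv", sep="\t")
    truth = None
    truth_path = indir / "truth.json"
    if truth_path.exists():
        truth = TruthTables.from_json(truth_path.read_text())
    return {
        "orfs": orfs,
        "counts": counts,
        "prokaryote_panel_nt": prok_nt,
        "prokaryote_panel_aa": prok_aa,
        "eukaryote_panel_aa": euk_aa,
        "cog_of_orf": dict(zip(cog["orf_id"], cog["cog_class"])),
        "intron_of_orf": dict(zip(introns["orf_id"], introns["intron"].astype(bool))),
        "truth": truth,
    }
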