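"""TPM computation, low-count filtering and differential-expression calling.

Quantified per-ORF read counts for two salt conditions (>=2 replicates each)
are turned into TPM, filtered for low expression (75th quantile of counts
< 10 reads), and tested for a condition effect with a negative-binomial
likelihood-ratio test. Calls require both significance (adjusted p < 0.05, or
posterior probability > 0.95 for ingested empirical-Bayes callers) and a
shrunken fold change outside (0.5, 2), both bounds strict. A consensus
operation intersects the calls of several callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "compute_tpm",
    "condition_mean_tpm",
    "low_expression_filter",
    "estimate_size_factors",
    "nb_de_test",
    "shrunken_fold_change",
    "bh_adjust",
    "call_de",
    "summarize_expression",
    "gene_level_de",
    "consensus_de",
]


@dataclass
class CountMatrix:
    """Per-ORF integer read counts with sample conditions and ORF lengths."""

    counts: pd.DataFrame  # rows = ORF ids, columns = sample ids
    condition_of_sample: Mapping[str, str]
    length_of_orf: Mapping[str, int]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.condition_of_sample]
        if missing:
            raise ValueError(f"samples without a condition: {missing}")
        conds = pd.Series({s: self.condition_of_sample[s] for s in self.counts.columns})
        if (conds.value_counts() < 2).any():
            raise ValueError("every condition needs at least 2 replicates")
        for orf in self.counts.index:
            length = self.length_of_orf.get(orf, 0)
            if length <= 0:
                raise ValueError(f"ORF {orf!r} has no positive length")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            c = self.condition_of_sample[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_of_sample[s] == condition]

    def lengths(self) -> np.ndarray:
        return np.array([self.length_of_orf[o] for o in self.counts.index], dtype=float)

    def subset(self, orf_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[list(orf_ids)], self.condition_of_sample, self.length_of_orf
        )

    @classmethod
    def from_tsv(cls, counts_tsv: str | Path, samples_tsv: str | Path, lengths_tsv: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        samples = pd.read_csv(samples_tsv, sep="\t")
        lengths = pd.read_csv(lengths_tsv, sep="\t")
        return cls(
            counts,
            dict(zip(samples.iloc[:, 0], samples.iloc[:, 1])),
            dict(zip(lengths.iloc[:, 0], lengths.iloc[:, 1])),
        )


def compute_tpm(counts: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalised rates scaled to 1e6 per sample."""
    lengths = counts.lengths()
    rates = counts.counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero sample(s), TPM undefined: {bad}")
    return rates.div(totals, axis=1) * 1e6


def condition_mean_tpm(counts: CountMatrix) -> pd.DataFrame:
    """Per-ORF TPM averaged within each condition (one column per condition).

    Abundance statements ("above 10 TPM", ">600 TPM") refer to this
    replicate-averaged quantity, which is robust to single stray reads.
    """
    tpm = compute_tpm(counts)
    return pd.DataFrame(
        {c: tpm[counts.samples_of(c)].mean(axis=1) for c in counts.conditions}
    )


def low_expression_filter(
    counts: CountMatrix, quantile: float = 0.75, threshold: float = 10.0
) -> list[str]:
    """Retain ORFs whose count quantile across all samples is >= threshold.

    The quantile uses linear interpolation between order statistics (the
    common "type 7" rule); an ORF is removed iff its 75th percentile of
    counts over all samples is strictly below 10 reads.
    """
    q = np.quantile(counts.counts.values, quantile, axis=1)
    keep = q >= threshold
    return [o for o, k in zip(counts.counts.index, keep) if k]


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios library size factors (geometric reference sample)."""
    mat = counts.counts.values.astype(float)
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat)
    usable = np.isfinite(log_mat).all(axis=1)
    if usable.sum() >= 1:
        ref = log_mat[usable].mean(axis=0)  # per-sample shift vs geometric mean
        log_ratios = log_mat[usable] - log_mat[usable].mean(axis=1, keepdims=True)
        factors = np.exp(np.median(log_ratios, axis=0))
    else:  # fall back to total-count scaling
        totals = mat.sum(axis=0)
        factors = totals / totals.mean()
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.counts.columns)


def _moment_dispersions(
    norm: np.ndarray, groups: np.ndarray, prior_df: float = 20.0
) -> np.ndarray:
    """Per-gene NB dispersions, moment estimates shrunk toward the common value.

    Within-condition means and variances give raw estimates
    (var - mean) / mean^2. At typical replicate counts these are very noisy
    and biased low, which makes downstream likelihood-ratio tests
    anticonservative, so each gene's raw value is moderated toward the
    dataset-wide mean of raw estimates with a prior weight of ``prior_df``
    pseudo-degrees against the residual degrees of freedom (samples minus
    the two condition means)."""
    means = np.zeros(norm.shape[0])
    pooled_var = np.zeros(norm.shape[0])
    n_groups = 0
    for g in np.unique(groups):
        sub = norm[:, groups == g]
        means += sub.mean(axis=1)
        pooled_var += sub.var(axis=1, ddof=1)
        n_groups += 1
    means /= n_groups
    pooled_var /= n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (pooled_var - means) / means**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    # the plain mean of raw estimates is unbiased for a shared dispersion
    # (sample variances are unbiased); medians or positive-only summaries
    # under-estimate it and make the LRT anticonservative
    common = float(np.clip(raw.mean(), 1e-4, 10.0)) if raw.size else 0.01
    resid_df = max(norm.shape[1] - n_groups, 1)
    w = resid_df / (resid_df + prior_df)
    shrunk = w * np.clip(raw, 0.0, 10.0) + (1.0 - w) * common
    return np.maximum(shrunk, 1e-8)


def nb_de_test(counts: CountMatrix) -> pd.DataFrame:
    """Negative-binomial likelihood-ratio test of the condition effect per ORF.

    Counts are modelled as NB with a log link, library-size offsets
    (median-of-ratios) and a per-gene dispersion fixed at a moment-based
    common-then-shrunk estimate; the condition coefficient is tested with a
    chi-square(1) likelihood-ratio test. Returns log2fc (model coefficient)
    and a two-sided p-value per ORF.
    """
    conds = counts.conditions
    if len(conds) != 2:
        raise ValueError("nb_de_test requires exactly 2 conditions")
    for c in conds:
        if len(counts.samples_of(c)) < 2:
            raise ValueError("need >=2 replicates per condition")
    sf = estimate_size_factors(counts).values
    mat = counts.counts.values.astype(float)
    groups = np.array([0 if counts.condition_of_sample[s] == conds[0] else 1 for s in counts.counts.columns])
    dispersions = _moment_dispersions(mat / sf, groups)
    offset = np.log(sf)
    x0 = np.ones((mat.shape[1], 1))
    x1 = np.column_stack([np.ones(mat.shape[1]), groups])

    out_lfc = np.zeros(mat.shape[0])
    out_p = np.ones(mat.shape[0])
    for i in range(mat.shape[0]):
        y = mat[i]
        if y.sum() == 0 or np.ptp(y / sf) == 0:
            continue
        fam = sm.families.NegativeBinomial(alpha=float(dispersions[i]))
        try:
            fit0 = sm.GLM(y, x0, family=fam, offset=offset).fit()
            fit1 = sm.GLM(y, x1, family=fam, offset=offset).fit()
        except Exception:
            continue
        lr = max(0.0, 2.0 * (fit1.llf - fit0.llf))
        out_p[i] = stats.chi2.sf(lr, df=1)
        out_lfc[i] = fit1.params[1] / np.log(2)
    return pd.DataFrame(
        {"orf_id": counts.counts.index, "log2fc": out_lfc, "p_value": out_p}
    ).set_index("orf_id")


def shrunken_fold_change(mean1: float, mean2: float, pseudocount: float = 1.0) -> float:
    """Bounded fold-change estimate (mean2 + pc) / (mean1 + pc).

    A transparent stand-in for posterior fold change: monotone in mean2 and
    bounded away from 0 and infinity for zero means.
    """
    if mean1 < 0 or mean2 < 0:
        raise ValueError("means must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return (mean2 + pseudocount) / (mean1 + pseudocount)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    summary: pd.DataFrame,
    alpha: float = 0.05,
    fc_low: float = 0.5,
    fc_high: float = 2.0,
    posterior_mode: bool = False,
    posterior_cutoff: float = 0.95,
) -> pd.DataFrame:
    """Apply the significance + fold-change thresholds, all strict.

    DE iff (adj_p < alpha, or posterior > 0.95 in posterior mode) AND
    (fc < 0.5 OR fc > 2); direction is up iff fc > fc_high. ``summary`` needs
    columns ``fc`` and ``adj_p`` (or ``posterior``).
    """
    stat_col = "posterior" if posterior_mode else "adj_p"
    for col in (stat_col, "fc"):
        if col not in summary.columns:
            raise ValueError(f"missing column {col!r}")
    fc = summary["fc"].values.astype(float)
    if posterior_mode:
        significant = summary[stat_col].values > posterior_cutoff
    else:
        significant = summary[stat_col].values < alpha
    extreme = (fc < fc_low) | (fc > fc_high)
    de = significant & extreme
    direction = np.where(de & (fc > fc_high), "up", np.where(de, "down", "none"))
    out = summary.copy()
    out["de_flag"] = de
    out["direction"] = direction
    return out


def summarize_expression(
    counts: CountMatrix,
    alpha: float = 0.05,
    fc_low: float = 0.5,
    fc_high: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full per-ORF expression summary on a (filtered) count matrix.

    Combines TPM condition means (for reporting), raw and shrunken fold
    change of condition 2 over condition 1, the NB test p-value, BH
    adjustment and the DE call. Fold changes are computed on size-factor
    normalised counts rather than TPM: TPM is a within-sample composition
    measure, so a few very highly expressed responsive transcripts would
    bias the TPM ratio of every other gene, while median-of-ratios
    normalisation is robust to such composition shifts.
    """
    tpm = compute_tpm(counts)
    c1, c2 = counts.conditions
    mean_tpm1 = tpm[counts.samples_of(c1)].mean(axis=1)
    mean_tpm2 = tpm[counts.samples_of(c2)].mean(axis=1)
    sf = estimate_size_factors(counts)
    norm = counts.counts.div(sf, axis=1)
    mean1 = norm[counts.samples_of(c1)].mean(axis=1)
    mean2 = norm[counts.samples_of(c2)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_fc = np.where(mean1 > 0, mean2 / mean1, np.inf)
    shrunk = np.array(
        [shrunken_fold_change(m1, m2, pseudocount) for m1, m2 in zip(mean1, mean2)]
    )
    nb = nb_de_test(counts)
    summary = pd.DataFrame(
        {
            "mean_tpm_cond1": mean_tpm1,
            "mean_tpm_cond2": mean_tpm2,
            "raw_fc": raw_fc,
            "fc": shrunk,
            "log2fc": nb["log2fc"],
            "p_value": nb["p_value"],
        },
        index=counts.counts.index,
    )
    summary["adj_p"] = bh_adjust(summary["p_value"].values)
    summary = call_de(summary, alpha=alpha, fc_low=fc_low, fc_high=fc_high)
    summary = summary.rename(columns={"fc": "shrunken_fc"})
    summary.index.name = "orf_id"
    return summary


def gene_level_de(summary: pd.DataFrame, gene_of_orf: Mapping[str, str]) -> pd.DataFrame:
    """Reduce ORF-level calls to genes: DE if any isoform is DE; direction from
    the isoform with the smallest adjusted p-value among DE isoforms."""
    df = summary.copy()
    df["gene_id"] = [gene_of_orf[o] for o in df.index]
    rows = []
    for gid, grp in df.groupby("gene_id", sort=True):
        de = bool(grp["de_flag"].any())
        if de:
            flagged = grp[grp["de_flag"]]
            best = flagged.loc[flagged["adj_p"].idxmin()]
            direction = best["direction"]
        else:
            direction = "none"
        rows.append(
            {
                "gene_id": gid,
                "de_flag": de,
                "direction": direction,
                "max_tpm": float(
                    grp[["mean_tpm_cond1", "mean_tpm_cond2"]].values.max()
                ),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def consensus_de(calls: Mapping[str, pd.DataFrame]) -> dict:
    """Agreement table between >=2 caller outputs keyed by ORF.

    Each value is a DataFrame with a ``de_flag`` column (and optionally
    ``direction``) indexed by ORF id. ORFs absent from a caller count as not
    flagged by it but are marked missing. Returns the per-ORF table plus
    intersection / pairwise / union counts; conflicting directions among
    agreeing callers are flagged, not an error.
    """
    if len(calls) < 2:
        raise ValueError("consensus needs at least 2 callers")
    names = sorted(calls)
    universe = sorted(set().union(*[set(df.index) for df in calls.values()]))
    table = pd.DataFrame(index=pd.Index(universe, name="orf_id"))
    for name in names:
        df = calls[name]
        table[f"{name}_de"] = [bool(df.loc[o, "de_flag"]) if o in df.index else False for o in universe]
        table[f"{name}_missing"] = [o not in df.index for o in universe]
    flag_cols = [f"{n}_de" for n in names]
    table["n_callers_flagging"] = table[flag_cols].sum(axis=1)
    all_flag = table[flag_cols].all(axis=1)
    any_flag = table[flag_cols].any(axis=1)

    conflicts = []
    for o in table.index[all_flag]:
        dirs = {
            str(calls[n].loc[o, "direction"])
            for n in names
            if o in calls[n].index and "direction" in calls[n].columns
        }
        dirs.discard("none")
        if len(dirs) > 1:
            conflicts.append(o)
    table["direction_conflict"] = table.index.isin(conflicts)

    pair_counts = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pair_counts[(a, b)] = int((table[f"{a}_de"] & table[f"{b}_de"]).sum())
    return {
        "table": table,
        "n_all": int(all_flag.sum()),
        "n_any": int(any_flag.sum()),
        "pair_counts": pair_counts,
        "per_caller": {n: int(table[f"{n}_de"].sum()) for n in names},
    }
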