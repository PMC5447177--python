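"""Enrichment and duplication-by-expression association statistics.

COG-class enrichment among foreground gene sets uses the hypergeometric
test with BH correction, after removing a fixed list of uninformative
classes. The association between duplication and differential expression is
tested two ways: a hypergeometric overlap test (fraction of duplicated genes
that are DE), and the mixed-direction cluster statistic — the fraction of
duplicate clusters containing both an up- and a down-regulated member —
compared against a cluster-randomization null (genes sampled without
replacement from the dataset and re-partitioned into the observed cluster
sizes) with a closed-form expectation as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .expression_de import bh_adjust

__all__ = [
    "DEFAULT_EXCLUDED_CLASSES",
    "RandomizationResult",
    "hypergeometric_tail",
    "class_enrichment",
    "dup_de_overlap_test",
    "mixed_direction_fraction",
    "randomization_null",
    "analytic_mixed_expectation",
]

# classes with very few genes, or without obvious biological meaning, are
# dropped before testing so they do not dilute the BH family
DEFAULT_EXCLUDED_CLASSES = (
    "Cell motility",
    "Defense mechanisms",
    "Unknown function",
    "General predictions only",
    "Nuclear structures",
    "No hits found",
)


@dataclass
class RandomizationResult:
    observed_fraction: float | None
    null_mean: float
    null_sd: float
    n_reps: int
    empirical_p: float | None
    seed: int


def hypergeometric_tail(N: int, K: int, n: int, k: int, tail: str = "upper") -> float:
    """P(X >= k) (or <= k for the lower tail) under Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    if k > K:
        raise ValueError(f"observed k={k} exceeds marked K={K}")
    if tail == "upper":
        return float(hypergeom.sf(k - 1, N, K, n))
    if tail == "lower":
        return float(hypergeom.cdf(k, N, K, n))
    raise ValueError(f"unknown tail {tail!r}")


def class_enrichment(
    annotations: Mapping[str, Iterable[str]],
    foreground: Iterable[str],
    universe: Iterable[str],
    excluded_classes: Sequence[str] = DEFAULT_EXCLUDED_CLASSES,
) -> pd.DataFrame:
    """Per-class hypergeometric enrichment of a foreground within a universe.

    Genes may carry several classes and then count once per class. Both tails
    are computed; the reported ``p_value`` is the tail matching the observed
    direction (enriched when the foreground count exceeds its expectation)
    and BH correction runs across the retained classes only — excluded
    classes are absent from the output and from the BH family.
    """
    fg = set(foreground)
    uni = set(universe)
    missing = fg - uni
    if missing:
        raise ValueError(f"foreground genes outside universe: {sorted(missing)[:5]}")
    excluded = set(excluded_classes)
    class_members: dict[str, set[str]] = {}
    for gene in uni:
        for cls in annotations.get(gene, ()):
            if cls not in excluded:
                class_members.setdefault(cls, set()).add(gene)
    rows = []
    N, n = len(uni), len(fg)
    for cls in sorted(class_members):
        members = class_members[cls]
        K = len(members)
        k = len(members & fg)
        expected = n * K / N
        p_up = hypergeometric_tail(N, K, n, k, "upper")
        p_low = hypergeometric_tail(N, K, n, k, "lower")
        direction = "enriched" if k > expected else "depleted"
        rows.append(
            {
                "class_label": cls,
                "n_class_fg": k,
                "n_fg": n,
                "n_class_bg": K,
                "n_universe": N,
                "p_upper": p_up,
                "p_lower": p_low,
                "p_value": p_up if direction == "enriched" else p_low,
                "direction": direction,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["adj_p"] = bh_adjust(table["p_value"].values)
    else:
        table["adj_p"] = []
    return table


def dup_de_overlap_test(
    duplicated: Iterable[str], de: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """Fraction of duplicated genes that are DE, with its hypergeometric
    upper-tail p-value against the universe."""
    dup, de_set, uni = set(duplicated), set(de), set(universe)
    if not dup:
        raise ValueError("empty duplicated set")
    if not dup <= uni or not de_set <= uni:
        raise ValueError("duplicated and DE sets must lie within the universe")
    overlap = len(dup & de_set)
    fraction = overlap / len(dup)
    p = hypergeometric_tail(len(uni), len(de_set), len(dup), overlap, "upper")
    return fraction, p


def mixed_direction_fraction(
    clusters: Sequence[Iterable[str]], direction: Mapping[str, str]
) -> float:
    """Fraction of clusters containing both an up- and a down-regulated gene."""
    if not clusters:
        raise ValueError("no clusters given")
    n_mixed = 0
    for cluster in clusters:
        genes = list(cluster)
        for g in genes:
            if g not in direction:
                raise ValueError(f"gene {g!r} has no direction entry")
        labels = {direction[g] for g in genes}
        if "up" in labels and "down" in labels:
            n_mixed += 1
    return n_mixed / len(clusters)


def _mixed_fraction_from_labels(
    codes: np.ndarray, boundaries: np.ndarray, n_clusters: int
) -> float:
    ups = np.add.reduceat(codes == 1, boundaries)
    downs = np.add.reduceat(codes == 2, boundaries)
    return float(((ups > 0) & (downs > 0)).sum() / n_clusters)


def randomization_null(
    universe_labels: Sequence[str],
    n_genes: int,
    cluster_sizes: Sequence[int],
    n_reps: int = 1000,
    seed: int = 0,
    observed: float | None = None,
) -> RandomizationResult:
    """Monte-Carlo null for the mixed-direction cluster fraction.

    Each replicate draws ``n_genes`` labels without replacement from the
    complete gene dataset's up/down/none labels, partitions them into the
    given cluster sizes and records the mixed fraction. Reports the null mean
    and sample SD, and — when an observed fraction is supplied — the
    empirical p-value with the (r+1)/(n+1) convention, which is never exactly
    zero.
    """
    sizes = np.asarray(list(cluster_sizes), dtype=int)
    if sizes.sum() != n_genes:
        raise ValueError(f"cluster sizes sum to {sizes.sum()}, expected {n_genes}")
    if (sizes < 1).any():
        raise ValueError("cluster sizes must be positive")
    labels = np.asarray(list(universe_labels))
    if n_genes > labels.size:
        raise ValueError("n_genes exceeds the universe size")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    code_map = {"up": 1, "down": 2}
    codes_all = np.array([code_map.get(l, 0) for l in labels], dtype=np.int8)
    boundaries = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_reps)
    for r in range(n_reps):
        draw = rng.choice(codes_all, size=n_genes, replace=False)
        fractions[r] = _mixed_fraction_from_labels(draw, boundaries, len(sizes))
    null_mean = float(fractions.mean())
    null_sd = float(fractions.std(ddof=1)) if n_reps > 1 else 0.0
    empirical_p = None
    if observed is not None:
        empirical_p = float(((fractions >= observed).sum() + 1) / (n_reps + 1))
    return RandomizationResult(observed, null_mean, null_sd, n_reps, empirical_p, seed)


def analytic_mixed_expectation(
    N: int, n_up: int, n_down: int, cluster_sizes: Sequence[int]
) -> float:
    """Closed-form expectation of the mixed-direction cluster fraction.

    For a cluster of size k filled by sampling without replacement,
    P(both directions present) = 1 - P(no up) - P(no down) + P(neither),
    each term a hypergeometric probability of drawing zero marked genes;
    the expectation of the fraction is the mean over clusters.
    """
    if n_up + n_down > N:
        raise ValueError("n_up + n_down exceeds N")
    probs = []
    for k in cluster_sizes:
        if k > N:
            raise ValueError(f"cluster size {k} exceeds N={N}")
        p_no_up = hypergeom.pmf(0, N, n_up, k)
        p_no_down = hypergeom.pmf(0, N, n_down, k)
        p_neither = hypergeom.pmf(0, N, n_up + n_down, k)
        probs.append(1.0 - p_no_up - p_no_down + p_neither)
    return float(np.mean(probs))
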