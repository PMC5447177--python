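"""Detection of recently duplicated genes by similarity ranking and phylogeny.

A focal-species gene is a *candidate recent duplicate* when its best protein
hit is another conspecific sequence that strictly outscores every homolog
from other organisms. Candidates are grouped into clusters (connected
components of mutual passing hits, identity > 30% over > 2/3 of the shorter
sequence), a bootstrapped neighbour-joining tree is built per cluster from
the cluster members plus their non-focal homologs, and a cluster is accepted
when its focal sequences form an exclusive clade with bootstrap support
strictly above 50%. Clusters whose members have no non-focal homolog at all
are reported as species-only. A >90%-identity deduplication used for
copy-number surveys is also provided.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = [
    "HomologHit",
    "PanelSeq",
    "DuplicateCluster",
    "PhyloTree",
    "pairwise_protein_similarity",
    "gather_homologs",
    "classify_candidate_duplicates",
    "build_bootstrap_tree",
    "test_exclusive_clade",
    "detect_duplicate_clusters",
    "count_gene_copies",
]

_AA_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZXJUO*")


@dataclass
class HomologHit:
    query_id: str
    subject_id: str
    subject_origin: str  # focal | other_eukaryote | prokaryote
    score: float
    identity: float
    coverage_shorter: float


@dataclass(frozen=True)
class PanelSeq:
    seq_id: str
    seq: str
    origin: str


@dataclass
class DuplicateCluster:
    cluster_id: str
    member_gene_ids: frozenset[str]
    category: str  # species_only | exclusive_clade | rejected
    clade_support: float | None = None
    tree: "PhyloTree | None" = None
    reason: str | None = None


@dataclass
class PhyloTree:
    """An unrooted tree summarised as supported bipartitions.

    Each non-trivial bipartition is stored by the side that does not contain
    the lexicographically smallest leaf; support values are percentages in
    [0, 100] or None when unavailable.
    """

    leaves: frozenset[str]
    bipartitions: dict[frozenset[str], float | None]
    newick: str | None = None

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = TreeNode.read(io.StringIO(text))
        leaves = frozenset(t.name for t in tree.tips())
        bip: dict[frozenset[str], float | None] = {}
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if len(side) < 2 or len(side) > len(leaves) - 2:
                continue
            support: float | None = None
            if node.name is not None:
                try:
                    support = float(node.name)
                except ValueError:
                    support = None
            canon = _canonical_side(side, leaves)
            # the same unrooted bipartition can surface from both sides of
            # the (arbitrary) root; keep the side that carries a support
            existing = bip.get(canon)
            if existing is None or (support is not None and support > existing):
                bip[canon] = support
        return cls(leaves=leaves, bipartitions=bip, newick=text)


def _canonical_side(side: frozenset[str], leaves: frozenset[str]) -> frozenset[str]:
    anchor = min(leaves)
    return frozenset(leaves - side) if anchor in side else side


def _protein_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


def pairwise_protein_similarity(
    a: str,
    b: str,
    query_id: str = "query",
    subject_id: str = "subject",
    subject_origin: str = "focal",
) -> HomologHit:
    """Local protein alignment (BLOSUM62, affine gaps 11/1).

    Reports the alignment score, identity over aligned columns (internal gaps
    included) and the fraction of the shorter sequence spanned by the aligned
    region.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    for name, seq in (("a", a), ("b", b)):
        bad = set(seq.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(f"non-amino-acid symbols in {name}: {sorted(bad)}")
    aligner = _protein_aligner()
    alignments = aligner.align(a.upper(), b.upper())
    if alignments.score <= 0:
        return HomologHit(query_id, subject_id, subject_origin, 0.0, 0.0, 0.0)
    aln = alignments[0]
    counts = aln.counts()
    internal = counts.internal_insertions + counts.internal_deletions
    columns = counts.identities + counts.mismatches + internal
    identity = counts.identities / columns if columns else 0.0
    spans_a, spans_b = aln.aligned
    span_a = spans_a[-1][1] - spans_a[0][0]
    span_b = spans_b[-1][1] - spans_b[0][0]
    shorter_span = span_a if len(a) <= len(b) else span_b
    coverage = shorter_span / min(len(a), len(b))
    return HomologHit(
        query_id, subject_id, subject_origin, float(alignments.score), identity, min(coverage, 1.0)
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class HomologSearch:
    """All-against-all protein search over a mixed-origin sequence panel.

    Uses an exact shared-k-mer prefilter (default k=5) before alignment:
    pairs above ~30% identity at realistic lengths essentially always share a
    5-mer, while unrelated pairs rarely do, keeping the search near-linear.
    Set ``prefilter_k=None`` to align every pair.
    """

    def __init__(self, db: Sequence[PanelSeq], prefilter_k: int | None = 5):
        self.db = {p.seq_id: p for p in db}
        if len(self.db) != len(db):
            raise ValueError("duplicate sequence ids in panel")
        self.prefilter_k = prefilter_k
        self._postings: dict[str, list[str]] = {}
        if prefilter_k is not None:
            for p in db:
                for kmer in _kmer_set(p.seq.upper(), prefilter_k):
                    self._postings.setdefault(kmer, []).append(p.seq_id)

    def candidates(self, query_seq: str) -> list[str]:
        if self.prefilter_k is None:
            return sorted(self.db)
        hits: dict[str, int] = {}
        for kmer in _kmer_set(query_seq.upper(), self.prefilter_k):
            for sid in self._postings.get(kmer, ()):
                hits[sid] = hits.get(sid, 0) + 1
        # two-hit seeding: homologs above ~30% identity share many exact
        # words, single shared words are noise
        return sorted(sid for sid, n in hits.items() if n >= 2)

    def search(
        self,
        query_id: str,
        query_seq: str,
        min_identity: float = 0.30,
        min_coverage: float = 2.0 / 3.0,
    ) -> list[HomologHit]:
        hits = []
        for sid in self.candidates(query_seq):
            if sid == query_id:
                continue
            p = self.db[sid]
            hit = pairwise_protein_similarity(query_seq, p.seq, query_id, sid, p.origin)
            if hit.identity > min_identity and hit.coverage_shorter > min_coverage:
                hits.append(hit)
        hits.sort(key=lambda h: (-h.score, h.subject_id))
        return hits


def gather_homologs(
    query_id: str,
    query_seq: str,
    db: Sequence[PanelSeq],
    min_identity: float = 0.30,
    min_coverage: float = 2.0 / 3.0,
) -> list[HomologHit]:
    """Homologs of one query: identity > 30% AND coverage of the shorter
    sequence > 2/3, both strict. Empty result is allowed."""
    search = HomologSearch(db, prefilter_k=None)
    return search.search(query_id, query_seq, min_identity, min_coverage)


def classify_candidate_duplicates(
    focal: Mapping[str, str],
    panel: Sequence[PanelSeq],
    min_identity: float = 0.30,
    min_coverage: float = 2.0 / 3.0,
    prefilter_k: int | None = 5,
) -> tuple[dict[str, str], dict[str, list[HomologHit]]]:
    """Classify each focal gene by conspecific-vs-panel similarity ranking.

    candidate: best passing hit is conspecific and strictly outscores every
    non-focal hit (ties are conservatively non_candidate);
    species_only: conspecific homologs exist but none from any other
    organism; non_candidate: otherwise. Scores are alignment scores, not
    E-values, so the ranking is database-size independent.
    """
    db = [PanelSeq(gid, seq, "focal") for gid, seq in sorted(focal.items())]
    db += list(panel)
    search = HomologSearch(db, prefilter_k=prefilter_k)
    categories: dict[str, str] = {}
    all_hits: dict[str, list[HomologHit]] = {}
    for gid in sorted(focal):
        hits = search.search(gid, focal[gid], min_identity, min_coverage)
        all_hits[gid] = hits
        focal_scores = [h.score for h in hits if h.subject_origin == "focal"]
        nonfocal_scores = [h.score for h in hits if h.subject_origin != "focal"]
        if not hits:
            categories[gid] = "non_candidate"
        elif not nonfocal_scores:
            categories[gid] = "species_only"
        elif focal_scores and max(focal_scores) > max(nonfocal_scores):
            categories[gid] = "candidate"
        else:
            categories[gid] = "non_candidate"
    return categories, all_hits


# ---------------------------------------------------------------------------
# tree building


def _anchored_alignment(seqs: Mapping[str, str], max_gap_fraction: float = 0.5):
    """Reference-anchored multiple alignment.

    The longest sequence anchors the column space; every other sequence is
    aligned to it pairwise (semi-global, BLOSUM62) and its residues are placed
    at the matched reference positions. Insertions relative to the reference
    are dropped; columns with more than ``max_gap_fraction`` gaps are trimmed.
    Exact for indel-free sequence families, approximate otherwise.
    """
    ids = sorted(seqs)
    ref_id = min(ids, key=lambda i: (-len(seqs[i]), i))
    ref = seqs[ref_id].upper()
    aligner = _protein_aligner()
    aligner.mode = "global"
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    n_cols = len(ref)
    rows = {}
    for sid in ids:
        if sid == ref_id:
            rows[sid] = np.frombuffer(ref.encode(), dtype="S1")
            continue
        seq = seqs[sid].upper()
        aln = aligner.align(ref, seq)[0]
        row = np.full(n_cols, b"-", dtype="S1")
        for (rs, re_), (qs, qe) in zip(*aln.aligned):
            row[rs:re_] = np.frombuffer(seq[qs:qe].encode(), dtype="S1")
        rows[sid] = row
    mat = np.vstack([rows[sid] for sid in ids])
    gap_frac = (mat == b"-").mean(axis=0)
    mat = mat[:, gap_frac <= max_gap_fraction]
    return ids, mat


def _p_distance_matrix(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    dm = np.zeros((n, n))
    gap = mat == b"-"
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(gap[i] | gap[j])
            n_valid = int(valid.sum())
            if n_valid == 0:
                d = 1.0
            else:
                d = float((mat[i, valid] != mat[j, valid]).mean())
            dm[i, j] = dm[j, i] = d
    return dm


def _nj_bipartitions(dm: np.ndarray, ids: Sequence[str]) -> tuple[TreeNode, set[frozenset[str]]]:
    tree = nj(DistanceMatrix(dm, ids))
    leaves = frozenset(ids)
    bips = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(leaves) - 2:
            bips.add(_canonical_side(side, leaves))
    return tree, bips


def build_bootstrap_tree(
    sequences: Mapping[str, str],
    n_bootstrap: int = 100,
    seed: int = 0,
    max_gap_fraction: float = 0.5,
) -> PhyloTree:
    """Neighbour-joining tree with column-resampled bootstrap supports.

    Sequences are placed in a reference-anchored alignment, pairwise
    p-distances feed NJ, and supports are the percentage of ``n_bootstrap``
    column-resampled replicates whose NJ tree contains each bipartition of
    the full-data tree. Deterministic given the seed.
    """
    if len(sequences) < 4:
        raise ValueError(
            "build_bootstrap_tree needs >=4 sequences; for 3 taxa any 2-vs-1 "
            "split is trivially monophyletic (use the forced-topology rule)"
        )
    ids, mat = _anchored_alignment(sequences, max_gap_fraction)
    if mat.shape[1] == 0:
        raise ValueError("alignment has no retained columns")
    tree, main_bips = _nj_bipartitions(_p_distance_matrix(mat), ids)
    rng = np.random.default_rng(seed)
    counts = {b: 0 for b in main_bips}
    for _ in range(n_bootstrap):
        cols = rng.integers(0, mat.shape[1], mat.shape[1])
        _, bips = _nj_bipartitions(_p_distance_matrix(mat[:, cols]), ids)
        for b in main_bips:
            if b in bips:
                counts[b] += 1
    leaves = frozenset(ids)
    supports = {b: 100.0 * counts[b] / n_bootstrap for b in main_bips}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = _canonical_side(side, leaves)
        if canon in supports:
            node.name = f"{supports[canon]:g}"
    newick = str(tree).strip()
    return PhyloTree(leaves=leaves, bipartitions=supports, newick=newick)


def test_exclusive_clade(
    tree: PhyloTree,
    focal_leaves: Iterable[str],
    min_support: float = 50.0,
) -> tuple[bool, float | None]:
    """Does the tree contain an edge splitting exactly the focal leaves off?

    True iff some internal edge bipartitions the leaves into exactly
    ``focal_leaves`` vs the rest with support strictly above ``min_support``.
    With a single non-focal leaf the split is topologically forced and passes
    with support None. Exclusivity is tested on unrooted bipartitions, so the
    result is rooting-invariant.
    """
    focal = frozenset(focal_leaves)
    if not focal <= tree.leaves:
        raise ValueError(f"focal leaves missing from tree: {sorted(focal - tree.leaves)}")
    if len(focal) < 2:
        raise ValueError("need at least 2 focal leaves")
    others = tree.leaves - focal
    if not others:
        raise ValueError("need at least 1 non-focal leaf")
    if len(others) == 1:
        return True, None
    canon = _canonical_side(focal, tree.leaves)
    if canon not in tree.bipartitions:
        return False, None
    support = tree.bipartitions[canon]
    if support is None:
        return False, None
    return support > min_support, support


def detect_duplicate_clusters(
    focal: Mapping[str, str],
    panel: Sequence[PanelSeq],
    tree_source: str = "internal",
    external_trees: Mapping[str, PhyloTree] | None = None,
    min_identity: float = 0.30,
    min_coverage: float = 2.0 / 3.0,
    min_support: float = 50.0,
    n_bootstrap: int = 100,
    seed: int = 0,
    prefilter_k: int | None = 5,
) -> tuple[list[DuplicateCluster], dict]:
    """Full duplicate-gene pipeline: classify, cluster, tree, clade test.

    Candidate and species-only genes are clustered by connected components of
    mutual passing conspecific hits; per cluster the member sequences plus
    all their non-focal homologs are given to the bootstrap NJ tree (or an
    ingested external Newick containing the members), and the cluster is
    accepted as ``exclusive_clade`` iff the members form an exclusive clade
    with support > ``min_support``.
    """
    categories, hits = classify_candidate_duplicates(
        focal, panel, min_identity, min_coverage, prefilter_k
    )
    eligible = sorted(
        g for g, c in categories.items() if c in ("candidate", "species_only")
    )
    passing_focal = {
        g: {h.subject_id for h in hits[g] if h.subject_origin == "focal"} for g in eligible
    }
    index = {g: i for i, g in enumerate(eligible)}
    parent = list(range(len(eligible)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for g in eligible:
        for s in passing_focal[g]:
            if s in index and g in passing_focal.get(s, ()):  # mutual
                ri, rj = find(index[g]), find(index[s])
                if ri != rj:
                    parent[rj] = ri

    comps: dict[int, list[str]] = {}
    for g in eligible:
        comps.setdefault(find(index[g]), []).append(g)
    member_sets = sorted(
        [sorted(m) for m in comps.values() if len(m) >= 2], key=lambda m: m[0]
    )

    panel_by_id = {p.seq_id: p for p in panel}
    clusters: list[DuplicateCluster] = []
    width = max(4, len(str(len(member_sets))))
    for i, members in enumerate(member_sets, start=1):
        cid = f"cl{i:0{width}d}"
        member_set = frozenset(members)
        nonfocal_ids = sorted(
            {h.subject_id for g in members for h in hits[g] if h.subject_origin != "focal"}
        )
        if not nonfocal_ids:
            clusters.append(DuplicateCluster(cid, member_set, "species_only"))
            continue
        if tree_source == "external":
            tree = None
            for t in (external_trees or {}).values():
                if member_set <= t.leaves and (t.leaves - member_set):
                    tree = t
                    break
            if tree is None:
                clusters.append(
                    DuplicateCluster(
                        cid, member_set, "rejected", reason="no external tree covers members"
                    )
                )
                continue
            ok, support = test_exclusive_clade(tree, member_set, min_support)
        else:
            leaf_seqs = {g: focal[g] for g in members}
            for sid in nonfocal_ids:
                leaf_seqs[sid] = panel_by_id[sid].seq
            if len(leaf_seqs) == len(members) + 1:
                # 2+ focal vs a single outgroup: topologically forced clade
                ok, support, tree = True, None, None
            else:
                tree = build_bootstrap_tree(leaf_seqs, n_bootstrap, seed + i)
                ok, support = test_exclusive_clade(tree, member_set, min_support)
        if ok:
            clusters.append(
                DuplicateCluster(cid, member_set, "exclusive_clade", support, tree)
            )
        else:
            clusters.append(
                DuplicateCluster(
                    cid, member_set, "rejected", support, tree, reason="clade test failed"
                )
            )

    summary = {
        "n_clusters": len(clusters),
        "n_genes_clustered": sum(len(c.member_gene_ids) for c in clusters),
        "by_category": {
            cat: sum(1 for c in clusters if c.category == cat)
            for cat in ("species_only", "exclusive_clade", "rejected")
        },
        "n_genes_by_category": {
            cat: sum(len(c.member_gene_ids) for c in clusters if c.category == cat)
            for cat in ("species_only", "exclusive_clade", "rejected")
        },
        "categories": categories,
        "hits": hits,
    }
    return clusters, summary


def count_gene_copies(
    candidates: Mapping[str, str], identity_dedup: float = 0.90
) -> int:
    """Copy count after collapsing near-identical sequences.

    Sequences with pairwise identity strictly above ``identity_dedup`` are
    merged by single-linkage; the number of resulting groups is the copy
    count used for receptor-family surveys.
    """
    ids = sorted(candidates)
    if not ids:
        raise ValueError("need at least one sequence")
    parent = list(range(len(ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            hit = pairwise_protein_similarity(candidates[ids[i]], candidates[ids[j]])
            if hit.identity > identity_dedup:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    return len({find(i) for i in range(len(ids))})
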