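"""Similarity ranking, NJ bootstrap trees and the exclusive-clade test."""

import dendropy
import numpy as np
import pytest

import halotrans.duplication as dup
from halotrans.duplication import test_exclusive_clade as exclusive_clade
from halotrans.duplication import (
    HomologHit,
    PanelSeq,
    PhyloTree,
    build_bootstrap_tree,
    classify_candidate_duplicates,
    count_gene_copies,
    detect_duplicate_clusters,
    gather_homologs,
    pairwise_protein_similarity,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(rng, n):
    return "".join(rng.choice(AA, n))


def mutate(rng, seq, rate):
    return "".join(
        c if rng.random() > rate else rng.choice([a for a in AA if a != c]) for c in seq
    )


class TestPairwiseSimilarity:
    def test_self_alignment(self, rng):
        s = random_protein(rng, 150)
        hit = pairwise_protein_similarity(s, s)
        assert hit.identity == 1.0 and hit.coverage_shorter == 1.0

    def test_ten_percent_substitutions(self):
        local = np.random.default_rng(7)
        a = random_protein(local, 300)
        b = list(a)
        for pos in local.choice(300, 30, replace=False):
            b[pos] = next(x for x in AA if x != a[pos])
        hit = pairwise_protein_similarity(a, "".join(b))
        assert hit.identity == pytest.approx(0.90, abs=0.02)

    def test_unrelated_scores_below_self(self, rng):
        a, b = random_protein(rng, 100), random_protein(rng, 100)
        self_score = pairwise_protein_similarity(a, a).score
        assert pairwise_protein_similarity(a, b).score < self_score

    def test_bad_symbols_error(self):
        with pytest.raises(ValueError):
            pairwise_protein_similarity("ACDE1", "ACDE")


class TestGatherHomologs:
    def test_identical_sequence_is_gathered(self, rng):
        q = random_protein(rng, 120)
        db = [PanelSeq("hit", q, "focal"), PanelSeq("noise", random_protein(rng, 120), "focal")]
        hits = gather_homologs("q", q, db)
        assert [h.subject_id for h in hits][:1] == ["hit"]

    @pytest.mark.parametrize(
        "identity,coverage,included",
        [
            (0.30, 0.9, False),  # identity must be strictly > 30%
            (0.31, 0.60, False),  # coverage must be strictly > 2/3
            (0.50, 0.70, True),
            (0.30001, 2 / 3 + 1e-6, True),
        ],
    )
    def test_threshold_strictness(self, monkeypatch, identity, coverage, included):
        def fake_similarity(a, b, query_id="q", subject_id="s", subject_origin="focal"):
            return HomologHit(query_id, subject_id, subject_origin, 100.0, identity, coverage)

        monkeypatch.setattr(dup, "pairwise_protein_similarity", fake_similarity)
        hits = gather_homologs("q", "ACDEFGHIKL", [PanelSeq("s", "ACDEFGHIKL", "focal")])
        assert bool(hits) == included


class TestClassification:
    def build_panel(self, rng):
        anc = random_protein(rng, 200)
        focal = {
            "dupA": mutate(rng, anc, 0.03),
            "dupB": mutate(rng, anc, 0.03),
            "lonely": random_protein(rng, 200),
        }
        panel = [
            PanelSeq("euk_far", mutate(rng, anc, 0.5), "other_eukaryote"),
            PanelSeq("euk_rand", random_protein(rng, 200), "other_eukaryote"),
        ]
        return focal, panel

    def test_conspecific_best_hit_is_candidate(self, rng):
        focal, panel = self.build_panel(rng)
        categories, _ = classify_candidate_duplicates(focal, panel, prefilter_k=None)
        assert categories["dupA"] == "candidate"
        assert categories["dupB"] == "candidate"
        assert categories["lonely"] == "non_candidate"

    def test_species_only_without_panel_homolog(self, rng):
        focal, _ = self.build_panel(rng)
        categories, _ = classify_candidate_duplicates(focal, [], prefilter_k=None)
        assert categories["dupA"] == "species_only"

    def test_tie_is_conservative(self, monkeypatch):
        """Equal top scores for focal and panel hits yield non_candidate."""

        def fake_similarity(a, b, query_id="q", subject_id="s", subject_origin="focal"):
            return HomologHit(query_id, subject_id, subject_origin, 50.0, 0.5, 1.0)

        monkeypatch.setattr(dup, "pairwise_protein_similarity", fake_similarity)
        categories, _ = classify_candidate_duplicates(
            {"g1": "ACDEFGHIKL", "g2": "ACDEFGHIKL"},
            [PanelSeq("e1", "ACDEFGHIKL", "other_eukaryote")],
            prefilter_k=None,
        )
        assert categories["g1"] == "non_candidate"


class TestBootstrapTree:
    def test_two_pairs_topology(self, rng):
        anc = random_protein(rng, 250)
        seqs = {
            "F1": mutate(rng, anc, 0.02),
            "F2": mutate(rng, anc, 0.02),
            "E1": mutate(rng, anc, 0.45),
            "E2": mutate(rng, anc, 0.45),
        }
        tree = build_bootstrap_tree(seqs, n_bootstrap=100, seed=3)
        ok, support = exclusive_clade(tree, {"F1", "F2"})
        assert ok and support > 90

    def test_input_order_invariance(self, rng):
        anc = random_protein(rng, 200)
        seqs = {f"s{i}": mutate(rng, anc, 0.1 * (i + 1) / 6) for i in range(6)}
        t1 = build_bootstrap_tree(seqs, 50, seed=9)
        t2 = build_bootstrap_tree(dict(reversed(list(seqs.items()))), 50, seed=9)
        assert set(t1.bipartitions) == set(t2.bipartitions)

    def test_fewer_than_four_sequences_errors(self, rng):
        seqs = {f"s{i}": random_protein(rng, 50) for i in range(3)}
        with pytest.raises(ValueError, match="2-vs-1"):
            build_bootstrap_tree(seqs)

    def test_deterministic_given_seed(self, rng):
        anc = random_protein(rng, 150)
        seqs = {f"s{i}": mutate(rng, anc, 0.2) for i in range(5)}
        t1 = build_bootstrap_tree(seqs, 30, seed=4)
        t2 = build_bootstrap_tree(seqs, 30, seed=4)
        assert t1.bipartitions == t2.bipartitions and t1.newick == t2.newick


def random_support_tree(rng, n_leaves=8):
    """Random binary topology with random integer supports, as newick."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        support = int(rng.integers(0, 101))
        merged = f"({a},{b}){support}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


def dendropy_exclusive(newick, focal, min_support=50.0):
    """Oracle: enumerate all bipartitions with dendropy and test exclusivity."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    taxa = {t.label for t in tree.taxon_namespace}
    for edge in tree.bipartition_edge_map.values():
        bip = edge.bipartition
        side = {t.label for t in bip.leafset_taxa(tree.taxon_namespace)}
        for candidate in (side, taxa - side):
            if candidate == set(focal):
                head = edge.head_node
                label = head.label
                if label is None:
                    continue
                if float(label) > min_support:
                    return True
    return False


class TestExclusiveClade:
    def test_supported_pair(self):
        tree = PhyloTree.from_newick("((F1,F2)75,(E1,E2));")
        assert exclusive_clade(tree, {"F1", "F2"}) == (True, 75.0)

    def test_paraphyly(self):
        tree = PhyloTree.from_newick("((F1,E1),(F2,E2));")
        assert exclusive_clade(tree, {"F1", "F2"}) == (False, None)

    def test_support_exactly_50_fails(self):
        tree = PhyloTree.from_newick("((F1,F2)50,(E1,E2));")
        assert exclusive_clade(tree, {"F1", "F2"}) == (False, 50.0)

    def test_single_outgroup_is_forced(self):
        tree = PhyloTree.from_newick("((F1,F2),E1);")
        assert exclusive_clade(tree, {"F1", "F2"}) == (True, None)

    def test_missing_focal_leaf_errors(self):
        tree = PhyloTree.from_newick("((F1,F2)75,(E1,E2));")
        with pytest.raises(ValueError):
            exclusive_clade(tree, {"F1", "ghost"})

    def test_agrees_with_bipartition_enumeration(self):
        """100 random 8-leaf trees with random supports match the dendropy
        brute-force enumeration for random focal subsets."""
        local = np.random.default_rng(2024)
        for _ in range(100):
            newick = random_support_tree(local)
            tree = PhyloTree.from_newick(newick)
            k = int(local.integers(2, 7))
            focal = set(local.choice([f"L{i}" for i in range(8)], k, replace=False))
            mine, _ = exclusive_clade(tree, focal)
            assert mine == dendropy_exclusive(newick, focal)


class TestDetectClusters:
    def test_families_recovered_and_ortholog_rejected(self, rng):
        anc1, anc2 = random_protein(rng, 220), random_protein(rng, 220)
        focal = {
            "a1": mutate(rng, anc1, 0.03),
            "a2": mutate(rng, anc1, 0.03),
            "b1": mutate(rng, anc2, 0.03),
            "b2": mutate(rng, anc2, 0.03),
            "solo": random_protein(rng, 220),
        }
        panel = [
            PanelSeq("euk_a", mutate(rng, anc1, 0.5), "other_eukaryote"),
            # an ortholog nested inside family b's clade (closer than the
            # paralogs are to each other)
            PanelSeq("euk_b_inside", mutate(rng, focal["b1"], 0.01), "other_eukaryote"),
        ]
        clusters, summary = detect_duplicate_clusters(focal, panel, prefilter_k=None, seed=11)
        by_members = {frozenset(c.member_gene_ids): c for c in clusters}
        a = by_members.get(frozenset({"a1", "a2"}))
        assert a is not None and a.category == "exclusive_clade"
        # b1's best hit is the nested ortholog, so family b never forms
        assert frozenset({"b1", "b2"}) not in by_members
        assert summary["categories"]["b1"] == "non_candidate"

    def test_species_only_cluster(self, rng):
        anc = random_protein(rng, 200)
        focal = {"x1": mutate(rng, anc, 0.03), "x2": mutate(rng, anc, 0.03)}
        clusters, _ = detect_duplicate_clusters(focal, [], prefilter_k=None)
        assert clusters[0].category == "species_only"

    def test_raising_min_support_never_accepts_more(self, rng):
        anc = random_protein(rng, 200)
        focal = {f"g{i}": mutate(rng, anc, 0.05) for i in range(4)}
        panel = [PanelSeq("e", mutate(rng, anc, 0.5), "other_eukaryote")]
        accepted = []
        for min_support in (0, 50, 90, 100):
            clusters, _ = detect_duplicate_clusters(
                focal, panel, min_support=min_support, prefilter_k=None, seed=2
            )
            accepted.append(sum(c.category == "exclusive_clade" for c in clusters))
        assert all(a >= b for a, b in zip(accepted, accepted[1:]))


class TestCopyCount:
    def test_near_identical_collapse(self, monkeypatch):
        table = {("a", "b"): 0.95, ("a", "c"): 0.50, ("b", "c"): 0.50}

        def fake_similarity(x, y, query_id="q", subject_id="s", subject_origin="focal"):
            key = (min(x[0], y[0]), max(x[0], y[0]))
            return HomologHit("q", "s", "focal", 10.0, table[key], 1.0)

        monkeypatch.setattr(dup, "pairwise_protein_similarity", fake_similarity)
        seqs = {"a": "a" * 10, "b": "b" * 10, "c": "c" * 10}
        assert count_gene_copies(seqs) == 2

    def test_identity_boundary_strict(self, monkeypatch):
        monkeypatch.setattr(
            dup,
            "pairwise_protein_similarity",
            lambda x, y, **k: HomologHit("q", "s", "focal", 10.0, 0.90, 1.0),
        )
        assert count_gene_copies({"a": "aa", "b": "bb"}) == 2

    def test_chain_is_single_linkage(self, monkeypatch):
        table = {("a", "b"): 0.92, ("b", "c"): 0.92, ("a", "c"): 0.84}

        def fake_similarity(x, y, **kwargs):
            key = (min(x[0], y[0]), max(x[0], y[0]))
            return HomologHit("q", "s", "focal", 10.0, table[key], 1.0)

        monkeypatch.setattr(dup, "pairwise_protein_similarity", fake_similarity)
        assert count_gene_copies({"a": "a" * 5, "b": "b" * 5, "c": "c" * 5}) == 1

    def test_real_sequences(self, rng):
        anc = random_protein(rng, 200)
        assert count_gene_copies({"a": anc, "b": mutate(rng, anc, 0.02)}) == 1
        assert count_gene_copies({"a": anc, "b": mutate(rng, anc, 0.30)}) == 2
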