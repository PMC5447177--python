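"""Isoform collapsing and contamination screening against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import lcs_length_dp, partition_by_closure, ungapped_contamination_decision
from halotrans.transcript_catalog import (
    GeneRecord,
    OrfRecord,
    classify_origin_by_abundance,
    collapse_orfs_to_genes,
    longest_shared_stretch,
    screen_prokaryotic_similarity,
)

BASES = "ACGT"


def random_nt(rng, n):
    return "".join(rng.choice(list(BASES), n))


class TestLongestSharedStretch:
    def test_identity(self, rng):
        s = random_nt(rng, 80)
        assert longest_shared_stretch(s, s) == 80

    def test_planted_block(self, rng):
        """Two sequences engineered to share exactly one 50-nt block."""
        block = random_nt(rng, 50)
        # disjoint alphabets outside the block prevent accidental overlap
        a = "A" * 40 + block + "C" * 40
        b = "G" * 40 + block + "T" * 40
        # the planted block could extend by flank characters; oracle decides
        assert longest_shared_stretch(a, b) == lcs_length_dp(a, b) == 50

    def test_no_common_kmer(self):
        assert longest_shared_stretch("AAAA", "GGGG") == 0
        assert longest_shared_stretch("AAAA", "GGGA") == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            longest_shared_stretch("", "ACGT")

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60), st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_matches_dp_oracle(self, a, b):
        assert longest_shared_stretch(a, b) == lcs_length_dp(a, b)


class TestCollapse:
    def test_shared_50_boundary(self):
        """The isoform rule is inclusive: >=50 shared nt joins, 49 does not."""
        block50 = ("ACGT" * 13)[:50]  # position 49 is 'C', so 'T' flanks don't extend
        a = OrfRecord("A", "A" * 30 + block50 + "A" * 30)
        b = OrfRecord("B", "G" * 30 + block50 + "G" * 30)
        c = OrfRecord("C", "T" * 30 + block50[:49] + "T" * 30)
        assert lcs_length_dp(a.nt_seq, b.nt_seq) == 50
        assert lcs_length_dp(a.nt_seq, c.nt_seq) == 49
        genes = collapse_orfs_to_genes([a, b, c], min_shared=50)
        parts = {g.orf_ids for g in genes}
        assert frozenset({"A", "B"}) in parts and frozenset({"C"}) in parts

    def test_transitive_closure(self, rng):
        """A~B and B~C chain into one gene even when A,C are unrelated."""
        b1, b2 = random_nt(rng, 55), random_nt(rng, 55)
        a = OrfRecord("A", "A" * 20 + b1)
        b = OrfRecord("B", b1 + "C" * 10 + b2)
        c = OrfRecord("C", b2 + "G" * 20)
        genes = collapse_orfs_to_genes([a, b, c])
        assert len(genes) == 1 and genes[0].orf_ids == frozenset("ABC")

    def test_singletons(self, rng):
        orfs = [OrfRecord(f"o{i}", random_nt(rng, 120)) for i in range(12)]
        genes = collapse_orfs_to_genes(orfs)
        assert len(genes) == 12

    def test_duplicate_ids_error(self):
        with pytest.raises(ValueError):
            collapse_orfs_to_genes([OrfRecord("A", "ACGT" * 20), OrfRecord("A", "ACGT" * 20)])

    def test_representative_is_longest_tie_lexicographic(self, rng):
        block = random_nt(rng, 60)
        a = OrfRecord("zzz", block + "A" * 30)
        b = OrfRecord("aaa", block + "G" * 30)
        genes = collapse_orfs_to_genes([a, b])
        assert genes[0].representative_orf == "aaa"

    def test_matches_closure_oracle(self, rng):
        """Partition equals the all-pairs LCS transitive closure on 50 ORFs."""
        # a mix of random ORFs and seeded overlaps
        seqs = {}
        for i in range(30):
            seqs[f"r{i:02d}"] = random_nt(rng, 150)
        shared = [random_nt(rng, 60) for _ in range(6)]
        for i in range(20):
            s = shared[i % 6]
            seqs[f"s{i:02d}"] = random_nt(rng, 40) + s + random_nt(rng, 40)
        orfs = [OrfRecord(k, v) for k, v in sorted(seqs.items())]
        genes = collapse_orfs_to_genes(orfs)
        assert {frozenset(g.orf_ids) for g in genes} == partition_by_closure(seqs, 50)

    def test_lowering_min_shared_never_increases_gene_count(self, rng):
        orfs = [OrfRecord(f"o{i}", random_nt(rng, 200)) for i in range(20)]
        shared = random_nt(rng, 45)
        orfs += [OrfRecord(f"p{i}", random_nt(rng, 30) + shared + random_nt(rng, 30)) for i in range(5)]
        previous = None
        for min_shared in (60, 50, 45, 30, 20):
            n = len(collapse_orfs_to_genes([OrfRecord(o.orf_id, o.nt_seq) for o in orfs], min_shared))
            if previous is not None:
                assert n <= previous
            previous = n


class TestContaminationScreen:
    def make_db(self, _rng=None):
        local = np.random.default_rng(424242)
        return {f"db{i}": random_nt(local, 600) for i in range(4)}

    def test_mutated_block_discarded(self, rng):
        """A 120-bp block at ~93% identity (8 substitutions) is a contaminant."""
        db = self.make_db(rng)
        block = list(db["db0"][100:220])
        for pos in np.linspace(10, 110, 8, dtype=int):
            block[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[block[pos]]
        orf = OrfRecord("x", "".join(block))
        hit = screen_prokaryotic_similarity(orf, db)
        assert hit.decision == "discard"
        assert ungapped_contamination_decision(orf.nt_seq, db)

    def test_exact_100bp_kept(self, rng):
        """A region of exactly 100 bp at 100% identity is not >100 bp."""
        db = self.make_db(rng)
        orf = OrfRecord("x", db["db1"][50:150])
        hit = screen_prokaryotic_similarity(orf, db)
        assert hit.decision == "keep"
        assert not ungapped_contamination_decision(orf.nt_seq, db)
        # one base longer crosses the strict threshold
        orf2 = OrfRecord("y", db["db1"][50:151])
        assert screen_prokaryotic_similarity(orf2, db).decision == "discard"

    def test_identity_boundary_is_strict(self):
        """A 110-bp region whose best long window is exactly 90% identical is
        kept; removing one mismatch (90.9%) makes it a contaminant.

        The 11 mismatches sit in the central columns, so every window longer
        than 100 bp contains all of them and none exceeds 90% identity."""
        db = self.make_db()
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        block = list(db["db2"][100:210])
        positions = list(range(30, 85, 5))  # 11 central positions
        for pos in positions:
            block[pos] = flip[block[pos]]
        keep_orf = OrfRecord("x", "".join(block))
        assert screen_prokaryotic_similarity(keep_orf, db).decision == "keep"
        block[positions[0]] = db["db2"][100 + positions[0]]  # back to 10 mismatches
        discard_orf = OrfRecord("y", "".join(block))
        assert screen_prokaryotic_similarity(discard_orf, db).decision == "discard"

    def test_unrelated_kept(self, rng):
        db = self.make_db(rng)
        orf = OrfRecord("x", random_nt(rng, 300))
        assert screen_prokaryotic_similarity(orf, db).decision == "keep"

    def test_db_order_invariance(self, rng):
        db = self.make_db(rng)
        orf = OrfRecord("x", db["db3"][10:200])
        h1 = screen_prokaryotic_similarity(orf, db)
        h2 = screen_prokaryotic_similarity(orf, dict(reversed(list(db.items()))))
        assert (h1.subject_id, h1.decision) == (h2.subject_id, h2.decision)

    def test_random_cases_match_window_oracle(self, rng):
        """Decisions agree with exhaustive ungapped window scanning."""
        db = self.make_db(rng)
        cases = []
        for i in range(10):
            src = db[f"db{i % 4}"]
            start = int(rng.integers(0, 300))
            length = int(rng.integers(80, 200))
            block = list(src[start : start + length])
            n_mut = int(rng.integers(0, max(2, length // 8)))
            for pos in rng.choice(len(block), size=min(n_mut, len(block)), replace=False):
                block[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[block[pos]]
            cases.append("".join(block))
        for i, seq in enumerate(cases):
            mine = screen_prokaryotic_similarity(OrfRecord(f"c{i}", seq), db).decision == "discard"
            oracle = ungapped_contamination_decision(seq, db)
            assert mine == oracle, f"case {i}: mine={mine} oracle={oracle}"


class TestOriginClassification:
    def gene(self, intron):
        return GeneRecord("g", frozenset({"o"}), "o", has_intron=intron)

    @pytest.mark.parametrize(
        "intron,tpm,affinity,expected",
        [
            (True, 3986.0, True, "eukaryotic"),  # intron rescues despite affinity
            (False, 8.0, True, "contaminant"),  # below the 10-TPM ceiling
            (False, 10.0, True, "contaminant"),  # ceiling is inclusive (not above 10)
            (False, 100.0, True, "uncertain"),  # between the evidence levels
            (False, 600.0, True, "uncertain"),  # 600 exactly is not >600
            (False, 601.0, True, "eukaryotic"),  # strictly above 600
            (False, 5.0, False, "eukaryotic"),  # no affinity: no question raised
        ],
    )
    def test_decision_table(self, intron, tpm, affinity, expected):
        assert classify_origin_by_abundance(self.gene(intron), tpm, affinity) == expected

    def test_negative_tpm_errors(self):
        with pytest.raises(ValueError):
            classify_origin_by_abundance(self.gene(False), -1.0, True)
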