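"""Lateral-gene-transfer candidate screening and short protein motif scans.

A gene whose best protein hits are prokaryotic is only accepted as a lateral
acquisition when eukaryotic-origin evidence backs it: a spliceosomal intron
or transcript abundance far above the contamination ceiling (>600 TPM, while
confirmed food-source contaminants stayed <=10 TPM). Clade exclusivity with
prokaryotes on a supplied tree raises confidence but is not required. The
module also scans proteins for wildcard motifs (kinase motif PxLXHGDLWSxN,
protein-kinase-C site Tx[K/R]) and for ER-retention signals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .duplication import HomologHit, PhyloTree, test_exclusive_clade

__all__ = [
    "LgtCandidate",
    "MotifHit",
    "screen_lgt_candidate",
    "scan_motif",
    "check_er_retention",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class LgtCandidate:
    gene_id: str
    best_hits_prokaryotic: bool
    prokaryote_clade_exclusive: bool
    clade_support: float | None
    max_tpm: float
    has_intron: bool
    absent_in_sister: bool | None
    verdict: str  # lgt_candidate | probable_contaminant | uncertain | not_lgt


@dataclass
class MotifHit:
    sequence_id: str
    motif_name: str
    start_position: int  # 1-based
    matched_substring: str


def screen_lgt_candidate(
    gene_id: str,
    hits: Sequence[HomologHit],
    max_tpm: float,
    has_intron: bool,
    tree: PhyloTree | None = None,
    prokaryote_leaves: Sequence[str] = (),
    absent_in_sister: bool | None = None,
    high_tpm: float = 600.0,
    contaminant_tpm: float = 10.0,
) -> LgtCandidate:
    """Combine similarity, expression, intron and tree evidence into a verdict.

    Decision table: no prokaryotic affinity -> not_lgt; prokaryotic affinity
    with an intron or TPM > ``high_tpm`` -> lgt_candidate; prokaryotic
    affinity with TPM <= ``contaminant_tpm`` and no intron ->
    probable_contaminant; anything else -> uncertain.
    """
    if max_tpm < 0:
        raise ValueError("max_tpm must be non-negative")
    best_prok = False
    if hits:
        best_score = max(h.score for h in hits)
        best_origins = {h.subject_origin for h in hits if h.score == best_score}
        best_prok = best_origins == {"prokaryote"}
    clade_excl, support = False, None
    if tree is not None and prokaryote_leaves:
        focal = {gene_id} | (set(prokaryote_leaves) & tree.leaves)
        if gene_id in tree.leaves and len(focal) >= 2 and tree.leaves - focal:
            clade_excl, support = test_exclusive_clade(tree, focal)
    if not best_prok:
        verdict = "not_lgt"
    elif has_intron or max_tpm > high_tpm:
        verdict = "lgt_candidate"
    elif max_tpm <= contaminant_tpm and not has_intron:
        verdict = "probable_contaminant"
    else:
        verdict = "uncertain"
    return LgtCandidate(
        gene_id, best_prok, clade_excl, support, max_tpm, has_intron, absent_in_sister, verdict
    )


def _parse_motif(pattern: str) -> list[str | None]:
    """Tokenise a motif: residue, wildcard (x/X) or bracketed alternation.

    Both ``[KR]`` and ``[K/R]`` denote "K or R"; x and X match any residue.
    """
    if not pattern:
        raise ValueError("empty motif pattern")
    tokens: list[str | None] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch in "xX":
            tokens.append(None)
            i += 1
        elif ch == "[":
            end = pattern.find("]", i)
            if end == -1:
                raise ValueError(f"unclosed bracket in motif {pattern!r}")
            inner = pattern[i + 1 : end].replace("/", "")
            if not inner or any(c.upper() not in _AA for c in inner):
                raise ValueError(f"illegal alternation {pattern[i:end + 1]!r}")
            tokens.append("".join(sorted(set(inner.upper()))))
            i = end + 1
        elif ch.upper() in _AA:
            tokens.append(ch.upper())
            i += 1
        else:
            raise ValueError(f"illegal motif character {ch!r} in {pattern!r}")
    return tokens


def scan_motif(protein: str, pattern: str, sequence_id: str = "", motif_name: str | None = None) -> list[MotifHit]:
    """All (possibly overlapping) matches of a wildcard motif, 1-based."""
    tokens = _parse_motif(pattern)
    regex = "".join("." if t is None else (f"[{t}]" if len(t) > 1 else t) for t in tokens)
    hits = []
    seq = protein.upper()
    for m in re.finditer(f"(?=({regex}))", seq):
        hits.append(
            MotifHit(sequence_id, motif_name or pattern, m.start() + 1, m.group(1))
        )
    return hits


def check_er_retention(protein: str) -> dict[str, bool]:
    """ER-retention signal flags: KDEL/HDEL/KK/KxK at the C-terminus, RR at
    the N-terminus (KxK means K at positions -3 and -1)."""
    seq = protein.upper()
    flags = {
        "KDEL_C": False,
        "HDEL_C": False,
        "KK_C": False,
        "KxK_C": False,
        "RR_N": False,
    }
    if len(seq) >= 4:
        flags["KDEL_C"] = seq.endswith("KDEL")
        flags["HDEL_C"] = seq.endswith("HDEL")
    if len(seq) >= 2:
        flags["KK_C"] = seq.endswith("KK")
        flags["RR_N"] = seq.startswith("RR")
    if len(seq) >= 3:
        flags["KxK_C"] = seq[-3] == "K" and seq[-1] == "K"
    return flags
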