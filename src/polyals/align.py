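"""Pairwise and progressive multiple alignment.

Pairwise alignment is global Needleman–Wunsch (match +1, mismatch −1,
gap −2, free end gaps), delegated to Biopython's PairwiseAligner with
exactly those scores. Multiple alignment is progressive over a UPGMA
guide tree built from 6-mer distances, merging profiles through their
consensus sequences. This is deliberately desk-scale machinery: the
homoeologs and clone libraries it serves diverge by a few percent at
most, where any reasonable scheme recovers the same alignment.
"""

from __future__ import annotations

from typing import Sequence as TSequence

import numpy as np
from Bio import Align as _bioalign
from Bio.Align import substitution_matrices

from .seqcore import (
    GAP,
    IUPAC_SETS,
    Alignment,
    DistanceMatrix,
    Sequence,
    TreeNode,
    consensus,
    upgma,
)

_ALPHABET = "".join(sorted(IUPAC_SETS)) + GAP


def _substitution_matrix() -> substitution_matrices.Array:
    """+1 where IUPAC sets intersect, −1 otherwise, 0 against a gap column."""
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if a == GAP or b == GAP:
                m[a, b] = 0.0
            else:
                m[a, b] = 1.0 if IUPAC_SETS[a] & IUPAC_SETS[b] else -1.0
    return m


def _dna_aligner() -> _bioalign.PairwiseAligner:
    aligner = _bioalign.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _substitution_matrix()
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


_ALIGNER = _dna_aligner()


def pairwise_align(a: Sequence, b: Sequence) -> Alignment:
    """Global alignment of two sequences with free end gaps."""
    aln = _ALIGNER.align(a.residues, b.residues)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return Alignment([
        Sequence(a.id, ga, dict(a.meta)),
        Sequence(b.id, gb, dict(b.meta)),
    ])


def _kmer_sets(seqs: TSequence[Sequence], k: int = 6) -> list[set[str]]:
    return [
        {s.residues[i:i + k] for i in range(max(1, len(s) - k + 1))}
        for s in seqs
    ]


def kmer_guide_tree(seqs: TSequence[Sequence], k: int = 6) -> TreeNode:
    """UPGMA guide tree over Jaccard 6-mer distances."""
    sets = _kmer_sets(seqs, k)
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            d[i, j] = d[j, i] = 1.0 - len(sets[i] & sets[j]) / union if union else 0.0
    return upgma(DistanceMatrix([s.id for s in seqs], d))


def _profile_consensus(rows: list[Sequence]) -> str:
    """Column consensus keeping gap-majority columns as N placeholders so the
    profile-profile step sees every column exactly once."""
    L = len(rows[0])
    out = []
    for col in range(L):
        column = [r.residues[col] for r in rows]
        counts: dict[str, int] = {}
        for ch in column:
            counts[ch] = counts.get(ch, 0) + 1
        best = max(sorted(counts), key=lambda c: counts[c])
        out.append("N" if best == GAP else best)
    return "".join(out)


def _merge_profiles(p1: list[Sequence], p2: list[Sequence]) -> list[Sequence]:
    c1 = _profile_consensus(p1)
    c2 = _profile_consensus(p2)
    aln = _ALIGNER.align(c1, c2)[0]
    g1, g2 = str(aln[0]), str(aln[1])

    def expand(rows: list[Sequence], gapped: str) -> list[Sequence]:
        new_rows = []
        for r in rows:
            out, i = [], 0
            for ch in gapped:
                if ch == GAP:
                    out.append(GAP)
                else:
                    out.append(r.residues[i])
                    i += 1
            new_rows.append(Sequence(r.id, "".join(out), dict(r.meta)))
        return new_rows

    return expand(p1, g1) + expand(p2, g2)


def progressive_align(seqs: TSequence[Sequence]) -> Alignment:
    """Progressive multiple alignment over a 6-mer UPGMA guide tree."""
    if not seqs:
        raise ValueError("nothing to align")
    if len(seqs) == 1:
        return Alignment([Sequence(seqs[0].id, seqs[0].residues, dict(seqs[0].meta))])
    if len(seqs) == 2:
        return pairwise_align(seqs[0], seqs[1])
    by_id = {s.id: s for s in seqs}
    if len(by_id) != len(seqs):
        raise ValueError("duplicate sequence ids")
    guide = kmer_guide_tree(seqs)

    def build(node: TreeNode) -> list[Sequence]:
        if node.is_leaf:
            s = by_id[node.label]  # type: ignore[index]
            return [Sequence(s.id, s.residues, dict(s.meta))]
        profile = build(node.children[0])
        for child in node.children[1:]:
            profile = _merge_profiles(profile, build(child))
        return profile

    rows = build(guide)
    order = {s.id: i for i, s in enumerate(seqs)}
    rows.sort(key=lambda r: order[r.id])
    return Alignment(rows)


def align_or_passthrough(seqs: TSequence[Sequence]) -> Alignment:
    """Alignment of a set of sequences, skipping the progressive step when
    all inputs are already the same length (substitution-only data)."""
    if len({len(s) for s in seqs}) == 1:
        return Alignment([Sequence(s.id, s.residues, dict(s.meta)) for s in seqs])
    return progressive_align(seqs)


def msa_consensus(seqs: TSequence[Sequence], id: str = "consensus") -> Sequence:
    """Align then collapse to a majority consensus (gap columns dropped)."""
    return consensus(align_or_passthrough(seqs).rows, id=id)
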