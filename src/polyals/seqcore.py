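"""Core sequence, alignment, distance and UPGMA machinery.

Everything downstream (CAPS barcoding, homoeolog assignment, mutation
calling, primer design) is built on the primitives here: IUPAC-aware
nucleotide sequences, gapped alignments with column/source coordinate
maps, p-distances under pairwise deletion, and deterministic UPGMA
trees serialisable as newick.

Coordinates are 1-based and inclusive throughout; gaps never consume
source coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence as TSequence

import numpy as np

# ---------------------------------------------------------------------------
# IUPAC alphabet

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
GAP = "-"
ALPHABET = frozenset(IUPAC_SETS) | {GAP}

_SET_TO_CODE = {v: k for k, v in IUPAC_SETS.items()}

#: 4-bit encoding (A=1, C=2, G=4, T=8); gap encodes to 0.
_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_CHAR_BITS = np.zeros(128, dtype=np.uint8)
for _c, _s in IUPAC_SETS.items():
    _CHAR_BITS[ord(_c)] = sum(_BITS[b] for b in _s)


def ambiguity_code(bases: Iterable[str]) -> str:
    """IUPAC code for a set of unambiguous bases (e.g. {G,T} -> K)."""
    s = frozenset(bases)
    if not s or not s <= frozenset("ACGT"):
        raise ValueError(f"not a set of unambiguous bases: {sorted(s)}")
    return _SET_TO_CODE[s]


def bases_match(a: str, b: str) -> bool:
    """True iff the IUPAC sets of two residues intersect (gaps never match)."""
    if a == GAP or b == GAP:
        return False
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


def revcomp(s: str) -> str:
    return s.translate(_RC_TABLE)[::-1]


_RC_PAIRS = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
             "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
             "B": "V", "D": "H", "H": "D", "V": "B", "N": "N", "-": "-"}
_RC_TABLE = str.maketrans(
    "".join(_RC_PAIRS) + "".join(_RC_PAIRS).lower(),
    "".join(_RC_PAIRS.values()) + "".join(_RC_PAIRS.values()).lower(),
)


class NoComparableSitesError(ValueError):
    """Raised when pairwise deletion leaves zero comparable sites."""


# ---------------------------------------------------------------------------
# Sequence / Alignment containers


@dataclass
class Sequence:
    """An identified IUPAC nucleotide string with free-form metadata.

    ``U`` is normalised to ``T`` on construction; the gap character is
    legal only for rows living inside an :class:`Alignment`.
    """

    id: str
    residues: str
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.residues = self.residues.upper().replace("U", "T")
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(f"{self.id}: non-IUPAC characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "Sequence":
        return Sequence(self.id, self.residues.replace(GAP, ""), dict(self.meta))

    def reverse_complement(self) -> "Sequence":
        return Sequence(self.id, revcomp(self.residues), dict(self.meta))


@dataclass
class Alignment:
    """Equal-length gapped rows plus column<->source coordinate maps."""

    rows: list[Sequence]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("alignment rows differ in length")
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def colmap(self, row_id: str) -> list[int | None]:
        """Per column (1-based index into the list), the 1-based source
        position in that row's ungapped sequence, or None at gaps."""
        row = self[row_id]
        out: list[int | None] = []
        pos = 0
        for ch in row.residues:
            if ch == GAP:
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out

    def source_to_column(self, row_id: str) -> dict[int, int]:
        """Inverse map: source position -> alignment column (both 1-based)."""
        return {src: col + 1
                for col, src in enumerate(self.colmap(row_id))
                if src is not None}

    def __getitem__(self, row_id: str) -> Sequence:
        for r in self.rows:
            if r.id == row_id:
                return r
        raise KeyError(row_id)

    def __iter__(self):
        return iter(self.rows)


# ---------------------------------------------------------------------------
# Distances


def p_distance(a: Sequence | str, b: Sequence | str) -> float:
    """Proportion of differing sites between two aligned sequences.

    Pairwise deletion: columns where either row shows a gap or N are
    excluded. Ambiguity codes count as a match iff their IUPAC sets
    intersect. Raises :class:`NoComparableSitesError` if nothing is left.
    """
    ra = a.residues if isinstance(a, Sequence) else a
    rb = b.residues if isinstance(b, Sequence) else b
    if len(ra) != len(rb):
        raise ValueError("p_distance requires equal-length (aligned) inputs")
    comparable = 0
    diffs = 0
    for x, y in zip(ra, rb):
        if x in (GAP, "N") or y in (GAP, "N"):
            continue
        comparable += 1
        if not IUPAC_SETS[x] & IUPAC_SETS[y]:
            diffs += 1
    if comparable == 0:
        raise NoComparableSitesError("no comparable sites")
    return diffs / comparable


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance fractions with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("non-zero diagonal")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


def _encode(residues: str) -> np.ndarray:
    return _CHAR_BITS[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def distance_matrix(seqs: TSequence[Sequence]) -> DistanceMatrix:
    """All-pairs p-distance of pre-aligned sequences (vectorised).

    Exactly equivalent to calling :func:`p_distance` on every pair; the
    bitmask formulation is just fast enough for clone libraries.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences are not aligned (unequal lengths)")
    enc = np.stack([_encode(s.residues) for s in seqs])
    # comparable: neither gap (0) nor N (15)
    usable = (enc != 0) & (enc != 15)
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        both = usable[i] & usable[i + 1:]
        comp = both.sum(axis=1)
        if np.any(comp == 0):
            raise NoComparableSitesError("no comparable sites")
        mismatch = ((enc[i] & enc[i + 1:]) == 0) & both
        d[i, i + 1:] = mismatch.sum(axis=1) / comp
    d = d + d.T
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree; height in expected-distance units."""

    height: float
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> list[str]:
        return [l.label for l in self.leaves()]  # type: ignore[misc]

    def newick(self) -> str:
        return self._nwk(parent_height=None) + ";"

    def _nwk(self, parent_height: float | None) -> str:
        if self.is_leaf:
            body = self.label or ""
        else:
            body = "(" + ",".join(c._nwk(self.height) for c in self.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - self.height:.6f}"


def upgma(m: DistanceMatrix) -> TreeNode:
    """UPGMA agglomeration of a distance matrix.

    Repeatedly merges the pair of clusters with minimal average linkage;
    the merged node sits at half the merge distance. Ties are broken by
    the lexicographically smallest pair of cluster keys, where a
    cluster's key is the sorted tuple of its leaf labels — making the
    result independent of input order and platform.
    """
    d = np.array(m.d, dtype=float)
    if np.any(np.isnan(d)):
        raise ValueError("NaN distances")
    if np.any(d < 0):
        raise ValueError("negative distances")
    n = len(m.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")

    nodes: dict[int, TreeNode] = {
        i: TreeNode(0.0, label=lab) for i, lab in enumerate(m.labels)
    }
    sizes = {i: 1 for i in range(n)}
    keys = {i: (lab,) for i, lab in enumerate(m.labels)}
    dist = {(i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    nxt = n

    def pair_dist(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                dij = pair_dist(i, j)
                a, b = sorted((keys[i], keys[j]))
                cand = (dij, a, b, i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        dij, _, _, i, j = best  # type: ignore[misc]
        node = TreeNode(dij / 2.0, children=[nodes[i], nodes[j]])
        nodes[nxt] = node
        sizes[nxt] = sizes[i] + sizes[j]
        keys[nxt] = tuple(sorted(keys[i] + keys[j]))
        active -= {i, j}
        for k in active:
            dk = (sizes[i] * pair_dist(i, k) + sizes[j] * pair_dist(j, k)) / (
                sizes[i] + sizes[j]
            )
            dist[(min(k, nxt), max(k, nxt))] = dk
        active.add(nxt)
        nxt += 1

    return nodes[nxt - 1]


def cut_tree(root: TreeNode, height: float) -> list[list[str]]:
    """Leaf-label groups of the maximal subtrees whose root height <= height."""
    clusters: list[list[str]] = []

    def walk(node: TreeNode) -> None:
        if node.height <= height + 1e-12:
            clusters.append(node.leaf_labels())
        else:
            for c in node.children:
                walk(c)

    walk(root)
    return clusters


# ---------------------------------------------------------------------------
# Consensus & translation


def consensus(seqs: TSequence[Sequence], id: str = "consensus") -> Sequence:
    """Majority-rule column consensus of aligned sequences.

    Each residue votes for every base in its IUPAC set (one vote per
    base). Tied top bases collapse to the ambiguity code of the tied
    set; columns where gaps outnumber residues are dropped.
    """
    if not seqs:
        raise ValueError("consensus of empty input")
    if len(seqs) == 1:
        return Sequence(id, seqs[0].residues, dict(seqs[0].meta))
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences are not aligned")
    out = []
    for col in range(L):
        column = [s.residues[col] for s in seqs]
        gaps = column.count(GAP)
        if gaps > len(column) - gaps:
            continue
        votes: dict[str, int] = {"A": 0, "C": 0, "G": 0, "T": 0}
        for ch in column:
            if ch == GAP:
                continue
            for b in IUPAC_SETS[ch]:
                votes[b] += 1
        top = max(votes.values())
        winners = frozenset(b for b, v in votes.items() if v == top)
        out.append(_SET_TO_CODE[winners])
    if not out:
        raise ValueError("consensus is empty (all columns gap-majority)")
    return Sequence(id, "".join(out))


_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@lru_cache(maxsize=4096)
def translate_codon(codon: str) -> str:
    """Standard-code translation of one codon; ambiguity that changes the
    product gives 'X', ambiguity that does not (e.g. GCN) is resolved."""
    if GAP in codon:
        return "X"
    aas = {
        _CODON_TABLE[b1 + b2 + b3]
        for b1 in IUPAC_SETS[codon[0]]
        for b2 in IUPAC_SETS[codon[1]]
        for b3 in IUPAC_SETS[codon[2]]
    }
    return aas.pop() if len(aas) == 1 else "X"


def translate(s: Sequence | str, frame: int = 1) -> str:
    """Translate from the given frame (1|2|3); trailing partial codon dropped."""
    if frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2 or 3")
    residues = s.residues if isinstance(s, Sequence) else s
    residues = residues[frame - 1:]
    if len(residues) < 3:
        raise ValueError("fewer than 3 bases from frame start")
    return "".join(
        translate_codon(residues[i:i + 3]) for i in range(0, len(residues) - 2, 3)
    )
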