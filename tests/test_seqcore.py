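"""Sequence primitives: p-distance, consensus, translation, UPGMA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyals.seqcore import (
    Alignment,
    DistanceMatrix,
    NoComparableSitesError,
    Sequence,
    consensus,
    cut_tree,
    distance_matrix,
    p_distance,
    translate,
    translate_codon,
    upgma,
)

# ---------------------------------------------------------------------------
# brute-force UPGMA oracle: explicit average-linkage recomputation from the
# original matrix at every step


def upgma_oracle(labels, d):
    clusters = [frozenset([i]) for i in range(len(labels))]
    heights = {c: 0.0 for c in clusters}
    trees = {c: labels[i] for i, c in enumerate(clusters)}

    def linkage(a, b):
        return float(np.mean([d[i][j] for i in a for j in b]))

    def key(c):
        return tuple(sorted(labels[i] for i in c))

    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a == b:
                    continue
                ka, kb = sorted((key(a), key(b)))
                cand = (linkage(a, b), ka, kb, a, b)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        dist, _, _, a, b = best
        merged = a | b
        heights[merged] = dist / 2.0
        trees[merged] = (trees[a], trees[b])
        clusters = [c for c in clusters if c not in (a, b)] + [merged]
    root = clusters[0]
    return trees[root], heights


def canonical(node):
    """Order-independent (shape, heights) form of a TreeNode."""
    if node.is_leaf:
        return node.label
    return (
        round(node.height, 9),
        frozenset(canonical(c) for c in node.children),
    )


def canonical_oracle(tree, heights, cluster=None):
    if isinstance(tree, str):
        return tree

    def walk(t):
        if isinstance(t, str):
            return t, frozenset([t])
        (ca, la), (cb, lb) = walk(t[0]), walk(t[1])
        leaves = la | lb
        h = next(h for c, h in heights.items()
                 if {_label_index[x] for x in leaves} == set(c))
        return (round(h, 9), frozenset([ca, cb])), leaves

    return walk(tree)[0]


_label_index = {}


def oracle_canonical(labels, d):
    global _label_index
    _label_index = {lab: i for i, lab in enumerate(labels)}
    tree, heights = upgma_oracle(labels, d)
    return canonical_oracle(tree, heights)


# ---------------------------------------------------------------------------
# p-distance


@pytest.mark.parametrize("a, b, expected", [
    ("ACGT", "ACGT", 0.0),
    ("ACGT", "ACGA", 0.25),
    ("AC-T", "ACGT", 0.0),        # 3 comparable sites under pairwise deletion
    ("ANGT", "ACGT", 0.0),        # N excluded
    ("RCGT", "ACGT", 0.0),        # R={A,G} intersects {A}
    ("RCGT", "CCGT", 1 / 4),      # R does not intersect {C}
])
def test_p_distance_examples(a, b, expected):
    assert p_distance(a, b) == pytest.approx(expected)


def test_p_distance_no_comparable_sites():
    with pytest.raises(NoComparableSitesError, match="no comparable sites"):
        p_distance("--NN", "AC-N")


@given(st.lists(st.sampled_from("ACGTN-"), min_size=4, max_size=60))
@settings(max_examples=100, deadline=None)
def test_p_distance_symmetric_zero_bounded(chars):
    s = "".join(chars)
    rng = np.random.default_rng(len(s))
    other = "".join(
        c if rng.random() < 0.7 else "ACGT"[rng.integers(0, 4)] for c in chars
    )
    try:
        d1 = p_distance(s, other)
        d2 = p_distance(other, s)
    except NoComparableSitesError:
        return
    assert d1 == d2
    assert 0.0 <= d1 <= 1.0
    if s.replace("-", "").replace("N", ""):
        comparable_self = any(c not in "-N" for c in s)
        if comparable_self:
            assert p_distance(s, s) == 0.0


def test_distance_matrix_matches_bruteforce_loop():
    rng = np.random.default_rng(42)
    seqs = [
        Sequence(f"s{i}", "".join("ACGTN-"[j] for j in rng.integers(0, 6, 80)))
        for i in range(8)
    ]
    # guard against all-gap rows
    seqs = [Sequence(s.id, s.residues[:-4] + "ACGT") for s in seqs]
    m = distance_matrix(seqs)
    for i, a in enumerate(seqs):
        for j, b in enumerate(seqs):
            if i < j:
                assert m.d[i, j] == pytest.approx(p_distance(a, b))
    assert np.allclose(m.d, m.d.T)


def test_distance_matrix_duplicate_ids():
    seqs = [Sequence("x", "ACGT"), Sequence("x", "ACGA")]
    with pytest.raises(ValueError, match="duplicate"):
        distance_matrix(seqs)


# ---------------------------------------------------------------------------
# UPGMA


def test_upgma_two_taxa():
    m = DistanceMatrix(["a", "b"], np.array([[0, 0.2], [0.2, 0]]))
    tree = upgma(m)
    assert tree.height == pytest.approx(0.1)
    assert sorted(tree.leaf_labels()) == ["a", "b"]
    assert tree.newick() == "(a:0.100000,b:0.100000);"


def test_upgma_four_taxon_oracle():
    labels = ["a", "b", "c", "d"]
    d = [
        [0.0, 0.10, 0.30, 0.32],
        [0.10, 0.0, 0.28, 0.30],
        [0.30, 0.28, 0.0, 0.06],
        [0.32, 0.30, 0.06, 0.0],
    ]
    tree = upgma(DistanceMatrix(labels, np.array(d)))
    assert canonical(tree) == oracle_canonical(labels, d)


@pytest.mark.parametrize("seed", range(30))
def test_upgma_matches_bruteforce_random(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    labels = [f"t{i}" for i in range(n)]
    tree = upgma(DistanceMatrix(labels, d))
    assert canonical(tree) == oracle_canonical(labels, d.tolist())


def test_upgma_matches_scipy_average_linkage():
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(7)
    n = 12
    d = rng.random((n, n)) + 0.01
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    tree = upgma(DistanceMatrix([f"t{i}" for i in range(n)], d))
    z = linkage(squareform(d), method="average")

    def node_heights(node, acc):
        if not node.is_leaf:
            acc.append(node.height)
            for c in node.children:
                node_heights(c, acc)
        return acc

    mine = sorted(node_heights(tree, []))
    scipys = sorted(z[:, 2] / 2.0)
    assert np.allclose(mine, scipys)


def test_upgma_ultrametric():
    rng = np.random.default_rng(3)
    n = 9
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    tree = upgma(DistanceMatrix([f"t{i}" for i in range(n)], d))

    def depths(node, h0):
        if node.is_leaf:
            return [h0]
        out = []
        for c in node.children:
            assert c.height <= node.height + 1e-12
            out.extend(depths(c, h0 + (node.height - c.height)))
        return out

    ds = depths(tree, 0.0)
    assert max(ds) - min(ds) < 1e-9


def test_upgma_rejects_bad_matrices():
    with pytest.raises(ValueError, match="negative"):
        upgma(DistanceMatrix(["a", "b"], np.array([[0, -0.1], [-0.1, 0]])))


def test_cut_tree_recovers_groups():
    m = DistanceMatrix(
        ["a", "b", "c", "d"],
        np.array([
            [0.0, 0.02, 0.4, 0.4],
            [0.02, 0.0, 0.4, 0.4],
            [0.4, 0.4, 0.0, 0.02],
            [0.4, 0.4, 0.02, 0.0],
        ]),
    )
    groups = cut_tree(upgma(m), 0.05)
    assert sorted(sorted(g) for g in groups) == [["a", "b"], ["c", "d"]]


def test_upgma_separates_rbcl_haplotype_groups(models):
    """rbcL sequences from the two species groups form two clean clades."""
    from polyals import synthdata

    panel = synthdata.sample_rbcl_panel(models, n_per_group=5, seed=2)
    tree = upgma(distance_matrix(panel))
    assert len(tree.children) == 2
    sides = [set(c.leaf_labels()) for c in tree.children]
    reds = {s.id for s in panel if s.meta["group"] == "red"}
    whites = {s.id for s in panel if s.meta["group"] == "white"}
    assert {frozenset(reds), frozenset(whites)} == {frozenset(s) for s in sides}


# ---------------------------------------------------------------------------
# consensus & translation


def test_consensus_examples():
    assert consensus([Sequence("a", "ACGT")]).residues == "ACGT"
    seqs = [Sequence(i, s) for i, s in zip("abc", ["ACGT", "ACGT", "ACTT"])]
    assert consensus(seqs).residues == "ACGT"
    two = [Sequence("a", "AG"), Sequence("b", "AT")]
    assert consensus(two).residues == "AK"


def test_consensus_drops_gap_majority_columns():
    seqs = [Sequence(i, s) for i, s in zip("abc", ["A-G", "A-G", "ACG"])]
    assert consensus(seqs).residues == "AG"


def test_consensus_idempotent_on_gapfree():
    rng = np.random.default_rng(5)
    seqs = [
        Sequence(f"s{i}", "".join("ACGT"[j] for j in rng.integers(0, 4, 50)))
        for i in range(7)
    ]
    c1 = consensus(seqs)
    assert consensus([c1]).residues == c1.residues


def test_consensus_empty_error():
    with pytest.raises(ValueError):
        consensus([])


@pytest.mark.parametrize("codon, aa", [
    ("GCT", "A"), ("AAT", "N"), ("TGG", "W"), ("TTG", "L"),
    ("TAA", "*"), ("GCN", "A"), ("GAN", "X"), ("NNN", "X"),
])
def test_translate_codon(codon, aa):
    assert translate_codon(codon) == aa


def test_translate_frames_and_trailing():
    assert translate("GCTAAT") == "AN"
    assert translate("GGCTAAT", frame=2) == "AN"
    assert translate("GCTAA") == "A"          # trailing partial codon dropped
    with pytest.raises(ValueError):
        translate("AC")


def test_alignment_colmap_roundtrip():
    aln = Alignment([Sequence("a", "AC-GT"), Sequence("b", "ACCGT")])
    cm = aln.colmap("a")
    assert cm == [1, 2, None, 3, 4]
    inv = aln.source_to_column("a")
    for col, src in enumerate(cm, start=1):
        if src is not None:
            assert inv[src] == col
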