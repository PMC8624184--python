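"""Assignment of cloned ALS sequences to homoeologous gene copies.

Allopolyploid *Echinochloa* carries multiple ALS homoeologs — three in
hexaploid *E. crus-galli* (ALS1/ALS2/ALS3) and two in tetraploid
*E. oryzicola* (ALS1/ALS2). Clone libraries (each clone one sequenced
molecule) are clustered by p-distance UPGMA: the number of clusters
recovers the per-species copy number, cluster consensuses anchor the
copy labels, and partial (5'/3') clone libraries are assigned to the
anchors to estimate per-copy sampling proportions.

Clustering follows a hierarchical protocol — per plant, then per
population, then per species, then all together — implemented as
successive re-clustering of cluster consensuses, so that library-scale
noise is absorbed before across-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence as TSequence

from .align import align_or_passthrough, msa_consensus, pairwise_align
from .mutations import ReferenceALS, call_tsr, default_reference
from .seqcore import (
    Sequence,
    TreeNode,
    consensus,
    cut_tree,
    distance_matrix,
    p_distance,
    upgma,
)

#: cloned gene parts: slices into the full-length CDS
PART_SLICES = {
    "full": slice(None),
    "5prime": slice(0, 620),
    "3prime": slice(-1000, None),
}

#: default inter-copy assignment threshold (p-distance): midway between
#: sequencing-error scale (~0.002) and inter-homoeolog divergence (~0.02)
DEFAULT_THRESHOLD = 0.01


@dataclass
class CloneSet:
    """A clone library; every clone carries population/plant/part metadata."""

    clones: list[Sequence]

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError("empty clone set")
        parts = {c.meta.get("part", "full") for c in self.clones}
        if len(parts) != 1:
            raise ValueError(f"clones of mixed part: {sorted(parts)}")

    @property
    def part(self) -> str:
        return self.clones[0].meta.get("part", "full")

    def __len__(self) -> int:
        return len(self.clones)

    def __iter__(self):
        return iter(self.clones)


@dataclass
class ClusterResult:
    clusters: list[list[Sequence]]   # ordered by size descending
    tree: TreeNode                   # joint UPGMA tree over all clones


def _flat_cluster(seqs: list[Sequence], threshold: float) -> list[list[Sequence]]:
    if len(seqs) == 1:
        return [list(seqs)]
    aln = align_or_passthrough(seqs)
    tree = upgma(distance_matrix(aln.rows))
    by_id = {s.id: s for s in seqs}
    groups = cut_tree(tree, threshold / 2.0)
    return [[by_id[i] for i in g] for g in groups]


def cluster_clones(cs: CloneSet, threshold: float = DEFAULT_THRESHOLD,
                   hierarchical: bool = True) -> ClusterResult:
    """Cluster a clone library into putative gene copies.

    The UPGMA tree is cut at height ``threshold/2`` so clusters are groups
    with average divergence at most ``threshold``. With ``hierarchical``
    (the default) clones are first clustered within each plant, cluster
    consensuses are re-clustered within each population, then within each
    species, then all together; cluster membership is tracked through the
    consensuses back to the original clones.
    """
    if len(cs) < 2:
        raise ValueError("need at least 2 clones")

    if not hierarchical:
        clusters = _flat_cluster(list(cs.clones), threshold)
    else:
        # units: (consensus sequence, member clones)
        units: list[tuple[Sequence, list[Sequence]]] = [
            (c, [c]) for c in cs.clones
        ]
        for level, keys in enumerate((
            ("species", "population", "plant"),
            ("species", "population"),
            ("species",),
            (),
        )):
            grouped: dict[tuple, list[tuple[Sequence, list[Sequence]]]] = {}
            for unit in units:
                key = tuple(unit[1][0].meta.get(k, "") for k in keys)
                grouped.setdefault(key, []).append(unit)
            new_units: list[tuple[Sequence, list[Sequence]]] = []
            for key in sorted(grouped):
                members = grouped[key]
                reps = [u[0] for u in members]
                rep_clusters = _flat_cluster(reps, threshold)
                for j, rc in enumerate(rep_clusters):
                    rep_ids = {r.id for r in rc}
                    clones = [c for u in members if u[0].id in rep_ids for c in u[1]]
                    cons = msa_consensus(
                        clones, id=f"L{level}|{'|'.join(key)}|{j}"
                    )
                    cons.meta = dict(clones[0].meta)
                    new_units.append((cons, clones))
            units = new_units
        clusters = [u[1] for u in units]

    clusters.sort(key=lambda cl: (-len(cl), min(c.id for c in cl)))
    aln = align_or_passthrough(list(cs.clones))
    tree = upgma(distance_matrix(aln.rows))
    return ClusterResult(clusters, tree)


@dataclass
class CopyAnchor:
    """A labelled consensus anchoring one homoeologous copy."""

    label: str
    consensus: Sequence
    provenance: list[str] = field(default_factory=list)


def derive_anchors(
    clusters: TSequence[list[Sequence]],
    reference: ReferenceALS | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[CopyAnchor]:
    """Label full-length clone clusters as ALS1/ALS2/ALS3 anchors.

    Labelling rule: ALS1 is the cluster shared by both species groups
    and (when present) carrying the known resistance mutations; ALS3 is
    the cluster containing only red-species clones; ALS2 is the
    remainder. When the signals are absent or conflict, raises
    ``ValueError("anchor labeling ambiguous")`` listing the clusters.
    """
    if not clusters:
        raise ValueError("no clusters to label")
    ref = reference or default_reference()

    species_sets = [
        {c.meta.get("species", "?") for c in cl} for cl in clusters
    ]
    mutated = []
    for i, cl in enumerate(clusters):
        for clone in cl:
            if any(call.flag == "known-resistance" for call in call_tsr(clone, ref)):
                mutated.append(i)
                break
    cross = [i for i, s in enumerate(species_sets) if len(s) > 1]

    def ambiguous(why: str) -> ValueError:
        listing = "; ".join(
            f"cluster{i}(n={len(cl)}, species={sorted(species_sets[i])})"
            for i, cl in enumerate(clusters)
        )
        return ValueError(f"anchor labeling ambiguous: {why} [{listing}]")

    if len(mutated) > 1:
        raise ambiguous("resistance mutations split across clusters")
    if mutated:
        if cross and mutated[0] not in cross:
            raise ambiguous("mutated cluster is not the cross-species cluster")
        als1 = mutated[0]
    elif len(cross) == 1:
        als1 = cross[0]
    else:
        raise ambiguous("no mutation signal and no unique cross-species cluster")

    labels = {als1: "ALS1"}
    rest = [i for i in range(len(clusters)) if i != als1]
    if len(rest) == 1:
        labels[rest[0]] = "ALS2"
    elif len(rest) == 2:
        red_only = [i for i in rest if species_sets[i] == {"red"}]
        if len(red_only) != 1:
            raise ambiguous("cannot separate ALS2 from ALS3 (red-only rule)")
        labels[red_only[0]] = "ALS3"
        labels[next(i for i in rest if i != red_only[0])] = "ALS2"
    elif rest:
        raise ambiguous(f"{len(clusters)} clusters exceed the 3-copy model")

    anchors = []
    for i in sorted(labels, key=lambda i: labels[i]):
        cons = msa_consensus(clusters[i], id=labels[i])
        anchors.append(CopyAnchor(labels[i], cons, [c.id for c in clusters[i]]))

    for a in anchors:
        for b in anchors:
            if a.label < b.label and len(a.consensus) == len(b.consensus):
                if p_distance(a.consensus, b.consensus) <= threshold:
                    raise ValueError(
                        f"anchors {a.label}/{b.label} closer than the "
                        f"assignment threshold {threshold}"
                    )
    return anchors


def trim_anchors(anchors: Iterable[CopyAnchor], part: str) -> list[CopyAnchor]:
    """Trim full-length anchors to a cloned part (5' 620 bp / 3' 1000 bp)."""
    if part not in PART_SLICES:
        raise ValueError(f"unknown part {part!r}")
    sl = PART_SLICES[part]
    return [
        CopyAnchor(
            a.label,
            Sequence(a.consensus.id, a.consensus.residues[sl],
                     {**a.consensus.meta, "part": part}),
            list(a.provenance),
        )
        for a in anchors
    ]


@dataclass
class AssignmentRecord:
    clone_id: str
    population: str
    species: str
    copy: str          # ALS1/ALS2/ALS3 or unassigned(tie)/unassigned(distant)
    distance: float
    margin: float


@dataclass
class CloneAssignment:
    records: list[AssignmentRecord]

    @property
    def assigned(self) -> list[AssignmentRecord]:
        return [r for r in self.records if not r.copy.startswith("unassigned")]

    def proportions(self) -> dict[str, float]:
        """Per-copy fraction over assigned clones."""
        n = len(self.assigned)
        out: dict[str, float] = {}
        for r in self.assigned:
            out[r.copy] = out.get(r.copy, 0) + 1
        return {k: v / n for k, v in sorted(out.items())} if n else {}

    def by_species(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, int]] = {}
        for r in self.assigned:
            out.setdefault(r.species, {}).setdefault(r.copy, 0)
            out[r.species][r.copy] += 1
        return {
            sp: {k: v / sum(c.values()) for k, v in sorted(c.items())}
            for sp, c in sorted(out.items())
        }

    def as_copy_map(self) -> dict[str, str]:
        return {r.clone_id: r.copy for r in self.assigned}


_TIE_EPS = 1e-12


def assign_to_copies(cs: CloneSet, anchors: TSequence[CopyAnchor],
                     threshold: float = DEFAULT_THRESHOLD) -> CloneAssignment:
    """Assign each clone to its nearest anchor by p-distance.

    Clones farther than ``threshold`` from every anchor are flagged
    ``unassigned(distant)``; exact ties between the two nearest anchors
    are flagged ``unassigned(tie)`` rather than force-assigned (chimeric
    PCR clones exist in real libraries).
    """
    if not anchors:
        raise ValueError("empty anchor list")
    records = []
    for clone in cs:
        dists = []
        for anchor in anchors:
            if len(clone) == len(anchor.consensus):
                d = p_distance(clone, anchor.consensus)
            else:
                aln = pairwise_align(clone, anchor.consensus)
                d = p_distance(aln.rows[0], aln.rows[1])
            dists.append((d, anchor.label))
        dists.sort()
        best_d, best_label = dists[0]
        margin = (dists[1][0] - best_d) if len(dists) > 1 else float("inf")
        if len(dists) > 1 and margin < _TIE_EPS:
            copy = "unassigned(tie)"
        elif best_d > threshold:
            copy = "unassigned(distant)"
        else:
            copy = best_label
        records.append(AssignmentRecord(
            clone.id,
            clone.meta.get("population", ""),
            clone.meta.get("species", ""),
            copy, best_d, max(margin, 0.0),
        ))
    return CloneAssignment(records)
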