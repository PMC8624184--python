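"""Target-site-resistance calling at standardized ALS codons.

ALS (acetolactate synthase) resistance positions are reported in the
herbicide-resistance convention of numbering against a reference ALS
protein, so that species-specific indels do not shift the positions.
The watched codons are 122, 197 and 574, with the known resistance
alleles Ala122{Val,Thr,Asn}, Pro197{Ser,Leu} and Trp574Leu.

Queries (cloned cDNA sequences, full-length or partial) are mapped onto
the reference by translating in the frame without internal stops and
globally aligning the protein to the reference protein; calls are then
made codon-by-codon at the watched positions the query covers. Clones
are single molecules, so each clone yields one haplotype call; a
plant's genotype is the multiset of its clones' calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import Align as _bioalign

from .seqcore import Sequence, translate, translate_codon

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "X": "Xaa", "*": "Ter",
}

#: known target-site-resistance alleles: standardized position -> amino acids
KNOWN_RESISTANCE_ALLELES: dict[int, frozenset[str]] = {
    122: frozenset("VTN"),   # Ala122 -> Val / Thr / Asn
    197: frozenset("SL"),    # Pro197 -> Ser / Leu
    574: frozenset("L"),     # Trp574 -> Leu
}

WATCH_POSITIONS = (122, 197, 574)


@dataclass
class ReferenceALS:
    """Numbering reference: a CDS whose protein defines codon coordinates."""

    name: str
    cds: str
    watch_positions: tuple[int, ...] = WATCH_POSITIONS
    allele_table: Mapping[int, frozenset[str]] = field(
        default_factory=lambda: dict(KNOWN_RESISTANCE_ALLELES)
    )

    def __post_init__(self) -> None:
        if len(self.cds) % 3:
            raise ValueError("reference CDS length not a multiple of 3")
        self._protein = translate(self.cds)
        if "*" in self._protein[:-1]:
            raise ValueError("reference CDS has internal stop codons")
        n = len(self._protein)
        if any(not 1 <= p <= n for p in self.watch_positions):
            raise ValueError("watch position outside reference protein")
        for pos, aas in self.allele_table.items():
            if not set(aas) <= set(AA3) - {"X", "*"}:
                raise ValueError(f"invalid amino acids in allele table at {pos}")

    @property
    def protein(self) -> str:
        return self._protein

    def codon(self, position: int) -> str:
        return self.cds[3 * (position - 1):3 * position]


def default_reference() -> ReferenceALS:
    """The package's shipped ALS numbering reference.

    A synthetic stand-in: a deterministic 670-codon CDS carrying the
    field-standard wild-type residues Ala122, Pro197 and Trp574 at the
    standardized coordinates (the real Arabidopsis reference protein can
    be substituted by constructing :class:`ReferenceALS` directly).
    """
    from . import synthdata  # deferred; synthdata builds on this module's consumers

    return ReferenceALS("synthetic-ALS-reference", synthdata.reference_cds())


def _protein_aligner() -> _bioalign.PairwiseAligner:
    a = _bioalign.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -2.0
    a.extend_gap_score = -2.0
    a.end_insertion_score = 0.0
    a.end_deletion_score = 0.0
    a.wildcard = "X"
    return a


_PROT_ALIGNER = _protein_aligner()


@dataclass
class _QueryMap:
    frame: int
    #: query codon index (1-based, within frame) -> standardized position
    mapping: dict[int, int]
    identity: float

    @property
    def inverse(self) -> dict[int, int]:
        return {v: k for k, v in self.mapping.items()}


def _map_to_reference(query: Sequence, ref: ReferenceALS) -> _QueryMap:
    best: _QueryMap | None = None
    best_score = None
    for frame in (1, 2, 3):
        if len(query) - frame + 1 < 3:
            continue
        # stray stops (e.g. PCR-error artefacts) are treated as X rather
        # than disqualifying the frame; the true frame wins on score
        prot = translate(query, frame).replace("*", "X")
        aln = _PROT_ALIGNER.align(ref.protein, prot)[0]
        gref, gq = str(aln[0]), str(aln[1])
        mapping: dict[int, int] = {}
        matches = compared = 0
        rpos = qpos = 0
        for cr, cq in zip(gref, gq):
            if cr != "-":
                rpos += 1
            if cq != "-":
                qpos += 1
            if cr != "-" and cq != "-":
                mapping[qpos] = rpos
                compared += 1
                if cr == cq:
                    matches += 1
        if not compared:
            continue
        identity = matches / compared
        if best_score is None or aln.score > best_score:
            best_score = aln.score
            best = _QueryMap(frame, mapping, identity)
    if best is None or best.identity < 0.5:
        raise ValueError("query does not align to ALS reference")
    return best


def standardize_numbering(query: Sequence, ref: ReferenceALS | None = None) -> dict[int, int]:
    """Map query codon indices (1-based, in the best reading frame) to
    standardized reference positions. Positions falling in query gaps are
    absent from the map."""
    ref = ref or default_reference()
    return dict(_map_to_reference(query, ref).mapping)


@dataclass
class CodonCall:
    """One watched codon observed in one clone."""

    position: int
    ref_codon: str
    ref_aa: str
    obs_codon: str
    obs_aa: str
    edits: str          # e.g. "GC→AA" (concatenated changed bases, 5'->3')
    flag: str           # wild-type | synonymous | known-resistance |
                        # novel-nonsynonymous | ambiguous

    @property
    def aa_change(self) -> str:
        if self.flag in ("wild-type", "synonymous"):
            return f"{AA3[self.ref_aa]}{self.position}{AA3[self.ref_aa]}"
        return f"{AA3[self.ref_aa]}{self.position}{AA3[self.obs_aa]}"


def _edit_string(ref_codon: str, obs_codon: str) -> str:
    changed = [(r, o) for r, o in zip(ref_codon, obs_codon) if r != o]
    if not changed:
        return ""
    return "".join(r for r, _ in changed) + "→" + "".join(o for _, o in changed)


def call_tsr(query: Sequence, ref: ReferenceALS | None = None) -> list[CodonCall]:
    """Call target-site-resistance codons on one clone.

    Emits one :class:`CodonCall` per watched position the query covers.
    Codons containing ambiguity codes are flagged "ambiguous" and never
    called resistant.
    """
    ref = ref or default_reference()
    qmap = _map_to_reference(query, ref)
    inverse = qmap.inverse
    coding = query.residues[qmap.frame - 1:]
    calls: list[CodonCall] = []
    for pos in sorted(ref.watch_positions):
        if pos not in inverse:
            continue
        qidx = inverse[pos]
        obs_codon = coding[3 * (qidx - 1):3 * qidx]
        ref_codon = ref.codon(pos)
        ref_aa = translate_codon(ref_codon)
        if any(c not in "ACGT" for c in obs_codon):
            flag, obs_aa = "ambiguous", "X"
        else:
            obs_aa = translate_codon(obs_codon)
            if obs_codon == ref_codon:
                flag = "wild-type"
            elif obs_aa == ref_aa:
                flag = "synonymous"
            elif obs_aa in ref.allele_table.get(pos, frozenset()):
                flag = "known-resistance"
            else:
                flag = "novel-nonsynonymous"
        calls.append(CodonCall(
            pos, ref_codon, ref_aa, obs_codon, obs_aa,
            _edit_string(ref_codon, obs_codon), flag,
        ))
    return calls


RESISTANCE_FLAGS = ("known-resistance", "novel-nonsynonymous")


def mutation_by_copy(
    copy_map: Mapping[str, str],
    calls: Mapping[str, Iterable[CodonCall]],
    populations: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Cross-tabulate resistance calls by gene-copy label (and population).

    ``copy_map``: clone id -> assigned copy label. Returns the table plus
    warnings for any resistance call found outside ALS1 — violations of
    the single-copy expectation are flagged, never suppressed.
    """
    rows = []
    warnings: list[str] = []
    for clone_id, clone_calls in calls.items():
        copy = copy_map.get(clone_id)
        if copy is None:
            continue
        pop = (populations or {}).get(clone_id, "")
        for call in clone_calls:
            if call.flag not in RESISTANCE_FLAGS:
                continue
            rows.append({
                "copy": copy, "population": pop, "position": call.position,
                "aa_change": call.aa_change, "flag": call.flag,
            })
            if copy != "ALS1":
                warnings.append(
                    f"resistance call outside ALS1: clone {clone_id} "
                    f"({call.aa_change}) assigned to {copy}"
                )
    if not rows:
        return (
            pd.DataFrame(columns=["copy", "population", "position",
                                  "aa_change", "flag", "n_clones"]),
            warnings,
        )
    df = (
        pd.DataFrame(rows)
        .groupby(["copy", "population", "position", "aa_change", "flag"])
        .size()
        .reset_index(name="n_clones")
        .sort_values(["copy", "population", "position"])
        .reset_index(drop=True)
    )
    return df, warnings
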