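"""Seeded generators for every input the pipeline consumes.

The generators encode the study system: two *Echinochloa* species
groups — a "red" allohexaploid (*E. crus-galli*-like, three ALS
homoeologs, rbcL without the diagnostic TasI site) and a "white"
allotetraploid (*E. oryzicola*-like, two ALS homoeologs, rbcL with the
TasI site inside the CAPS amplicon) — plus clone libraries, rbcL
barcode panels and qPCR Ct tables with known ground truth.

Template backbones are random sequences constrained to contain the
published primer binding sequences verbatim at consistent coordinates,
so the printed primer strings work as-is on synthetic data:

* CAPS-rbcL primers bracket a 221-bp rbcL amplicon whose TasI digest in
  the white haplotype yields the 134+87 band pair;
* the allele-specific ALS primers (F1_590Tm/F2_590Cm, R1_621/R2_621)
  bind around the copy-diagnostic SNPs at standardized codons 590 and
  621, with a FokI site only in ALS1 cutting a 105-bp band.

Resistance mutations (Ala122Asn for red, Trp574Leu for white) live only
in ALS1-derived clones of resistant populations. All randomness flows
from numpy's default generator under explicit seeds; identical seeds
give byte-identical output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence as TSequence

import numpy as np
import pandas as pd

from . import barcoding
from .barcoding import CapsMarker, FokI, PrimerPair, TasI, digest, in_silico_pcr
from .homoeolog import PART_SLICES, CloneSet
from .seqcore import _CODON_TABLE, Sequence, revcomp, translate

# ---------------------------------------------------------------------------
# Published primer sequences (study inputs)

CAPS_RBCL_F = "CAACTGTTTGGACTGATGGAC"
CAPS_RBCL_R = "CGTAGATCCTCCAAACGTAGAGC"
RBCL_F1 = "GCAGCATTCCGAGTAACTCCTCA"
RBCL_R2 = "TTGGTGGAGGAACTTTAGGACATC"

#: allele-specific qPCR primers; the forward pair carries a deliberate
#: extra mismatch at the 3rd base from the 3' end
F1_590Tm = "GAGCACACACATACTTGGGGCAT"     # forward, specific for ALS1
F2_590Cm = "AGCACACACATACTTGGGGCAC"      # forward, specific for ALS2-3
R1_621 = "GAGCATCTTCTTAATTGCTGCACGG"     # reverse, specific for ALS1
R2_621 = "GAGCATCTTCTTGATTGCTGCACGT"     # reverse, specific for ALS2-3

#: cloning primers (metadata only; cloning itself is emulated by slicing)
CLONING_PRIMERS = {
    "ECH_F": "TCGCAAGGGCGCGGACATCCTCGT",
    "5RACE-1": "GCCGCGACTCACCAACAAGA",
    "ECH_5F": "AGGTCACSCGCTCCATCACCA",
    "ECH-3R": "TCCTGCCATCACCHTCCAKGA",
}

# ---------------------------------------------------------------------------
# Synthetic ALS reference geometry (all coordinates 1-based on the CDS)

_REFERENCE_SEED = 20211841
N_CODONS = 670
CDS_LEN = N_CODONS * 3

#: watched wild-type codons at the standardized resistance positions
_WATCH_CODONS = {122: "GCT", 197: "CCA", 574: "TGG"}

# allele-specific amplicon geometry: the forward primers end (3') on the
# SNP in codon 590 (CDS nt 1768) and the reverse primers end on the SNP
# in codon 621 (CDS nt 1862); the F2+R2 product is exactly 140 bp
_FWD_SNP = 1768
_FWD_WIN_START = 1746          # 5' end of the 23-nt F1 window
_REV_WIN_START = 1862
_REV_WIN_END = 1886            # F1 amplicon: 1746..1886 (141 bp)
_AMPLICON_SPAN = (_FWD_WIN_START, _REV_WIN_END)

# ALS2-3 ("ancestral") states of the constrained windows
_BASE_FWD_WINDOW = "GAGCACACACATACTTGGGG" + "A" + "A" + "C"   # 1746..1768
_ALS1_FWD_WINDOW = _BASE_FWD_WINDOW[:-1] + "T"
_BASE_REV_WINDOW = revcomp(R2_621)                            # 1862..1886
_ALS1_REV_WINDOW = revcomp(R1_621)
# FokI: ALS1 carries GGATG at 1837..1841, cutting the top strand before
# 1851 -> 105 + 36 bp fragments of the 141-bp F1+R1 product
_FOKI_AT = 1837
_BASE_FOKI_WINDOW = "GAATG"
_ALS1_FOKI_WINDOW = "GGATG"

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(c for c in _CODON_TABLE if c not in _STOPS)

#: CDS positions whose bases are dictated by the primer/SNP/enzyme design
_FORCED_POSITIONS = (
    frozenset(range(_FWD_WIN_START, 1771))          # F window + codon 590
    | frozenset({1861})
    | frozenset(range(_REV_WIN_START, _REV_WIN_END + 1))
    | frozenset(range(_FOKI_AT, _FOKI_AT + 6))   # +1: keeps codon 614 sense
    | frozenset(p for pos in _WATCH_CODONS for p in range(3 * pos - 2, 3 * pos + 1))
)

#: CDS positions (1-based) never touched by random divergence/error-free
#: template construction: the full allele-specific amplicon span plus the
#: watched resistance codons
PROTECTED_POSITIONS = frozenset(
    range(_AMPLICON_SPAN[0], _AMPLICON_SPAN[1] + 1)
) | frozenset(
    p for pos in _WATCH_CODONS for p in range(3 * pos - 2, 3 * pos + 1)
)


def _set_span(seq: list[str], start: int, text: str) -> None:
    seq[start - 1:start - 1 + len(text)] = list(text)


def _codon_of(seq: list[str], idx: int) -> str:
    return "".join(seq[3 * idx - 3:3 * idx])


@lru_cache(maxsize=1)
def reference_cds() -> str:
    """The synthetic ALS reference CDS (670 codons, deterministic).

    Carries the field-standard wild-type states Ala122 (GCT), Pro197
    (CCA) and Trp574 (TGG), the ALS2-3 state of the allele-specific
    primer windows, and no FokI site inside the amplicon span. This is a
    synthetic stand-in for the real reference ALS coding sequence.
    """
    rng = np.random.default_rng(_REFERENCE_SEED)
    seq = list("".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), N_CODONS)
    ))
    for pos, codon in _WATCH_CODONS.items():
        _set_span(seq, 3 * pos - 2, codon)
    _set_span(seq, _FWD_WIN_START, _BASE_FWD_WINDOW)
    _set_span(seq, 1769, "CT")            # completes codon 590 (CCT, Pro)
    _set_span(seq, 1861, "T")             # codon 621 first base
    _set_span(seq, _REV_WIN_START, _BASE_REV_WINDOW)
    _set_span(seq, _FOKI_AT, _BASE_FOKI_WINDOW)
    _set_span(seq, _FOKI_AT + 5, "C")     # codon 614 = TGC whatever the site state

    # repair any stop codon whose bases are at least partly free
    for idx in range(1, N_CODONS + 1):
        if _codon_of(seq, idx) in _STOPS:
            start = 3 * idx - 2
            free = [p for p in range(start, start + 3)
                    if p not in PROTECTED_POSITIONS
                    and not any(3 * w - 2 <= p <= 3 * w for w in _WATCH_CODONS)]
            if not free:
                raise AssertionError(f"stop codon in constrained region {idx}")
            for base in "CG":
                seq[free[0] - 1] = base
                if _codon_of(seq, idx) not in _STOPS:
                    break

    # scrub stray FokI sites (either strand) from the amplicon span,
    # flipping only non-forced bases and never creating stops
    span_lo, span_hi = _AMPLICON_SPAN
    for _ in range(100):
        s = "".join(seq)
        hits = [
            i for pat in ("GGATG", "CATCC")
            for i in range(span_lo - 1, span_hi - 4)
            if s[i:i + 5] == pat
        ]
        if not hits:
            break
        i = hits[0]
        fixed = False
        for p in range(i + 1, i + 6):               # 1-based site positions
            if p in _FORCED_POSITIONS:
                continue
            for base in "ACGT":
                if base == seq[p - 1]:
                    continue
                old = seq[p - 1]
                seq[p - 1] = base
                window = "".join(seq[i:i + 5])
                if (_codon_of(seq, (p + 2) // 3) not in _STOPS
                        and window not in ("GGATG", "CATCC")):
                    fixed = True
                    break
                seq[p - 1] = old
            if fixed:
                break
        if not fixed:
            raise AssertionError("cannot scrub FokI site from amplicon span")

    cds = "".join(seq)
    span = cds[span_lo - 1:span_hi]
    assert "GGATG" not in span and "CATCC" not in span
    prot = translate(cds)
    assert "*" not in prot, "reference CDS has internal stops"
    assert prot[121] == "A" and prot[196] == "P" and prot[573] == "W"
    return cds


def _apply_als1_states(cds: str) -> str:
    seq = list(cds)
    _set_span(seq, _FWD_WIN_START, _ALS1_FWD_WINDOW)
    _set_span(seq, _REV_WIN_START, _ALS1_REV_WINDOW)
    _set_span(seq, _FOKI_AT, _ALS1_FOKI_WINDOW)
    return "".join(seq)


def _diverge(cds: str, rng: np.random.Generator, rate: float,
             protected: frozenset[int] = PROTECTED_POSITIONS) -> str:
    """Random substitutions at unprotected positions, never creating stops."""
    seq = list(cds)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        pos = i + 1
        if pos in protected:
            continue
        choices = [b for b in "ACGT" if b != seq[i]]
        new = choices[rng.integers(0, 3)]
        old = seq[i]
        seq[i] = new
        if _codon_of(seq, (pos + 2) // 3) in _STOPS:
            seq[i] = old
    return "".join(seq)


# ---------------------------------------------------------------------------
# rbcL geometry

_RBCL_LEN = 600
_RBCL_FWD_AT = 100                 # CAPS_RBCL_F at 100..120
_RBCL_REV_AT = 298                 # revcomp(CAPS_RBCL_R) at 298..320
_RBCL_TASI_AT = 234                # white AATT -> cut before amplicon pos 135
_RBCL_AMPLICON = (100, 320)        # 221 bp


def _build_rbcl(rng: np.random.Generator) -> tuple[str, str]:
    """(red haplotype, white haplotype); white digests 134+87, red is uncut."""
    bases = "ACGT"
    seq = list("".join(bases[i] for i in rng.integers(0, 4, _RBCL_LEN)))
    _set_span(seq, _RBCL_FWD_AT, CAPS_RBCL_F)
    _set_span(seq, _RBCL_REV_AT, revcomp(CAPS_RBCL_R))

    protected = set(range(_RBCL_FWD_AT, _RBCL_FWD_AT + len(CAPS_RBCL_F)))
    protected |= set(range(_RBCL_REV_AT, _RBCL_REV_AT + len(CAPS_RBCL_R)))
    protected |= set(range(_RBCL_TASI_AT, _RBCL_TASI_AT + 4))

    # scrub stray TasI sites from the amplicon so the designed site is the
    # only polymorphism that matters
    lo, hi = _RBCL_AMPLICON
    while True:
        s = "".join(seq)
        i = s.find("AATT", lo - 1, hi)
        if i == -1:
            break
        free = [p for p in range(i + 1, i + 5) if p not in protected]
        if not free:
            raise AssertionError("TasI site overlaps constrained window")
        seq[free[0] - 1] = "C"

    red = list(seq)
    white = list(seq)
    _set_span(red, _RBCL_TASI_AT, "ACTT")
    _set_span(white, _RBCL_TASI_AT, "AATT")

    # a handful of additional group-diagnostic substitutions outside the
    # constrained windows, so the two haplotype groups split cleanly in
    # UPGMA trees even without the enzyme site
    free_positions = [p for p in range(1, _RBCL_LEN + 1) if p not in protected]
    snp_sites = rng.choice(len(free_positions), size=6, replace=False)
    for k in sorted(snp_sites):
        p = free_positions[k]
        cur = white[p - 1]
        for base in [b for b in bases if b != cur]:
            white[p - 1] = base
            ctx = "".join(white[max(0, p - 5):p + 4])
            if "AATT" not in ctx:
                break
            white[p - 1] = cur
    return "".join(red), "".join(white)


# ---------------------------------------------------------------------------
# Species models


@dataclass
class SpeciesModel:
    """Templates for one species group: an rbcL haplotype plus ALS copies."""

    name: str
    species: str                    # "red" | "white"
    rbcl: Sequence
    als: dict[str, Sequence]        # copy label -> full-length CDS template


#: resistance mutations: name -> (standardized codon, replacement codon)
MUTATION_SPECS = {
    "Ala122Asn": (122, "AAT"),      # GCT -> AAT
    "Trp574Leu": (574, "TTG"),      # TGG -> TTG
}

#: inter-copy divergence (p-distance scale) between homoeolog templates
DEFAULT_INTER_COPY_DIVERGENCE = 0.02
#: cross-species divergence of the shared homoeologs ALS1/ALS2
CROSS_SPECIES_DIVERGENCE = 0.002


def make_species_models(
    seed: int = 0,
    inter_copy_divergence: float = DEFAULT_INTER_COPY_DIVERGENCE,
) -> tuple[SpeciesModel, SpeciesModel]:
    """Deterministic (red hexaploid, white tetraploid) template models.

    The red model carries three ALS copies (ALS1/ALS2/ALS3), the white
    model the two shared copies (ALS1/ALS2) at small cross-species
    divergence. Construction is verified against the module's own
    invariants (CAPS digest patterns, FokI specificity, open reading
    frames) before returning.
    """
    rng = np.random.default_rng(seed)
    base = reference_cds()
    half = inter_copy_divergence / 2.0

    als1 = _diverge(_apply_als1_states(base), rng, half)
    anc = _diverge(base, rng, half)
    als2 = _diverge(anc, rng, half)
    als3 = _diverge(anc, rng, half)
    als1_w = _diverge(als1, rng, CROSS_SPECIES_DIVERGENCE)
    als2_w = _diverge(als2, rng, CROSS_SPECIES_DIVERGENCE)

    rbcl_red, rbcl_white = _build_rbcl(rng)

    red = SpeciesModel(
        "red-hexaploid", "red",
        Sequence("rbcL-red", rbcl_red, {"group": "red"}),
        {
            "ALS1": Sequence("ALS1-red", als1, {"species": "red", "copy": "ALS1"}),
            "ALS2": Sequence("ALS2-red", als2, {"species": "red", "copy": "ALS2"}),
            "ALS3": Sequence("ALS3-red", als3, {"species": "red", "copy": "ALS3"}),
        },
    )
    white = SpeciesModel(
        "white-tetraploid", "white",
        Sequence("rbcL-white", rbcl_white, {"group": "white"}),
        {
            "ALS1": Sequence("ALS1-white", als1_w, {"species": "white", "copy": "ALS1"}),
            "ALS2": Sequence("ALS2-white", als2_w, {"species": "white", "copy": "ALS2"}),
        },
    )
    _check_invariants(red, white)
    return red, white


def _check_invariants(red: SpeciesModel, white: SpeciesModel) -> None:
    caps = PrimerPair("CAPS-rbcL", CAPS_RBCL_F, CAPS_RBCL_R)
    red_frags = digest(in_silico_pcr(red.rbcl, caps), TasI)
    white_frags = digest(in_silico_pcr(white.rbcl, caps), TasI)
    assert red_frags == [221], red_frags
    assert white_frags == [87, 134], white_frags

    f1r1 = PrimerPair("F1R1", F1_590Tm, R1_621)
    f2r2 = PrimerPair("F2R2", F2_590Cm, R2_621)
    for model in (red, white):
        for label, tmpl in model.als.items():
            assert "*" not in translate(tmpl.residues), f"stop in {tmpl.id}"
            if label == "ALS1":
                frags = digest(in_silico_pcr(tmpl, f1r1, max_mismatch=1), FokI)
                assert frags == [36, 105], (tmpl.id, frags)
            else:
                frags = digest(in_silico_pcr(tmpl, f2r2, max_mismatch=1), FokI)
                assert frags == [140], (tmpl.id, frags)


def caps_rbcl_marker(models: TSequence[SpeciesModel]) -> CapsMarker:
    """The CAPS-rbcL marker with per-group expected band patterns."""
    primers = PrimerPair("CAPS-rbcL", CAPS_RBCL_F, CAPS_RBCL_R)
    patterns = {
        m.species: tuple(digest(in_silico_pcr(m.rbcl, primers), TasI))
        for m in models
    }
    return CapsMarker(primers, TasI, patterns)


# ---------------------------------------------------------------------------
# Sampling


@dataclass(frozen=True)
class PopulationSpec:
    id: str
    species: str                  # "red" | "white"
    resistant: bool = False
    mutation: str | None = None   # key into MUTATION_SPECS

    def __post_init__(self) -> None:
        if self.resistant and self.mutation not in MUTATION_SPECS:
            raise ValueError(f"{self.id}: resistant population needs a mutation")


#: the study's populations: S = susceptible, R = resistant
STUDY_POPULATIONS: tuple[PopulationSpec, ...] = (
    PopulationSpec("16S", "red"),
    PopulationSpec("95R", "red", True, "Ala122Asn"),
    PopulationSpec("100R", "red", True, "Ala122Asn"),
    PopulationSpec("161S", "white"),
    PopulationSpec("44R", "white", True, "Trp574Leu"),
    PopulationSpec("45R", "white", True, "Trp574Leu"),
    PopulationSpec("46R", "white", True, "Trp574Leu"),
)

#: per-copy sampling proportions reported for the 138-clone 3' library
STUDY_PROPORTIONS = {"ALS1": 0.55, "ALS2": 0.30, "ALS3": 0.15}


@dataclass
class GeneratorConfig:
    """Knobs of the clone-library sampler; defaults are the study conditions."""

    seed: int = 0
    n_clones: int = 60
    proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(STUDY_PROPORTIONS)
    )
    error_rate: float = 0.002      # per-base substitution rate (PCR+sequencing)
    indel_rate: float = 0.0
    part: str = "3prime"
    populations: tuple[PopulationSpec, ...] = STUDY_POPULATIONS

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error rate outside [0, 0.05]")
        if self.part not in PART_SLICES:
            raise ValueError(f"unknown part {self.part!r}")


def _mutate_codon(cds: str, position: int, codon: str) -> str:
    return cds[:3 * position - 3] + codon + cds[3 * position:]


def _apply_errors(residues: str, rng: np.random.Generator,
                  sub_rate: float, indel_rate: float) -> str:
    seq = list(residues)
    if sub_rate > 0:
        for i in np.nonzero(rng.random(len(seq)) < sub_rate)[0]:
            seq[i] = [b for b in "ACGT" if b != seq[i]][rng.integers(0, 3)]
    if indel_rate > 0:
        out: list[str] = []
        for ch in seq:
            u = rng.random()
            if u < indel_rate / 2:
                continue                      # deletion
            out.append(ch)
            if indel_rate / 2 <= u < indel_rate:
                out.append("ACGT"[rng.integers(0, 4)])  # insertion
        seq = out
    return "".join(seq)


def sample_clone_library(
    models: SpeciesModel | TSequence[SpeciesModel] | Mapping[str, SpeciesModel],
    config: GeneratorConfig,
) -> CloneSet:
    """Draw a clone library with known copy-of-origin truth labels.

    Each clone: a copy is drawn from the configured proportions
    (renormalised over the copies available in the supplied species), a
    compatible population and plant are drawn, the configured gene part
    is sliced out, resistant populations receive their mutation in every
    ALS1-derived clone, and i.i.d. per-base errors are applied. Truth
    labels (``true_copy``, ``mutation``) are kept in clone metadata.
    """
    if isinstance(models, SpeciesModel):
        models = [models]
    if isinstance(models, Mapping):
        models = list(models.values())
    by_species = {m.species: m for m in models}
    pops = [p for p in config.populations if p.species in by_species]
    if not pops:
        raise ValueError("no populations compatible with the supplied models")

    available = sorted({c for m in by_species.values() for c in m.als})
    props = {c: config.proportions.get(c, 0.0) for c in available}
    total = sum(props.values())
    if total <= 0:
        raise ValueError("no probability mass on available copies")
    labels = sorted(props)
    weights = np.array([props[c] / total for c in labels])

    rng = np.random.default_rng(config.seed)
    sl = PART_SLICES[config.part]
    clones = []
    for i in range(config.n_clones):
        copy = labels[rng.choice(len(labels), p=weights)]
        candidates = [p for p in pops if copy in by_species[p.species].als]
        pop = candidates[rng.integers(0, len(candidates))]
        plant = str(1 + rng.integers(0, 2))
        cds = by_species[pop.species].als[copy].residues
        mutation = ""
        if pop.resistant and copy == "ALS1":
            position, codon = MUTATION_SPECS[pop.mutation]
            cds = _mutate_codon(cds, position, codon)
            mutation = pop.mutation
        part_seq = cds[sl]
        part_seq = _apply_errors(part_seq, rng, config.error_rate, config.indel_rate)
        clones.append(Sequence(
            f"{pop.id}-{plant}-{config.part}-c{i:03d}",
            part_seq,
            {
                "population": pop.id, "plant": plant, "species": pop.species,
                "part": config.part, "true_copy": copy, "mutation": mutation,
            },
        ))
    return CloneSet(clones)


def sample_rbcl_panel(
    models: TSequence[SpeciesModel],
    n_per_group: int = 21,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[Sequence]:
    """An rbcL barcode validation panel with group truth labels."""
    rng = np.random.default_rng(seed)
    panel = []
    for m in models:
        for i in range(n_per_group):
            residues = _apply_errors(m.rbcl.residues, rng, error_rate, 0.0)
            panel.append(Sequence(
                f"{m.species}-{i + 1:02d}", residues, {"group": m.species},
            ))
    return panel


# ---------------------------------------------------------------------------
# qPCR simulation


#: reference-gene Ct baselines within the study's observed ranges
REFERENCE_BASELINES = {"Rubisco": 22.2, "18S": 21.9}
#: the full candidate screen (gene -> (mean Ct, Ct sd across samples))
REFERENCE_SCREEN_PANEL = {
    "Rubisco": (22.0, 0.25), "18S": (21.8, 0.25),
    "Actin": (26.0, 0.8), "CAP": (29.0, 1.2), "Tubuline": (27.0, 0.9),
    "GAPDH": (25.0, 0.7), "EF1": (26.5, 0.6), "Ubiquitine": (27.5, 1.0),
}
_REFERENCE_RANGES = {"Rubisco": (19.6, 24.9), "18S": (20.4, 23.7)}

QPCR_TARGETS = ("ALS1", "ALS2-3")
ALS_BASE_CT = 28.0


def simulate_qpcr(
    populations: TSequence[PopulationSpec] = STUDY_POPULATIONS,
    seed: int = 0,
    *,
    als1_delta_ct: float = 1.0,
    baseline_untreated_pops: tuple[str, ...] = ("16S", "161S"),
    noise_sd: float = 0.3,
    n_bio: int = 3,
    n_tech: int = 3,
    als_base_ct: float = ALS_BASE_CT,
    ref_baselines: Mapping[str, float] = REFERENCE_BASELINES,
) -> pd.DataFrame:
    """Simulate a replicated Ct table for the copy-expression experiment.

    ALS1 is more expressed than ALS2-3 by ``als1_delta_ct`` cycles
    (Ct lower by that amount) in every sample except the untreated
    samples of the calibrator-eligible baseline populations, which sit
    at the common base level — so relative quantification against an
    untreated susceptible calibrator recovers a fold-change of
    ``2**als1_delta_ct`` for ALS1. Three technical by three biological
    replicates per cell by default.
    """
    rng = np.random.default_rng(seed)
    rows = []
    targets = list(QPCR_TARGETS) + sorted(ref_baselines)
    for pop in populations:
        for treatment in ("untreated", "treated"):
            for target in targets:
                if target in ref_baselines:
                    base = ref_baselines[target]
                else:
                    base = als_base_ct
                    if target == "ALS1" and not (
                        treatment == "untreated"
                        and pop.id in baseline_untreated_pops
                    ):
                        base -= als1_delta_ct
                for bio in range(1, n_bio + 1):
                    for tech in range(1, n_tech + 1):
                        ct = base + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                        rows.append({
                            "population": pop.id, "treatment": treatment,
                            "bio_rep": bio, "target": target,
                            "tech_rep": tech, "ct": round(float(ct), 4),
                        })
    return pd.DataFrame(rows)


def printed_allele_designs():
    """The published allele-specific primer quartet wrapped as designs.

    F1_590Tm+R1_621 target ALS1; F2_590Cm+R2_621 target ALS2-3. Useful
    for validating the synthetic templates against the printed primers
    (FokI cuts only the ALS1-class product).
    """
    from .primers import AllelePrimerDesign, DiagnosticSNP

    snp_f = DiagnosticSNP(_FWD_SNP, 590, "T", "C")
    snp_r = DiagnosticSNP(_REV_WIN_START, 621, "C", "A")
    d1 = AllelePrimerDesign(
        "ALS1", frozenset({"ALS1"}),
        PrimerPair("F1_590Tm+R1_621", F1_590Tm, R1_621),
        snp_f, snp_r, 1766, "C", (_FWD_WIN_START, _REV_WIN_END),
    )
    d23 = AllelePrimerDesign(
        "ALS2-3", frozenset({"ALS2", "ALS3"}),
        PrimerPair("F2_590Cm+R2_621", F2_590Cm, R2_621),
        snp_f, snp_r, 1766, "C", (_FWD_WIN_START + 1, _REV_WIN_END),
    )
    return d1, d23


def simulate_reference_screen(seed: int = 0, n_samples: int = 12) -> pd.DataFrame:
    """Ct draws for the eight candidate reference genes over a sample panel.

    Rubisco and 18S are the most expressed (lowest Ct) and most stable
    candidates; their draws are truncated to the study's printed ranges.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, (mean, sd) in REFERENCE_SCREEN_PANEL.items():
        for i in range(n_samples):
            ct = float(rng.normal(mean, sd))
            lo, hi = _REFERENCE_RANGES.get(gene, (0.0, float("inf")))
            while not lo <= ct <= hi:
                ct = float(rng.normal(mean, sd))
            rows.append({
                "population": "161S" if i % 2 == 0 else "45R",
                "treatment": "untreated",
                "bio_rep": i + 1, "target": gene, "tech_rep": 1,
                "ct": round(ct, 4),
            })
    return pd.DataFrame(rows)
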