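"""Allele-specific qPCR primer design for homoeolog discrimination.

The design follows ARMS-PCR practice: a primer pair whose 3'-terminal
bases sit on copy-diagnostic SNPs (forward on one SNP, reverse on a
second, downstream SNP), so that Taq extension fails on the wrong
allele class; the forward primer additionally carries a deliberate
mismatch at the 3rd base from its 3' end, mismatching every template,
to sharpen discrimination. Specificity is verified in silico by
restriction digestion of the predicted amplicons (FokI cuts only the
ALS1-class product in this study system).

No thermodynamic scoring is attempted: candidate windows are filtered
for cross-copy conservation and length only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence as TSequence

import pandas as pd

from .barcoding import (
    AmplificationError,
    FokI,
    MIN_VISIBLE_FRAGMENT,
    PrimerPair,
    RestrictionEnzyme,
    TasI,
    _occurrences,
    digest,
    in_silico_pcr,
)
from .seqcore import Alignment, Sequence, revcomp


@dataclass(frozen=True)
class DiagnosticSNP:
    """A site separating the target copy set from all other copies."""

    nt_pos: int        # 1-based position on the (gap-free) copy alignment/CDS
    codon_pos: int     # standardized codon coordinate containing the SNP
    target_base: str
    other_base: str


def _class_label(copies: Iterable[str]) -> str:
    """Compact class name: {ALS2, ALS3} -> "ALS2-3", {ALS1} -> "ALS1"."""
    copies = sorted(copies)
    if len(copies) > 1 and all(c.startswith("ALS") for c in copies):
        return "ALS" + "-".join(c[3:] for c in copies)
    return "+".join(copies)


def diagnostic_snps(copy_alignment: Alignment, target: set[str]) -> list[DiagnosticSNP]:
    """Sites where all target copies share one base and all non-target
    copies share a different base (unambiguous, gap-free columns only).

    Rows of ``copy_alignment`` are copy consensus templates identified by
    copy label. Positions are reported both as nucleotide coordinates and
    as the standardized codon coordinate containing the nucleotide.
    """
    labels = {r.id for r in copy_alignment.rows}
    if not target <= labels:
        raise ValueError(f"target copies {sorted(target - labels)} not in alignment")
    others = labels - target
    out: list[DiagnosticSNP] = []
    for col in range(copy_alignment.length):
        t_bases = {r.residues[col] for r in copy_alignment.rows if r.id in target}
        o_bases = {r.residues[col] for r in copy_alignment.rows if r.id in others}
        if len(t_bases) == 1 and len(o_bases) == 1 and t_bases != o_bases:
            tb, ob = t_bases.pop(), o_bases.pop()
            if tb in "ACGT" and ob in "ACGT":
                out.append(DiagnosticSNP(col + 1, (col + 3) // 3, tb, ob))
    return out


@dataclass
class AllelePrimerDesign:
    """One allele class's primer pair with its design annotations."""

    allele_class: str
    copies: frozenset[str]
    primers: PrimerPair
    fwd_snp: DiagnosticSNP
    rev_snp: DiagnosticSNP
    mismatch_nt_pos: int           # template position of the introduced mismatch
    mismatch_base: str             # the base carried by the primer there
    amplicon_span: tuple[int, int]
    #: template id -> predicted product length (None = no amplification)
    amplicon_bp: dict[str, int | None] = field(default_factory=dict)

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_span[1] - self.amplicon_span[0] + 1


def _window_usable(class_rows: list[list[Sequence]], lo: int, hi: int) -> bool:
    """True if columns lo..hi (1-based) are unambiguous and identical
    *within* each allele class (across-class differences are allowed —
    they are extra discriminating positions the class primer absorbs)."""
    if lo < 1 or hi > len(class_rows[0][0]):
        return False
    for p in range(lo, hi + 1):
        for rows in class_rows:
            bases = {r.residues[p - 1] for r in rows}
            if len(bases) != 1 or bases.pop() not in "ACGT":
                return False
    return True


def _contains_site(primer: str, enzymes: Iterable[RestrictionEnzyme]) -> bool:
    for e in enzymes:
        if _occurrences(primer, e.site):
            return True
        if not e.palindromic and _occurrences(primer, revcomp(e.site)):
            return True
    return False


def design_allele_primers(
    copy_alignment: Alignment,
    snp_pair: tuple[DiagnosticSNP, ...] | list[DiagnosticSNP],
    target: set[str],
    length_range: tuple[int, int] = (20, 25),
    amplicon_range: tuple[int, int] = (60, 200),
    mismatch_offset: int = 3,
    avoid_enzymes: Iterable[RestrictionEnzyme] = (TasI, FokI),
) -> tuple[AllelePrimerDesign, AllelePrimerDesign]:
    """Design the allele-specific primer quartet around two diagnostic SNPs.

    The forward primers end (3') on the first SNP and carry the
    introduced mismatch at ``mismatch_offset`` bases from the 3' end; the
    reverse primers end on the second SNP on the bottom strand. Both
    allele classes use identical binding windows, so their amplicons have
    equal length. Returns (target-class design, other-class design).
    """
    if len(snp_pair) < 2:
        raise ValueError("second discriminating SNP required")
    snp1, snp2 = snp_pair[0], snp_pair[1]
    if snp2.nt_pos <= snp1.nt_pos:
        raise ValueError("reverse SNP must lie downstream of the forward SNP")
    rows = copy_alignment.rows
    if any("-" in r.residues for r in rows):
        raise ValueError("copy alignment must be gap-free for primer design")
    lo_len, hi_len = length_range
    if not 1 < mismatch_offset <= lo_len:
        raise ValueError("introduced mismatch must be internal to the primer "
                         "and distinct from the 3'-terminal SNP")
    others = {r.id for r in rows} - target
    target_rows = [r for r in rows if r.id in target]
    other_rows = [r for r in rows if r.id in others]
    classes = [target_rows, other_rows]

    sep = snp2.nt_pos - snp1.nt_pos
    if sep + 2 * lo_len - 1 > amplicon_range[1] or sep + 2 * hi_len - 1 < amplicon_range[0]:
        raise ValueError(
            f"SNPs {sep} bp apart give an amplicon outside {amplicon_range}"
        )

    fwd_len = next(
        (L for L in range(hi_len, lo_len - 1, -1)
         if _window_usable(classes, snp1.nt_pos - L + 1, snp1.nt_pos)),
        None,
    )
    if fwd_len is None:
        raise ValueError("no usable forward primer window")
    rev_len = next(
        (L for L in range(hi_len, lo_len - 1, -1)
         if _window_usable(classes, snp2.nt_pos, snp2.nt_pos + L - 1)),
        None,
    )
    if rev_len is None:
        raise ValueError("no usable reverse primer window")

    span = (snp1.nt_pos - fwd_len + 1, snp2.nt_pos + rev_len - 1)
    amplicon_len = span[1] - span[0] + 1
    if not amplicon_range[0] <= amplicon_len <= amplicon_range[1]:
        raise ValueError(
            f"SNPs give a {amplicon_len}-bp amplicon outside {amplicon_range}"
        )

    mm_index = fwd_len - mismatch_offset           # 0-based within the primer
    mm_nt_pos = span[0] + mm_index
    #: the introduced mismatch must mismatch every template
    column_bases = {r.residues[mm_nt_pos - 1] for r in rows}

    def build(label_copies: set[str], class_template: Sequence,
              mm_base: str) -> AllelePrimerDesign:
        fwd = list(class_template.residues[span[0] - 1:snp1.nt_pos])
        fwd[mm_index] = mm_base
        rev_window = class_template.residues[snp2.nt_pos - 1:span[1]]
        label = _class_label(label_copies)
        pair = PrimerPair(f"AS_{label}", "".join(fwd), revcomp(rev_window))
        return AllelePrimerDesign(
            label, frozenset(label_copies), pair, snp1, snp2,
            mm_nt_pos, mm_base, span,
        )

    design_t = design_o = None
    for candidate in "ACGT":
        if candidate in column_bases:
            continue
        trial_t = build(target, target_rows[0], candidate)
        trial_o = build(others, other_rows[0], candidate)
        if not (
            _contains_site(trial_t.primers.forward, avoid_enzymes)
            or _contains_site(trial_o.primers.forward, avoid_enzymes)
        ):
            design_t, design_o = trial_t, trial_o
            break
    if design_t is None:
        raise ValueError("no introduced-mismatch base avoids enzyme sites")

    for design in (design_t, design_o):
        for row in rows:
            try:
                amp = in_silico_pcr(row, design.primers, max_mismatch=1)
                design.amplicon_bp[row.id] = len(amp)
            except AmplificationError:
                design.amplicon_bp[row.id] = None
    return design_t, design_o


@dataclass
class SpecificityReport:
    """Per design x template amplification and digestion outcomes."""

    table: pd.DataFrame
    specific: bool
    notes: list[str] = field(default_factory=list)


def validate_fok1(
    designs: TSequence[AllelePrimerDesign],
    templates: TSequence[Sequence],
    enzyme: RestrictionEnzyme = FokI,
    max_mismatch: int = 1,
) -> SpecificityReport:
    """Check that restriction digestion separates the allele classes.

    Runs every design on every template; a design is expected to amplify
    exactly its own copies (templates carry their copy label in
    ``meta['copy']`` or their id). The report is "specific" iff
    amplification is class-exact, the cut/uncut outcome is uniform
    within each design's products, and the two designs' outcomes differ
    — i.e. a combination of the two band patterns never occurs.
    """
    rows = []
    notes: list[str] = []
    outcomes: dict[str, set[bool]] = {}
    class_exact = True
    for design in designs:
        for tmpl in templates:
            copy = tmpl.meta.get("copy", tmpl.id)
            expected = copy in design.copies
            try:
                amp = in_silico_pcr(tmpl, design.primers, max_mismatch=max_mismatch)
                fragments = digest(amp, enzyme)
                visible = [f for f in fragments if f >= MIN_VISIBLE_FRAGMENT]
                cut = len(visible) > 1
                rows.append({
                    "design": design.allele_class, "template": tmpl.id,
                    "amplified": True, "amplicon_bp": len(amp),
                    "fragments": "+".join(str(f) for f in fragments),
                    "cut": cut,
                })
                outcomes.setdefault(design.allele_class, set()).add(cut)
                if not expected:
                    class_exact = False
                    notes.append(
                        f"{design.allele_class} amplified off-target {tmpl.id}"
                    )
            except AmplificationError as err:
                rows.append({
                    "design": design.allele_class, "template": tmpl.id,
                    "amplified": False, "amplicon_bp": None,
                    "fragments": "", "cut": None,
                })
                if expected:
                    class_exact = False
                    notes.append(
                        f"{design.allele_class} failed on own template {tmpl.id}: {err}"
                    )
    uniform = all(len(v) == 1 for v in outcomes.values())
    separated = (
        len(outcomes) == 2
        and uniform
        and len({next(iter(v)) for v in outcomes.values()}) == 2
    )
    if not uniform:
        notes.append("mixed cut/uncut patterns within one allele class")
    specific = class_exact and separated
    return SpecificityReport(pd.DataFrame(rows), specific, notes)
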