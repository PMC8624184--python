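"""CAPS diagnostic markers: in-silico PCR, restriction digestion, marker
discovery and sample classification.

A CAPS (cleaved amplified polymorphic sequence) marker is a primer pair
plus a restriction enzyme whose recognition site is polymorphic between
groups: the amplicon digests into group-diagnostic band patterns. Here
the canonical application is the chloroplast rbcL marker separating the
"red" (*E. crus-galli*) from the "white" (*E. oryzicola*) *Echinochloa*
species groups with the enzyme TasI (AATT).

Fragment lengths are accounted on the top strand only; sticky-end
overhangs are ignored, matching gel-band granularity. Band patterns are
compared ignoring fragments shorter than 30 bp, which would run off a
2% agarose gel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .seqcore import GAP, IUPAC_SETS, Alignment, Sequence, revcomp

#: fragments below this length are invisible on the gel and excluded from
#: band-pattern comparison (they still appear in raw digests).
MIN_VISIBLE_FRAGMENT = 30


class AmplificationError(ValueError):
    """No product, or no unique product, from in-silico PCR."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Recognition pattern plus cut offsets for both strands.

    Offsets are measured in bp from the pattern start on the strand
    carrying the pattern: the sense-strand cut falls immediately before
    ``site_start + cut_offset_top`` (1-based) and the antisense cut
    before ``site_start + cut_offset_bottom``. TasI (^AATT, 5' overhang)
    has offsets 0/4; FokI (GGATG 9/13) cuts 9 nt past its 5-nt site on
    the sense strand (offset 5+9=14) and 13 nt past it on the antisense
    strand (offset 5+13=18). When ``cut_offset_bottom`` is omitted the
    symmetric value ``len(site) - cut_offset_top`` is used. A site only
    counts when both strand cuts land inside the molecule (a single
    nick does not separate fragments on a gel). Non-palindromic enzymes
    are scanned on both strands, with cuts of bottom-strand sites mapped
    back to top-strand coordinates.
    """

    name: str
    site: str
    cut_offset_top: int
    palindromic: bool
    cut_offset_bottom: int | None = None

    def __post_init__(self) -> None:
        if not self.site or any(c not in IUPAC_SETS for c in self.site):
            raise ValueError(f"{self.name}: invalid recognition site")
        if self.cut_offset_top < 0:
            raise ValueError(f"{self.name}: negative cut offset")
        if self.cut_offset_bottom is None:
            object.__setattr__(
                self, "cut_offset_bottom", len(self.site) - self.cut_offset_top
            )


TasI = RestrictionEnzyme("TasI", "AATT", 0, palindromic=True)
FokI = RestrictionEnzyme("FokI", "GGATG", 14, palindromic=False,
                         cut_offset_bottom=18)

#: editable enzyme catalogue (name -> enzyme); extend via :func:`add_enzyme`
ENZYMES: dict[str, RestrictionEnzyme] = {"TasI": TasI, "FokI": FokI}


def add_enzyme(name: str, site: str, cut_offset_top: int, palindromic: bool) -> RestrictionEnzyme:
    enz = RestrictionEnzyme(name, site, cut_offset_top, palindromic)
    ENZYMES[name] = enz
    return enz


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both written 5'->3'.

    The reverse primer anneals to the top strand through its reverse
    complement, as ordered.
    """

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 15:
                raise ValueError(f"{self.name} {label} primer shorter than 15 nt")
            if set(p) - set("ACGT"):
                raise ValueError(f"{self.name} {label} primer has ambiguous bases")


@dataclass
class CapsMarker:
    """A primer pair, an enzyme, and the expected band pattern per group."""

    primers: PrimerPair
    enzyme: RestrictionEnzyme
    group_patterns: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        self.group_patterns = {
            g: tuple(sorted(p)) for g, p in self.group_patterns.items()
        }
        visible = {g: _visible(p) for g, p in self.group_patterns.items()}
        if len(set(visible.values())) < 2:
            raise ValueError("marker needs at least two distinct group patterns")


def _visible(fragments: Iterable[int]) -> tuple[int, ...]:
    return tuple(sorted(f for f in fragments if f >= MIN_VISIBLE_FRAGMENT))


# ---------------------------------------------------------------------------
# Pattern matching / site scanning


def _site_matches(residues: str, start0: int, pattern: str) -> bool:
    """Pattern occurrence at 0-based start; sequence ambiguity never matches."""
    if start0 + len(pattern) > len(residues):
        return False
    for off, pc in enumerate(pattern):
        sc = residues[start0 + off]
        if sc not in "ACGT" or sc not in IUPAC_SETS[pc]:
            return False
    return True


def _occurrences(residues: str, pattern: str) -> list[int]:
    """All (overlapping) 1-based pattern start positions on the top strand."""
    return [
        i + 1
        for i in range(len(residues) - len(pattern) + 1)
        if _site_matches(residues, i, pattern)
    ]


def find_sites(s: Sequence | str, enzyme: RestrictionEnzyme) -> list[int]:
    """Top-strand cut positions: the cut falls immediately before each
    returned 1-based position. Sorted and deduplicated; sites whose cuts
    (on either strand) fall outside the molecule are dropped, matching
    gel behaviour — a single-strand nick does not split a band."""
    residues = s.residues if isinstance(s, Sequence) else s
    L = len(residues)
    cuts: set[int] = set()

    def add(top_cut: int, bottom_cut: int) -> None:
        if 2 <= top_cut <= L and 2 <= bottom_cut <= L:
            cuts.add(top_cut)

    for start in _occurrences(residues, enzyme.site):
        add(start + enzyme.cut_offset_top, start + enzyme.cut_offset_bottom)
    if not enzyme.palindromic:
        # a bottom-strand site reads as revcomp(site) on the top strand;
        # its offsets run 3'-ward on the bottom strand (leftward on top),
        # and its *bottom* offset cut is the one severing the top strand
        n = len(enzyme.site)
        for start in _occurrences(residues, revcomp(enzyme.site)):
            add(start + n - enzyme.cut_offset_bottom,
                start + n - enzyme.cut_offset_top)
    return sorted(cuts)


def digest(amplicon: Sequence | str, enzyme: RestrictionEnzyme) -> list[int]:
    """Sorted top-strand fragment lengths; fragments sum to the amplicon
    length, and an uncut amplicon yields a single full-length fragment."""
    residues = amplicon.residues if isinstance(amplicon, Sequence) else amplicon
    cuts = find_sites(residues, enzyme)
    bounds = [1] + cuts + [len(residues) + 1]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


# ---------------------------------------------------------------------------
# In-silico PCR


def _binding_sites(template: str, primer: str, max_mismatch: int,
                   three_prime_is_last: bool) -> list[int]:
    """0-based start positions where the primer binds the top strand with at
    most ``max_mismatch`` mismatches and an exact 3'-terminal match.

    ``three_prime_is_last``: True for a forward primer laid out 5'->3' on the
    top strand; False for the reverse-complemented reverse primer, whose
    3' terminus is the window's first base.
    """
    hits = []
    w = len(primer)
    for i in range(len(template) - w + 1):
        window = template[i:i + w]
        three = -1 if three_prime_is_last else 0
        if window[three] != primer[three]:
            continue
        mism = sum(
            1 for a, b in zip(window, primer)
            if a not in "ACGT" or a not in IUPAC_SETS[b]
        )
        if mism <= max_mismatch:
            hits.append(i)
    return hits


def in_silico_pcr(template: Sequence, primers: PrimerPair,
                  max_mismatch: int = 0) -> Sequence:
    """Predict the PCR product of a primer pair on a top-strand template.

    The amplicon spans from the outer 5' end of the forward primer to the
    outer 5' end of the reverse primer (both primers included). Raises
    :class:`AmplificationError` with "no amplification" when either primer
    finds no site, or "non-specific amplification" when no unique shortest
    product exists.
    """
    t = template.residues
    fwd_sites = _binding_sites(t, primers.forward, max_mismatch, True)
    rev_rc = revcomp(primers.reverse)
    rev_sites = _binding_sites(t, rev_rc, max_mismatch, False)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            if r >= f + len(primers.forward):
                products.append((f, r + len(rev_rc)))  # 0-based half-open
    if not products:
        raise AmplificationError("no amplification")
    products.sort(key=lambda p: (p[1] - p[0], p[0]))
    shortest = [p for p in products if p[1] - p[0] == products[0][1] - products[0][0]]
    if len(set(shortest)) > 1:
        raise AmplificationError("non-specific amplification")
    f, end = shortest[0]
    return Sequence(
        f"{template.id}|amplicon",
        t[f:end],
        {**template.meta, "amplicon_start": str(f + 1), "amplicon_end": str(end)},
    )


# ---------------------------------------------------------------------------
# Marker discovery and application


def _conserved(rows: list[Sequence], col0: int, length: int) -> bool:
    if col0 < 0 or col0 + length > len(rows[0]):
        return False
    for off in range(length):
        column = {r.residues[col0 + off] for r in rows}
        if len(column) != 1 or GAP in column or column <= {"N"}:
            return False
        if next(iter(column)) not in "ACGT":
            return False
    return True


def _pattern_difference(p1: tuple[int, ...], p2: tuple[int, ...]) -> int:
    """Smallest gel-length separation distinguishing two visible band
    patterns; 0 if they are indistinguishable."""
    v1, v2 = _visible(p1), _visible(p2)
    if v1 == v2:
        return 0
    only1 = [f for f in v1 if f not in v2]
    only2 = [f for f in v2 if f not in v1]
    uniques = only1 + only2
    others = {**{f: None for f in v1}, **{f: None for f in v2}}
    best = None
    for f in uniques:
        pool = [g for g in (v2 if f in only1 else v1)]
        gap = min((abs(f - g) for g in pool), default=f)
        best = gap if best is None else min(best, gap)
    return best if best is not None else 0


def discover_caps(aln: Alignment, groups: Mapping[str, str],
                  enzymes: Iterable[RestrictionEnzyme] = (TasI,),
                  window: int = 150,
                  primer_lengths: tuple[int, int] = (18, 25)) -> list[CapsMarker]:
    """Enumerate candidate CAPS markers on a grouped alignment.

    A diagnostic site is an enzyme site present (at the same alignment
    column) in every member of exactly one group and absent from all
    members of the others. For each, the nearest fully conserved primer
    windows within ``window`` bp flanking the site are selected. Markers
    are ranked by decreasing minimum fragment-length difference between
    groups. Returns an empty list when nothing is diagnostic.
    """
    group_rows: dict[str, list[Sequence]] = {}
    for row in aln.rows:
        g = groups.get(row.id)
        if g is None:
            raise ValueError(f"row {row.id} has no group label")
        group_rows.setdefault(g, []).append(row)
    if len(group_rows) < 2:
        raise ValueError("need at least two groups")

    markers: list[tuple[int, str, CapsMarker]] = []
    for enzyme in enzymes:
        # per row: alignment columns (1-based) of site starts
        site_cols: dict[str, set[int]] = {}
        for row in aln.rows:
            src2col = aln.source_to_column(row.id)
            cols = set()
            for start in _occurrences(row.ungapped().residues, enzyme.site):
                if start in src2col:
                    cols.add(src2col[start])
            if not enzyme.palindromic:
                for start in _occurrences(row.ungapped().residues, revcomp(enzyme.site)):
                    if start in src2col:
                        cols.add(src2col[start])
            site_cols[row.id] = cols

        candidate_cols: set[int] = set()
        for g, rows in group_rows.items():
            shared = set.intersection(*(site_cols[r.id] for r in rows))
            for c in shared:
                if all(
                    c not in site_cols[r.id]
                    for og, orows in group_rows.items() if og != g
                    for r in orows
                ):
                    candidate_cols.add(c)

        lo, hi = primer_lengths
        for c in sorted(candidate_cols):
            fwd = rev = None
            # rightmost conserved window ending strictly before the site
            for end in range(c - 1, max(0, c - 1 - window), -1):
                for L in range(hi, lo - 1, -1):
                    if _conserved(aln.rows, end - L, L):
                        fwd = aln.rows[0].residues[end - L:end]
                        break
                if fwd:
                    break
            site_end = c + len(enzyme.site)
            for start in range(site_end, min(aln.length, site_end + window)):
                for L in range(hi, lo - 1, -1):
                    if _conserved(aln.rows, start - 1 + 0, L) and start - 1 + L <= aln.length:
                        if _conserved(aln.rows, start - 1, L):
                            rev = revcomp(aln.rows[0].residues[start - 1:start - 1 + L])
                            break
                if rev:
                    break
            if not fwd or not rev:
                continue
            try:
                primers = PrimerPair(f"caps_{enzyme.name}_{c}", fwd, rev)
            except ValueError:
                continue
            patterns = {}
            ok = True
            for g, rows in group_rows.items():
                try:
                    amp = in_silico_pcr(rows[0].ungapped(), primers, max_mismatch=2)
                except AmplificationError:
                    ok = False
                    break
                patterns[g] = tuple(digest(amp, enzyme))
            if not ok:
                continue
            diffs = [
                _pattern_difference(p1, p2)
                for g1, p1 in patterns.items()
                for g2, p2 in patterns.items() if g1 < g2
            ]
            if min(diffs, default=0) <= 0:
                continue
            try:
                marker = CapsMarker(primers, enzyme, patterns)
            except ValueError:
                continue
            markers.append((min(diffs), primers.name, marker))

    markers.sort(key=lambda t: (-t[0], t[1]))
    return [m for _, _, m in markers]


def classify_caps(sample: Sequence, marker: CapsMarker,
                  max_mismatch: int = 0) -> str:
    """Assign a sample to the group whose expected band pattern its
    amplicon digest reproduces (comparison ignores sub-30-bp fragments)."""
    try:
        amp = in_silico_pcr(sample, marker.primers, max_mismatch=max_mismatch)
    except AmplificationError:
        return "unclassified(no-amplicon)"
    observed = _visible(digest(amp, marker.enzyme))
    for group, pattern in sorted(marker.group_patterns.items()):
        if _visible(pattern) == observed:
            return group
    return "unclassified(novel-pattern)"
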