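"""CAPS machinery: site scanning, digestion, in-silico PCR, markers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyals import synthdata
from polyals.barcoding import (
    AmplificationError,
    CapsMarker,
    FokI,
    PrimerPair,
    RestrictionEnzyme,
    TasI,
    classify_caps,
    digest,
    discover_caps,
    find_sites,
    in_silico_pcr,
)
from polyals.seqcore import Alignment, Sequence, revcomp

RNG = np.random.default_rng(20)


def random_seq(n, rng=RNG):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# find_sites / digest


def test_tasi_cut_before_site_start():
    assert find_sites("GGAATTCC", TasI) == [3]


def test_tasi_no_site():
    assert find_sites("ACGTACGT", TasI) == []


def test_foki_downstream_cut_offset():
    # GGATG(9/13): top-strand cut 9 nt past the 5-nt site
    s = "GGATG" + "C" * 20
    assert find_sites(s, FokI) == [15]


def test_foki_bottom_strand_mapped_back():
    # CATCC on the top strand = GGATG on the bottom; for an antisense site
    # the 13-offset cut is the one severing the top strand: 13 nt upstream
    s = "C" * 20 + "CATCC" + "C" * 20
    assert find_sites(s, FokI) == [21 - 13]


def test_find_sites_matches_biopython():
    """Independent oracle: Bio.Restriction site/cut positions."""
    from Bio.Restriction import FokI as BioFokI, TasI as BioTasI
    from Bio.Seq import Seq

    rng = np.random.default_rng(99)
    for _ in range(20):
        s = random_seq(300, rng)
        assert find_sites(s, TasI) == sorted(BioTasI.search(Seq(s)))
        mine = find_sites(s, FokI)
        bio = sorted(p for p in BioFokI.search(Seq(s)) if 2 <= p <= len(s))
        assert mine == bio


def test_digest_examples():
    assert digest("A" * 217, TasI) == [217]
    amp = "G" * 134 + "AATT" + "G" * 83        # cut before position 135
    assert len(amp) == 221
    assert digest(amp, TasI) == [87, 134]


@given(st.integers(0, 2 ** 32 - 1))
@settings(max_examples=60, deadline=None)
def test_digest_conserves_length(seed):
    rng = np.random.default_rng(seed)
    s = random_seq(int(rng.integers(10, 400)), rng)
    for enzyme in (TasI, FokI):
        frags = digest(s, enzyme)
        assert sum(frags) == len(s)
        assert all(f > 0 for f in frags)


def test_overlapping_sites_all_reported():
    # boundary sites whose cuts fall off the molecule are dropped
    assert find_sites("AATTAATT", TasI) == []
    assert find_sites("GAATTAATTC", TasI) == [2, 6]


# ---------------------------------------------------------------------------
# in-silico PCR


FWD = "CAACTGTTTGGACTGATGGAC"
REV = "CGTAGATCCTCCAAACGTAGAGC"
PAIR = PrimerPair("toy", FWD, REV)


def test_pcr_constructed_template():
    template = Sequence("t", FWD + "ACGT" * 10 + revcomp(REV))
    amp = in_silico_pcr(template, PAIR)
    assert len(amp) == len(FWD) + 40 + len(REV)
    assert amp.residues.startswith(FWD)
    assert amp.residues.endswith(revcomp(REV))


def test_pcr_no_reverse_site():
    template = Sequence("t", FWD + "ACGT" * 10)
    with pytest.raises(AmplificationError, match="no amplification"):
        in_silico_pcr(template, PAIR)


def test_pcr_non_specific_two_products():
    core = FWD + "ACGT" * 5 + revcomp(REV)
    template = Sequence("t", core + "GGGG" + core)
    with pytest.raises(AmplificationError, match="non-specific"):
        in_silico_pcr(template, PAIR)


def test_pcr_three_prime_mismatch_blocks():
    # one mismatch at the forward 3' terminus is never tolerated
    bad_end = FWD[:-1] + ("A" if FWD[-1] != "A" else "C")
    template = Sequence("t", bad_end + "ACGT" * 10 + revcomp(REV))
    with pytest.raises(AmplificationError):
        in_silico_pcr(template, PAIR, max_mismatch=2)


def test_pcr_internal_mismatch_tolerance():
    mutated = FWD[:5] + ("A" if FWD[5] != "A" else "C") + FWD[6:]
    template = Sequence("t", mutated + "ACGT" * 10 + revcomp(REV))
    with pytest.raises(AmplificationError):
        in_silico_pcr(template, PAIR, max_mismatch=0)
    amp = in_silico_pcr(template, PAIR, max_mismatch=1)
    assert len(amp) == len(FWD) + 40 + len(REV)


# ---------------------------------------------------------------------------
# marker discovery & classification


def _toy_alignment():
    """300-bp two-group alignment differing only by one TasI site."""
    rng = np.random.default_rng(77)
    backbone = list(random_seq(300, rng))
    # scrub AATT so the designed site is unique
    s = "".join(backbone)
    while "AATT" in s:
        s = s.replace("AATT", "ACTT", 1)
    backbone = list(s)
    red = backbone.copy()
    white = backbone.copy()
    white[148:152] = "AATT"
    red[148:152] = "ACTT"
    rows = [
        Sequence("w1", "".join(white)), Sequence("w2", "".join(white)),
        Sequence("r1", "".join(red)), Sequence("r2", "".join(red)),
    ]
    groups = {"w1": "white", "w2": "white", "r1": "red", "r2": "red"}
    return Alignment(rows), groups


def test_discover_caps_toy_alignment():
    aln, groups = _toy_alignment()
    markers = discover_caps(aln, groups, enzymes=[TasI])
    assert markers, "expected at least one diagnostic marker"
    marker = markers[0]
    assert marker.enzyme.name == "TasI"
    assert len(marker.group_patterns["white"]) == 2
    assert len(marker.group_patterns["red"]) == 1


def test_discover_caps_identical_groups_empty():
    aln, _ = _toy_alignment()
    rows = [Sequence(f"s{i}", aln.rows[0].residues) for i in range(4)]
    aln2 = Alignment(rows)
    groups = {"s0": "a", "s1": "a", "s2": "b", "s3": "b"}
    assert discover_caps(aln2, groups, enzymes=[TasI]) == []


def test_discover_caps_invariant_to_row_order_and_labels():
    aln, groups = _toy_alignment()
    m1 = discover_caps(aln, groups, enzymes=[TasI])
    shuffled = Alignment(list(reversed(aln.rows)))
    relabel = {"w1": "G2", "w2": "G2", "r1": "G1", "r2": "G1"}
    m2 = discover_caps(shuffled, relabel, enzymes=[TasI])
    assert len(m1) == len(m2)
    assert m1[0].primers.forward == m2[0].primers.forward
    assert m1[0].primers.reverse == m2[0].primers.reverse
    p1 = sorted(map(sorted, m1[0].group_patterns.values()))
    p2 = sorted(map(sorted, m2[0].group_patterns.values()))
    assert p1 == p2


def test_discover_caps_on_rbcl_templates(models):
    """Only the white rbcL haplotype carries the diagnostic TasI site."""
    red, white = models
    aln = Alignment([
        Sequence("red", red.rbcl.residues),
        Sequence("white", white.rbcl.residues),
    ])
    markers = discover_caps(aln, {"red": "red", "white": "white"},
                            enzymes=[TasI])
    assert markers
    assert len(markers[0].group_patterns["white"]) > 1
    assert len(markers[0].group_patterns["red"]) == 1


def test_classify_caps_fixture_plants(models):
    marker = synthdata.caps_rbcl_marker(models)
    red, white = models
    assert classify_caps(red.rbcl, marker) == "red"
    assert classify_caps(white.rbcl, marker) == "white"


def test_classify_caps_panel_zero_error_is_exact(models):
    panel = synthdata.sample_rbcl_panel(models, n_per_group=21, error_rate=0.0)
    marker = synthdata.caps_rbcl_marker(models)
    assert len(panel) == 42
    for sample in panel:
        assert classify_caps(sample, marker) == sample.meta["group"]


@pytest.mark.parametrize("error_rate", [0.002, 0.01])
def test_classify_caps_failures_only_from_diagnostic_errors(models, error_rate):
    """Misclassification occurs only when error hits the amplicon region
    (primer windows or the enzyme site)."""
    marker = synthdata.caps_rbcl_marker(models)
    panel = synthdata.sample_rbcl_panel(models, n_per_group=40,
                                        error_rate=error_rate, seed=5)
    truth_template = {m.species: m.rbcl.residues for m in models}
    lo, hi = 100, 320          # fixture amplicon span on the template
    n_bad = 0
    for sample in panel:
        call = classify_caps(sample, marker)
        if call != sample.meta["group"]:
            n_bad += 1
            template = truth_template[sample.meta["group"]]
            assert sample.residues[lo - 1:hi] != template[lo - 1:hi], (
                "misclassified sample has a pristine amplicon region"
            )
    assert n_bad < len(panel) / 2


def test_caps_marker_requires_distinct_patterns():
    with pytest.raises(ValueError, match="distinct"):
        CapsMarker(PAIR, TasI, {"a": (221,), "b": (221,)})
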