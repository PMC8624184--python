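"""Reference-gene ranking and ΔΔCt relative quantification."""

import numpy as np
import pandas as pd
import pytest

from polyals import synthdata
from polyals.qpcr import (
    delta_delta_ct,
    evaluate_reference_genes,
    expression_frame,
    expression_table,
    read_ct_table,
    reference_ct,
)


def df_from(rows):
    return pd.DataFrame(
        rows, columns=["population", "treatment", "bio_rep", "target",
                       "tech_rep", "ct"]
    )


# ---------------------------------------------------------------------------
# reference genes


def test_lower_ct_ranks_first():
    rows = []
    for i in range(4):
        rows.append(("p", "untreated", i, "A", 1, 20.0 + 0.1 * i))
        rows.append(("p", "untreated", i, "B", 1, 30.0 + 0.1 * i))
    ranking = evaluate_reference_genes(df_from(rows))
    assert list(ranking["gene"]) == ["A", "B"]


def test_screen_selects_rubisco_and_18s():
    screen = synthdata.simulate_reference_screen(seed=4)
    ranking = evaluate_reference_genes(screen)
    assert set(ranking["gene"].head(2)) == {"Rubisco", "18S"}


def test_screen_within_printed_ranges():
    screen = synthdata.simulate_reference_screen(seed=9, n_samples=30)
    rub = screen[screen["target"] == "Rubisco"]["ct"]
    r18 = screen[screen["target"] == "18S"]["ct"]
    assert rub.between(19.6, 24.9).all()
    assert r18.between(20.4, 23.7).all()


def test_all_missing_gene_excluded_with_warning():
    rows = [("p", "untreated", i, "A", 1, 20.0 + i * 0.1) for i in range(3)]
    rows += [("p", "untreated", i, "B", 1, np.nan) for i in range(3)]
    with pytest.warns(UserWarning, match="excluded"):
        ranking = evaluate_reference_genes(df_from(rows))
    assert list(ranking["gene"]) == ["A"]


# ---------------------------------------------------------------------------
# reference Ct and ΔΔCt arithmetic


def test_reference_ct_mean_of_genes():
    rows = [("p", "t", 1, "Rubisco", 1, 20.0), ("p", "t", 1, "18S", 1, 22.0)]
    assert reference_ct(df_from(rows), ["Rubisco", "18S"]) == 21.0


def test_reference_ct_single_gene():
    rows = [("p", "t", 1, "Rubisco", 1, 20.5)]
    assert reference_ct(df_from(rows), ["Rubisco", "18S"]) == 20.5


def test_reference_ct_tech_means_first():
    rows = [("p", "t", 1, "Rubisco", k, ct)
            for k, ct in enumerate([20.0, 20.2, 20.4], 1)]
    rows += [("p", "t", 1, "18S", 1, 22.0)]
    assert reference_ct(df_from(rows), ["Rubisco", "18S"]) == pytest.approx(21.1)


def test_reference_ct_missing_errors():
    rows = [("p", "t", 1, "ALS1", 1, 25.0)]
    with pytest.raises(ValueError, match="no reference-gene data"):
        reference_ct(df_from(rows), ["Rubisco"])


def test_ddct_calibrator_is_unity():
    ddct, rq = delta_delta_ct(22.0, 20.0, 22.0, 20.0)
    assert ddct == 0.0 and rq == 1.0


def test_ddct_arithmetic():
    ddct, rq = delta_delta_ct(25.0, 20.0, 22.0, 20.0)
    assert ddct == 3.0
    assert rq == 0.125


def test_ddct_efficiency_hook():
    _, rq = delta_delta_ct(25.0, 20.0, 22.0, 20.0, efficiency=1.5)
    assert rq == pytest.approx(1.5 ** -3)


# ---------------------------------------------------------------------------
# expression table


def _closed_form_oracle(df, ref_genes, calibrator, targets):
    """Spreadsheet-style recomputation: plain dict arithmetic, no pandas
    grouping shared with the implementation."""
    cells = {}
    for (pop, trt, bio, target), grp in df.groupby(
        ["population", "treatment", "bio_rep", "target"]
    ):
        cells.setdefault((pop, trt), {}).setdefault(target, []).append(
            sum(grp["ct"]) / len(grp)
        )

    def mean(xs):
        return sum(xs) / len(xs)

    def ref_of(cell):
        return mean([mean(v) for t, v in cell.items() if t in ref_genes])

    cal = cells[calibrator]
    out = {}
    for (pop, trt), cell in cells.items():
        for t in targets:
            if t not in cell:
                continue
            ddct = (mean(cell[t]) - ref_of(cell)) - (mean(cal[t]) - ref_of(cal))
            out[(pop, trt, t)] = 2.0 ** (-ddct)
    return out


def test_expression_table_matches_closed_form_oracle():
    df = synthdata.simulate_qpcr(seed=13)
    results = expression_table(df, ("Rubisco", "18S"), ("16S", "untreated"))
    oracle = _closed_form_oracle(df, {"Rubisco", "18S"}, ("16S", "untreated"),
                                 ("ALS1", "ALS2-3"))
    assert len(results) == len(oracle)
    for r in results:
        assert r.rq == pytest.approx(oracle[(r.population, r.treatment, r.target)])


def test_calibrator_rq_exactly_one():
    df = synthdata.simulate_qpcr(seed=14)
    for cal in ("16S", "161S"):
        results = expression_table(df, ("Rubisco", "18S"), (cal, "untreated"))
        for r in results:
            if r.population == cal and r.treatment == "untreated":
                assert r.delta_delta_ct == 0.0
                assert r.rq == 1.0


def test_plate_offset_invariance():
    df = synthdata.simulate_qpcr(seed=15)
    shifted = df.copy()
    shifted["ct"] = shifted["ct"] + 3.7
    r1 = expression_table(df, ("Rubisco", "18S"), ("16S", "untreated"))
    r2 = expression_table(shifted, ("Rubisco", "18S"), ("16S", "untreated"))
    for a, b in zip(r1, r2):
        assert (a.population, a.treatment, a.target) == (
            b.population, b.treatment, b.target)
        assert a.rq == pytest.approx(b.rq)
        assert a.delta_delta_ct == pytest.approx(b.delta_delta_ct)


def test_replicate_order_irrelevant():
    df = synthdata.simulate_qpcr(seed=16)
    shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
    r1 = expression_frame(
        expression_table(df, ("Rubisco", "18S"), ("16S", "untreated")))
    r2 = expression_frame(
        expression_table(shuffled, ("Rubisco", "18S"), ("16S", "untreated")))
    key = ["population", "treatment", "target"]
    m = r1.merge(r2, on=key, suffixes=("_a", "_b"))
    assert np.allclose(m["rq_a"], m["rq_b"])


def test_noise_free_recovers_exact_fold():
    df = synthdata.simulate_qpcr(seed=0, noise_sd=0.0, als1_delta_ct=1.0)
    results = expression_table(df, ("Rubisco", "18S"), ("16S", "untreated"))
    for r in results:
        if r.treatment == "untreated" and r.population in ("16S", "161S"):
            continue                      # baseline cells sit at RQ 1 for both
        expected = 2.0 if r.target == "ALS1" else 1.0
        assert r.rq == pytest.approx(expected)


@pytest.mark.parametrize("fold", [0.5, 1.0, 2.0, 4.0])
def test_fold_change_recovery_within_15pct(fold):
    """Median recovered RQ over 20 seeds within 15% of truth at Ct noise 0.3."""
    recovered = []
    for seed in range(20):
        df = synthdata.simulate_qpcr(
            seed=seed, noise_sd=0.3, als1_delta_ct=float(np.log2(fold))
            if fold != 1.0 else 0.0,
        )
        results = expression_table(df, ("Rubisco", "18S"), ("16S", "untreated"))
        vals = [r.rq for r in results
                if r.target == "ALS1"
                and not (r.treatment == "untreated"
                         and r.population in ("16S", "161S"))]
        recovered.append(np.median(vals))
    assert abs(np.median(recovered) - fold) / fold <= 0.15


def test_untreated_als1_delta_ct_sign():
    """ALS1 sits at lower Ct than ALS2-3 (higher expression) in untreated
    samples of non-calibrator populations."""
    df = synthdata.simulate_qpcr(seed=17)
    results = expression_table(df, ("Rubisco", "18S"), ("161S", "untreated"))
    by = {(r.population, r.treatment, r.target): r for r in results}
    for pop in ("44R", "45R", "46R", "95R", "100R"):
        assert (by[(pop, "untreated", "ALS1")].delta_ct
                < by[(pop, "untreated", "ALS2-3")].delta_ct)


def test_technical_range_flagging_and_exclusions():
    rows = [("p", "u", 1, "ALS1", k, ct) for k, ct in enumerate([24.0, 25.5, 24.2], 1)]
    rows += [("p", "u", 1, "ALS2-3", k, 24.0) for k in range(1, 4)]
    rows += [("p", "u", 1, "Rubisco", k, 20.0) for k in range(1, 4)]
    df = df_from(rows)
    res = expression_table(df, ("Rubisco",), ("p", "u"), targets=("ALS1", "ALS2-3"))
    flagged = next(r for r in res if r.target == "ALS1")
    assert flagged.flagged_reps == 1
    # manual exclusion removes the replicate entirely
    res2 = expression_table(df, ("Rubisco",), ("p", "u"),
                            targets=("ALS2-3",),
                            exclusions=[("p", "u", 1, "ALS1")])
    assert {r.target for r in res2} == {"ALS2-3"}


def test_missing_target_omitted_with_warning():
    rows = [("cal", "u", 1, "ALS1", 1, 24.0), ("cal", "u", 1, "Rubisco", 1, 20.0),
            ("cal", "u", 1, "ALS2-3", 1, 25.0),
            ("q", "u", 1, "Rubisco", 1, 20.0), ("q", "u", 1, "ALS1", 1, 23.0)]
    with pytest.warns(UserWarning, match="missing"):
        res = expression_table(df_from(rows), ("Rubisco",), ("cal", "u"))
    assert ("q", "u", "ALS2-3") not in {
        (r.population, r.treatment, r.target) for r in res
    }


def test_read_ct_table_roundtrip(tmp_path):
    df = synthdata.simulate_qpcr(seed=18)
    df.loc[0, "ct"] = np.nan          # explicit no-amplification
    p = tmp_path / "ct.csv"
    df.to_csv(p, index=False)
    back = read_ct_table(p)
    assert back["ct"].isna().sum() == 1
    assert len(back) == len(df)
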