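"""Reference-gene evaluation and ΔΔCt relative expression.

Relative quantification follows the comparative-Ct (Livak) method:

    ΔCt   = Ct(target) − Ct(reference)          per sample
    ΔΔCt  = ΔCt(sample) − ΔCt(calibrator)
    RQ    = E^(−ΔΔCt),  E = 2 (perfect doubling) by default

where the reference Ct is the average of the chosen reference genes
(here *Rubisco* and *18S*) and the calibrator is a designated
population × treatment cell (the untreated susceptible plants in the
study design). Technical replicates are averaged before biological
replicates, in that fixed order; missing/no-amplification Ct values
are encoded as NA, excluded from means and never imputed.

Ct tables are tidy DataFrames with columns
``population, treatment, bio_rep, target, tech_rep, ct``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence as TSequence

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["population", "treatment", "bio_rep", "target", "tech_rep", "ct"]

#: technical replicates spanning more than this many cycles are flagged
TECH_RANGE_FLAG = 1.0


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct CSV; empty/NA ct fields mean no amplification."""
    df = pd.read_csv(path, dtype={"population": str, "treatment": str,
                                  "target": str})
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    if (df["ct"].dropna() <= 0).any():
        raise ValueError("non-positive Ct values present")
    return df[CT_COLUMNS]


def evaluate_reference_genes(records: pd.DataFrame,
                             candidates: Iterable[str] | None = None) -> pd.DataFrame:
    """Rank candidate reference genes by expression level and stability.

    Computes each gene's mean Ct (lower = more expressed) and the Ct
    standard deviation across samples (lower = more stable) over
    technical-replicate means, and orders genes by the sum of their two
    ranks (ties broken by mean Ct). Genes with no usable Ct are excluded
    with a warning. Top-k selection is the caller's choice.
    """
    df = records.copy()
    if candidates is not None:
        df = df[df["target"].isin(set(candidates))]
    if df.empty:
        raise ValueError("no candidate reference-gene records")
    tech = (
        df.groupby(["population", "treatment", "bio_rep", "target"])["ct"]
        .mean()
        .reset_index()
    )
    out = []
    for gene, g in tech.groupby("target"):
        cts = g["ct"].dropna()
        if cts.empty:
            warnings.warn(f"reference candidate {gene} has no usable Ct; excluded")
            continue
        out.append({"gene": gene, "mean_ct": cts.mean(),
                    "sd_ct": cts.std(ddof=1) if len(cts) > 1 else 0.0,
                    "n_samples": len(cts)})
    ranking = pd.DataFrame(out)
    if ranking.empty:
        raise ValueError("all candidate genes lack usable Ct values")
    ranking["rank_mean"] = ranking["mean_ct"].rank(method="min")
    ranking["rank_sd"] = ranking["sd_ct"].rank(method="min")
    ranking["rank_sum"] = ranking["rank_mean"] + ranking["rank_sd"]
    ranking = ranking.sort_values(["rank_sum", "mean_ct"]).reset_index(drop=True)
    return ranking


def reference_ct(sample_records: pd.DataFrame,
                 ref_genes: TSequence[str]) -> float:
    """Reference Ct of one sample: the mean over the chosen reference genes
    of each gene's technical-replicate mean Ct."""
    df = sample_records[sample_records["target"].isin(set(ref_genes))]
    per_gene = df.groupby("target")["ct"].mean().dropna()
    if per_gene.empty:
        raise ValueError("no reference-gene data for sample")
    return float(per_gene.mean())


def delta_delta_ct(ct_target: float, ct_ref: float,
                   ct_cal_target: float, ct_cal_ref: float,
                   efficiency: float = 2.0) -> tuple[float, float]:
    """(ΔΔCt, RQ) of one sample against the calibrator.

    The first parenthesis of the defining equation uses the sample's own
    reference Ct, the second the calibrator's reference Ct.
    """
    ddct = (ct_target - ct_ref) - (ct_cal_target - ct_cal_ref)
    return ddct, float(efficiency ** (-ddct))


@dataclass
class ExpressionResult:
    population: str
    treatment: str
    target: str
    mean_ct: float
    sd_ct: float
    ci_low: float
    ci_high: float
    n_bio: int
    ref_ct: float
    delta_ct: float
    delta_delta_ct: float
    rq: float
    calibrator: str
    flagged_reps: int     # technical triplicates spanning > 1 cycle


def _tech_means(records: pd.DataFrame) -> pd.DataFrame:
    g = records.groupby(["population", "treatment", "bio_rep", "target"])["ct"]
    tech = g.mean().reset_index(name="ct")
    tech["flag_range"] = (g.max() - g.min() > TECH_RANGE_FLAG).values
    return tech


def expression_table(
    records: pd.DataFrame,
    ref_genes: TSequence[str],
    calibrator: tuple[str, str],
    targets: TSequence[str] = ("ALS1", "ALS2-3"),
    efficiency: float = 2.0,
    ci_level: float = 0.95,
    exclusions: Iterable[tuple] | None = None,
) -> list[ExpressionResult]:
    """Full relative-expression table against one calibrator cell.

    ``calibrator`` is a (population, treatment) pair whose samples define
    the baseline (RQ exactly 1 for every target). ``exclusions`` is a
    manual list of (population, treatment, bio_rep, target) rows to drop
    (e.g. primer-dimer replicates); nothing is ever dropped silently.
    Populations missing a target are omitted with a warning.
    """
    df = records.copy()
    if exclusions:
        mask = pd.Series(False, index=df.index)
        for pop, trt, bio, target in exclusions:
            mask |= (
                (df["population"] == pop) & (df["treatment"] == trt)
                & (df["bio_rep"] == bio) & (df["target"] == target)
            )
        df = df[~mask]
    tech = _tech_means(df)

    cal_pop, cal_trt = calibrator
    cal = tech[(tech["population"] == cal_pop) & (tech["treatment"] == cal_trt)]
    if cal.empty:
        raise ValueError(f"no records for calibrator {cal_pop}:{cal_trt}")

    def cell_ref_ct(cell: pd.DataFrame) -> float:
        per_gene = (
            cell[cell["target"].isin(set(ref_genes))]
            .groupby("target")["ct"].mean().dropna()
        )
        if per_gene.empty:
            raise ValueError("no reference-gene data for sample")
        return float(per_gene.mean())

    cal_ref = cell_ref_ct(cal)
    cal_target_ct = {
        t: cal[cal["target"] == t]["ct"].mean() for t in targets
    }
    for t, v in cal_target_ct.items():
        if pd.isna(v):
            raise ValueError(f"calibrator lacks target {t}")

    results: list[ExpressionResult] = []
    alpha = 1.0 - ci_level
    for (pop, trt), cell in tech.groupby(["population", "treatment"]):
        try:
            ref = cell_ref_ct(cell)
        except ValueError:
            warnings.warn(f"{pop}:{trt}: no reference-gene data; omitted")
            continue
        for target in targets:
            sub = cell[cell["target"] == target].dropna(subset=["ct"])
            if sub.empty:
                warnings.warn(f"{pop}:{trt}: target {target} missing; omitted")
                continue
            cts = sub["ct"].to_numpy()
            n = len(cts)
            mean = float(cts.mean())
            sd = float(cts.std(ddof=1)) if n > 1 else 0.0
            if n > 1 and sd > 0:
                half = stats.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n)
            else:
                half = 0.0
            ddct, rq = delta_delta_ct(
                mean, ref, float(cal_target_ct[target]), cal_ref, efficiency
            )
            results.append(ExpressionResult(
                pop, trt, target, mean, sd, mean - half, mean + half, n,
                ref, mean - ref, ddct, rq, f"{cal_pop}:{cal_trt}",
                int(sub["flag_range"].sum()),
            ))
    return results


def expression_frame(results: TSequence[ExpressionResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def plot_rq(results: TSequence[ExpressionResult], path: str | Path,
            treatment: str | None = None) -> None:
    """Grouped RQ bar plot (one bar group per population, one bar per
    gene copy). Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = expression_frame(results)
    if treatment is not None:
        df = df[df["treatment"] == treatment]
    pops = sorted(df["population"].unique())
    targets = sorted(df["target"].unique())
    width = 0.8 / max(1, len(targets))
    fig, ax = plt.subplots(figsize=(1.5 * len(pops) + 2, 4))
    for k, t in enumerate(targets):
        sub = df[df["target"] == t].set_index("population")
        xs = [i + k * width for i in range(len(pops))]
        ys = [sub["rq"].get(p, float("nan")) for p in pops]
        ax.bar(xs, ys, width=width, label=t)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xticks([i + width * (len(targets) - 1) / 2 for i in range(len(pops))])
    ax.set_xticklabels(pops)
    ax.set_ylabel("RQ")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
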