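"""Cross-species panel statistics.

QC exclusions (extreme heterozygosity, inflated allelic balance),
ordinal regression of diversity metrics on IUCN extinction-risk rank,
wild/captive comparison and a phenotype correlation screen with
Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sohscan.errors import DegenerateDataError, UndefinedValueError
from sohscan.simulate import IUCN_CATEGORIES

# QC thresholds: genomes with exceptionally high heterozygosity, and
# (afterwards) allelic balance more than one s.d. above the panel mean.
HET_MAX = 0.02
AB_SD_FACTOR = 1.0

IUCN_RANK = {cat: r for r, cat in enumerate(IUCN_CATEGORIES)}  # LC=0 ... CR=4


def apply_qc_exclusions(
    panel: pd.DataFrame,
    het_max: float = HET_MAX,
    ab_sd_factor: float = AB_SD_FACTOR,
    ab_threshold: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop QC-failing genomes; return (clean panel, exclusion report).

    Rules apply sequentially: first het > `het_max` is dropped; then, on
    the remaining records, ab strictly above mean(ab) + `ab_sd_factor` *
    sd(ab) is dropped (threshold computed after the first rule). The
    allelic-balance cut is a fixed panel-level threshold: it is derived
    once from the input panel and recorded in the report's attrs, or
    supplied directly via `ab_threshold` (re-applying with the recorded
    threshold is a no-op). The report lists one row per excluded species
    with the rule and the offending value.
    """
    if len(panel) == 0:
        raise UndefinedValueError("empty panel")
    report_rows = []
    het_bad = panel["het"] > het_max
    for _, row in panel.loc[het_bad].iterrows():
        report_rows.append(
            {"species": row["species"], "rule": "het", "value": row["het"]}
        )
    remaining = panel.loc[~het_bad]
    ab = remaining["ab"].to_numpy(dtype=float)
    if ab_threshold is None:
        ab_threshold = float(np.mean(ab) + ab_sd_factor * np.std(ab, ddof=1))
    ab_bad = remaining["ab"] > ab_threshold
    for _, row in remaining.loc[ab_bad].iterrows():
        report_rows.append(
            {"species": row["species"], "rule": "ab", "value": row["ab"]}
        )
    clean = remaining.loc[~ab_bad].reset_index(drop=True)
    report = pd.DataFrame(report_rows, columns=["species", "rule", "value"])
    report.attrs["ab_threshold"] = ab_threshold
    return clean, report


@dataclass
class RegressionResult:
    """OLS fit of a diversity metric on IUCN ordinal rank."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    n_excluded: int = 0


def ordinal_iucn_regression(panel: pd.DataFrame, metric: str) -> RegressionResult:
    """OLS of `metric` on IUCN rank coded LC=0, NT=1, VU=2, EN=3, CR=4.

    Records with a category outside LC..CR (DD, EW, missing) or with the
    metric undefined are excluded and counted. Returns the slope, its
    two-sided p-value (slope != 0), R-squared and n.
    """
    usable = panel["iucn"].isin(IUCN_RANK) & panel[metric].notna()
    sub = panel.loc[usable]
    n_excluded = len(panel) - len(sub)
    if len(sub) < 3:
        raise UndefinedValueError("need >= 3 usable records for regression")
    x = sub["iucn"].map(IUCN_RANK).to_numpy(dtype=float)
    y = sub[metric].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDataError("all records share one IUCN category")
    if np.ptp(y) == 0:
        # constant metric: flat fit explains nothing
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0,
            p_value=1.0, n=len(sub), n_excluded=n_excluded,
        )
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(sub),
        n_excluded=n_excluded,
    )


@dataclass
class TTestResult:
    t: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def group_ttest(
    panel: pd.DataFrame,
    metric: str,
    group_col: str = "born",
    groups: tuple[str, str] = ("wild", "captive"),
    welch: bool = False,
) -> TTestResult:
    """Two-sided independent-samples t-test of `metric` between groups.

    Pooled-variance by default; Welch available via `welch=True`.
    Records outside the two groups (e.g. born unknown) or with the
    metric undefined are excluded.
    """
    a = panel.loc[(panel[group_col] == groups[0]) & panel[metric].notna(), metric]
    b = panel.loc[(panel[group_col] == groups[1]) & panel[metric].notna(), metric]
    if len(a) < 2 or len(b) < 2:
        raise UndefinedValueError("each group needs >= 2 records")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(
        t=float(res.statistic), p_value=float(res.pvalue),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        n_a=len(a), n_b=len(b),
    )


def phenotype_correlation_table(
    panel: pd.DataFrame,
    phenotypes: list[str],
    metrics: tuple[str, ...] = ("het", "soh"),
    iucn_subset: tuple[str, ...] | None = ("LC",),
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Pearson correlation screen of phenotypes against diversity metrics.

    Restricted to `iucn_subset` categories (default least concern only).
    Pairwise-complete observations; rows with fewer than 3 complete
    pairs get r = NaN. The Bonferroni flag compares each two-sided p to
    alpha / m with m = len(phenotypes) * len(metrics) unless
    `bonferroni_m` overrides it.
    """
    sub = panel if iucn_subset is None else panel.loc[panel["iucn"].isin(iucn_subset)]
    m = bonferroni_m if bonferroni_m is not None else len(phenotypes) * len(metrics)
    threshold = alpha / m
    rows = []
    for pheno in phenotypes:
        for metric in metrics:
            pair = sub[[pheno, metric]].dropna()
            if len(pair) < 3:
                rows.append({
                    "phenotype": pheno, "metric": metric,
                    "r": np.nan, "p_value": np.nan, "n": len(pair),
                    "bonferroni_significant": False,
                })
                continue
            r, p = stats.pearsonr(pair[pheno], pair[metric])
            rows.append({
                "phenotype": pheno, "metric": metric,
                "r": float(r), "p_value": float(p), "n": len(pair),
                "bonferroni_significant": bool(p < threshold),
            })
    table = pd.DataFrame(rows)
    table.attrs["bonferroni_m"] = m
    table.attrs["bonferroni_threshold"] = threshold
    return table


def _pearson(panel: pd.DataFrame, a: str, b: str) -> dict:
    pair = panel[[a, b]].dropna()
    r, p = stats.pearsonr(pair[a], pair[b])
    return {"r": float(r), "p": float(p), "n": len(pair)}


def panel_summary_statistics(panel: pd.DataFrame) -> dict:
    """The standard diversity-panel analysis bundle.

    Computes, at the stage of QC each statistic belongs to:

    * on the full panel: Pearson r of callable percentage vs
      heterozygosity (sequencing-quality confounder check);
    * after the extreme-heterozygosity exclusion only: least-concern
      median heterozygosity and SoH, and Pearson r of contig N50 vs SoH
      (assembly-contiguity confounder check);
    * after both QC exclusions: Pearson r of heterozygosity vs SoH,
      ordinal IUCN regressions for both metrics, and wild-vs-captive
      t-tests.
    """
    out: dict = {"n_input": len(panel)}
    out["callable_vs_het"] = _pearson(panel, "callable_pct", "het")
    after_het = panel.loc[panel["het"] <= HET_MAX]
    lc = after_het.loc[after_het["iucn"] == "LC"]
    out["lc_median_het"] = float(lc["het"].median())
    out["lc_median_soh"] = float(lc["soh"].median())
    out["n50_vs_soh"] = _pearson(after_het, "contig_n50", "soh")
    clean, report = apply_qc_exclusions(panel)
    out["n_clean"] = len(clean)
    out["ab_threshold"] = report.attrs["ab_threshold"]
    out["het_vs_soh"] = _pearson(clean, "het", "soh")
    for metric in ("het", "soh"):
        reg = ordinal_iucn_regression(clean, metric)
        out[f"{metric}_vs_iucn"] = {
            "slope": reg.slope, "r_squared": reg.r_squared,
            "p": reg.p_value, "n": reg.n,
        }
        tt = group_ttest(clean, metric)
        out[f"{metric}_wild_vs_captive"] = {
            "t": tt.t, "p": tt.p_value, "n": tt.n_a + tt.n_b,
        }
    return out
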