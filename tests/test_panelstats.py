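"""QC exclusions, IUCN ordinal regression, group t-test and the
phenotype correlation screen, each checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sohscan.errors import DegenerateDataError, UndefinedValueError
from sohscan.panelstats import (
    IUCN_RANK,
    apply_qc_exclusions,
    group_ttest,
    ordinal_iucn_regression,
    panel_summary_statistics,
    phenotype_correlation_table,
)
from sohscan.simulate import PanelSimConfig, simulate_species_panel


def small_panel(het, ab, species=None, iucn=None):
    n = len(het)
    return pd.DataFrame({
        "species": species or [f"sp{i}" for i in range(n)],
        "het": het,
        "ab": ab,
        "iucn": iucn or ["LC"] * n,
    })


class TestQcExclusions:
    def test_extreme_heterozygosity_excluded(self):
        panel = small_panel([0.021, 0.019, 0.002], [0.2, 0.2, 0.2])
        clean, report = apply_qc_exclusions(panel)
        assert "sp0" not in set(clean["species"])
        assert report.loc[report["species"] == "sp0", "rule"].item() == "het"

    def test_allelic_balance_threshold_strict(self):
        panel = small_panel([0.002] * 4, [0.30, 0.35, 0.36, 0.37])
        clean, _ = apply_qc_exclusions(panel, ab_threshold=0.36)
        assert set(clean["ab"]) == {0.30, 0.35, 0.36}  # > 0.36 strict

    def test_threshold_is_mean_plus_sd_after_het_rule(self):
        het = [0.03, 0.001, 0.002, 0.003, 0.004]
        ab = [0.9, 0.20, 0.25, 0.22, 0.40]
        panel = small_panel(het, ab)
        clean, report = apply_qc_exclusions(panel)
        # species 0 leaves under the het rule, so its huge ab must not
        # inflate the allelic-balance statistics
        rest = np.array(ab[1:])
        expected = rest.mean() + rest.std(ddof=1)
        assert report.attrs["ab_threshold"] == pytest.approx(expected)
        assert set(clean["species"]) == {
            s for s, a in zip(panel["species"][1:], rest) if a <= expected
        }

    def test_clean_panel_unchanged_and_report_empty(self):
        panel = small_panel([0.002, 0.003], [0.2, 0.21])
        clean, report = apply_qc_exclusions(panel)
        assert len(clean) == 2 and len(report) == 0

    def test_idempotent_with_recorded_threshold(self, default_panel):
        clean, report = apply_qc_exclusions(default_panel)
        again, report2 = apply_qc_exclusions(
            clean, ab_threshold=report.attrs["ab_threshold"]
        )
        assert again.equals(clean.reset_index(drop=True))
        assert len(report2) == 0

    def test_empty_panel_errors(self):
        with pytest.raises(UndefinedValueError):
            apply_qc_exclusions(small_panel([], []))


class TestOrdinalRegression:
    def test_exact_linear_metric(self):
        panel = pd.DataFrame({
            "iucn": ["LC", "NT", "VU", "EN", "CR"],
            "het": [0.005, 0.004, 0.003, 0.002, 0.001],
        })
        fit = ordinal_iucn_regression(panel, "het")
        assert fit.slope == pytest.approx(-0.001)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value < 1e-6

    def test_constant_metric(self):
        panel = pd.DataFrame({
            "iucn": ["LC", "NT", "VU"], "het": [0.002] * 3,
        })
        fit = ordinal_iucn_regression(panel, "het")
        assert fit.slope == 0.0 and fit.r_squared == 0.0

    def test_matches_closed_form_ols_oracle(self):
        """Slope, R^2 and the slope t-test p-value agree with a direct
        normal-equations computation on a fixed synthetic panel."""
        panel = simulate_species_panel(PanelSimConfig(seed=31))
        fit = ordinal_iucn_regression(panel, "soh")
        sub = panel.dropna(subset=["soh"])
        x = sub["iucn"].map(IUCN_RANK).to_numpy(float)
        y = sub["soh"].to_numpy(float)
        n = len(x)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        ss_res = (resid**2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1 - ss_res / ss_tot
        se = np.sqrt(ss_res / (n - 2) / sxx)
        t = slope / se
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert fit.n == n
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-10)
        assert fit.p_value == pytest.approx(p, rel=1e-10)

    def test_dd_and_ew_records_excluded(self):
        panel = pd.DataFrame({
            "iucn": ["LC", "NT", "VU", "DD", "EW"],
            "het": [0.004, 0.003, 0.002, 0.9, 0.9],
        })
        fit = ordinal_iucn_regression(panel, "het")
        assert fit.n == 3 and fit.n_excluded == 2

    def test_single_category_degenerate(self):
        panel = pd.DataFrame({"iucn": ["LC"] * 5, "het": np.linspace(0.001, 0.005, 5)})
        with pytest.raises(DegenerateDataError):
            ordinal_iucn_regression(panel, "het")

    def test_positive_soh_trend_detected_with_power(self):
        """Under the default rank effect on SoH (+0.04 per category,
        s.d. 0.1, 105 species) the regression recovers a significantly
        positive slope in > 80% of simulations."""
        hits = 0
        n_sim = 200
        for seed in range(n_sim):
            panel = simulate_species_panel(PanelSimConfig(seed=seed))
            fit = ordinal_iucn_regression(panel, "soh")
            hits += fit.slope > 0 and fit.p_value < 0.05
        assert hits / n_sim > 0.8

    def test_negative_het_trend_direction(self):
        panel = simulate_species_panel(PanelSimConfig(seed=41))
        fit = ordinal_iucn_regression(panel, "het")
        assert fit.slope < 0


class TestGroupTTest:
    def make_panel(self, wild, captive):
        return pd.DataFrame({
            "born": ["wild"] * len(wild) + ["captive"] * len(captive),
            "het": list(wild) + list(captive),
        })

    def test_identical_groups(self):
        panel = self.make_panel([1, 2, 3], [1, 2, 3])
        res = group_ttest(panel, "het")
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_pooled_variance_formula(self):
        a, b = [1.0, 1.1, 0.9, 1.2], [1.4, 1.5, 1.3]
        res = group_ttest(self.make_panel(a, b), "het")
        na, nb = len(a), len(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p = 2 * stats.t.sf(abs(t), na + nb - 2)
        assert res.t == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_unknown_born_excluded(self):
        panel = pd.DataFrame({
            "born": ["wild", "wild", "captive", "captive", "unknown"],
            "het": [1.0, 1.2, 1.1, 0.9, 50.0],
        })
        res = group_ttest(panel, "het")
        assert res.n_a == 2 and res.n_b == 2

    def test_small_group_errors(self):
        with pytest.raises(UndefinedValueError):
            group_ttest(self.make_panel([1.0], [2.0, 3.0]), "het")


class TestPhenotypeScreen:
    def lc_panel(self, n=75, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "iucn": ["LC"] * n,
            "het": rng.lognormal(np.log(0.0026), 0.3, n),
            "soh": rng.beta(2, 8, n),
            "litter_size": rng.lognormal(1.0, 0.5, n),
            "body_mass": rng.lognormal(6.0, 1.5, n),
        })

    def test_self_correlation_is_one(self):
        panel = self.lc_panel()
        panel["het_copy"] = panel["het"]
        table = phenotype_correlation_table(panel, ["het_copy"], metrics=("het",))
        assert table.loc[0, "r"] == pytest.approx(1.0)

    def test_null_phenotypes_rarely_flagged(self):
        """Independent phenotypes at n = 75 stay unflagged after
        Bonferroni correction in >= 95% of simulated panels."""
        clean = 0
        n_seeds = 60
        for seed in range(n_seeds):
            table = phenotype_correlation_table(
                self.lc_panel(seed=seed), ["litter_size", "body_mass"]
            )
            clean += not table["bonferroni_significant"].any()
        assert clean / n_seeds >= 0.95

    def test_bonferroni_m_counts_phenotype_metric_pairs(self):
        table = phenotype_correlation_table(
            self.lc_panel(), ["litter_size", "body_mass"], metrics=("het", "soh")
        )
        assert table.attrs["bonferroni_m"] == 4

    def test_too_few_pairs_yield_undefined_row(self):
        panel = self.lc_panel(n=5)
        panel.loc[panel.index[:-2], "litter_size"] = np.nan
        table = phenotype_correlation_table(panel, ["litter_size"], metrics=("het",))
        assert np.isnan(table.loc[0, "r"])
        assert not table.loc[0, "bonferroni_significant"]

    def test_analytic_p_matches_permutation_oracle(self):
        """Two-sided Pearson p at n = 20 agrees with a 100k-permutation
        null within Monte-Carlo error."""
        rng = np.random.default_rng(3)
        n = 20
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        panel = pd.DataFrame({"iucn": ["LC"] * n, "het": y, "pheno": x})
        table = phenotype_correlation_table(panel, ["pheno"], metrics=("het",))
        r_obs, p_analytic = table.loc[0, "r"], table.loc[0, "p_value"]

        n_perm = 100_000
        perm_rows = np.array([rng.permutation(x) for _ in range(n_perm)])
        xc = perm_rows - perm_rows.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        r_perm = xc @ yc / (np.linalg.norm(xc, axis=1) * np.linalg.norm(yc))
        p_perm = (np.abs(r_perm) >= abs(r_obs)).mean()
        mc_sd = np.sqrt(p_analytic * (1 - p_analytic) / n_perm)
        assert abs(p_perm - p_analytic) < max(4 * mc_sd, 0.002)

    def test_scale_and_symmetry_invariance(self):
        panel = self.lc_panel()
        t1 = phenotype_correlation_table(panel, ["litter_size"], metrics=("het",))
        panel2 = panel.assign(litter_size=panel["litter_size"] * 1e3 + 7)
        t2 = phenotype_correlation_table(panel2, ["litter_size"], metrics=("het",))
        assert t1.loc[0, "r"] == pytest.approx(t2.loc[0, "r"])


class TestPanelSummary:
    def test_summary_bundle_on_default_panel(self, default_panel):
        out = panel_summary_statistics(default_panel)
        assert out["n_input"] == 105
        assert out["n_clean"] < 105  # QC removed the contaminated subset
        assert out["callable_vs_het"]["r"] < 0  # built-in confounder direction
        assert out["soh_vs_iucn"]["slope"] > 0
        assert out["het_vs_iucn"]["slope"] < 0
        assert 0 < out["lc_median_soh"] < 1
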