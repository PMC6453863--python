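"""Univariate tests and the nested mixed model, cross-checked against
scipy/statsmodels oracles."""

import numpy as np
import pandas as pd
import pytest

from strutflow.core import HierarchySpec
from strutflow.stats import (
    FULL_MODEL,
    TERM_CSA,
    TERM_TYPE,
    compare_univariate,
    fit_multilevel,
    select_model,
)
from strutflow.synthetic import simulate_hierarchical_ess

# sized so both this fitter and the statsmodels oracle converge crisply
SMALL_SPEC = HierarchySpec(
    n_animals=6, scaffolds_per_animal=1, cross_sections_per_scaffold=10,
    sectors_per_cross_section=24, sd_animal_pa=0.3, sd_scaffold_pa=0.15,
    sd_cross_section_pa=0.15, sd_sector_pa=0.5, seed=21,
    allocation=(("absorb_like",), ("absorb_like",), ("absorb_like",),
                ("arteriosorb_like",), ("arteriosorb_like",),
                ("arteriosorb_like",)),
)


@pytest.fixture(scope="module")
def small_records():
    records, _ = simulate_hierarchical_ess(SMALL_SPEC)
    return records


def statsmodels_fit(records, reml):
    import statsmodels.formula.api as smf

    df = records.copy()
    df["csa_c"] = df.cross_sectional_area - df.cross_sectional_area.mean()
    df["arte"] = (df.scaffold_type == "arteriosorb_like").astype(float)
    md = smf.mixedlm(
        "ess ~ arte * csa_c", df, groups="animal_id", re_formula="1",
        vc_formula={"scaffold": "0 + C(scaffold_id)",
                    "cs": "0 + C(cross_section_id)"},
    )
    return md.fit(reml=reml, method="lbfgs")


class TestUnivariate:
    def test_chi_square_perfect_association(self):
        res = compare_univariate([[10, 0], [0, 10]], kind="chi_square")
        assert res.statistic == pytest.approx(20.0)

    def test_chi_square_rejects_tiny_expected_counts(self):
        with pytest.raises(ValueError, match="expected"):
            compare_univariate([[1, 0], [0, 1]], kind="chi_square")

    def test_mann_whitney_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        res = compare_univariate(a, b, kind="mann_whitney")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert res.statistic == pytest.approx(float(ref.statistic))
        assert res.pvalue == pytest.approx(float(ref.pvalue))

    def test_mann_whitney_needs_two_groups(self):
        with pytest.raises(ValueError):
            compare_univariate([1.0, 2.0], kind="mann_whitney")

    def test_kruskal_three_groups(self):
        res = compare_univariate([1, 2, 3], [4, 5, 6], [7, 8, 9],
                                 kind="kruskal_wallis")
        assert res.pvalue < 0.05

    def test_ks_normality_accepts_normal_sample(self):
        rng = np.random.default_rng(1)
        res = compare_univariate(rng.normal(0.73, 0.3, 500),
                                 kind="ks_normality")
        assert res.pvalue > 0.05

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown test kind"):
            compare_univariate([1.0], kind="t_test")


class TestMixedModelOracle:
    @pytest.mark.parametrize("reml", [False, True])
    def test_matches_statsmodels(self, small_records, reml):
        res = fit_multilevel(small_records, reml=reml)
        ref = statsmodels_fit(small_records, reml)
        assert np.allclose(res.fixed_effects.estimate.to_numpy(),
                           ref.params.to_numpy()[:4], atol=1e-4)
        assert np.allclose(res.fixed_effects.se.to_numpy(),
                           ref.bse.to_numpy()[:4], rtol=5e-3)
        assert res.variance_components["residual"] == pytest.approx(
            float(ref.scale), rel=1e-3)
        # one scaffold per animal: only the animal + scaffold sum is
        # identified, so compare the sum rather than the split
        mine = (res.variance_components["animal"]
                + res.variance_components["scaffold"])
        # statsmodels orders vcomp alphabetically: "cs" before "scaffold"
        theirs = float(ref.cov_re.iloc[0, 0]) + float(ref.vcomp[1])
        assert mine == pytest.approx(theirs, rel=2e-2, abs=1e-4)
        assert res.variance_components["cross_section"] == pytest.approx(
            float(ref.vcomp[0]), rel=2e-2, abs=1e-4)

    def test_ml_loglik_matches_statsmodels(self, small_records):
        res = fit_multilevel(small_records, reml=False)
        ref = statsmodels_fit(small_records, False)
        assert res.log_likelihood == pytest.approx(float(ref.llf), abs=1e-3)

    def test_ols_limit_with_no_random_variation(self):
        spec = HierarchySpec(n_animals=8, cross_sections_per_scaffold=8,
                             sectors_per_cross_section=72,
                             sd_animal_pa=0.0, sd_scaffold_pa=0.0,
                             sd_cross_section_pa=0.0, sd_sector_pa=0.5,
                             seed=2)
        records, _ = simulate_hierarchical_ess(spec)
        res = fit_multilevel(records, reml=False)
        # with no grouping variance the GLS fit collapses to OLS
        x = np.column_stack([
            np.ones(len(records)),
            (records.scaffold_type == "arteriosorb_like").astype(float),
        ])
        csa = records.cross_sectional_area - records.cross_sectional_area.mean()
        x = np.column_stack([x, csa, x[:, 1] * csa])
        beta = np.linalg.lstsq(x, records.ess.to_numpy(), rcond=None)[0]
        assert np.allclose(res.fixed_effects.estimate.to_numpy(), beta,
                           atol=1e-8)
        assert set(res.singular) == {"animal", "scaffold", "cross_section"}

    def test_satterthwaite_dfs_track_the_design_level(self, small_records):
        res = fit_multilevel(small_records)
        type_df = res.coef(res.fixed_effects.term[1]).df
        csa_df = res.coef("cross_sectional_area_centered").df
        # the type contrast lives at the animal level (few df); CSA varies
        # across cross-sections (many df)
        assert type_df < 10
        assert csa_df > 15

    def test_nesting_violation_rejected(self, small_records):
        bad = small_records.copy()
        bad.loc[bad.index[0], "scaffold_id"] = bad.scaffold_id.max()
        with pytest.raises(ValueError, match="nested"):
            fit_multilevel(bad)

    def test_missing_column_rejected(self, small_records):
        with pytest.raises(ValueError, match="missing columns"):
            fit_multilevel(small_records.drop(columns=["ess"]))

    def test_n_starts_validated(self, small_records):
        with pytest.raises(ValueError, match="n_starts"):
            fit_multilevel(small_records, n_starts=0)

    def test_single_start_reaches_same_optimum(self, small_records):
        a = fit_multilevel(small_records, reml=False, n_starts=1)
        b = fit_multilevel(small_records, reml=False, n_starts=3)
        assert a.log_likelihood == pytest.approx(b.log_likelihood, abs=1e-6)


class TestModelSelection:
    def candidates(self, records):
        return [
            fit_multilevel(records, fixed_terms=(), reml=False),
            fit_multilevel(records, fixed_terms=(TERM_TYPE,), reml=False),
            fit_multilevel(records, fixed_terms=FULL_MODEL, reml=False),
        ]

    def test_ranking_and_lrt(self, small_records):
        out = select_model(self.candidates(small_records))
        assert len(out["table"]) == 3
        assert out["best"].fixed_terms in ((TERM_TYPE,), FULL_MODEL)
        lrt = out["lrt"]
        null_vs_type = lrt[(lrt.reduced == "") & (lrt.full == TERM_TYPE)]
        assert len(null_vs_type) == 1
        assert (lrt.statistic >= 0).all()

    def test_rejects_mixed_datasets(self, small_records):
        other, _ = simulate_hierarchical_ess(
            HierarchySpec(n_animals=6, cross_sections_per_scaffold=6,
                          sectors_per_cross_section=12, seed=99,
                          allocation=SMALL_SPEC.allocation))
        a = fit_multilevel(small_records, reml=False)
        b = fit_multilevel(other, reml=False)
        with pytest.raises(ValueError, match="different records"):
            select_model([a, b])

    def test_rejects_reml_candidates(self, small_records):
        a = fit_multilevel(small_records, reml=True)
        with pytest.raises(ValueError, match="ML"):
            select_model([a])

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            select_model([])
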