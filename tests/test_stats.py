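"""Factorial ANOVA / ANCOVA / Tukey machinery against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dystroflux.stats import ancova_lsmeans, tukey_posthoc, two_way_anova


def make_cohort(rng, n=8, geno_shift=0.0, age_shift=0.0, base=10.0, sd=1.0):
    rows = []
    for g in ("mdx", "control"):
        for a in ("juvenile", "adult"):
            mu = base + geno_shift * (g == "mdx") + age_shift * (a == "adult")
            for v in rng.normal(mu, sd, n):
                rows.append({"genotype": g, "age_group": a, "y": v})
    return pd.DataFrame(rows)


def p_for(table: pd.DataFrame, effect: str) -> float:
    return float(table.loc[table.effect == effect, "p"].iloc[0])


class TestTwoWayAnova:
    def test_identical_cells_give_null_pvalues(self):
        """All four cells share the same values: every F is 0, p is 1."""
        rows = [
            {"genotype": g, "age_group": a, "y": v}
            for g in ("mdx", "control")
            for a in ("juvenile", "adult")
            for v in (1.0, 2.0, 3.0)
        ]
        table = two_way_anova(pd.DataFrame(rows), "y")
        for effect in ("genotype", "age_group", "genotype:age_group"):
            assert p_for(table, effect) == pytest.approx(1.0, abs=1e-9)

    def test_power_for_large_genotype_shift(self, rng):
        """3-SD genotype shift, n=20/cell: detected at p<0.001 in ≥99% of sims."""
        hits = 0
        for _ in range(200):
            df = make_cohort(rng, n=20, geno_shift=3.0)
            table = two_way_anova(df, "y")
            hits += p_for(table, "genotype") < 1e-3
            assert p_for(table, "genotype:age_group") >= 0  # fitted
        assert hits / 200 >= 0.99

    def test_matches_hand_computed_sums_of_squares(self, rng):
        """Balanced 12-row fixture: agrees with the classical ANOVA algebra."""
        df = make_cohort(rng, n=3, geno_shift=1.0, age_shift=0.5)
        table = two_way_anova(df, "y").set_index("effect")

        y = df["y"].to_numpy()
        grand = y.mean()
        cell = df.groupby(["genotype", "age_group"])["y"].mean()
        g_mean = df.groupby("genotype")["y"].mean()
        a_mean = df.groupby("age_group")["y"].mean()
        ss_g = sum(6 * (g_mean[g] - grand) ** 2 for g in g_mean.index)
        ss_a = sum(6 * (a_mean[a] - grand) ** 2 for a in a_mean.index)
        ss_ga = sum(
            3 * (cell[g, a] - g_mean[g] - a_mean[a] + grand) ** 2
            for g, a in cell.index
        )
        ss_e = sum(
            (row.y - cell[row.genotype, row.age_group]) ** 2
            for row in df.itertuples()
        )
        mse = ss_e / 8
        for effect, ss in (
            ("genotype", ss_g), ("age_group", ss_a), ("genotype:age_group", ss_ga)
        ):
            f_hand = ss / mse
            assert table.loc[effect, "F"] == pytest.approx(f_hand, rel=1e-9)
            assert table.loc[effect, "p"] == pytest.approx(
                sps.f.sf(f_hand, 1, 8), rel=1e-9
            )

    def test_empty_cell_rejected(self, rng):
        df = make_cohort(rng, n=3)
        df = df[~((df.genotype == "mdx") & (df.age_group == "adult"))]
        with pytest.raises(ValueError, match="cell"):
            two_way_anova(df, "y")

    def test_single_level_factor_dropped(self, rng):
        """A juvenile-only design is analysed for genotype alone."""
        df = make_cohort(rng, n=5)
        table = two_way_anova(df[df.age_group == "juvenile"], "y")
        assert set(table.effect) == {"genotype", "Residual"}


class TestAncovaLsMeans:
    def test_zero_variance_covariate_reduces_to_anova(self, rng):
        df = make_cohort(rng, n=6, geno_shift=1.0).assign(ffm=1.0)
        with pytest.warns(UserWarning, match="zero variance"):
            res = ancova_lsmeans(df, "y", covariates=("ffm",))
        raw = df.groupby(["genotype", "age_group"])["y"].mean()
        for _, row in res.means.iterrows():
            assert row.lsmean == pytest.approx(
                raw[row.genotype, row.age_group], abs=1e-10
            )
        anova = two_way_anova(df, "y").set_index("effect")
        merged = res.anova.set_index("effect")
        for effect in ("genotype", "age_group", "genotype:age_group"):
            assert merged.loc[effect, "p"] == pytest.approx(
                anova.loc[effect, "p"], rel=1e-9
            )

    def test_recovers_injected_slope_and_group_effect(self, rng):
        """y = 2·FFM + 1.5·[mdx] + noise: slope and adjusted difference recover."""
        df = make_cohort(rng, n=30, geno_shift=0.0)
        df["ffm"] = rng.normal(20, 3, len(df))
        df["y"] = 1.5 * (df.genotype == "mdx") + 2.0 * df.ffm + rng.normal(0, 0.5, len(df))
        res = ancova_lsmeans(df, "y", covariates=("ffm",))
        assert res.slopes["ffm"] == pytest.approx(2.0, abs=0.05)
        adj = res.means.groupby("genotype")["lsmean"].mean()
        assert adj["mdx"] - adj["control"] == pytest.approx(1.5, abs=0.3)

    def test_lsmeans_invariant_to_covariate_rescaling(self, rng):
        df = make_cohort(rng, n=10, geno_shift=1.0)
        df["ffm"] = rng.normal(20, 3, len(df))
        df["y"] = df["y"] + 0.3 * df["ffm"]
        res1 = ancova_lsmeans(df, "y", covariates=("ffm",))
        df2 = df.assign(ffm=df.ffm * 10 + 5)
        res2 = ancova_lsmeans(df2, "y", covariates=("ffm",))
        assert np.allclose(res1.means.lsmean, res2.means.lsmean, atol=1e-8)

    def test_stratifies_on_covariate_factor_interaction(self, rng):
        """Age-dependent covariate slope triggers per-age stratified fits."""
        df = make_cohort(rng, n=25)
        df["ffm"] = rng.normal(20, 3, len(df))
        slope = np.where(df.age_group == "adult", 3.0, 0.2)
        df["y"] = slope * df.ffm + rng.normal(0, 0.5, len(df))
        res = ancova_lsmeans(df, "y", covariates=("ffm",))
        assert res.stratified and "age_group" in res.stratified_by
        assert set(res.strata["age_group"]) == {"juvenile", "adult"}

    def test_collinear_covariates_rejected(self, rng):
        df = make_cohort(rng, n=6)
        df["ffm"] = rng.normal(20, 3, len(df))
        df["ffm2"] = 2 * df["ffm"]
        with pytest.raises(ValueError, match="collinear"):
            ancova_lsmeans(df, "y", covariates=("ffm", "ffm2"))

    def test_ffm_length_correlation_pattern_in_simulated_cohort(self):
        """The generated juvenile cohort reproduces the strong FFM–length
        correlation used to justify length adjustment."""
        from dystroflux.synthetic import default_cohort_spec, simulate_cohort

        cohort = simulate_cohort(default_cohort_spec(seed=11, n=40))
        juv = cohort[cohort.age_group == "juvenile"]
        r = np.corrcoef(juv.ffm_g, juv.body_len_mm)[0, 1]
        assert r > 0.9


class TestTukey:
    @staticmethod
    def toy(rng):
        rows = []
        for g, mu in (("a", 0.0), ("b", 0.8), ("c", 3.0)):
            for v in rng.normal(mu, 1.0, 10):
                rows.append({"group": g, "y": v})
        return pd.DataFrame(rows)

    def test_identical_groups_all_p_near_one(self):
        rows = [
            {"group": g, "y": v} for g in "abc" for v in (1.0, 2.0, 3.0, 4.0)
        ]
        out = tukey_posthoc(pd.DataFrame(rows), "y", factors=("group",))
        assert (out.p_adj > 0.98).all()

    def test_matches_studentized_range_oracle(self, rng):
        """Adjusted p equals the direct studentized-range computation."""
        df = self.toy(rng)
        out = tukey_posthoc(df, "y", factors=("group",))
        means = df.groupby("group")["y"].mean()
        mse = df.groupby("group")["y"].var(ddof=1).mean()
        n, k, dof = 10, 3, 27
        for _, row in out.iterrows():
            diff = abs(means[row.group2] - means[row.group1])
            q_obs = diff / np.sqrt(mse / n)
            p_hand = sps.studentized_range.sf(q_obs, k, dof)
            assert row.p_adj == pytest.approx(p_hand, abs=1e-4)

    def test_adjusted_p_at_least_pairwise_t(self, rng):
        df = self.toy(rng)
        out = tukey_posthoc(df, "y", factors=("group",))
        for _, row in out.iterrows():
            a = df.loc[df.group == row.group1, "y"]
            b = df.loc[df.group == row.group2, "y"]
            p_t = sps.ttest_ind(a, b).pvalue
            assert row.p_adj >= p_t - 1e-6

    def test_requires_two_groups(self):
        df = pd.DataFrame({"group": ["a"] * 4, "y": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError):
            tukey_posthoc(df, "y", factors=("group",))
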