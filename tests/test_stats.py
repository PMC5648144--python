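import numpy as np
import pandas as pd
import pytest

from enmfactorial.stats import (
    arcsine_transform,
    rm_anova,
    summarize_pairwise_tau,
)


def simulate_table(n_subjects, a=3, b=4, seed=0, subject_sd=1.0, noise_sd=1.0,
                   a_effect=None, cov=None):
    """Long table: per-subject offset + optional factor-A effect + noise."""
    rng = np.random.default_rng(seed)
    rows = []
    offsets = rng.normal(0, subject_sd, n_subjects)
    a_eff = a_effect if a_effect is not None else np.zeros(a)
    for s in range(n_subjects):
        if cov is not None:
            noise = rng.multivariate_normal(np.zeros(a * b), cov)
        else:
            noise = rng.normal(0, noise_sd, a * b)
        k = 0
        for ia in range(a):
            for ib in range(b):
                rows.append(
                    {
                        "species": f"s{s}",
                        "predictor": f"A{ia}",
                        "algorithm": f"B{ib}",
                        "y": offsets[s] + a_eff[ia] + noise[k],
                    }
                )
                k += 1
    return pd.DataFrame(rows)


def brute_force_ss(table):
    """Definitional sums of squares from cell means (independent oracle)."""
    piv = table.pivot_table(index="species", columns=["predictor", "algorithm"],
                            values="y")
    a_levels = sorted({c[0] for c in piv.columns})
    b_levels = sorted({c[1] for c in piv.columns})
    n, a, b = len(piv), len(a_levels), len(b_levels)
    Y = np.array(
        [[[piv.loc[s, (la, lb)] for lb in b_levels] for la in a_levels]
         for s in piv.index]
    )
    g = Y.mean()
    ss_a = n * b * sum((Y[:, i, :].mean() - g) ** 2 for i in range(a))
    ss_b = n * a * sum((Y[:, :, j].mean() - g) ** 2 for j in range(b))
    ss_ab = n * sum(
        (Y[:, i, j].mean() - Y[:, i, :].mean() - Y[:, :, j].mean() + g) ** 2
        for i in range(a)
        for j in range(b)
    )
    return ss_a, ss_b, ss_ab


class TestRMAnova:
    def test_two_level_effect_has_trivial_sphericity(self):
        t = simulate_table(8, a=2, b=3, seed=1)
        res = rm_anova(t, "y")
        eff = res.effects["Predictor"]
        assert eff.mauchly_w == 1.0
        assert eff.gg_epsilon == 1.0

    def test_epsilon_bounds(self):
        for seed in range(5):
            t = simulate_table(10, seed=seed)
            res = rm_anova(t, "y")
            for name, k in (("Predictor", 3), ("Algorithm", 4)):
                eps = res.effects[name].gg_epsilon
                assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_ss_match_definitional_oracle(self):
        t = simulate_table(6, a=3, b=2, seed=2, a_effect=np.array([0.0, 0.5, 1.0]))
        res = rm_anova(t, "y")
        ss_a, ss_b, ss_ab = brute_force_ss(t)
        assert res.effects["Predictor"].ss == pytest.approx(ss_a)
        assert res.effects["Algorithm"].ss == pytest.approx(ss_b)
        assert res.effects["PredictorxAlgorithm"].ss == pytest.approx(ss_ab)

    def test_ss_decomposition_identity(self):
        t = simulate_table(9, seed=3)
        res = rm_anova(t, "y")
        parts = res.ss_subject + sum(
            e.ss + e.ss_error for e in res.effects.values()
        )
        assert parts == pytest.approx(res.ss_total)

    def test_detects_real_effect(self):
        t = simulate_table(20, seed=4, a_effect=np.array([0.0, 1.0, 2.0]),
                           noise_sd=0.5)
        res = rm_anova(t, "y")
        assert res.effects["Predictor"].p_reported < 1e-4
        assert res.effects["Algorithm"].p_reported > 0.01

    def test_type_one_error_calibrated_under_null(self):
        # per-subject offsets + iid noise: both main effects should reject
        # at close to the nominal 5% rate
        n_tables = 500
        rejections = np.zeros(2)
        for seed in range(n_tables):
            t = simulate_table(12, seed=seed + 1000)
            res = rm_anova(t, "y")
            rejections[0] += res.effects["Predictor"].p_uncorrected < 0.05
            rejections[1] += res.effects["Algorithm"].p_uncorrected < 0.05
        rates = rejections / n_tables
        # binomial 99.9% band around 0.05 with n=500 is about +/- 0.032
        assert np.all(np.abs(rates - 0.05) < 0.035)

    def test_gg_correction_is_conservative_under_sphericity_violation(self):
        # compound-asymmetric covariance across the 12 cells violates
        # sphericity; GG-corrected rejections never exceed uncorrected ones
        rng = np.random.default_rng(0)
        sd = np.linspace(0.3, 3.0, 12)
        base = np.full((12, 12), 0.5)
        np.fill_diagonal(base, 1.0)
        cov = base * np.outer(sd, sd)
        unc = gg = 0
        for seed in range(300):
            t = simulate_table(10, seed=seed + 5000, cov=cov)
            res = rm_anova(t, "y")
            eff = res.effects["Algorithm"]
            unc += eff.p_uncorrected < 0.05
            gg += eff.p_gg < 0.05
        assert gg <= unc

    def test_unbalanced_table_rejected(self):
        t = simulate_table(5, seed=6).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova(t, "y")

    def test_matches_pingouin_two_way(self):
        pingouin = pytest.importorskip("pingouin")
        t = simulate_table(12, seed=7, a_effect=np.array([0.0, 0.3, 0.6]))
        res = rm_anova(t, "y")
        pg = pingouin.rm_anova(
            data=t, dv="y", within=["predictor", "algorithm"],
            subject="species", detailed=True,
        )
        for name, pg_name in [
            ("Predictor", "predictor"),
            ("Algorithm", "algorithm"),
            ("PredictorxAlgorithm", "predictor * algorithm"),
        ]:
            row = pg[pg["Source"] == pg_name].iloc[0]
            assert res.effects[name].F == pytest.approx(row["F"], rel=1e-6)
            assert res.effects[name].p_uncorrected == pytest.approx(
                row["p_unc"], rel=1e-6
            )

    def test_epsilon_matches_pingouin_one_way(self):
        pingouin = pytest.importorskip("pingouin")
        t = simulate_table(12, seed=8)
        res = rm_anova(t, "y")
        # collapse to the Algorithm main effect (mean over predictor levels)
        coll = t.groupby(["species", "algorithm"], as_index=False)["y"].mean()
        eps_pg = pingouin.epsilon(
            coll, subject="species", within="algorithm", dv="y",
            correction="gg",
        )
        assert res.effects["Algorithm"].gg_epsilon == pytest.approx(
            float(eps_pg), rel=1e-6
        )
        sph = pingouin.sphericity(
            coll, subject="species", within="algorithm", dv="y"
        )
        assert res.effects["Algorithm"].mauchly_w == pytest.approx(sph.W, rel=1e-6)
        # pingouin adds a higher-order term to the chi-square approximation
        assert res.effects["Algorithm"].mauchly_p == pytest.approx(
            sph.pval, abs=0.01
        )


class TestArcsine:
    def test_fixed_points(self):
        assert arcsine_transform(0.0) == 0.0
        assert arcsine_transform(1.0) == pytest.approx(np.pi / 2)
        assert arcsine_transform(-1.0) == pytest.approx(-np.pi / 2)

    def test_monotone(self):
        x = np.linspace(-1, 1, 50)
        assert np.all(np.diff(arcsine_transform(x)) > 0)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            arcsine_transform(1.5)

    def test_sqrt_variant_clips_negatives(self):
        out = arcsine_transform(np.array([-0.5, 0.25]), sqrt_variant=True)
        assert out[0] == 0.0
        assert out[1] == pytest.approx(np.arcsin(0.5))


class TestTauSummary:
    def frame(self, values, pair="C-E"):
        return pd.DataFrame(
            {
                "comparison": "predictor_pair",
                "within": "GAM",
                "pair": pair,
                "tau": values,
            }
        )

    def test_degenerate_cell(self):
        out = summarize_pairwise_tau(self.frame([1.0, 1.0, 1.0]),
                                     group=("within", "pair"))
        assert out["mean"].iloc[0] == 1.0
        assert out["ci_high"].iloc[0] - out["ci_low"].iloc[0] == 0.0

    def test_arithmetic(self):
        out = summarize_pairwise_tau(self.frame([0.2, 0.4, 0.6]),
                                     group=("within", "pair"))
        assert out["mean"].iloc[0] == pytest.approx(0.4)
        half = 1.959963984540054 * 0.2 / np.sqrt(3)
        assert out["ci_high"].iloc[0] - out["mean"].iloc[0] == pytest.approx(half)

    def test_ci_shrinks_with_sample_size(self):
        rng = np.random.default_rng(0)
        widths = []
        for n in (10, 40, 160):
            vals = rng.normal(0.5, 0.1, n)
            out = summarize_pairwise_tau(self.frame(vals),
                                         group=("within", "pair"))
            widths.append(float((out["ci_high"] - out["ci_low"]).iloc[0]))
        assert widths[0] > widths[1] > widths[2]
        # roughly 1/sqrt(n): quadrupling n about halves the width
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.5)

    def test_small_cell_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            out = summarize_pairwise_tau(self.frame([0.5]),
                                         group=("within", "pair"))
        assert out.empty
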