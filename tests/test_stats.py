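"""Model battery: exact-test oracles, parameter recovery, invariances."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import nucleofish as nf


def fisher_p_by_enumeration(table) -> float:
    """Independent oracle: sum hypergeometric probabilities of all tables
    with the observed margins that are no more probable than the observed
    one (two-sided Fisher convention)."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    n, r1, c1 = a + b + c + d, a + b, a + c
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def two_group_table(rng, n_per_group, means, sds=(1.0, 1.0), vol_slope=0.0):
    rows = []
    for g, mu, sd in zip(("matrepKO", "patrepKO"), means, sds):
        vol = np.exp(rng.normal(6.1, 0.2, n_per_group))
        d = mu + vol_slope * (vol - vol.mean()) + sd * rng.standard_normal(n_per_group)
        for i in range(n_per_group):
            rows.append((f"{g}_c{i}", g, g, "a1", d[i], vol[i]))
    return pd.DataFrame(rows, columns=["cell_id", "line_id", "genotype",
                                       "allele_id", "distance_um", "volume_um3"])


class TestDistanceModel:
    def test_identical_groups_zero_noise_slope_exactly_zero(self):
        rng = np.random.default_rng(0)
        t = two_group_table(rng, 50, (1.7, 1.7), sds=(0.0, 0.0))
        res = nf.fit_distance_model(t)
        assert abs(res.term("genotype[patrepKO]")["estimate"]) < 1e-10

    def test_recovers_simulated_effect(self):
        cfg = nf.SimulationConfig(seed=31, n_cells=400)
        t = nf.simulate_allele_table(cfg, groups=["matrepKO", "patrepKO"])
        res = nf.fit_distance_model(t)
        true_diff = (t[t.genotype == "patrepKO"].distance_um.mean()
                     - t[t.genotype == "matrepKO"].distance_um.mean())
        lo, hi = res.conf_int("genotype[patrepKO]")
        assert lo < true_diff < hi

    def test_slope_invariant_under_volume_shift(self):
        rng = np.random.default_rng(1)
        t = two_group_table(rng, 80, (1.58, 1.81), vol_slope=0.001)
        r1 = nf.fit_distance_model(t)
        t2 = t.assign(volume_um3=t.volume_um3 + 500.0)
        r2 = nf.fit_distance_model(t2)
        assert r1.term("genotype[patrepKO]")["estimate"] == pytest.approx(
            r2.term("genotype[patrepKO]")["estimate"], abs=1e-8)

    def test_single_level_rejected(self):
        rng = np.random.default_rng(2)
        t = two_group_table(rng, 10, (1.7, 1.7))
        with pytest.raises(ValueError, match="single level"):
            nf.DistanceModel(t[t.genotype == "matrepKO"])

    def test_reference_is_paternal_pattern_group(self):
        # positive slope must mean "maternal alleles further from border"
        rng = np.random.default_rng(3)
        t = two_group_table(rng, 200, (1.58, 1.81))
        res = nf.fit_distance_model(t)
        assert res.term("genotype[patrepKO]")["estimate"] > 0


class TestMixedDistanceModel:
    @staticmethod
    def _paired_table(rng, n_cells, cell_sd, resid_sd=0.5):
        cell_eff = cell_sd * rng.standard_normal(n_cells)
        rows = []
        for i in range(n_cells):
            vol = float(np.exp(rng.normal(6.1, 0.2)))
            n_expr = rng.integers(0, 3)
            for j in range(2):
                d = 1.5 + 0.2 * n_expr + cell_eff[i] + resid_sd * rng.standard_normal()
                rows.append((f"c{i}", d, vol, n_expr))
        return pd.DataFrame(rows, columns=["cell_id", "distance_um",
                                           "volume_um3", "n_expressed"])

    def test_zero_variance_matches_ols(self):
        rng = np.random.default_rng(4)
        t = self._paired_table(rng, 150, cell_sd=0.0)
        mixed = nf.fit_mixed_distance_model(t)
        ols = nf.fit_distance_model(t, predictor="n_expressed")
        for term in ("n_expressed[1]", "n_expressed[2]"):
            assert mixed.term(term)["estimate"] == pytest.approx(
                ols.term(term)["estimate"], abs=1e-4)

    def test_recovers_cell_intercept_sd(self):
        rng = np.random.default_rng(5)
        t = self._paired_table(rng, 500, cell_sd=0.5)
        res = nf.fit_mixed_distance_model(t)
        assert res.random_intercept_sd == pytest.approx(0.5, rel=0.2)
        assert res.n_cells == 500 < res.n_obs

    def test_singleton_cells_fall_back_to_ols(self):
        rng = np.random.default_rng(6)
        t = self._paired_table(rng, 60, cell_sd=0.3)
        t = t.groupby("cell_id", as_index=False).first()
        with pytest.warns(UserWarning, match="singleton|one allele"):
            res = nf.fit_mixed_distance_model(t)
        assert res.family == "linear"

    def test_matches_lme4_reference_fit(self, tmp_path):
        # independent cross-check against the R mixed-model reference
        rng = np.random.default_rng(7)
        t = self._paired_table(rng, 120, cell_sd=0.4)
        res = nf.fit_mixed_distance_model(t)
        csv = tmp_path / "table.csv"
        t.to_csv(csv, index=False)
        rout = tmp_path / "coef.csv"
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(distance_um ~ factor(n_expressed) + volume_um3
                      + (1 | cell_id), data = d, REML = TRUE)
            fe <- fixef(m)
            sd_re <- sqrt(unlist(VarCorr(m))[1])
            write.csv(data.frame(term = c(names(fe), "re_sd"),
                                 value = c(fe, sd_re)),
                      "{rout}", row.names = FALSE)
        """)
        rfile = tmp_path / "fit.R"
        rfile.write_text(script)
        subprocess.run(["Rscript", "--vanilla", str(rfile)], check=True,
                       capture_output=True)
        ref = pd.read_csv(rout).set_index("term")["value"]
        assert res.term("n_expressed[1]")["estimate"] == pytest.approx(
            ref["factor(n_expressed)1"], abs=1e-3)
        assert res.term("n_expressed[2]")["estimate"] == pytest.approx(
            ref["factor(n_expressed)2"], abs=1e-3)
        assert res.term("volume_um3")["estimate"] == pytest.approx(
            ref["volume_um3"], abs=1e-5)
        assert res.random_intercept_sd == pytest.approx(ref["re_sd"], abs=5e-3)


class TestExpressionModel:
    @staticmethod
    def _logit_table(rng, n, slope):
        d = rng.uniform(0.0, 4.0, n)
        vol = np.exp(rng.normal(6.1, 0.2, n))
        p = 1.0 / (1.0 + np.exp(-(-0.5 + slope * d)))
        return pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(n)],
            "distance_um": d, "volume_um3": vol,
            "expressed": rng.random(n) < p,
        })

    def test_null_slope_ci_covers_zero(self):
        rng = np.random.default_rng(8)
        res = nf.fit_expression_model(self._logit_table(rng, 2000, 0.0))
        lo, hi = res.conf_int("distance_um")
        assert lo < 0 < hi

    def test_recovers_unit_slope(self):
        rng = np.random.default_rng(9)
        res = nf.fit_expression_model(self._logit_table(rng, 2000, 1.0))
        lo, hi = res.conf_int("distance_um")
        assert lo < 1.0 < hi

    def test_complete_separation_diagnosed(self):
        t = pd.DataFrame({"cell_id": list("abcdefgh"),
                          "distance_um": [0.1, 0.2, 0.3, 0.4, 2.1, 2.2, 2.3, 2.4],
                          "expressed": [False] * 4 + [True] * 4})
        with pytest.raises(ValueError, match="separation"):
            nf.fit_expression_model(t, covariate=None)

    def test_single_class_rejected(self):
        t = pd.DataFrame({"cell_id": ["a", "b"], "distance_um": [1.0, 2.0],
                          "volume_um3": [400.0, 410.0],
                          "expressed": [True, True]})
        with pytest.raises(ValueError, match="single class"):
            nf.ExpressionModel(t)


class TestFisherNearFar:
    def test_perfect_independence(self):
        log2_or, p = nf.fisher_near_far([[10, 10], [10, 10]])
        assert log2_or == 0.0
        assert p == 1.0

    def test_p_matches_enumeration(self):
        log2_or, p = nf.fisher_near_far([[12, 5], [7, 9]])
        assert p == pytest.approx(fisher_p_by_enumeration([[12, 5], [7, 9]]),
                                  abs=1e-12)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            t = rng.integers(0, 16, (2, 2))
            if t.sum() == 0:
                continue
            _, p = nf.fisher_near_far(t)
            assert p == pytest.approx(fisher_p_by_enumeration(t), abs=1e-10)

    def test_zero_cell_infinite_or(self):
        log2_or, p = nf.fisher_near_far([[5, 0], [2, 7]])
        assert np.isinf(log2_or) and log2_or > 0
        assert 0 <= p <= 1

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            nf.fisher_near_far([[1, 2, 3], [4, 5, 6]])


class TestShellChisq:
    def test_equal_counts_zero_statistic(self):
        chi2, df, p = nf.shell_chisq([[10, 10, 10], [10, 10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert df == 2 and p == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        obs = np.array([[20, 15, 10], [18, 16, 11]], float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        by_hand = ((obs - expected) ** 2 / expected).sum()
        chi2, df, _ = nf.shell_chisq(obs)
        assert chi2 == pytest.approx(by_hand, abs=1e-12)
        assert df == 2

    def test_permutation_invariance(self):
        obs = [[20, 15, 10], [18, 16, 11]]
        chi2, *_ = nf.shell_chisq(obs)
        perm = [[10, 20, 15], [11, 18, 16]]
        chi2p, *_ = nf.shell_chisq(perm)
        flipped = [[18, 16, 11], [20, 15, 10]]
        chi2f, *_ = nf.shell_chisq(flipped)
        assert chi2 == pytest.approx(chi2p) == pytest.approx(chi2f)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            nf.shell_chisq([[0, 5, 3], [0, 2, 4]])


class TestSummaries:
    def test_mean_and_sample_sd(self):
        t = pd.DataFrame({"genotype": ["WT"] * 3, "distance_um": [1.0, 2.0, 3.0]})
        s = nf.summarize_groups(t)
        assert s["mean"].iloc[0] == pytest.approx(2.0)
        assert s["sd"].iloc[0] == pytest.approx(1.0)
        assert s["n"].iloc[0] == 3

    def test_expression_state_counts(self, allele_table):
        counts = nf.expression_state_counts(allele_table)
        total_cells = allele_table["cell_id"].nunique()
        state_cols = [c for c in counts.columns if c != "line_id"]
        assert counts[state_cols].to_numpy().sum() == total_cells
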