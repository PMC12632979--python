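"""Batch averaging, mixed-model hit calling, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest

from oracles import bh_step_up, reml_log_likelihood
from targetscreen import RunConfig, bh_adjust
from targetscreen.phenotypes import (analyze_assays, batch_log2fc, call_hits,
                                     fit_random_intercept_lmm,
                                     marginal_mean_tests)
from targetscreen.simulate import simulate_all

from conftest import small_sim_config


def _assay_table(target_reps, control_reps, assay="a", cell="scramble"):
    rows = []
    for b, (treps, creps) in enumerate(zip(target_reps, control_reps)):
        for r, v in enumerate(treps):
            rows.append({"assay": assay, "target": "T01", "cell_line": cell,
                         "dose": np.nan, "batch": f"b{b}", "replicate": f"r{r}",
                         "value": v})
        for r, v in enumerate(creps):
            rows.append({"assay": assay, "target": "ctrl", "cell_line": cell,
                         "dose": np.nan, "batch": f"b{b}", "replicate": f"r{r}",
                         "value": v})
    return pd.DataFrame(rows)


class TestBatchLog2fc:
    @pytest.mark.parametrize(
        "treps, creps, expected",
        [(((2, 2, 2),), ((2, 2, 2),), 0.0),
         (((4, 4),), ((2, 2),), 1.0),
         (((3, 5),), ((1, 3),), 1.0)],  # log2(mean 4 / mean 2)
    )
    def test_known_values(self, treps, creps, expected):
        fc = batch_log2fc(_assay_table(treps, creps))
        assert len(fc) == 1
        assert fc.loc[0, "log2fc"] == pytest.approx(expected)

    def test_missing_control_names_stratum(self):
        table = _assay_table(((2, 2),), ((2, 2),))
        table = table[table["target"] != "ctrl"]
        with pytest.raises(ValueError, match="no control rows"):
            batch_log2fc(table)

    def test_one_record_per_batch(self):
        fc = batch_log2fc(_assay_table(((2,), (4,), (8,)), ((1,), (1,), (1,))))
        assert list(fc["log2fc"]) == pytest.approx([1.0, 2.0, 3.0])


def _fc_records(effects, batch_sd, resid_sd, n_batches, rng,
                cell_lines=("scramble",), assay="a"):
    """log2FC records with a shared per-batch intercept, built directly."""
    rows = []
    b_int = rng.normal(0, batch_sd, n_batches)
    for b in range(n_batches):
        for line in cell_lines:
            for target, beta in effects.items():
                rows.append({"assay": assay, "target": target,
                             "cell_line": line, "dose": np.nan,
                             "batch": f"b{b}",
                             "log2fc": beta + b_int[b]
                             + rng.normal(0, resid_sd)})
    return pd.DataFrame(rows)


class TestLmm:
    def test_zero_batch_spread_gives_zero_variance_and_cell_means(self):
        # engineer exactly equal batch means: between-batch spread is zero
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.2, (6, 2))
        noise -= noise.mean(axis=1, keepdims=True)
        rows = []
        for b in range(6):
            for j, (t, beta) in enumerate((("T01", 0.5), ("T02", -0.2))):
                rows.append({"assay": "a", "target": t, "cell_line": "s",
                             "dose": np.nan, "batch": f"b{b}",
                             "log2fc": beta + noise[b, j]})
        fc = pd.DataFrame(rows)
        fit = fit_random_intercept_lmm(fc, "a")
        assert fit.batch_var == 0.0
        est = fit.effects.set_index("target")["estimate"]
        means = fc.groupby("target")["log2fc"].mean()
        assert est["T01"] == pytest.approx(means["T01"], abs=1e-10)
        assert est["T02"] == pytest.approx(means["T02"], abs=1e-10)

    def test_recovers_planted_effect_within_3_se(self):
        rng = np.random.default_rng(2)
        fc = _fc_records({"T01": 1.0, "T02": 0.0}, 0.5, 0.1, 50, rng)
        fit = fit_random_intercept_lmm(fc, "a")
        row = fit.effects.set_index("target").loc["T01"]
        assert abs(row["estimate"] - 1.0) < 3 * row["se"]
        assert fit.batch_var > 0

    def test_reml_criterion_beats_grid_search(self):
        """Returned variance estimates maximize the restricted likelihood."""
        rng = np.random.default_rng(3)
        fc = _fc_records({"T01": 0.4, "T02": -0.4}, 0.4, 0.3, 4, rng)
        fit = fit_random_intercept_lmm(fc, "a")
        cell = fc["target"]
        X = pd.get_dummies(cell, dtype=float).to_numpy()
        y = fc["log2fc"].to_numpy()
        groups = fc["batch"].to_numpy()
        ll_fit = reml_log_likelihood(y, X, groups, fit.batch_var, fit.resid_var)
        grid = np.linspace(0.01, 1.0, 100)
        ll_grid = max(
            reml_log_likelihood(y, X, groups, vb ** 2, ve ** 2)
            for vb in grid for ve in grid)
        assert ll_fit >= ll_grid - 1e-6

    def test_single_batch_downgrades_to_ols(self, caplog):
        rng = np.random.default_rng(4)
        fc = _fc_records({"T01": 1.0}, 0.0, 0.1, 1, rng)
        fit = fit_random_intercept_lmm(fc, "a")
        assert fit.method == "ols"
        assert fit.n_batches == 1

    def test_boundary_lmm_equals_ols_exactly(self):
        """With zero between-batch spread the mixed model reduces to OLS."""
        rng = np.random.default_rng(5)
        fc = _fc_records({"T01": 0.3, "T02": 0.1}, 0.0, 0.2, 6, rng)
        fit = fit_random_intercept_lmm(fc, "a")
        import statsmodels.api as sm
        X = pd.get_dummies(fc["target"], dtype=float).to_numpy()
        ols = sm.OLS(fc["log2fc"].to_numpy(), X).fit()
        est = fit.effects.sort_values("target")["estimate"].to_numpy()
        np.testing.assert_allclose(est, ols.params, rtol=0, atol=1e-12)


class TestMarginalTests:
    def test_zero_estimate_gives_p_one(self):
        fc = pd.DataFrame({"assay": "a", "target": "T01",
                           "cell_line": "scramble", "dose": np.nan,
                           "batch": [f"b{i}" for i in range(4)],
                           "log2fc": [0.1, -0.1, 0.1, -0.1]})
        fit = fit_random_intercept_lmm(fc, "a")
        out = marginal_mean_tests(fit)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_1_96_se_gives_p_005(self):
        fc = pd.DataFrame({"assay": "a", "target": "T01",
                           "cell_line": "scramble", "dose": np.nan,
                           "batch": [f"b{i}" for i in range(40)],
                           "log2fc": np.zeros(40)})
        fit = fit_random_intercept_lmm(fc, "a")
        # construct the Wald ratio directly: estimate = 1.96 * se
        fit.effects.loc[0, "se"] = 1.0
        fit.effects.loc[0, "estimate"] = 1.96
        out = marginal_mean_tests(fit)
        assert out.loc[0, "p"] == pytest.approx(0.05, abs=2e-4)

    def test_null_rejection_rate_calibrated(self):
        """Raw p < 0.05 rejection rate under the null stays near nominal."""
        rng = np.random.default_rng(6)
        ps = []
        for stratum in range(25):  # 25 strata x 20 null targets
            effects = {f"T{i:02d}": 0.0 for i in range(20)}
            fc = _fc_records(effects, 0.3, 0.2, 10, rng,
                             assay=f"a{stratum}")
            fit = fit_random_intercept_lmm(fc, f"a{stratum}")
            ps.extend(marginal_mean_tests(fit)["p"])
        rate = np.mean(np.asarray(ps) < 0.05)
        assert 0.03 <= rate <= 0.07


class TestBhAndHits:
    @pytest.mark.parametrize(
        "p, expected",
        [([0.03], [0.03]),
         ([0.02] * 5, [0.02] * 5),
         ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04])],
    )
    def test_bh_known_values(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_bh_matches_brute_force_step_up(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_step_up(p), atol=1e-12)

    def test_hit_boundary_inclusive(self):
        eff = pd.DataFrame({"assay": "a", "cell_line": "c", "dose": np.nan,
                            "target": ["T01", "T02"], "estimate": [1, 1],
                            "se": [1, 1], "p": [0.025, 0.051]})
        out = call_hits(eff, threshold=0.05)
        adj = out.set_index("target")["p_adj"]
        # engineered: adjusted p exactly 0.05 is a hit, 0.051 is not
        assert adj["T01"] == pytest.approx(0.05)
        assert bool(out.set_index("target").loc["T01", "hit"]) is True
        assert adj["T02"] == pytest.approx(0.051)
        assert bool(out.set_index("target").loc["T02", "hit"]) is False

    def test_no_contrast_mixes_cell_lines(self, small_data, small_run_config):
        effects = analyze_assays(small_data.assay_table, small_run_config)
        # one estimate per target per cell line per assay/dose stratum
        counts = effects.groupby(["assay", "dose", "target"], dropna=False).size()
        assert (counts == len(small_data.config.cell_lines)).all()

    def test_hits_recover_planted_effect_set(self):
        """On a small seeded screen the hit set equals the planted set.

        Six batches of four replicates keep the shared-control noise well
        below the planted 1-log2 effects, so recovery is exact.
        """
        cfg = small_sim_config(
            n_targets=8, n_dual_evidence=2, n_assay_only=0,
            assays=("alamarBlue",), dosed_assay="none",
            assay_design={"alamarBlue": (6, 4)},
            cell_lines=("scramble",), sensitized_line="scramble",
            sensitization=1.0)
        data = simulate_all(cfg)
        effects = analyze_assays(data.assay_table, RunConfig())
        hits = set(effects.loc[effects["hit"], "target"])
        assert hits == set(cfg.dual_evidence_targets)


def test_full_chain_type_one_error_controlled():
    """BH hit rate of the batch->LMM->BH chain under a global null stays at
    or below nominal: simulated readouts with no planted effects."""
    n_false = n_tests = 0
    for rep in range(5):
        data = simulate_all(small_sim_config(
            n_targets=10, n_dual_evidence=0, n_assay_only=0,
            assays=("alamarBlue", "MitoTracker"), dosed_assay="none",
            assay_design={"alamarBlue": (3, 3), "MitoTracker": (3, 3)},
            seed=rep))
        out = analyze_assays(data.assay_table, RunConfig())
        n_false += int(out["hit"].sum())
        n_tests += len(out)
    assert n_false / n_tests <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_tests)
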