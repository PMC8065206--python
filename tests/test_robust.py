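import numpy as np
import pytest
from scipy import optimize, stats

from ntekinetics.models import build_model
from ntekinetics.robust import (
    NotConvergedError,
    RankDeficiencyError,
    RobustOptions,
    fit_robust,
    rho,
    wald_inference,
)
from ntekinetics.synthetic import (
    SyntheticConfig,
    default_design,
    generate_processed,
)

from conftest import TRUTH


class TestPointEstimation:
    def test_noiseless_data_recovers_truth_exactly(self, best_spec, noiseless_data):
        fit = fit_robust(best_spec, noiseless_data)
        assert fit.converged
        for name, value in TRUTH.items():
            assert fit.params[name] == pytest.approx(value, abs=1e-6)

    def test_irls_matches_direct_loss_minimization(self, best_spec, small_design):
        """IRLS fixed point == generic minimizer of the same Huber loss."""
        worst = 0.0
        for seed in range(5):
            df = generate_processed(SyntheticConfig(seed=2000 + seed, design=small_design))
            fit = fit_robust(best_spec, df)
            X = best_spec.design_matrix(
                df["dose_gy"].to_numpy(), df["let_category"].to_numpy(object)
            )
            y = df["response"].to_numpy()

            def loss(th):
                return float(np.sum(rho((y - X @ th) / fit.scale, "huber", 1.345)))

            res = optimize.minimize(
                loss,
                fit.estimates + 0.05,
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
            )
            worst = max(worst, float(np.max(np.abs(res.x - fit.estimates))))
        assert worst < 1e-4

    def test_ols_mode_reproduces_linear_least_squares(self, best_spec, small_data):
        fit = fit_robust(best_spec, small_data, RobustOptions(loss="ols"))
        X = best_spec.design_matrix(
            small_data["dose_gy"].to_numpy(),
            small_data["let_category"].to_numpy(object),
        )
        beta = np.linalg.lstsq(X, small_data["response"].to_numpy(), rcond=None)[0]
        assert np.allclose(fit.estimates, beta, atol=1e-8)

    def test_robust_beats_ols_under_contamination(self, best_spec):
        """+1.0 shifts on 10% of samples hurt OLS's baseline more."""
        robust_wins = 0
        n_rep = 100
        for seed in range(n_rep):
            df = generate_processed(
                SyntheticConfig(
                    seed=4000 + seed,
                    contamination_fraction=0.1,
                    contamination_shift=1.0,
                )
            )
            rob = fit_robust(best_spec, df).params["B"]
            ols = fit_robust(best_spec, df, RobustOptions(loss="ols")).params["B"]
            robust_wins += abs(rob - TRUTH["B"]) < abs(ols - TRUTH["B"])
        assert robust_wins >= 0.95 * n_rep

    def test_bisquare_loss_also_converges(self, best_spec, small_data):
        fit = fit_robust(best_spec, small_data, RobustOptions(loss="bisquare"))
        assert fit.converged
        assert np.all(fit.robust_weights <= 1.0)

    def test_rank_deficiency_names_unsupported_parameter(self, best_spec, small_data):
        no_vh = small_data[small_data.let_category != "VH"]
        with pytest.raises(RankDeficiencyError, match="kTE_VH"):
            fit_robust(best_spec, no_vh)


class TestEquivariance:
    def test_response_shift_moves_baseline_only(self, best_spec, small_data):
        fit0 = fit_robust(best_spec, small_data)
        shifted = small_data.copy()
        shifted["response"] = shifted["response"] + 0.5
        fit1 = fit_robust(best_spec, shifted)
        assert fit1.params["B"] - fit0.params["B"] == pytest.approx(0.5, abs=1e-6)
        for slope in ("kNTE", "kTE_LMH", "kTE_VH"):
            assert fit1.params[slope] == pytest.approx(fit0.params[slope], abs=1e-6)

    def test_dose_rescaling_rescales_linear_slopes(self, best_spec, small_data):
        s = 2.0
        fit0 = fit_robust(best_spec, small_data)
        scaled = small_data.copy()
        scaled["dose_gy"] = scaled["dose_gy"] * s
        fit1 = fit_robust(
            best_spec, scaled, RobustOptions(k_nte_r=1e3 / s)
        )
        for slope in ("kTE_LMH", "kTE_VH"):
            assert fit1.params[slope] == pytest.approx(
                fit0.params[slope] / s, abs=1e-6
            )
        assert fit1.params["kNTE"] == pytest.approx(fit0.params["kNTE"], abs=1e-6)


class TestWaldInference:
    def test_duplicating_data_shrinks_se_by_sqrt2(self, best_spec, small_data):
        import pandas as pd

        fit1 = fit_robust(best_spec, small_data)
        doubled = pd.concat([small_data, small_data], ignore_index=True)
        fit2 = fit_robust(best_spec, doubled)
        ratio = fit2.standard_errors / fit1.standard_errors
        assert np.allclose(ratio, 1 / np.sqrt(2), atol=0.02)

    def test_noiseless_fit_has_zero_se(self, best_spec, noiseless_data):
        fit = fit_robust(best_spec, noiseless_data)
        assert np.all(fit.standard_errors < 1e-6)

    def test_inference_refused_for_nonconverged_fit(self, best_spec, small_data):
        fit = fit_robust(best_spec, small_data)
        fit.converged = False
        with pytest.raises(NotConvergedError):
            wald_inference(fit)

    def test_pvalues_uniform_under_true_zero(self, best_spec):
        """Wald p for kTE_LMH is ~U(0,1) when its true value is 0."""
        cfg = SyntheticConfig(
            te_slopes={"L": 0.0, "M": 0.0, "H": 0.0, "VH": 0.127},
            rat_sd=0.0,
            design=default_design(n_rats_per_cell=4, n_sham_rats=10),
        )
        idx = best_spec.parameter_names.index("kTE_LMH")
        pvals = [
            fit_robust(best_spec, generate_processed(cfg.with_(seed=3000 + s))).p_values[idx]
            for s in range(200)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.05


class TestRecovery:
    def test_parameter_recovery_at_study_scale(self, best_spec):
        """Bias and SE calibration of the main parameters over replicates.

        The Wald SEs assume independent observations, so the SE-vs-sampling-SD
        comparison uses replicates without the shared per-rat baseline shift
        (with it, the true sampling SD is inflated by the within-rat
        correlation the single-level fit ignores).
        """
        n_rep = 60
        est = []
        for seed in range(n_rep):
            df = generate_processed(SyntheticConfig(seed=5000 + seed, rat_sd=0.0))
            p = fit_robust(best_spec, df).params
            est.append([p["B"], p["kNTE"], p["kTE_VH"]])
        est = np.asarray(est)
        bias = est.mean(axis=0) - np.array(
            [TRUTH["B"], TRUTH["kNTE"], TRUTH["kTE_VH"]]
        )
        assert abs(bias[1]) < 0.01  # kNTE
        assert abs(bias[2]) < 0.01  # kTE_VH
        # sampling SDs of kNTE and kTE_VH within 50% of the reported SEs
        assert 0.5 * 0.025 < est[:, 1].std() < 1.5 * 0.025
        assert 0.5 * 0.035 < est[:, 2].std() < 1.5 * 0.035
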