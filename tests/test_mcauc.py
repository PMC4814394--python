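"""Monte-Carlo AUC interval construction and pairwise tests."""

import numpy as np
import pytest
from scipy import stats

from aakinetics import (
    KineticParams,
    TimeWindow,
    auc,
    mc_auc_ci,
    mc_pairwise_auc,
)
from aakinetics.fitting import PopulationFit
from aakinetics.mcauc import _auc_draws


def make_fit(params_by_label: dict, cov_blocks: dict) -> PopulationFit:
    """Assemble a synthetic PopulationFit with given fixed effects and
    per-supplement covariance blocks (transformed scale)."""
    labels = tuple(params_by_label)
    fe_t = {
        lab: np.array([np.log(p.k1), np.log(p.k3), np.log(p.x0), p.y0])
        for lab, p in params_by_label.items()
    }
    n = len(labels)
    cov = np.zeros((4 * n, 4 * n))
    for i, lab in enumerate(labels):
        cov[4 * i: 4 * i + 4, 4 * i: 4 * i + 4] = cov_blocks[lab]
    return PopulationFit(
        supplement_labels=labels,
        fixed_effects=dict(params_by_label),
        fixed_effects_transformed=fe_t,
        re_sd_subject=np.zeros(4),
        re_sd_interaction=np.zeros(4),
        residual_sd=0.1,
        loglik=0.0,
        covariance=cov,
        method="synthetic",
        converged=True,
    )


P_FAST = KineticParams(k1=0.06, k3=0.0133, x0=3.5, y0=2.6)
P_SLOW = KineticParams(k1=0.0194, k3=0.006, x0=3.88, y0=2.6)
SMALL_COV = np.diag([0.01**2, 0.01**2, 0.01**2, 0.02**2])


class TestAUCInterval:
    def test_zero_covariance_degenerates_to_point(self):
        fit = make_fit({"A": P_FAST}, {"A": np.zeros((4, 4))})
        est = mc_auc_ci(fit, "A", n_draws=2000, seed=0)
        point = auc(P_FAST, TimeWindow(0.0, 120.0))
        assert est.ci_low == pytest.approx(point)
        assert est.ci_high == pytest.approx(point)
        assert est.point == pytest.approx(point)
        assert not est.point_outside_ci

    def test_seeded_runs_identical(self):
        fit = make_fit({"A": P_FAST}, {"A": SMALL_COV})
        a = mc_auc_ci(fit, "A", n_draws=50_000, seed=42)
        b = mc_auc_ci(fit, "A", n_draws=50_000, seed=42)
        assert (a.ci_low, a.ci_high, a.point_median) == (
            b.ci_low, b.ci_high, b.point_median,
        )

    def test_percentiles_match_sorted_draw_oracle(self):
        fit = make_fit({"A": P_FAST}, {"A": SMALL_COV})
        n = 4000
        draws = _auc_draws(
            fit, "A", TimeWindow(0.0, 120.0), n, np.random.default_rng(1)
        )
        est = mc_auc_ci(fit, "A", n_draws=n, seed=1)
        srt = np.sort(draws)
        lo_oracle = np.quantile(srt, 0.025)
        hi_oracle = np.quantile(srt, 0.975)
        assert est.ci_low == pytest.approx(lo_oracle)
        assert est.ci_high == pytest.approx(hi_oracle)

    def test_interval_width_shrinks_with_covariance(self):
        widths = []
        for scale in (1.0, 0.25, 0.04):
            fit = make_fit({"A": P_FAST}, {"A": SMALL_COV * scale})
            est = mc_auc_ci(fit, "A", n_draws=20_000, seed=3)
            widths.append(est.ci_high - est.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_coverage_of_true_auc(self):
        """Simulating the estimator's sampling distribution: nominal 95 %
        intervals should cover the true AUC in roughly 95 % of replicates."""
        true_phi = np.array(
            [np.log(P_FAST.k1), np.log(P_FAST.k3), np.log(P_FAST.x0), P_FAST.y0]
        )
        cov = np.diag([0.08**2, 0.08**2, 0.10**2, 0.05**2])
        true_auc = auc(P_FAST, TimeWindow(0.0, 120.0))
        L = np.linalg.cholesky(cov)
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            phi_hat = true_phi + L @ rng.standard_normal(4)
            p_hat = KineticParams(
                k1=float(np.exp(phi_hat[0])), k3=float(np.exp(phi_hat[1])),
                x0=float(np.exp(phi_hat[2])), y0=float(max(phi_hat[3], 0.0)),
            )
            fit = make_fit({"A": p_hat}, {"A": cov})
            est = mc_auc_ci(
                fit, "A", n_draws=2000, seed=int(rng.integers(2**31 - 1))
            )
            hits += est.ci_low <= true_auc <= est.ci_high
        assert 0.88 <= hits / n_rep <= 0.99

    def test_too_few_draws_rejected(self):
        fit = make_fit({"A": P_FAST}, {"A": SMALL_COV})
        with pytest.raises(ValueError):
            mc_auc_ci(fit, "A", n_draws=500, seed=0)

    def test_non_psd_covariance_names_supplement(self):
        bad = np.diag([1.0, 1.0, 1.0, -1.0])
        fit = make_fit({"A": P_FAST}, {"A": bad})
        with pytest.raises(ValueError, match="'A'"):
            mc_auc_ci(fit, "A", n_draws=2000, seed=0)


class TestPairwise:
    def test_exchangeable_null_gives_large_p(self):
        fit = make_fit(
            {"A": P_FAST, "B": P_FAST}, {"A": SMALL_COV, "B": SMALL_COV}
        )
        pw = mc_pairwise_auc(fit, "A", "B", n_draws=50_000, seed=0)
        assert pw.p_value >= 0.8
        assert pw.diff_point == pytest.approx(0.0, abs=1e-9)

    def test_identical_labels_rejected(self):
        fit = make_fit({"A": P_FAST}, {"A": SMALL_COV})
        with pytest.raises(ValueError):
            mc_pairwise_auc(fit, "A", "A", n_draws=2000, seed=0)

    def test_separated_supplements_hit_empirical_floor(self):
        fit = make_fit(
            {"A": P_FAST, "B": P_SLOW},
            {"A": np.zeros((4, 4)), "B": np.zeros((4, 4))},
        )
        n = 2000
        pw = mc_pairwise_auc(fit, "A", "B", n_draws=n, seed=0)
        assert pw.p_value == pytest.approx(2.0 / n)
        assert pw.diff_point > 0

    def test_five_sigma_separation_always_significant(self):
        """Shift one supplement's AUC by ~5 SE of the difference: every
        seeded replicate must reject at far below 0.1 %."""
        cov = np.diag([0.03**2, 0.0, 0.0, 0.0])
        # AUC is locally linear in log k1; 5-sigma shift on the difference
        base = np.log(P_FAST.k1)
        shift = 5.0 * 0.03 * np.sqrt(2)
        p_b = KineticParams(
            k1=float(np.exp(base + shift)), k3=P_FAST.k3, x0=P_FAST.x0, y0=P_FAST.y0
        )
        fit = make_fit({"A": P_FAST, "B": p_b}, {"A": cov, "B": cov})
        for seed in range(5):
            pw = mc_pairwise_auc(fit, "A", "B", n_draws=20_000, seed=seed)
            assert pw.p_value < 0.001

    def test_null_p_values_roughly_uniform(self):
        """Two supplements with identical true kinetics: resampling the
        estimation noise of both point estimates, the empirical two-sided
        p-value should be approximately U(0, 1)."""
        cov = np.diag([0.05**2, 0.04**2, 0.05**2, 0.03**2])
        true_phi = np.array(
            [np.log(P_FAST.k1), np.log(P_FAST.k3), np.log(P_FAST.x0), P_FAST.y0]
        )
        L = np.linalg.cholesky(cov)
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(500):
            params = {}
            for lab in ("A", "B"):
                phi_hat = true_phi + L @ rng.standard_normal(4)
                params[lab] = KineticParams(
                    k1=float(np.exp(phi_hat[0])), k3=float(np.exp(phi_hat[1])),
                    x0=float(np.exp(phi_hat[2])), y0=float(max(phi_hat[3], 0.0)),
                )
            fit = make_fit(params, {"A": cov, "B": cov})
            ps.append(
                mc_pairwise_auc(
                    fit, "A", "B", n_draws=1000,
                    seed=int(rng.integers(2**31 - 1)),
                ).p_value
            )
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01
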