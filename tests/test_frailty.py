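import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import recurmi as rm
from recurmi.frailty import CoxFrailtyModel, ModelSpec, make_strata
from conftest import brute_force_partial_loglik

UNSTRAT_NOFRAILTY = ModelSpec("counting_process", "none", "none")


class TestPartialLoglik:
    def test_uniform_risk_set(self):
        """One event with two subjects at risk and beta=0 contributes log(1/2)."""
        df = pd.DataFrame(
            {"id": [1, 2], "start": [0.0, 0.0], "stop": [3.0, 5.0],
             "status": [1, 0], "x1": [1.0, 0.0]}
        )
        df.attrs["layout"] = "counting_process"
        ll = rm.partial_loglik(df, [0.0], spec=UNSTRAT_NOFRAILTY)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    @pytest.mark.parametrize("beta", [0.0, 0.5, -0.3, 1.2])
    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_brute_force_on_fixture(self, tiny_table, beta, ties):
        spec = ModelSpec("counting_process", "none", "none", ties=ties)
        mine = rm.partial_loglik(tiny_table, [beta], spec=spec)
        oracle = brute_force_partial_loglik(tiny_table, [beta], ties=ties)
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_matches_brute_force_with_frailty_and_strata(self, tiny_table):
        offsets = {1: 0.3, 2: -0.2, 3: 0.1, 4: 0.0, 5: -0.5}
        spec = ModelSpec("counting_process", "episode_only", "none")
        mine = rm.partial_loglik(tiny_table, [0.4], frailty_offsets=offsets,
                                 spec=spec)
        oracle = brute_force_partial_loglik(
            tiny_table.assign(strat=np.minimum(tiny_table["episode"], 3)),
            [0.4], offsets=offsets, strata_col="strat",
        )
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_common_frailty_shift_cancels(self, tiny_table):
        """Adding a constant to every log-frailty leaves the value unchanged."""
        base = {i: 0.1 * i for i in range(1, 6)}
        shifted = {i: v + 0.7 for i, v in base.items()}
        a = rm.partial_loglik(tiny_table, [0.3], frailty_offsets=base,
                              spec=UNSTRAT_NOFRAILTY)
        b = rm.partial_loglik(tiny_table, [0.3], frailty_offsets=shifted,
                              spec=UNSTRAT_NOFRAILTY)
        assert a == pytest.approx(b, abs=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(data=st.data())
    def test_matches_brute_force_on_random_fixtures(self, data):
        """Random small start-stop fixtures agree with risk-set enumeration."""
        rng_seed = data.draw(st.integers(0, 10_000))
        beta = data.draw(st.floats(-1.5, 1.5))
        rng = np.random.default_rng(rng_seed)
        n = rng.integers(3, 7)
        start = rng.uniform(0, 3, size=n).round(1)
        stop = start + rng.uniform(0.5, 4, size=n).round(1) + 0.1
        status = rng.integers(0, 2, size=n)
        if status.sum() == 0:
            status[0] = 1
        df = pd.DataFrame(
            {"id": np.arange(1, n + 1), "start": start, "stop": stop,
             "status": status, "x1": rng.integers(0, 2, size=n).astype(float)}
        )
        df.attrs["layout"] = "counting_process"
        mine = rm.partial_loglik(df, [beta], spec=UNSTRAT_NOFRAILTY)
        oracle = brute_force_partial_loglik(df, [beta])
        assert mine == pytest.approx(oracle, abs=1e-9)


class TestPlainCoxFit:
    def test_matches_lifelines_stratified(self, clean_cohort):
        """No-frailty stratified fit agrees with lifelines CoxTimeVaryingFitter."""
        lifelines = pytest.importorskip("lifelines")
        df = rm.build_risk_intervals(clean_cohort, "counting_process")
        spec = ModelSpec("counting_process", "episode_only", "none",
                         episode_col="true_episode")
        fit = CoxFrailtyModel(df, spec).fit()
        ldf = df.assign(strat=np.minimum(df["true_episode"], 3))
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(ldf[["id", "start", "stop", "status", "strat", "x1", "x2", "x3"]],
                id_col="id", start_col="start", stop_col="stop",
                event_col="status", strata=["strat"])
        np.testing.assert_allclose(fit.params.to_numpy(), ctv.params_.to_numpy(),
                                   atol=1e-6)
        np.testing.assert_allclose(fit.bse.to_numpy(),
                                   ctv.standard_errors_.to_numpy(), atol=1e-6)

    def test_no_heterogeneity_gives_zero_theta(self, clean_cohort):
        """Frailty fit on exponential data without heterogeneity collapses
        to the plain Cox fit with theta ~ 0."""
        df = rm.build_risk_intervals(clean_cohort, "counting_process")
        spec_g = ModelSpec("counting_process", "episode_only", "gamma",
                           episode_col="true_episode")
        spec_0 = ModelSpec("counting_process", "episode_only", "none",
                           episode_col="true_episode")
        fg = CoxFrailtyModel(df, spec_g).fit()
        f0 = CoxFrailtyModel(df, spec_0).fit()
        assert fg.theta <= 0.05
        np.testing.assert_allclose(fg.params.to_numpy(), f0.params.to_numpy(),
                                   atol=1e-3)

    def test_stratified_equals_unstratified_on_duplicated_data(self, tiny_table):
        """Identical data in two strata reproduce the one-stratum coefficients."""
        double = pd.concat(
            [tiny_table.assign(grp=0), tiny_table.assign(grp=1, id=tiny_table.id + 10)],
            ignore_index=True,
        )
        double.attrs["layout"] = "counting_process"
        spec1 = ModelSpec("counting_process", "none", "none")
        fit_single = CoxFrailtyModel(tiny_table, spec1).fit()
        # strata via the episode machinery: use grp as a fake episode index
        double2 = double.assign(episode=double["grp"] + 1)
        fit_strat = CoxFrailtyModel(double2,
                                    ModelSpec("counting_process", "episode_only",
                                              "none")).fit()
        np.testing.assert_allclose(fit_strat.params.to_numpy(),
                                   fit_single.params.to_numpy(), atol=1e-6)


def _simulate_frailty_data(n=300, theta=0.4, seed=5, followup=1825.0):
    """Recurrent exponential episodes with true gamma frailty (oracle data)."""
    rng = np.random.default_rng(seed)
    nu = rng.gamma(1 / theta, theta, size=n)
    rows = []
    for i in range(n):
        x = (rng.uniform(size=2) < 0.5).astype(float)
        t, k = 0.0, 1
        while True:
            lam = nu[i] * np.exp(np.log(1 / 900.0) + 0.4 * x[0] + 0.8 * x[1])
            g = rng.exponential(1 / lam)
            if t + g >= followup:
                rows.append((i + 1, t, followup, 0, k, *x))
                break
            rows.append((i + 1, t, t + g, 1, k, *x))
            t, k = t + g, k + 1
    df = pd.DataFrame(rows, columns=["id", "start", "stop", "status",
                                     "episode", "x1", "x2"])
    df.attrs["layout"] = "counting_process"
    return df


class TestGammaFrailty:
    def test_recovers_heterogeneity(self):
        df = _simulate_frailty_data(n=300, theta=0.4, seed=5)
        fit = CoxFrailtyModel(df, ModelSpec("counting_process", "none",
                                            "gamma")).fit()
        assert fit.converged
        assert 0.15 < fit.theta < 0.8
        assert fit.frailty.mean() == pytest.approx(1.0, abs=0.05)
        assert np.all(np.abs(fit.params.to_numpy() - [0.4, 0.8])
                      < 3.5 * fit.bse.to_numpy())

    def test_matches_r_survival_coxph(self, tmp_path):
        """Independent oracle: coxph(..., frailty.gamma) from R survival."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = _simulate_frailty_data(n=250, theta=0.5, seed=11)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "fit.csv"
        script = textwrap.dedent(f"""
            library(survival)
            d <- read.csv("{csv}")
            f <- coxph(Surv(start, stop, status) ~ x1 + x2 + frailty.gamma(id),
                       data = d)
            res <- data.frame(coef = coef(f),
                              se = sqrt(diag(vcov(f)))[1:2],
                              theta = f$history[[1]]$theta)
            write.csv(res, "{out}")
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        r = pd.read_csv(out, index_col=0)
        fit = CoxFrailtyModel(df, ModelSpec("counting_process", "none",
                                            "gamma")).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), r["coef"].to_numpy(),
                                   atol=5e-3)
        np.testing.assert_allclose(fit.bse.to_numpy(), r["se"].to_numpy(),
                                   atol=5e-3)
        assert fit.theta == pytest.approx(r["theta"].iloc[0], abs=0.03)

    def test_large_fixed_theta_tracks_event_counts(self):
        """With theta fixed large the frailties approach d_i / Lambda_i, so
        they order subjects by their event counts."""
        df = _simulate_frailty_data(n=200, theta=0.6, seed=3)
        fit = CoxFrailtyModel(df, ModelSpec("counting_process", "none", "gamma",
                                            theta=30.0)).fit()
        d = df.groupby("id")["status"].sum()
        time = df.groupby("id").apply(
            lambda g: (g["stop"] - g["start"]).sum(), include_groups=False
        )
        crude = d / time
        heavy = crude.rank()
        est = fit.frailty.loc[d.index].rank()
        assert np.corrcoef(heavy, est)[0, 1] > 0.85

    def test_single_episode_cp_gt_equivalence(self, clean_cohort):
        """When every subject has one interval starting at 0, the two
        layouts carry the same information and the fits coincide."""
        first = [
            rm.SubjectRecord(id=s.id, covariates=s.covariates,
                             prior_risk=False, k0=0, entry_time=0.0,
                             prior_time=0.0, intervals=[s.intervals[0]])
            for s in clean_cohort
        ]
        cp = rm.build_risk_intervals(first, "counting_process")
        gt = rm.build_risk_intervals(first, "gap_time")
        f_cp = CoxFrailtyModel(cp, rm.SPECIFIC_CP).fit()
        f_gt = CoxFrailtyModel(gt, rm.SPECIFIC_GT).fit()
        np.testing.assert_allclose(f_cp.params.to_numpy(), f_gt.params.to_numpy(),
                                   atol=1e-8)
        assert f_cp.theta == pytest.approx(f_gt.theta, abs=1e-6)


class TestFitInterface:
    def test_zero_events_rejected(self):
        df = pd.DataFrame({"id": [1], "start": [0.0], "stop": [1.0],
                           "status": [0], "x1": [1.0]})
        df.attrs["layout"] = "counting_process"
        with pytest.raises(ValueError, match="no events"):
            CoxFrailtyModel(df, UNSTRAT_NOFRAILTY)

    def test_event_free_stratum_dropped_with_warning(self, tiny_table, caplog):
        df = tiny_table.copy()
        df.loc[df["episode"] == 2, "status"] = 0  # stratum k2 now event-free
        df.attrs["layout"] = "counting_process"
        with caplog.at_level("WARNING", logger="recurmi.frailty"):
            CoxFrailtyModel(df, ModelSpec("counting_process", "episode_only",
                                          "none"))
        assert "event-free strata" in caplog.text

    def test_layout_mismatch_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="layout"):
            CoxFrailtyModel(tiny_table, rm.SPECIFIC_GT)

    def test_preset_lookup(self, tiny_table):
        with pytest.raises(ValueError, match="unknown model"):
            rm.fit_model(tiny_table, "not-a-model")

    def test_strata_labels(self, small_cohort):
        df = rm.build_risk_intervals(small_cohort, "counting_process")
        lab = make_strata(df, rm.SPECIFIC_CP)
        assert set(lab.str[:2].unique()) <= {"k1", "k2", "k3"}
        assert lab.str.contains(":r").all()


class TestWaldCI:
    def test_length_formula(self):
        fit = _fake_fit(beta=0.0, se=0.1)
        ci = rm.wald_ci(fit)
        assert (ci["upper"] - ci["lower"]).iloc[0] == pytest.approx(0.39199, abs=1e-5)

    def test_interval_values(self):
        ci = rm.wald_ci(_fake_fit(beta=0.5, se=0.2))
        assert ci["lower"].iloc[0] == pytest.approx(0.108, abs=1e-3)
        assert ci["upper"].iloc[0] == pytest.approx(0.892, abs=1e-3)

    def test_zero_se_degenerate(self):
        ci = rm.wald_ci(_fake_fit(beta=0.3, se=0.0))
        assert ci["lower"].iloc[0] == ci["upper"].iloc[0] == 0.3


def _fake_fit(beta, se):
    return rm.FitResult(
        params=pd.Series([beta], index=["x1"]),
        bse=pd.Series([se], index=["x1"]),
        theta=0.0, frailty=pd.Series([1.0]), loglik=0.0, converged=True,
        n_subjects=1, n_events=1,
    )
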