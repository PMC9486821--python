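"""Model: marginal likelihood, sampler invariants, diagnostics, summaries."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from occomm import MCMCConfig, ModelSpec, fit, occupancy_likelihood, rhat, summarize
from occomm.model import _Data, _occ_ll, convergence_report
from occomm.core import logit


def brute_force_marginal(psi, p, y):
    """Enumeration oracle: sum over the latent state z in {0, 1}."""
    valid = ~np.isnan(y)
    p, y = np.asarray(p)[valid], np.asarray(y)[valid]
    total = 0.0
    for z in (0, 1):
        prob = psi if z == 1 else 1.0 - psi
        for pk, yk in zip(p, y):
            pe = z * pk
            prob *= pe if yk == 1 else 1.0 - pe
        total += prob
    return total


class TestOccupancyLikelihood:
    def test_single_occasion_detected(self):
        assert occupancy_likelihood(0.5, [0.5], [1.0]) == pytest.approx(0.25)

    def test_all_zero_history_certain_occupancy(self):
        assert occupancy_likelihood(1.0, [0.2, 0.2], [0.0, 0.0]) == pytest.approx(0.64)

    def test_matches_enumeration_on_random_cases(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            k = rng.integers(1, 4)
            psi = rng.random()
            p = rng.random(k)
            y = (rng.random(k) < 0.5).astype(float)
            y[rng.random(k) < 0.2] = np.nan
            want = brute_force_marginal(psi, p, y)
            assert occupancy_likelihood(psi, p, y) == pytest.approx(want, abs=1e-12)

    def test_missing_occasions_are_skipped(self):
        full = occupancy_likelihood(0.3, [0.4], [1.0])
        padded = occupancy_likelihood(0.3, [0.4, 0.9], [1.0, np.nan])
        assert padded == pytest.approx(full, abs=1e-15)


def _toy_spec(J, C=0, seed=0):
    rng = np.random.default_rng(seed)
    cov = pd.DataFrame(
        {f"x{c}": rng.standard_normal(J) for c in range(C)}
    )
    if C:
        cov = (cov - cov.mean()) / cov.std(ddof=0)
    return ModelSpec(
        landuse=np.where(np.arange(J) % 2 == 0, "NFM", "LPF"),
        fmu=np.where(np.arange(J) < J // 2, "Pasin", "Raplex"),
        road=(np.arange(J) % 3 == 0).astype(float),
        covariates=cov,
    )


def test_sampler_loglik_matches_enumeration_small_instances():
    # every instance with <=3 species, <=4 stations, <=3 occasions
    rng = np.random.default_rng(11)
    for S in (1, 2, 3):
        for J in (1, 2, 4):
            for K in (1, 2, 3):
                spec = _toy_spec(J, C=0)
                effort = rng.integers(0, 2 * K + 1, size=(J, K)).astype(float)
                y = (rng.random((S, J, K)) < 0.4).astype(float)
                y[:, effort == 0] = np.nan
                data = _Data(spec, y, effort)
                lpsi = rng.normal(0, 1, (S, J))
                alpha0 = rng.normal(-0.5, 1, (S, len(set(spec.fmu)) + 1))
                from occomm.model import _det_ll

                road_s = rng.normal(0, 0.5, S)
                aeff = 0.3
                A = _det_ll(data, alpha0[:, data.fmu], aeff, road_s)
                got = _occ_ll(lpsi, A, data.det_any)
                for s in range(S):
                    for j in range(J):
                        lp = (
                            alpha0[s, data.fmu[j]]
                            + aeff * data.e_c[j]
                            + road_s[s] * data.road[j]
                        )
                        p = 1 / (1 + np.exp(-lp))
                        psi = 1 / (1 + np.exp(-lpsi[s, j]))
                        want = brute_force_marginal(psi, p, y[s, j])
                        assert np.exp(got[s, j]) == pytest.approx(want, abs=1e-12)


def test_zero_effort_occasions_contribute_nothing():
    # deleting all-zero-effort occasions leaves the log-density bitwise equal
    rng = np.random.default_rng(5)
    spec = _toy_spec(6)
    K = 5
    effort = rng.integers(0, 11, size=(6, K)).astype(float)
    effort[:, 2] = 0.0
    y = (rng.random((4, 6, K)) < 0.3).astype(float)
    y[:, effort == 0] = np.nan
    keep = [0, 1, 3, 4]
    d_full = _Data(spec, y, effort)
    d_trim = _Data(spec, y[:, :, keep], effort[:, keep])
    # same effort centring so the likelihoods are directly comparable
    assert d_full.effort_center == d_trim.effort_center
    from occomm.model import _det_ll

    alpha0 = rng.normal(-1, 1, (4, 2))
    road_s = rng.normal(0, 0.5, 4)
    A_full = _det_ll(d_full, alpha0[:, d_full.fmu], 0.25, road_s)
    A_trim = _det_ll(d_trim, alpha0[:, d_trim.fmu], 0.25, road_s)
    assert np.array_equal(A_full, A_trim)


def test_fit_validates_dimensions(small_spec, small_survey):
    with pytest.raises(ValueError, match="effort"):
        fit(small_spec, small_survey.detections, small_survey.effort.values[:5],
            MCMCConfig(chains=2, iterations=20, burn_in=10, seed=0))


def test_mcmc_config_validation():
    with pytest.raises(ValueError):
        MCMCConfig(chains=0).validate()
    with pytest.raises(ValueError, match="burn_in"):
        MCMCConfig(iterations=100, burn_in=100).validate()
    full = MCMCConfig.full_profile()
    assert (full.chains, full.iterations, full.burn_in, full.thin) == (
        3, 300_000, 50_000, 20,
    )


def test_detected_stations_have_z_one_in_every_draw(small_fit, small_survey):
    det_any = (np.nan_to_num(small_survey.detections.values) == 1).any(axis=2)
    z = small_fit["z"].values  # (chain, draw, S, J)
    assert (z[:, :, det_any] == 1).all()


def test_posterior_draws_finite_and_sds_positive(small_fit):
    for name, da in small_fit.data_vars.items():
        assert np.isfinite(da.values).all(), name
    for name in ("sd_beta0", "sd_beta", "sd_alpha0", "sd_road"):
        assert (small_fit[name].values > 0).all()


def test_fit_is_seed_reproducible(small_spec, small_survey, small_fit):
    cfg = MCMCConfig(chains=2, iterations=500, burn_in=250, thin=5, seed=11)
    again = fit(small_spec, small_survey.detections, small_survey.effort, cfg)
    assert np.array_equal(again["beta0"].values, small_fit["beta0"].values)
    assert np.array_equal(again["alpha_eff"].values, small_fit["alpha_eff"].values)


class TestRhat:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(3, 1000))
        assert abs(rhat(arr) - 1.0) < 0.05

    def test_disjoint_chains_flagged(self):
        arr = np.concatenate(
            [np.random.default_rng(1).normal(0, 0.1, (1, 500)),
             np.random.default_rng(2).normal(10, 0.1, (1, 500))]
        )
        assert rhat(arr) > 1.1

    def test_hand_formula_on_tiny_array(self):
        arr = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 7.0]])
        m, n = arr.shape
        W = arr.var(axis=1, ddof=1).mean()
        B_over_n = arr.mean(axis=1).var(ddof=1)
        want = np.sqrt(((n - 1) / n * W + B_over_n) / W)
        assert rhat(arr) == pytest.approx(want, abs=1e-14)

    def test_zero_variance_is_undefined_not_converged(self):
        arr = np.ones((2, 10))
        assert np.isnan(rhat(arr))

    def test_requires_chains_and_draws(self):
        with pytest.raises(ValueError):
            rhat(np.ones((1, 100)))

    def test_matches_arviz_on_well_mixed_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(4)
        arr = rng.normal(size=(4, 2000))
        ours = rhat(arr)
        theirs = float(
            az.rhat(az.convert_to_dataset(arr[None].transpose(1, 2, 0)))["x"].values.item()
        )
        # different R-hat flavours (classic vs rank-normalized split) agree
        # closely when chains are well mixed
        assert abs(ours - theirs) < 0.02


def test_convergence_report_flags_bad_parameters(small_fit):
    rep = convergence_report(small_fit)
    assert {"parameter", "rhat", "flagged"} <= set(rep.columns)
    assert len(rep) > 50  # species x parameter rows all present


def _draws_from(values):
    return xr.Dataset({"theta": (("chain", "draw"), np.asarray(values, dtype=float))})


class TestSummarize:
    def test_all_positive_draws_strong_support(self):
        tab = summarize(_draws_from([np.linspace(0.5, 2, 100)]))
        assert tab.loc[0, "support"] == "strong" and tab.loc[0, "sign"] == "+"

    def test_symmetric_draws_weak(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 4000)
        tab = summarize(_draws_from([x]))
        assert tab.loc[0, "support"] == "weak"

    def test_nested_interval_rule_moderate(self):
        # 95% interval spans zero, 75% interval does not
        x = np.concatenate([np.full(4, -0.1), np.full(96, 0.5)])
        tab = summarize(_draws_from([x]))
        assert tab.loc[0, "support"] == "moderate"

    def test_percentile_definition(self):
        x = np.arange(1000.0)
        tab = summarize(_draws_from([x]))
        assert tab.loc[0, "q2.5"] == pytest.approx(np.percentile(x, 2.5))
        assert tab.loc[0, "q87.5"] == pytest.approx(np.percentile(x, 87.5))

    def test_strong_implies_moderate_nesting(self, small_fit):
        tab = summarize(small_fit, parameters=["beta"])
        strong = tab[tab["support"] == "strong"]
        # every strong 95% interval excludes zero, hence so does its 75%
        ok = (strong["q12.5"] > 0) | (strong["q87.5"] < 0)
        assert ok.all()


def test_unknown_labels_rejected():
    with pytest.raises(ValueError, match="landuse"):
        ModelSpec(
            landuse=np.array(["forest"]), fmu=np.array(["Pasin"]),
            road=np.zeros(1), covariates=pd.DataFrame(index=[0]),
        )


def test_unscaled_covariates_rejected():
    with pytest.raises(ValueError, match="scaled"):
        ModelSpec(
            landuse=np.array(["NFM"] * 4), fmu=np.array(["Pasin"] * 4),
            road=np.zeros(4),
            covariates=pd.DataFrame({"elev": [100.0, 300.0, 250.0, 700.0]}),
        )
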