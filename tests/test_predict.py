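"""Landscape projection: psi formula, PAO, richness, determinism."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from occomm import PredictionGrid, pao, predict_psi, richness
from occomm.core import inv_logit


def _draws(beta0, beta, species=None):
    """Posterior Dataset with one chain and literal draws.

    beta0: (n, S, 2), beta: (n, S, C)."""
    beta0 = np.asarray(beta0, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n, S = beta0.shape[:2]
    species = species or [f"sp{i}" for i in range(S)]
    return xr.Dataset(
        {
            "beta0": (("chain", "draw", "species", "landuse"), beta0[None]),
            "beta": (("chain", "draw", "species", "covariate"), beta[None]),
        },
        coords={
            "chain": [0], "draw": np.arange(n), "species": species,
            "landuse": ["NFM", "LPF"],
            "covariate": [f"x{c}" for c in range(beta.shape[2])],
        },
    )


def _grid(n_nfm=3, n_lpf=2, C=1, values=0.0):
    cells = pd.DataFrame({"landuse": ["NFM"] * n_nfm + ["LPF"] * n_lpf})
    for c in range(C):
        cells[f"x{c}"] = values
    return PredictionGrid(cells=cells, covariate_names=[f"x{c}" for c in range(C)])


class TestPredictPsi:
    def test_zero_covariates_give_intercept_only_psi(self):
        d = _draws(beta0=[[[0.7, -0.4]]], beta=[[[0.5]]])
        psi = predict_psi(d, _grid(), sample_stride=1)
        assert psi.shape == (1, 1, 5)
        assert psi[0, 0, :3] == pytest.approx(inv_logit(0.7))
        assert psi[0, 0, 3:] == pytest.approx(inv_logit(-0.4))

    def test_saturation_at_large_intercept(self):
        d = _draws(beta0=[[[40.0, 40.0]]], beta=[[[0.0]]])
        assert predict_psi(d, _grid(), 1) == pytest.approx(1.0)

    def test_hand_computed_linear_predictor(self):
        d = _draws(beta0=[[[0.2, 0.0]]], beta=[[[0.5, -1.0]]])
        grid = PredictionGrid(
            cells=pd.DataFrame({"landuse": ["NFM"], "x0": [1.2], "x1": [0.4]}),
            covariate_names=["x0", "x1"],
        )
        want = inv_logit(0.2 + 0.5 * 1.2 - 1.0 * 0.4)
        assert predict_psi(d, grid, 1)[0, 0, 0] == pytest.approx(want)

    def test_stride_selects_every_nth_pooled_sample(self):
        b0 = np.zeros((10, 1, 2))
        b0[:, 0, 0] = np.arange(10)
        d = _draws(beta0=b0, beta=np.zeros((10, 1, 1)))
        psi = predict_psi(d, _grid(), sample_stride=4)
        assert psi.shape[0] == 3  # samples 0, 4, 8
        assert psi[:, 0, 0] == pytest.approx(inv_logit([0.0, 4.0, 8.0]))

    def test_covariate_mismatch_rejected(self):
        d = _draws(beta0=[[[0.0, 0.0]]], beta=[[[0.0, 0.0]]])
        with pytest.raises(ValueError, match="covariate"):
            predict_psi(d, _grid(C=1), 1)

    def test_scaler_signature_mismatch_rejected(self):
        d = _draws(beta0=[[[0.0, 0.0]]], beta=[[[0.0]]])
        d.attrs["scaler_signature"] = "model-scaling"
        with pytest.raises(ValueError, match="scaled"):
            predict_psi(d, _grid(), 1)


class TestPAO:
    def test_certain_occupancy_gives_100(self):
        d = _draws(beta0=np.full((3, 2, 2), 40.0), beta=np.zeros((3, 2, 1)))
        tab = pao(d, _grid(), sample_stride=1, seed=0)
        assert tab["mean"].to_numpy() == pytest.approx(100.0)
        assert tab["sd"].to_numpy() == pytest.approx(0.0)

    def test_zero_occupancy_gives_0(self):
        d = _draws(beta0=np.full((3, 1, 2), -40.0), beta=np.zeros((3, 1, 1)))
        tab = pao(d, _grid(), 1, seed=0)
        assert tab["mean"].to_numpy() == pytest.approx(0.0)

    def test_half_occupancy_within_binomial_tolerance(self):
        d = _draws(beta0=np.zeros((20, 1, 2)), beta=np.zeros((20, 1, 1)))
        grid = _grid(n_nfm=4000, n_lpf=4000)
        tab = pao(d, grid, 1, seed=1)
        se = 100 * np.sqrt(0.25 / 4000)
        assert tab["mean"].to_numpy() == pytest.approx(50.0, abs=4 * se)

    def test_same_seed_bit_identical(self):
        d = _draws(beta0=np.random.default_rng(0).normal(size=(5, 3, 2)),
                   beta=np.zeros((5, 3, 1)))
        grid = _grid(50, 30)
        a = pao(d, grid, 1, seed=9)
        b = pao(d, grid, 1, seed=9)
        pd.testing.assert_frame_equal(a, b)
        assert np.array_equal(a.attrs["samples"], b.attrs["samples"])


class TestRichness:
    def test_full_occupancy_richness_equals_species_count(self):
        S = 6
        d = _draws(beta0=np.full((2, S, 2), 40.0), beta=np.zeros((2, S, 1)))
        r = richness(d, _grid(), 1, seed=0)
        assert r["cell_mean"].values == pytest.approx(S)
        assert r["cell_sd"].values == pytest.approx(0.0)

    def test_subset_capped_at_subset_size(self):
        S = 6
        d = _draws(beta0=np.full((2, S, 2), 40.0), beta=np.zeros((2, S, 1)))
        subset = [f"sp{i}" for i in range(4)]
        r = richness(d, _grid(), 1, seed=0, species_subset=subset)
        assert r["cell_mean"].values == pytest.approx(4)

    def test_mean_richness_matches_sum_of_psi(self):
        rng = np.random.default_rng(2)
        S = 8
        b0 = np.tile(rng.normal(0, 1, (1, S, 1)), (40, 1, 2))
        d = _draws(beta0=b0, beta=np.zeros((40, S, 1)))
        grid = _grid(n_nfm=2000, n_lpf=2000)
        r = richness(d, grid, 1, seed=3)
        want = inv_logit(b0[0, :, 0]).sum()
        got = float(r["landuse_mean"].sel(landuse="NFM"))
        mc_se = np.sqrt(S * 0.25 / 2000 / 40)
        assert got == pytest.approx(want, abs=5 * mc_se + 0.05)

    def test_expected_richness_mode_is_deterministic_sum(self):
        d = _draws(beta0=np.full((3, 4, 2), 0.0), beta=np.zeros((3, 4, 1)))
        r = richness(d, _grid(), 1, seed=0, bernoulli=False)
        assert r["cell_mean"].values == pytest.approx(2.0)  # 4 x 0.5

    def test_subset_richness_never_exceeds_full(self):
        rng = np.random.default_rng(5)
        d = _draws(beta0=rng.normal(0, 1, (6, 5, 2)), beta=np.zeros((6, 5, 1)))
        grid = _grid(40, 20)
        full = richness(d, grid, 1, seed=7)
        sub = richness(d, grid, 1, seed=7, species_subset=["sp0", "sp1"])
        assert (sub["cell_mean"].values <= full["cell_mean"].values + 1e-12).all()
        assert (full["cell_mean"].values <= 5).all()

    def test_empty_subset_rejected(self):
        d = _draws(beta0=np.zeros((2, 2, 2)), beta=np.zeros((2, 2, 1)))
        with pytest.raises(ValueError, match="empty"):
            richness(d, _grid(), 1, seed=0, species_subset=[])


def test_grid_validation():
    with pytest.raises(ValueError, match="landuse"):
        PredictionGrid(cells=pd.DataFrame({"x0": [0.0]}), covariate_names=["x0"])
    with pytest.raises(ValueError, match="covariate"):
        PredictionGrid(cells=pd.DataFrame({"landuse": ["NFM"]}), covariate_names=["x0"])
    with pytest.raises(ValueError, match="unknown landuse"):
        PredictionGrid(
            cells=pd.DataFrame({"landuse": ["plantation"], "x0": [0.0]}),
            covariate_names=["x0"],
        )


def test_end_to_end_prediction_from_fit(small_fit, small_design):
    rng = np.random.default_rng(1)
    cells = pd.DataFrame({"landuse": rng.choice(["NFM", "LPF"], 300)})
    for c in small_design.covariate_names:
        cells[c] = rng.standard_normal(300)
    grid = PredictionGrid(cells=cells, covariate_names=list(small_design.covariate_names))
    tab = pao(small_fit, grid, sample_stride=10, seed=0)
    assert ((tab["mean"] >= 0) & (tab["mean"] <= 100)).all()
    assert (tab["q2.5"] <= tab["q97.5"]).all()
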