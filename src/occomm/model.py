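"""Bayesian hierarchical community occupancy model.

Model
-----
For species ``i`` at station ``j`` with landuse stratum ``lu(j)`` (NFM/LPF),
survey site ``fmu(j)`` (Pasin/Raplex), road placement ``road(j)`` and scaled
habitat covariates ``x_j``:

.. math::

    z_{ij} \\sim \\mathrm{Bernoulli}(\\psi_{ij}),\\qquad
    \\mathrm{logit}\\,\\psi_{ij} = \\beta^0_{i,lu(j)} + \\beta_i^\\top x_j

    y_{ijk} \\mid z_{ij} \\sim \\mathrm{Bernoulli}(z_{ij}\\, p_{ijk}),\\qquad
    \\mathrm{logit}\\, p_{ijk} = \\alpha^0_{i,fmu(j)} + \\alpha^{eff} e_{jk}
        + \\alpha^{road}_i \\, road(j)

with species-level parameters drawn from community distributions:
landuse-specific occupancy intercept hyperparameters, covariate-specific
slope hyperparameters, site-specific detection intercept hyperparameters,
and one community distribution for the road effect.  The effort coefficient
``alpha_eff`` is a single fixed effect shared across species, per functional
camera-day (effort 0-10; internally mean-centred for sampler mixing and
reported on the raw scale).  Occasions with zero effort carry no data and
contribute nothing to the likelihood.

Inference is MCMC with the latent ``z`` marginalized out of the likelihood:
vectorized adaptive random-walk Metropolis for species-level blocks and
hyper-SDs, conjugate Gibbs for the hypermeans.  ``z`` is re-sampled from its
full conditional at each saved draw so state-dependent summaries are
available downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from occomm.core import FMUS, LANDUSES, log_sigmoid, substream

__all__ = [
    "Priors",
    "ModelSpec",
    "MCMCConfig",
    "fit",
    "occupancy_likelihood",
    "rhat",
    "convergence_report",
    "summarize",
]


@dataclass
class Priors:
    """Weakly informative defaults for a logit-scale hierarchical model."""

    hypermean_sd: float = 1.5     # Normal(0, sd) on all hypermeans
    hypersd_scale: float = 1.0    # half-Normal(scale) on all hyper-SDs
    effort_sd: float = 1.5        # Normal(0, sd) on the effort coefficient


@dataclass
class ModelSpec:
    """Design information for one survey: station strata and covariates.

    ``covariates`` must be on the scaled (mean 0, variance 1) analysis
    scale; ``scaler_signature`` optionally records the scaling constants so
    prediction grids can be verified against them.
    """

    landuse: np.ndarray            # (J,) str labels in LANDUSES
    fmu: np.ndarray                # (J,) str labels in FMUS
    road: np.ndarray               # (J,) 0/1
    covariates: pd.DataFrame       # (J, C) scaled
    priors: Priors = field(default_factory=Priors)
    scaler_signature: str | None = None

    def __post_init__(self):
        self.landuse = np.asarray(self.landuse)
        self.fmu = np.asarray(self.fmu)
        self.road = np.asarray(self.road, dtype=float)
        bad_lu = set(self.landuse) - set(LANDUSES)
        if bad_lu:
            raise ValueError(f"unknown landuse labels: {sorted(bad_lu)}")
        bad_fmu = set(self.fmu) - set(FMUS)
        if bad_fmu:
            raise ValueError(f"unknown FMU labels: {sorted(bad_fmu)}")
        X = self.covariates.to_numpy(dtype=float)
        # coarse guard against forgetting to z-scale (e.g. raw elevations)
        if X.size and (
            np.abs(X.mean(axis=0)).max() > 0.5 or np.abs(X.std(axis=0) - 1).max() > 0.5
        ):
            raise ValueError(
                "covariates do not look scaled (column means ~0, SD ~1 expected)"
            )

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    @property
    def landuse_idx(self) -> np.ndarray:
        return np.array([LANDUSES.index(v) for v in self.landuse])

    @property
    def fmu_idx(self) -> np.ndarray:
        return np.array([FMUS.index(v) for v in self.fmu])


@dataclass
class MCMCConfig:
    chains: int = 3
    iterations: int = 6000   # total per chain, including burn-in
    burn_in: int = 2000
    thin: int = 2
    seed: int = 0

    @classmethod
    def full_profile(cls, seed: int = 0) -> "MCMCConfig":
        """The full field protocol: 3 x 300k iterations, 50k burn-in, thin 20."""
        return cls(chains=3, iterations=300_000, burn_in=50_000, thin=20, seed=seed)

    @classmethod
    def desk_profile(cls, seed: int = 0) -> "MCMCConfig":
        """Workstation-scale profile for synthetic surveys."""
        return cls(chains=3, iterations=6000, burn_in=2000, thin=2, seed=seed)

    def validate(self):
        if min(self.chains, self.iterations, self.thin) < 1 or self.burn_in < 0:
            raise ValueError("MCMC settings must be positive")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")


def occupancy_likelihood(psi: float, p: np.ndarray, y: np.ndarray) -> float:
    """Likelihood of one species' detection history at one station,
    marginal over the latent occupancy state.

    ``p`` and ``y`` are occasion-level arrays; occasions with missing data
    (NaN in ``y``) are skipped.  If the species was detected at least once,
    the site must be occupied: the likelihood is
    ``psi * prod_k p_k^y_k (1-p_k)^(1-y_k)``.  Otherwise the all-zero
    history can arise occupied-but-missed or unoccupied:
    ``psi * prod_k (1-p_k) + (1 - psi)``.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    valid = ~np.isnan(y)
    p, y = p[valid], y[valid]
    bern = np.prod(np.where(y == 1, p, 1.0 - p))
    if (y == 1).any():
        out = psi * bern
    else:
        out = psi * bern + (1.0 - psi)
    if not -1e-9 <= out <= 1 + 1e-9:
        raise FloatingPointError(f"marginal likelihood {out} outside [0, 1]")
    return float(out)


# ---------------------------------------------------------------------------
# Sampler internals.  The state is a dict of numpy arrays; likelihood pieces
# are cached: `A[s, j]` is the detection log-likelihood of the history at
# (s, j) conditional on occupancy, and `lpsi[s, j]` the occupancy logit.
# ---------------------------------------------------------------------------


class _Data:
    def __init__(self, spec: ModelSpec, y: np.ndarray, effort: np.ndarray):
        self.spec = spec
        if y.ndim != 3:
            raise ValueError("detection array must be species x station x occasion")
        S, J, K = y.shape
        if effort.shape != (J, K):
            raise ValueError(
                f"effort shape {effort.shape} does not match stations x occasions ({J}, {K})"
            )
        if len(spec.landuse) != J:
            raise ValueError("spec station count does not match detection array")
        mask = effort > 0
        if np.isnan(y[:, mask]).any():
            raise ValueError("missing detections where effort > 0")
        if (~np.isnan(y[:, ~mask])).any():
            raise ValueError("non-missing detections where effort = 0")
        self.S, self.J, self.K = S, J, K
        self.mask = mask
        self.maskf = mask.astype(float)
        self.y = np.nan_to_num(y)                      # (S, J, K)
        self.det_any = (self.y == 1).any(axis=2)       # (S, J)
        self.effort = effort.astype(float)
        self.effort_center = float(self.effort[mask].mean()) if mask.any() else 0.0
        self.e_c = np.where(mask, self.effort - self.effort_center, 0.0)
        self.lu = spec.landuse_idx
        self.fmu = spec.fmu_idx
        self.road = spec.road
        self.X = spec.covariates.to_numpy(dtype=float)  # (J, C)
        self.C = self.X.shape[1]


def _det_ll(data: _Data, alpha0_j, aeff_c, road_s, cols=slice(None)):
    """Detection log-likelihood A[s, j] for a station subset.

    ``alpha0_j``: (S, Jsub) intercept per species/station; ``aeff_c`` scalar
    coefficient on centred effort; ``road_s``: (S,) species road effects.
    """
    lp = (
        alpha0_j[:, :, None]
        + aeff_c * data.e_c[None, cols, :]
        + (road_s[:, None] * data.road[None, cols])[:, :, None]
    )
    # log Bernoulli(y | logit p) = y*lp - log(1 + e^lp), zeroed where masked
    contrib = data.y[:, cols, :] * lp - data.maskf[None, cols, :] * np.logaddexp(0.0, lp)
    return contrib.sum(axis=2)


def _occ_ll(lpsi, A, det_any):
    """Marginal log-likelihood per (species, station)."""
    lp_occ = log_sigmoid(lpsi)
    lp_un = lp_occ - lpsi  # log sigmoid(-x) = log sigmoid(x) - x
    return np.where(det_any, lp_occ + A, np.logaddexp(lp_occ + A, lp_un))


class _State:
    """Current parameter values plus cached likelihood pieces."""

    def __init__(self, data: _Data, rng: np.random.Generator, hierarchical: bool):
        S, C = data.S, data.C
        pr = data.spec.priors
        self.hierarchical = hierarchical
        self.beta0 = rng.normal(0, 0.5, (S, len(LANDUSES)))
        self.beta = rng.normal(0, 0.25, (S, C))
        self.alpha0 = rng.normal(-1.0, 0.5, (S, len(FMUS)))
        self.road = rng.normal(0, 0.25, S)
        self.aeff = rng.normal(0, 0.1)
        self.mu_beta0 = np.zeros(len(LANDUSES))
        self.sd_beta0 = np.ones(len(LANDUSES))
        self.mu_beta = np.zeros(C)
        self.sd_beta = np.full(C, 0.5)
        self.mu_alpha0 = np.full(len(FMUS), -1.0)
        self.sd_alpha0 = np.ones(len(FMUS))
        self.mu_road = 0.0
        self.sd_road = 0.5
        if not hierarchical:
            # Species parameters get the hypermean priors directly
            # (fixed N(0, hypermean_sd)); hyper nodes are frozen.
            self.mu_beta0[:] = 0.0
            self.sd_beta0[:] = pr.hypermean_sd
            self.mu_beta[:] = 0.0
            self.sd_beta[:] = pr.hypermean_sd
            self.mu_alpha0[:] = 0.0
            self.sd_alpha0[:] = pr.hypermean_sd
            self.mu_road = 0.0
            self.sd_road = pr.hypermean_sd
        self.refresh(data)

    def refresh(self, data: _Data):
        self.lpsi = self.beta0[:, data.lu] + self.beta @ data.X.T
        self.A = _det_ll(data, self.alpha0[:, data.fmu], self.aeff, self.road)
        # cached marginal log-likelihood per (species, station)
        self.ll = _occ_ll(self.lpsi, self.A, data.det_any)


def _halfnormal_logpdf(x, scale):
    return -0.5 * (x / scale) ** 2


def fit(
    spec: ModelSpec,
    detections: xr.DataArray | np.ndarray,
    effort: xr.DataArray | np.ndarray,
    config: MCMCConfig | None = None,
    hierarchical: bool = True,
) -> xr.Dataset:
    """Fit the community occupancy model by MCMC.

    Parameters
    ----------
    spec:
        Station strata, covariates and priors.
    detections, effort:
        Species x station x occasion detections (NaN where effort is 0) and
        station x occasion functional camera-days.
    config:
        Chains/iterations/burn-in/thinning; defaults to the desk profile.
    hierarchical:
        If False, species-level parameters get fixed Normal(0, hypermean_sd)
        priors instead of community hyperdistributions (useful for
        single-species checks against grid integration).

    Returns
    -------
    xarray.Dataset with dims ``(chain, draw, ...)``: species-level
    parameters, hyperparameters, the effort coefficient (reported per raw
    camera-day, intercepts at effort 0) and the latent states ``z``.
    """
    config = config or MCMCConfig.desk_profile()
    config.validate()
    y = detections.values if isinstance(detections, xr.DataArray) else np.asarray(detections)
    eff = effort.values if isinstance(effort, xr.DataArray) else np.asarray(effort)
    species = (
        list(detections.coords["species"].values)
        if isinstance(detections, xr.DataArray) and "species" in detections.coords
        else [f"sp{i + 1:02d}" for i in range(y.shape[0])]
    )
    data = _Data(spec, y.astype(float), eff)

    chains = []
    for c in range(config.chains):
        rng = substream(config.seed, f"mcmc-chain-{c}")
        chains.append(_run_chain(data, rng, config, hierarchical))
    ds = xr.concat(chains, dim="chain")
    ds = ds.assign_coords(
        chain=np.arange(config.chains),
        species=species,
        landuse=list(LANDUSES),
        fmu=list(FMUS),
        covariate=spec.covariate_names,
        station=np.arange(data.J),
    )
    ds.attrs.update(
        chains=config.chains,
        iterations=config.iterations,
        burn_in=config.burn_in,
        thin=config.thin,
        seed=config.seed,
        effort_center=data.effort_center,
        hierarchical=int(hierarchical),
    )
    return ds


def _run_chain(data: _Data, rng, config: MCMCConfig, hierarchical: bool) -> xr.Dataset:
    S, C = data.S, data.C
    nL, nF = len(LANDUSES), len(FMUS)
    pr = data.spec.priors
    for attempt in range(10):
        st = _State(data, rng, hierarchical)
        ll = _occ_ll(st.lpsi, st.A, data.det_any).sum()
        if np.isfinite(ll):
            break
    else:
        raise RuntimeError("could not find a finite-density initial state")

    # Adaptive step sizes per scalar component of each RWM block.
    steps = {
        "beta0": np.full((S, nL), 0.3),
        "beta": np.full((S, C), 0.3),
        "alpha0": np.full((S, nF), 0.3),
        "road": np.full(S, 0.3),
        "aeff": 0.05,
        "sd": np.full(nL + C + nF + 1, 0.3),
        "shift": np.full(nL + C + nF + 1, 0.2),
        "scale": np.full(nL + C + nF + 1, 0.2),
    }
    acc = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in steps.items()}
    adapt_window = 50

    n_keep = (config.iterations - config.burn_in) // config.thin
    out = {
        "beta0": np.empty((n_keep, S, nL)),
        "beta": np.empty((n_keep, S, C)),
        "alpha0": np.empty((n_keep, S, nF)),
        "alpha_road": np.empty((n_keep, S)),
        "alpha_eff": np.empty(n_keep),
        "mu_beta0": np.empty((n_keep, nL)),
        "sd_beta0": np.empty((n_keep, nL)),
        "mu_beta": np.empty((n_keep, C)),
        "sd_beta": np.empty((n_keep, C)),
        "mu_alpha0": np.empty((n_keep, nF)),
        "sd_alpha0": np.empty((n_keep, nF)),
        "mu_road": np.empty(n_keep),
        "sd_road": np.empty(n_keep),
        "z": np.empty((n_keep, S, data.J), dtype=np.int8),
    }

    kept = 0
    for it in range(config.iterations):
        _update_psi_blocks(st, data, rng, steps, acc)
        _update_det_blocks(st, data, rng, steps, acc)
        _update_effort(st, data, rng, steps, acc, pr)
        if hierarchical:
            _update_hypers(st, data, rng, steps, acc, pr)
        if it < config.burn_in and (it + 1) % adapt_window == 0:
            _adapt(steps, acc, adapt_window)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            _store(out, kept, st, data, rng)
            kept += 1

    draw = np.arange(n_keep)
    ds = xr.Dataset(
        {
            "beta0": (("draw", "species", "landuse"), out["beta0"]),
            "beta": (("draw", "species", "covariate"), out["beta"]),
            "alpha0": (("draw", "species", "fmu"), out["alpha0"]),
            "alpha_road": (("draw", "species"), out["alpha_road"]),
            "alpha_eff": (("draw",), out["alpha_eff"]),
            "mu_beta0": (("draw", "landuse"), out["mu_beta0"]),
            "sd_beta0": (("draw", "landuse"), out["sd_beta0"]),
            "mu_beta": (("draw", "covariate"), out["mu_beta"]),
            "sd_beta": (("draw", "covariate"), out["sd_beta"]),
            "mu_alpha0": (("draw", "fmu"), out["mu_alpha0"]),
            "sd_alpha0": (("draw", "fmu"), out["sd_alpha0"]),
            "mu_road": (("draw",), out["mu_road"]),
            "sd_road": (("draw",), out["sd_road"]),
            "z": (("draw", "species", "station"), out["z"]),
        },
        coords={"draw": draw},
    ).expand_dims("chain")
    return ds


def _norm_lpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2  # constants cancel in MH ratios


def _update_psi_blocks(st: _State, data: _Data, rng, steps, acc):
    """Vectorized RWM across species for occupancy intercepts and slopes."""
    for l in range(len(LANDUSES)):
        cols = data.lu == l
        prop = st.beta0[:, l] + steps["beta0"][:, l] * rng.standard_normal(data.S)
        delta = (prop - st.beta0[:, l])[:, None]
        lpsi_new = st.lpsi[:, cols] + delta
        ll_new = _occ_ll(lpsi_new, st.A[:, cols], data.det_any[:, cols])
        dprior = _norm_lpdf(prop, st.mu_beta0[l], st.sd_beta0[l]) - _norm_lpdf(
            st.beta0[:, l], st.mu_beta0[l], st.sd_beta0[l]
        )
        accept = np.log(rng.random(data.S)) < (
            ll_new.sum(axis=1) - st.ll[:, cols].sum(axis=1) + dprior
        )
        st.beta0[accept, l] = prop[accept]
        st.lpsi[np.ix_(accept, cols)] = lpsi_new[accept]
        st.ll[np.ix_(accept, np.flatnonzero(cols))] = ll_new[accept]
        acc["beta0"][accept, l] += 1

    for c in range(data.C):
        prop = st.beta[:, c] + steps["beta"][:, c] * rng.standard_normal(data.S)
        lpsi_new = st.lpsi + np.outer(prop - st.beta[:, c], data.X[:, c])
        ll_new = _occ_ll(lpsi_new, st.A, data.det_any)
        dprior = _norm_lpdf(prop, st.mu_beta[c], st.sd_beta[c]) - _norm_lpdf(
            st.beta[:, c], st.mu_beta[c], st.sd_beta[c]
        )
        accept = np.log(rng.random(data.S)) < (
            ll_new.sum(axis=1) - st.ll.sum(axis=1) + dprior
        )
        st.beta[accept, c] = prop[accept]
        st.lpsi[accept] = lpsi_new[accept]
        st.ll[accept] = ll_new[accept]
        acc["beta"][accept, c] += 1


def _update_det_blocks(st: _State, data: _Data, rng, steps, acc):
    """Vectorized RWM across species for detection intercepts and road effects."""
    for f in range(len(FMUS)):
        cols = data.fmu == f
        prop = st.alpha0[:, f] + steps["alpha0"][:, f] * rng.standard_normal(data.S)
        A_new = _det_ll(data, np.repeat(prop[:, None], cols.sum(), 1), st.aeff, st.road, cols)
        ll_new = _occ_ll(st.lpsi[:, cols], A_new, data.det_any[:, cols])
        dprior = _norm_lpdf(prop, st.mu_alpha0[f], st.sd_alpha0[f]) - _norm_lpdf(
            st.alpha0[:, f], st.mu_alpha0[f], st.sd_alpha0[f]
        )
        accept = np.log(rng.random(data.S)) < (
            ll_new.sum(axis=1) - st.ll[:, cols].sum(axis=1) + dprior
        )
        st.alpha0[accept, f] = prop[accept]
        sub = np.flatnonzero(cols)
        st.A[np.ix_(accept, sub)] = A_new[accept]
        st.ll[np.ix_(accept, sub)] = ll_new[accept]
        acc["alpha0"][accept, f] += 1

    cols = data.road == 1
    if cols.any():
        prop = st.road + steps["road"] * rng.standard_normal(data.S)
        fmu_sub = data.fmu[cols]
        A_new = _det_ll(data, st.alpha0[:, fmu_sub], st.aeff, prop, cols)
        ll_new = _occ_ll(st.lpsi[:, cols], A_new, data.det_any[:, cols])
        dprior = _norm_lpdf(prop, st.mu_road, st.sd_road) - _norm_lpdf(
            st.road, st.mu_road, st.sd_road
        )
        accept = np.log(rng.random(data.S)) < (
            ll_new.sum(axis=1) - st.ll[:, cols].sum(axis=1) + dprior
        )
        st.road[accept] = prop[accept]
        sub = np.flatnonzero(cols)
        st.A[np.ix_(accept, sub)] = A_new[accept]
        st.ll[np.ix_(accept, sub)] = ll_new[accept]
        acc["road"][accept] += 1


def _update_effort(st: _State, data: _Data, rng, steps, acc, pr: Priors):
    prop = st.aeff + steps["aeff"] * rng.standard_normal()
    A_new = _det_ll(data, st.alpha0[:, data.fmu], prop, st.road)
    ll_new = _occ_ll(st.lpsi, A_new, data.det_any)
    dprior = _norm_lpdf(prop, 0.0, pr.effort_sd) - _norm_lpdf(st.aeff, 0.0, pr.effort_sd)
    if np.log(rng.random()) < ll_new.sum() - st.ll.sum() + dprior:
        st.aeff = prop
        st.A = A_new
        st.ll = ll_new
        acc["aeff"] += 1


def _gibbs_hypermean(values, sd, prior_sd, rng):
    n = len(values)
    post_var = 1.0 / (1.0 / prior_sd**2 + n / sd**2)
    post_mean = post_var * values.sum() / sd**2
    return rng.normal(post_mean, np.sqrt(post_var))


def _mh_hypersd(values, mu, sd, step, scale, rng):
    """RWM on log(sd) with half-Normal(scale) prior; returns (sd, accepted)."""
    prop = sd * np.exp(step * rng.standard_normal())
    n = len(values)
    ss = ((values - mu) ** 2).sum()

    def logpost(s):
        return (
            -n * np.log(s) - 0.5 * ss / s**2 + _halfnormal_logpdf(s, scale) + np.log(s)
        )  # + log(s) is the log-scale Jacobian

    if np.log(rng.random()) < logpost(prop) - logpost(sd):
        return prop, True
    return sd, False


def _group_delta(st: _State, data: _Data, kind: str, idx: int, v_new: np.ndarray):
    """Log-likelihood change for replacing one species-parameter group's
    values wholesale, plus a closure that applies the move to the cache."""
    if kind == "beta0":
        cols = data.lu == idx
        lpsi_new = st.lpsi[:, cols] + (v_new - st.beta0[:, idx])[:, None]
        ll_new = _occ_ll(lpsi_new, st.A[:, cols], data.det_any[:, cols])
        d_ll = ll_new.sum() - st.ll[:, cols].sum()

        def apply():
            st.beta0[:, idx] = v_new
            st.lpsi[:, cols] = lpsi_new
            st.ll[:, cols] = ll_new

    elif kind == "beta":
        lpsi_new = st.lpsi + np.outer(v_new - st.beta[:, idx], data.X[:, idx])
        ll_new = _occ_ll(lpsi_new, st.A, data.det_any)
        d_ll = ll_new.sum() - st.ll.sum()

        def apply():
            st.beta[:, idx] = v_new
            st.lpsi[:] = lpsi_new
            st.ll[:] = ll_new

    elif kind == "alpha0":
        cols = data.fmu == idx
        A_new = _det_ll(
            data, np.repeat(v_new[:, None], cols.sum(), 1), st.aeff, st.road, cols
        )
        ll_new = _occ_ll(st.lpsi[:, cols], A_new, data.det_any[:, cols])
        d_ll = ll_new.sum() - st.ll[:, cols].sum()

        def apply():
            st.alpha0[:, idx] = v_new
            st.A[:, cols] = A_new
            st.ll[:, cols] = ll_new

    elif kind == "road":
        cols = data.road == 1
        if not cols.any():
            return 0.0, lambda: setattr(st, "road", v_new)
        fmu_sub = data.fmu[cols]
        A_new = _det_ll(data, st.alpha0[:, fmu_sub], st.aeff, v_new, cols)
        ll_new = _occ_ll(st.lpsi[:, cols], A_new, data.det_any[:, cols])
        d_ll = ll_new.sum() - st.ll[:, cols].sum()

        def apply():
            st.road = v_new
            st.A[:, cols] = A_new
            st.ll[:, cols] = ll_new

    else:  # pragma: no cover
        raise KeyError(kind)
    return d_ll, apply


def _interweave_moves(st: _State, data: _Data, rng, steps, acc, pr: Priors, g: int,
                      kind: str, idx: int, get_mu_sd, set_mu_sd):
    """Non-centered (interweaved) joint moves for one hyper-group.

    The centered parameterization mixes poorly when species-level data are
    weak (the classic hierarchical funnel): the hyper-SD cannot grow unless
    all species values spread with it.  Two joint proposals fix this:

    * translate: mu' = mu + d with all species values shifted by d — the
      species-level prior is invariant, so only the likelihood and the
      hypermean prior enter the ratio;
    * rescale: sd' = c*sd with species values moved to mu + c*(theta - mu) —
      the species prior times the transformation Jacobian cancels exactly,
      leaving likelihood, hyper-SD prior and the log-scale proposal Jacobian.
    """
    mu, sd, values = get_mu_sd()

    d = steps["shift"][g] * rng.standard_normal()
    d_ll, apply = _group_delta(st, data, kind, idx, values + d)
    dprior = _norm_lpdf(mu + d, 0.0, pr.hypermean_sd) - _norm_lpdf(mu, 0.0, pr.hypermean_sd)
    if np.log(rng.random()) < d_ll + dprior:
        apply()
        set_mu_sd(mu + d, sd)
        mu, sd, values = get_mu_sd()
        acc["shift"][g] += 1

    c = np.exp(steps["scale"][g] * rng.standard_normal())
    d_ll, apply = _group_delta(st, data, kind, idx, mu + c * (values - mu))
    dprior = (
        _halfnormal_logpdf(c * sd, pr.hypersd_scale)
        - _halfnormal_logpdf(sd, pr.hypersd_scale)
        + np.log(c)  # proposal Jacobian on log(sd)
    )
    if np.log(rng.random()) < d_ll + dprior:
        apply()
        set_mu_sd(mu, c * sd)
        acc["scale"][g] += 1


def _update_hypers(st: _State, data: _Data, rng, steps, acc, pr: Priors):
    groups = []
    for l in range(len(LANDUSES)):
        groups.append(("beta0", l, st.beta0[:, l]))
    for c in range(data.C):
        groups.append(("beta", c, st.beta[:, c]))
    for f in range(len(FMUS)):
        groups.append(("alpha0", f, st.alpha0[:, f]))
    groups.append(("road", 0, st.road))

    for g, (kind, idx, _) in enumerate(groups):
        if kind == "road":
            def get():
                return st.mu_road, st.sd_road, st.road

            def put(mu, sd):
                st.mu_road, st.sd_road = mu, sd

        else:
            mu_arr, sd_arr, val_arr = {
                "beta0": (st.mu_beta0, st.sd_beta0, st.beta0),
                "beta": (st.mu_beta, st.sd_beta, st.beta),
                "alpha0": (st.mu_alpha0, st.sd_alpha0, st.alpha0),
            }[kind]

            def get(mu_arr=mu_arr, sd_arr=sd_arr, val_arr=val_arr, idx=idx):
                return mu_arr[idx], sd_arr[idx], val_arr[:, idx]

            def put(mu, sd, mu_arr=mu_arr, sd_arr=sd_arr, idx=idx):
                mu_arr[idx], sd_arr[idx] = mu, sd

        mu, sd, vals = get()
        mu = _gibbs_hypermean(vals, sd, pr.hypermean_sd, rng)
        sd, ok = _mh_hypersd(vals, mu, sd, steps["sd"][g], pr.hypersd_scale, rng)
        put(mu, sd)
        acc["sd"][g] += ok
        _interweave_moves(st, data, rng, steps, acc, pr, g, kind, idx, get, put)


def _adapt(steps, acc, window):
    for key in ("beta0", "beta", "alpha0", "road", "sd", "shift", "scale"):
        rate = acc[key] / window
        steps[key] = np.clip(steps[key] * np.exp(rate - 0.44), 1e-3, 10.0)
        acc[key][:] = 0.0
    rate = float(acc["aeff"]) / window
    steps["aeff"] = float(np.clip(steps["aeff"] * np.exp(rate - 0.44), 1e-4, 10.0))
    acc["aeff"] = 0.0


def _store(out, k, st: _State, data: _Data, rng):
    out["beta0"][k] = st.beta0
    out["beta"][k] = st.beta
    out["alpha0"][k] = st.alpha0
    out["alpha_road"][k] = st.road
    # Report the detection intercept at effort 0 on the raw camera-day scale.
    out["alpha0"][k] -= st.aeff * data.effort_center
    out["alpha_eff"][k] = st.aeff
    out["mu_beta0"][k] = st.mu_beta0
    out["sd_beta0"][k] = st.sd_beta0
    out["mu_beta"][k] = st.mu_beta
    out["sd_beta"][k] = st.sd_beta
    out["mu_alpha0"][k] = st.mu_alpha0 - st.aeff * data.effort_center
    out["sd_alpha0"][k] = st.sd_alpha0
    out["mu_road"][k] = st.mu_road
    out["sd_road"][k] = st.sd_road
    # z from its full conditional: forced to 1 where the species was
    # detected, otherwise Bernoulli(psi-given-all-zero-history).
    lp_occ = log_sigmoid(st.lpsi) + st.A
    lp_un = log_sigmoid(-st.lpsi)
    p_z = np.exp(lp_occ - np.logaddexp(lp_occ, lp_un))
    z = (rng.random(p_z.shape) < p_z).astype(np.int8)
    z[data.det_any] = 1
    out["z"][k] = z


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------


def rhat(draws: xr.Dataset | np.ndarray, parameter: str | None = None):
    """Gelman-Rubin potential scale reduction factor.

    Accepts either a fitted Dataset plus a parameter name (extra dims are
    broadcast) or a raw ``(chain, draw)`` array.  Returns NaN when both the
    within- and between-chain variances are zero (undefined, *not*
    converged).
    """
    if isinstance(draws, xr.Dataset):
        arr = draws[parameter].values  # (chain, draw, ...)
    else:
        arr = np.asarray(draws, dtype=float)
    if arr.ndim < 2 or arr.shape[0] < 2 or arr.shape[1] < 4:
        raise ValueError("need >= 2 chains and >= 4 draws per chain")
    m, n = arr.shape[:2]
    means = arr.mean(axis=1)                      # (chain, ...)
    W = arr.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / W)
    out = np.where((W == 0) & (B_over_n == 0), np.nan, out)
    return float(out) if np.ndim(out) == 0 else out


def convergence_report(draws: xr.Dataset, threshold: float = 1.1) -> pd.DataFrame:
    """R-hat for every scalar parameter; flags values >= threshold (or NaN)."""
    rows = []
    for name, da in draws.data_vars.items():
        if name == "z":
            continue
        vals = da.values  # (chain, draw, ...)
        m, n = vals.shape[:2]
        flat = vals.reshape(m, n, -1)
        r = rhat(flat) if flat.shape[2] > 1 else np.array([rhat(flat[:, :, 0])])
        extra = [d for d in da.dims if d not in ("chain", "draw")]
        if extra:
            idx = pd.MultiIndex.from_product([da.coords[d].values for d in extra])
            labels = [f"{name}[{','.join(map(str, t))}]" for t in idx]
        else:
            labels = [name]
        for lab, rv in zip(labels, np.atleast_1d(r)):
            rows.append((lab, float(rv), not (rv < threshold)))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "flagged"])


def summarize(
    draws: xr.Dataset,
    parameters: list[str] | None = None,
) -> pd.DataFrame:
    """Posterior mean, SD, 95%/75% credible intervals and support class.

    Draws are pooled across chains (burn-in and thinning were applied at
    sampling time).  A coefficient has *strong* support when the 95%
    credible interval (2.5-97.5 percentiles) excludes zero, *moderate* when
    only the 75% interval (12.5-87.5) does, otherwise *weak*.
    """
    names = parameters or [n for n in draws.data_vars if n != "z"]
    rows = []
    for name in names:
        da = draws[name]
        extra = [d for d in da.dims if d not in ("chain", "draw")]
        flat = da.values.reshape(-1, *da.values.shape[2:])  # pool chains
        if extra:
            stacked = flat.reshape(flat.shape[0], -1)
            idx = pd.MultiIndex.from_product(
                [da.coords[d].values for d in extra]
            ) if len(extra) > 1 else da.coords[extra[0]].values
            labels = [
                f"{name}[{','.join(map(str, i)) if isinstance(i, tuple) else i}]"
                for i in (idx if len(extra) > 1 else list(idx))
            ]
        else:
            stacked = flat.reshape(-1, 1)
            labels = [name]
        q = np.percentile(stacked, [2.5, 12.5, 87.5, 97.5], axis=0)
        mean, sd = stacked.mean(axis=0), stacked.std(axis=0, ddof=1)
        for i, lab in enumerate(labels):
            lo95, lo75, hi75, hi95 = q[0, i], q[1, i], q[2, i], q[3, i]
            if lo95 > 0 or hi95 < 0:
                support = "strong"
            elif lo75 > 0 or hi75 < 0:
                support = "moderate"
            else:
                support = "weak"
            rows.append(
                (lab, mean[i], sd[i], lo95, hi95, lo75, hi75, support,
                 "+" if mean[i] >= 0 else "-")
            )
    return pd.DataFrame(
        rows,
        columns=["parameter", "mean", "sd", "q2.5", "q97.5", "q12.5", "q87.5",
                 "support", "sign"],
    )
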