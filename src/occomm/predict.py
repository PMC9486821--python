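"""Landscape projection: per-cell occupancy, percent area occupied, richness.

Predictions use only the occupancy half of the model (landuse-specific
intercepts plus covariate effects); detection parameters never enter, since
percent area occupied and richness are state quantities, not observation
quantities.  Following the Monte-Carlo protocol of the analysis this
package reproduces, every ``sample_stride``-th pooled posterior sample is
projected, one fresh Bernoulli occupancy draw is made per cell, species and
sample, and summaries (mean, SD, 95% credible interval) are taken over
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from occomm.core import LANDUSES, inv_logit, substream

__all__ = ["PredictionGrid", "predict_psi", "psi_sample_iter", "pao", "richness"]


@dataclass
class PredictionGrid:
    """Cells with scaled covariates and one landuse label each.

    ``scaler_signature`` must match the signature stored on the fitted
    model's :class:`~occomm.model.ModelSpec` (both None is accepted for
    fully synthetic workflows where covariates are generated on the scaled
    scale directly).
    """

    cells: pd.DataFrame
    covariate_names: list[str]
    scaler_signature: str | None = None

    def __post_init__(self):
        missing = set(self.covariate_names) - set(self.cells.columns)
        if missing:
            raise ValueError(f"grid missing covariate columns: {sorted(missing)}")
        if "landuse" not in self.cells.columns:
            raise ValueError("grid must carry a 'landuse' column")
        bad = set(self.cells["landuse"]) - set(LANDUSES)
        if bad:
            raise ValueError(f"unknown landuse labels in grid: {sorted(bad)}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def landuse_idx(self) -> np.ndarray:
        return np.array([LANDUSES.index(v) for v in self.cells["landuse"]])

    @property
    def X(self) -> np.ndarray:
        return self.cells[self.covariate_names].to_numpy(dtype=float)


def _check_scaling(draws: xr.Dataset, grid: PredictionGrid):
    model_sig = draws.attrs.get("scaler_signature")
    if model_sig is not None and grid.scaler_signature != model_sig:
        raise ValueError(
            "prediction grid was not scaled with the model's training "
            "constants (scaler signatures differ)"
        )


def _pooled(draws: xr.Dataset, name: str) -> np.ndarray:
    """Pool chains preserving draw order within each chain."""
    v = draws[name].values
    return v.reshape(-1, *v.shape[2:])


def psi_sample_iter(draws: xr.Dataset, grid: PredictionGrid, sample_stride: int = 20):
    """Yield ``(sample_index, psi)`` with ``psi`` of shape (species, cells)
    for every ``sample_stride``-th pooled posterior sample."""
    _check_scaling(draws, grid)
    beta0 = _pooled(draws, "beta0")   # (N, S, L)
    beta = _pooled(draws, "beta")     # (N, S, C)
    if beta.shape[2] != len(grid.covariate_names):
        raise ValueError("grid covariates do not match the fitted covariate set")
    lu = grid.landuse_idx
    X = grid.X
    for n in range(0, beta0.shape[0], sample_stride):
        lpsi = beta0[n][:, lu] + beta[n] @ X.T
        yield n, inv_logit(lpsi)


def predict_psi(
    draws: xr.Dataset, grid: PredictionGrid, sample_stride: int = 20
) -> np.ndarray:
    """Materialized per-sample occupancy probabilities.

    Shape ``(n_samples, species, cells)``; use :func:`psi_sample_iter` for
    grids too large to hold all samples in memory.
    """
    return np.stack([psi for _, psi in psi_sample_iter(draws, grid, sample_stride)])


def pao(
    draws: xr.Dataset,
    grid: PredictionGrid,
    sample_stride: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Percent area occupied per species and landuse stratum.

    Per posterior sample and species, one Bernoulli variable is drawn per
    cell from the predicted occupancy probability; PAO is 100x the occupied
    fraction of cells within each landuse.  Returns per species x landuse
    the posterior mean, SD and 95% credible interval over samples, with the
    raw per-sample values in the ``samples`` attribute.
    """
    rng = substream(seed, "pao")
    species = list(draws.coords["species"].values)
    lu_idx = grid.landuse_idx
    masks = [lu_idx == l for l in range(len(LANDUSES))]
    per_sample = []
    for _, psi in psi_sample_iter(draws, grid, sample_stride):
        occ = rng.random(psi.shape) < psi
        per_sample.append(
            [100.0 * occ[:, m].mean(axis=1) for m in masks]
        )  # list over landuse of (S,)
    arr = np.array(per_sample)  # (n_samples, L, S)
    rows = []
    for l, lu in enumerate(LANDUSES):
        q = np.percentile(arr[:, l, :], [2.5, 97.5], axis=0)
        for s, sp in enumerate(species):
            rows.append(
                (sp, lu, arr[:, l, s].mean(), arr[:, l, s].std(ddof=1),
                 q[0, s], q[1, s])
            )
    out = pd.DataFrame(
        rows, columns=["species", "landuse", "mean", "sd", "q2.5", "q97.5"]
    )
    out.attrs["samples"] = arr
    return out


def richness(
    draws: xr.Dataset,
    grid: PredictionGrid,
    sample_stride: int = 20,
    seed: int = 0,
    species_subset: list[str] | None = None,
    bernoulli: bool = True,
) -> xr.Dataset:
    """Per-cell species richness with posterior uncertainty.

    Per posterior sample, occupancy states are drawn per species and cell
    (or, with ``bernoulli=False``, expected richness ``sum_i psi_i`` is used
    directly) and summed over species.  Returns per-cell posterior mean/SD
    plus landuse-average richness per sample and its mean/SD.
    """
    rng = substream(seed, "richness")
    species = list(draws.coords["species"].values)
    if species_subset is not None:
        if not species_subset:
            raise ValueError("species subset is empty")
        missing = set(species_subset) - set(species)
        if missing:
            raise ValueError(f"subset species not in model: {sorted(missing)}")
        keep = np.array([sp in set(species_subset) for sp in species])
    else:
        keep = np.ones(len(species), dtype=bool)

    lu_idx = grid.landuse_idx
    masks = [lu_idx == l for l in range(len(LANDUSES))]
    cell_sum = np.zeros(grid.n_cells)
    cell_sumsq = np.zeros(grid.n_cells)
    lu_means = []
    n_samples = 0
    for _, psi in psi_sample_iter(draws, grid, sample_stride):
        psi = psi[keep]
        if bernoulli:
            r = (rng.random(psi.shape) < psi).sum(axis=0).astype(float)
        else:
            r = psi.sum(axis=0)
        cell_sum += r
        cell_sumsq += r**2
        lu_means.append([r[m].mean() for m in masks])
        n_samples += 1
    mean = cell_sum / n_samples
    var = np.maximum(cell_sumsq / n_samples - mean**2, 0.0)
    lu_arr = np.array(lu_means)  # (n_samples, L)
    return xr.Dataset(
        {
            "cell_mean": ("cell", mean),
            "cell_sd": ("cell", np.sqrt(var)),
            "landuse_samples": (("sample", "landuse"), lu_arr),
            "landuse_mean": ("landuse", lu_arr.mean(axis=0)),
            "landuse_sd": ("landuse", lu_arr.std(axis=0, ddof=1)),
        },
        coords={
            "cell": np.arange(grid.n_cells),
            "landuse": list(LANDUSES),
            "sample": np.arange(n_samples),
        },
        attrs={"n_species": int(keep.sum()), "bernoulli": int(bernoulli)},
    )
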