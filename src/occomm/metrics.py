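"""Occupancy-based community metrics: defaunation index, diversity profiles.

Both metrics operate on *mean predicted occupancy* vectors — per species,
the mean of predicted occupancy probability over the cells of one landuse
stratum — computed per posterior sample so that the full posterior of each
metric is propagated.

The defaunation index is a Bray-Curtis-style dissimilarity between a
reference assemblage (the less-disturbed stratum, NFM) and a focal
assemblage (LPF):

    D = sum_i w_i (ref_i - focal_i) / sum_i w_i (ref_i + focal_i),

ranging -1..1; positive values mean species have lost occupancy in the
focal stratum.  Diversity profiles are Hill numbers D_q over an order grid
q >= 0, with occupancy standing in for relative abundance: q = 0 is species
richness, q = 1 exponential Shannon entropy, q = 2 inverse Simpson.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from occomm.core import LANDUSES

__all__ = [
    "mean_occupancy",
    "defaunation_index",
    "defaunation_posterior",
    "DefaunationResult",
    "hill_diversity",
    "diversity_profile",
    "subset_metrics",
]

DEFAULT_Q_GRID = np.round(np.arange(0.0, 4.01, 0.1), 10)


def mean_occupancy(psi_samples: np.ndarray, landuse_idx: np.ndarray) -> dict[str, np.ndarray]:
    """Per-landuse mean predicted occupancy vectors, one per posterior sample.

    ``psi_samples``: (n_samples, species, cells); returns landuse label ->
    (n_samples, species) array of cell-averaged occupancy.
    """
    psi_samples = np.asarray(psi_samples, dtype=float)
    out = {}
    for l, lu in enumerate(LANDUSES):
        m = np.asarray(landuse_idx) == l
        if not m.any():
            raise ValueError(f"no cells with landuse {lu}")
        out[lu] = psi_samples[:, :, m].mean(axis=2)
    return out


def defaunation_index(
    reference: np.ndarray, focal: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Occupancy-based defaunation index of the focal relative to the
    reference assemblage; bounded in [-1, 1]."""
    ref = np.asarray(reference, dtype=float)
    foc = np.asarray(focal, dtype=float)
    if ref.shape != foc.shape:
        raise ValueError("reference and focal vectors differ in length")
    w = np.ones_like(ref) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any() or not (w > 0).any():
        raise ValueError("weights must be >= 0 and not all zero")
    denom = float((w * (ref + foc)).sum())
    if denom == 0:
        raise ValueError("defaunation index undefined: both assemblages all-zero")
    return float((w * (ref - foc)).sum() / denom)


@dataclass
class DefaunationResult:
    mean: float
    sd: float
    q2_5: float
    q97_5: float
    samples: np.ndarray

    def __repr__(self):
        return (
            f"DefaunationResult(mean={self.mean:.4f}, sd={self.sd:.4f}, "
            f"95% BCI=[{self.q2_5:.4f}, {self.q97_5:.4f}], "
            f"n={len(self.samples)})"
        )


def defaunation_posterior(
    reference_samples: np.ndarray,
    focal_samples: np.ndarray,
    weights: np.ndarray | None = None,
) -> DefaunationResult:
    """Posterior of the defaunation index: the index per posterior sample,
    summarized by mean, SD and 95% credible interval."""
    ref = np.atleast_2d(np.asarray(reference_samples, dtype=float))
    foc = np.atleast_2d(np.asarray(focal_samples, dtype=float))
    vals = np.array(
        [defaunation_index(r, f, weights) for r, f in zip(ref, foc)]
    )
    q = np.percentile(vals, [2.5, 97.5])
    sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
    return DefaunationResult(float(vals.mean()), float(sd), float(q[0]), float(q[1]), vals)


def hill_diversity(occ: np.ndarray, q: float) -> float:
    """Hill number of order q for an occupancy vector.

    Occupancies are normalized to relative weights p_i = occ_i / sum(occ);
    zero-occupancy species are excluded.  D_0 is the count of species with
    positive occupancy; D_1 the exponential of Shannon entropy (the q -> 1
    continuity limit); general q uses (sum p_i^q)^(1/(1-q)).
    """
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    occ = np.asarray(occ, dtype=float)
    if (occ < 0).any():
        raise ValueError("occupancies must be >= 0")
    occ = occ[occ > 0]
    if occ.size == 0:
        raise ValueError("all-zero occupancy vector has no diversity")
    # log-space for robustness to extreme occupancy ratios
    logp = np.log(occ) - np.log(occ.sum())
    if abs(q - 1.0) < 1e-10:
        return float(np.exp(-(np.exp(logp) * logp).sum()))
    from scipy.special import logsumexp

    return float(np.exp(logsumexp(q * logp) / (1.0 - q)))


def diversity_profile(
    occ_samples: np.ndarray, q_grid: np.ndarray = DEFAULT_Q_GRID
) -> pd.DataFrame:
    """Posterior diversity profile over an order grid.

    ``occ_samples``: (n_samples, species) occupancy vectors.  Returns per q
    the posterior mean and SD of D_q; the evenness diagnostic D_2/D_0
    (posterior mean) is stored in ``attrs["evenness"]`` and the per-sample
    profile matrix in ``attrs["samples"]``.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid.size < 2 or (np.diff(q_grid) <= 0).any():
        raise ValueError("q_grid must be sorted and contain >= 2 points")
    for marker in (0.0, 1.0, 2.0):
        if not np.isclose(q_grid, marker).any():
            raise ValueError(f"q_grid must include q = {marker:g}")
    occ = np.atleast_2d(np.asarray(occ_samples, dtype=float))
    prof = np.array([[hill_diversity(row, q) for q in q_grid] for row in occ])
    out = pd.DataFrame(
        {
            "q": q_grid,
            "mean": prof.mean(axis=0),
            "sd": prof.std(axis=0, ddof=1) if len(prof) > 1 else np.zeros(len(q_grid)),
        }
    )
    i0 = int(np.argmin(np.abs(q_grid - 0.0)))
    i2 = int(np.argmin(np.abs(q_grid - 2.0)))
    out.attrs["evenness"] = float((prof[:, i2] / prof[:, i0]).mean())
    out.attrs["samples"] = prof
    return out


def subset_metrics(
    reference_samples: np.ndarray,
    focal_samples: np.ndarray,
    flags: np.ndarray,
    q_grid: np.ndarray = DEFAULT_Q_GRID,
    weights: np.ndarray | None = None,
) -> tuple[DefaunationResult, pd.DataFrame]:
    """Defaunation index and (focal-stratum) diversity profile restricted to
    flagged (threatened/endemic) species."""
    flags = np.asarray(flags, dtype=bool)
    if not flags.any():
        raise ValueError("no species flagged; subset metrics undefined")
    ref = np.atleast_2d(reference_samples)[:, flags]
    foc = np.atleast_2d(focal_samples)[:, flags]
    w = None if weights is None else np.asarray(weights)[flags]
    return (
        defaunation_posterior(ref, foc, w),
        diversity_profile(foc, q_grid),
    )
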