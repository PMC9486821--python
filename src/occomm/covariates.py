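"""Habitat covariate engineering and collinearity screening.

Computes the derived covariates used in the occupancy model — terrain
ruggedness from an elevation raster, quartic-kernel village density, and
distance to the nearest access feature (logging road, skid trail or large
river) — plus z-scaling with stored constants and Spearman-based
collinearity screening with the majority-support retention rule.

All geometry is planar: coordinates must be projected (metres) before use.
Raster layers are plain 2-D numpy arrays; vector features are shapely
geometries (or anything ``shapely.geometry.shape`` accepts).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

log = logging.getLogger(__name__)


def terrain_ruggedness(grid: np.ndarray, window: int = 3) -> np.ndarray:
    """Terrain ruggedness index: mean |elevation difference| to neighbours.

    For each cell, the mean absolute difference between the focal cell and
    every other cell of the ``window x window`` neighbourhood (3 or 7 in the
    standard formulations).  Edge cells use the neighbours that exist.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    z = np.asarray(grid, dtype=float)
    if z.ndim != 2:
        raise ValueError("elevation grid must be 2-D")
    if not np.isfinite(z).all():
        raise ValueError("elevation grid contains non-finite values")
    r = window // 2
    total = np.zeros_like(z)
    count = np.zeros_like(z)
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            if di == 0 and dj == 0:
                continue
            shifted = _shift(z, di, dj)
            valid = ~np.isnan(shifted)
            total[valid] += np.abs(z - shifted)[valid]
            count += valid
    return total / count


def _shift(z: np.ndarray, di: int, dj: int) -> np.ndarray:
    """Shift a 2-D array, padding exposed edges with NaN."""
    out = np.full_like(z, np.nan)
    src_i = slice(max(0, -di), z.shape[0] - max(0, di))
    dst_i = slice(max(0, di), z.shape[0] + min(0, di))
    src_j = slice(max(0, -dj), z.shape[1] - max(0, dj))
    dst_j = slice(max(0, dj), z.shape[1] + min(0, dj))
    out[dst_i, dst_j] = z[src_i, src_j]
    return out


def village_density(
    points: np.ndarray, villages: np.ndarray, radius: float = 15000.0
) -> np.ndarray:
    """Quartic-kernel density of village points within a search radius.

    For each query point, sums ``(1 - (d/r)^2)^2`` over villages with
    ``d < r``.  The kernel's global normalizing constant is omitted: the
    covariate is z-scored before modelling, so any constant factor cancels.
    An empty village set gives density 0 everywhere.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vil = np.asarray(villages, dtype=float).reshape(-1, 2)
    if vil.size == 0:
        out = np.zeros(len(pts))
    else:
        d = np.hypot(
            pts[:, None, 0] - vil[None, :, 0], pts[:, None, 1] - vil[None, :, 1]
        )
        u = d / radius
        k = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
        out = k.sum(axis=1)
    return out if np.asarray(points).ndim == 2 else float(out[0])


def distance_to_access(points, access_features) -> np.ndarray:
    """Planar distance (same units as coordinates) to the nearest access
    feature — any mix of shapely points, lines or GeoJSON-like mappings.

    Line features are treated as continuous: the distance is to the nearest
    point on the segment, not to its vertices.
    """
    feats = [
        f if isinstance(f, BaseGeometry) else shape(f) for f in access_features
    ]
    if not feats:
        raise ValueError("access feature set is empty")
    from shapely.geometry import Point

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.array(
        [min(Point(x, y).distance(f) for f in feats) for x, y in pts]
    )
    return out if np.asarray(points).ndim == 2 else float(out[0])


@dataclass
class Scaler:
    """Column z-scaler with stored constants, so prediction grids are scaled
    with the same statistics as the modelled stations."""

    means: pd.Series
    sds: pd.Series

    @classmethod
    def fit(cls, df: pd.DataFrame, columns: list[str] | None = None) -> "Scaler":
        cols = list(columns) if columns is not None else list(df.columns)
        sub = df[cols].astype(float)
        if sub.isna().any().any():
            raise ValueError("covariate matrix has missing values")
        sds = sub.std(ddof=0)
        if (sds == 0).any():
            bad = list(sds.index[sds == 0])
            raise ValueError(f"constant covariate column(s): {bad}")
        return cls(means=sub.mean(), sds=sds)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c in self.means.index:
            out[c] = (df[c].astype(float) - self.means[c]) / self.sds[c]
        return out

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c in self.means.index:
            out[c] = df[c].astype(float) * self.sds[c] + self.means[c]
        return out

    def signature(self) -> str:
        """Stable fingerprint of the scaling constants; used to verify that
        prediction grids were scaled with the training statistics."""
        payload = {
            c: (round(float(self.means[c]), 12), round(float(self.sds[c]), 12))
            for c in self.means.index
        }
        return json.dumps(payload, sort_keys=True)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.signature())

    @classmethod
    def from_json(cls, path: str | Path) -> "Scaler":
        d = json.loads(Path(path).read_text())
        cols = list(d)
        return cls(
            means=pd.Series({c: d[c][0] for c in cols}),
            sds=pd.Series({c: d[c][1] for c in cols}),
        )


def spearman_screen(
    matrix: pd.DataFrame, threshold: float = 0.7
) -> list[tuple[str, str, float]]:
    """All unordered covariate pairs with |Spearman rho| above the threshold.

    Rank correlation uses midranks for ties.  Constant columns have
    undefined rho; they are excluded from pairing with a warning.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 stations to screen correlations")
    cols = list(matrix.columns)
    constant = [c for c in cols if matrix[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant column(s) excluded from correlation screen: {constant}",
            stacklevel=2,
        )
    usable = [c for c in cols if c not in constant]
    flagged = []
    for a, b in combinations(usable, 2):
        rho = stats.spearmanr(matrix[a], matrix[b]).statistic
        if abs(rho) > threshold:
            flagged.append((a, b, float(rho)))
    return flagged


def retain_covariate(
    pair: tuple[str, str], single_covariate_fits: dict[str, pd.DataFrame]
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Choose which member of a correlated covariate pair to keep.

    ``single_covariate_fits`` maps covariate name -> the support table of a
    single-covariate community occupancy fit (as from
    :func:`occomm.model.summarize`, restricted to that covariate's
    species-level slopes).  The member with more strongly supported species
    (95% credible interval excluding zero) is retained; ties go to the
    member with more moderately supported species, then alphabetically.
    """
    counts = {}
    for name in pair:
        tab = single_covariate_fits[name]
        strong = int((tab["support"] == "strong").sum())
        moderate = int((tab["support"] == "moderate").sum())
        counts[name] = (strong, moderate)
    a, b = pair
    key = lambda n: (counts[n][0], counts[n][1], -ord(n[0]))  # noqa: E731
    if counts[a] == counts[b]:
        chosen = min(a, b)
    else:
        chosen = a if key(a) > key(b) else b
    log.info(
        "retained %s from pair %s (strong/moderate counts %s)", chosen, pair, counts
    )
    return chosen, counts
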