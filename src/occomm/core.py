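"""Shared constants and small numeric helpers."""

from __future__ import annotations

import zlib

import numpy as np

#: Landuse strata, in index order used throughout the package.
LANDUSES = ("NFM", "LPF")

#: Survey sites (forest management units), in index order.
FMUS = ("Pasin", "Raplex")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from one global seed.

    Every stage of the pipeline draws from its own substream so that, e.g.,
    changing the number of MCMC iterations does not perturb the synthetic
    survey that was generated from the same config seed.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def inv_logit(x):
    """Numerically stable logistic function."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def log_sigmoid(x):
    """log(1 / (1 + exp(-x))), stable for large |x|."""
    x = np.asarray(x, dtype=float)
    return -np.logaddexp(0.0, -x)
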