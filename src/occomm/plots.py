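"""Plot helpers for report artifacts (matplotlib, file output only)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_defaunation(samples, mean, bci, path: str | Path):
    """Histogram of the defaunation-index posterior with mean and 95% BCI."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(np.asarray(samples), bins=30, color="#7fb3d5", edgecolor="white")
    ax.axvline(mean, color="k", lw=1.5, label=f"mean = {mean:.3f}")
    for b in bci:
        ax.axvline(b, color="k", lw=1, ls=":")
    ax.set_xlabel("defaunation index")
    ax.set_ylabel("posterior samples")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_diversity_profiles(profiles: dict, path: str | Path):
    """Diversity profiles (mean with SD shading) per landuse stratum."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    colors = {"NFM": "#1b7837", "LPF": "#b35806"}
    for label, df in profiles.items():
        c = colors.get(label, None)
        ax.plot(df["q"], df["mean"], label=label, color=c)
        ax.fill_between(
            df["q"], df["mean"] - df["sd"], df["mean"] + df["sd"],
            alpha=0.25, color=c,
        )
    for q in (0, 1, 2):
        ax.axvline(q, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("diversity order q")
    ax.set_ylabel("Hill diversity $D_q$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
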