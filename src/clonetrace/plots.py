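"""Optional plotting helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .divmetrics import cumulative_abundance_curve, relative_abundance

__all__ = ["plot_cumulative_abundance", "plot_rank_abundance", "plot_rarefaction"]


def plot_cumulative_abundance(counts_by_sample: dict, path: str) -> None:
    """Cumulative clone-abundance curves, one line per sample."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, counts in counts_by_sample.items():
        curve = cumulative_abundance_curve(relative_abundance(counts))
        ax.plot(curve["rank"], curve["cumulative_fraction"], label=name)
    ax.set_xscale("log")
    ax.set_xlabel("clone rank")
    ax.set_ylabel("cumulative read fraction")
    ax.axhline(0.5, ls=":", c="grey", lw=0.8)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rank_abundance(counts, path: str, sample: str = "") -> None:
    """Clone frequencies ranked from most to least abundant."""
    p = relative_abundance(counts).sort_values(ascending=False)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(range(1, len(p) + 1), p.values, lw=1)
    ax.set_yscale("log")
    ax.set_xlabel("clone rank")
    ax.set_ylabel("clone frequency")
    if sample:
        ax.set_title(sample)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rarefaction(curves: dict[str, pd.DataFrame], path: str) -> None:
    """Shannon index vs subsampled read depth, one line per sample."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        ax.errorbar(curve["depth"], curve["shannon_mean"], yerr=curve["shannon_sd"],
                    label=name, capsize=2)
    ax.set_xscale("log")
    ax.set_xlabel("subsampled read depth")
    ax.set_ylabel("Shannon index")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
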