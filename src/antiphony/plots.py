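"""Optional figures: correlograms with Poisson limits, LMM diagnostics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .exchange import Correlogram, poisson_limits  # noqa: E402


def plot_correlogram(correlogram: Correlogram, alpha: float = 0.05,
                     path=None, title: str | None = None):
    """Lag histogram with baseline rate and Poisson limits overlaid."""
    lo, up, lam = poisson_limits(correlogram.baseline_counts, alpha=alpha)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(correlogram.bin_centers, correlogram.counts,
           width=correlogram.bin_width, color="0.4", edgecolor="none")
    ax.axhline(lam, color="tab:blue", lw=1, label=f"baseline λ = {lam:.2f}")
    ax.axhline(up, color="tab:red", ls="--", lw=1,
               label=f"{100 * (1 - alpha):.0f}% limits")
    if lo > 0:
        ax.axhline(lo, color="tab:red", ls="--", lw=1)
    ax.axvspan(0, 0.5, color="tab:orange", alpha=0.12, label="answer window")
    ax.set_xlabel("lag of partner call relative to focal call (s)")
    ax.set_ylabel("count")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_lmm_diagnostics(fitted, path=None):
    """Residual-vs-fitted, residual distribution and residual QQ panels."""
    import scipy.stats as sps

    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    axes[0].scatter(fitted.fittedvalues, fitted.resid, s=10, color="0.3")
    axes[0].axhline(0, color="tab:red", lw=1)
    axes[0].set_xlabel("fitted")
    axes[0].set_ylabel("residual")
    axes[1].hist(fitted.resid, bins=20, color="0.5")
    axes[1].set_xlabel("residual")
    sps.probplot(fitted.resid, plot=axes[2])
    axes[2].set_title("")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
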