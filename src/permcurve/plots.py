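"""Static plots: p-value traces, the U-curve, fragility bars and the
selection coverage plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_traces", "plot_ucurve", "plot_fragility", "plot_coverage", "plot_all"]


def _neglog10(p):
    return -np.log10(np.maximum(p, 1e-300))


def plot_traces(fitted, path, max_features: int = 100) -> None:
    """-log10 median p-value of each feature against the mixing proportion,
    colored by observed significance rank."""
    tr = fitted.traces_
    x = tr.ks / tr.K
    order = np.argsort(fitted.selection_.observed_p, kind="stable")[:max_features]
    cmap = plt.get_cmap("rainbow")
    fig, ax = plt.subplots(figsize=(7, 5))
    for rank, j in enumerate(order):
        ax.plot(x, _neglog10(tr.p_median[:, j]),
                color=cmap(rank / max(len(order) - 1, 1)), lw=0.8)
    ax.axhline(-np.log10(tr.alpha), color="grey", ls="--", lw=1)
    ax.set_xlabel("proportion of mixing k/K")
    ax.set_ylabel(r"$-\log_{10}$ median p-value")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ucurve(fitted, path) -> None:
    """Proportion of significant features against the mixing proportion,
    with 2.5-97.5% per-draw bands."""
    c = fitted.curve_
    fig, ax = plt.subplots(figsize=(7, 5))
    y = c.nsig / c.n_features
    ax.vlines(c.mixing, c.nsig_q025 / c.n_features, c.nsig_q975 / c.n_features,
              color="black", lw=1)
    ax.plot(c.mixing[1:], y[1:], "ko", ms=4)
    ax.plot(c.mixing[0], y[0], "r^", ms=8)
    ax.set_xlabel("proportion of mixing k/K")
    ax.set_ylabel("proportion of significant features")
    ax.set_title(f"AOI={c.aoi:.3g}  AUMC={c.aumc:.3g}  slope0={c.slope0:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fragility(fitted, path, top: int = 50) -> None:
    """Fragility index of the most significant features, most robust first."""
    fr = fitted.fragility_
    order = np.argsort(fitted.selection_.observed_p, kind="stable")[:top]
    fi = fr.fi[order]
    rank = np.argsort(-fi, kind="stable")
    fig, ax = plt.subplots(figsize=(8, 4))
    levels = {v: i for i, v in enumerate(np.unique(fi))}
    cmap = plt.get_cmap("viridis")
    colors = [cmap(levels[v] / max(len(levels) - 1, 1)) for v in fi[rank]]
    ax.bar(np.arange(len(rank)), fi[rank], color=colors)
    ax.set_xlabel(f"top {len(rank)} features (decreasing fragility)")
    ax.set_ylabel("fragility index")
    ax.set_ylim(0, fr.K_f + 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_coverage(fitted, path, top: int = 50) -> None:
    """Observed -log10 p of the top features against the 95% band of the
    fully mixed null: selected features lie right of their bar."""
    sel = fitted.selection_
    order = np.argsort(sel.observed_p, kind="stable")[:top]
    ypos = np.arange(len(order))[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.16 * len(order) + 2))
    ax.hlines(ypos, sel.null_band_low[order], sel.null_band_high[order],
              color="grey", lw=2, label="95% null band at $K_f$")
    colors = np.where(sel.selected[order], "tab:red", "tab:blue")
    ax.scatter(sel.observed_neglogp[order], ypos, c=colors, s=14, zorder=3)
    ax.set_yticks(ypos)
    ax.set_yticklabels([str(sel.feature_ids[j]) for j in order], fontsize=6)
    ax.set_xlabel(r"$-\log_{10}$ p-value")
    ax.legend(loc="lower right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_all(fitted, outdir) -> None:
    outdir = Path(outdir)
    plot_traces(fitted, outdir / "traces.png")
    plot_ucurve(fitted, outdir / "ucurve.png")
    plot_fragility(fitted, outdir / "fragility.png")
    plot_coverage(fitted, outdir / "coverage.png")
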