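"""Study plots: true-vs-estimated global effects and coverage histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def global_ce_scatter(rounds: pd.DataFrame, method: str = "egger", ax=None):
    """True vs estimated global CEs with ±2·sigma (blue) and ±2·tau (orange) bars."""
    sub = rounds[rounds["method"] == method]
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    x = sub["true_global"].to_numpy()
    y = sub["estimate"].to_numpy()
    ax.errorbar(x, y, yerr=2 * sub["tau"], fmt="none", ecolor="tab:orange",
                elinewidth=2, alpha=0.7, label=r"$\pm 2\tau$")
    ax.errorbar(x, y, yerr=2 * sub["sigma"], fmt="o", ecolor="tab:blue",
                color="k", ms=3, elinewidth=2, label=r"$\pm 2\sigma$")
    lims = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax.plot(lims, lims, "k--", lw=0.8)
    ax.set_xlabel("true global CE")
    ax.set_ylabel("estimated global CE")
    ax.set_title(method)
    ax.legend(frameon=False)
    return ax


def local_coverage_hist(rounds: pd.DataFrame, method: str = "egger", ax=None):
    """Per-round local 95% CI coverage distribution with the mean marked."""
    sub = rounds[rounds["method"] == method]
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    cov = sub["local_coverage"].dropna().to_numpy()
    ax.hist(cov, bins=np.linspace(0, 1, 21), color="tab:gray")
    if cov.size:
        ax.axvline(cov.mean(), color="tab:red", label=f"mean {cov.mean():.2f}")
        ax.legend(frameon=False)
    ax.set_xlabel("local CE 95% CI coverage")
    ax.set_ylabel("rounds")
    return ax


def study_figure(rounds: pd.DataFrame, out_path: str | Path) -> Path:
    """Two-row study figure (scatter + coverage) for each MR method."""
    methods = sorted(rounds["method"].unique())
    fig, axes = plt.subplots(2, len(methods), figsize=(4 * len(methods), 7),
                             squeeze=False)
    for j, method in enumerate(methods):
        global_ce_scatter(rounds, method, ax=axes[0][j])
        local_coverage_hist(rounds, method, ax=axes[1][j])
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
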