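"""Random-effects meta-analysis of per-region causal effects.

Each sequence region is a 'study' with an effect estimate and standard
error; the global causal effect is the DerSimonian–Laird random-effects
mean.  Two dispersion scales are reported: sigma, the standard error of
the meta-analytic mean, and tau, the between-region SD; the ±2·sigma
and ±2·tau intervals come from `interval`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class GlobalCE:
    """Meta-analytic global causal effect for one exposure/outcome pair."""

    pair: str
    mean: float
    sigma: float  # standard error of the mean
    tau: float  # between-region SD
    n_regions: int
    weights: np.ndarray = field(repr=False, default=None)


def dersimonian_laird_tau2(
    estimates: np.ndarray, ses: np.ndarray
) -> tuple[float, float]:
    """DerSimonian–Laird between-study variance; returns (tau2, Q)."""
    w = 1.0 / ses**2
    theta_fixed = np.sum(w * estimates) / np.sum(w)
    q = float(np.sum(w * (estimates - theta_fixed) ** 2))
    k = estimates.size
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    return float(tau2), q


def random_effects_meta(
    local_ces: pd.DataFrame | None = None,
    *,
    estimates: np.ndarray | None = None,
    ses: np.ndarray | None = None,
    pair: str = "exposure->outcome",
    method: str = "dl",
) -> GlobalCE:
    """DerSimonian–Laird random-effects pooling of local causal effects.

    Accepts either a local-CE table (columns ``estimate``, ``se``) or raw
    arrays.  Non-finite rows are dropped.  ``method="reml"`` switches to
    an iterated (REML) tau² estimate; the classical DL moment estimator
    is the default.
    """
    if local_ces is not None:
        estimates = local_ces["estimate"].to_numpy(dtype=float)
        ses = local_ces["se"].to_numpy(dtype=float)
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    ok = np.isfinite(estimates) & np.isfinite(ses) & (ses > 0)
    estimates, ses = estimates[ok], ses[ok]
    # a region with an (essentially) zero standard error would absorb all
    # inverse-variance weight; such fits are degenerate (e.g. a perfect
    # 3-instrument regression), not infinitely informative — drop them
    if ses.size:
        floor = max(1e-8, 1e-4 * float(np.median(ses)))
        degenerate = ses < floor
        if degenerate.any():
            warnings.warn(
                f"dropping {int(degenerate.sum())} regions with degenerate "
                f"(near-zero) standard errors"
            )
            estimates, ses = estimates[~degenerate], ses[~degenerate]
    k = estimates.size
    if k == 0:
        raise ValueError("no usable regions for meta-analysis")
    if k == 1:
        warnings.warn("single region: degenerate meta-analysis with tau = 0")
        return GlobalCE(
            pair=pair,
            mean=float(estimates[0]),
            sigma=float(ses[0]),
            tau=0.0,
            n_regions=1,
            weights=np.ones(1),
        )
    if method == "dl":
        tau2, _ = dersimonian_laird_tau2(estimates, ses)
    elif method == "reml":
        tau2 = _reml_tau2(estimates, ses)
    else:
        raise ValueError(f"unknown meta-analysis method {method!r}")
    w_star = 1.0 / (ses**2 + tau2)
    mean = float(np.sum(w_star * estimates) / np.sum(w_star))
    sigma = float(1.0 / np.sqrt(np.sum(w_star)))
    return GlobalCE(
        pair=pair,
        mean=mean,
        sigma=sigma,
        tau=float(np.sqrt(tau2)),
        n_regions=k,
        weights=w_star / np.sum(w_star),
    )


def _reml_tau2(estimates: np.ndarray, ses: np.ndarray, tol: float = 1e-10) -> float:
    """Iterated REML estimate of tau² (fixed-point updates)."""
    tau2 = dersimonian_laird_tau2(estimates, ses)[0]
    for _ in range(200):
        w = 1.0 / (ses**2 + tau2)
        mu = np.sum(w * estimates) / np.sum(w)
        num = np.sum(w**2 * ((estimates - mu) ** 2 - ses**2)) + np.sum(
            w**2 * tau2 / np.sum(w)
        )
        new = max(0.0, float(num / np.sum(w**2)))
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    return tau2


def interval(global_ce: GlobalCE, k: float = 2.0) -> dict[str, tuple[float, float]]:
    """mean ± k·sigma and mean ± k·tau interval bounds (both reported)."""
    m = global_ce.mean
    return {
        "sigma": (m - k * global_ce.sigma, m + k * global_ce.sigma),
        "tau": (m - k * global_ce.tau, m + k * global_ce.tau),
    }


def global_ce_table(results: list[GlobalCE]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair": g.pair,
                "mean": g.mean,
                "sigma": g.sigma,
                "tau": g.tau,
                "n_regions": g.n_regions,
            }
            for g in results
        ]
    )


def forest_table(local_ces: pd.DataFrame, global_ce: GlobalCE) -> pd.DataFrame:
    """Long-format forest-plot-ready table: per-region rows plus the pooled row."""
    rows = local_ces[["region_id", "estimate", "se"]].copy()
    rows["kind"] = "region"
    pooled = pd.DataFrame(
        [
            {
                "region_id": global_ce.pair,
                "estimate": global_ce.mean,
                "se": global_ce.sigma,
                "kind": "pooled",
            }
        ]
    )
    return pd.concat([rows, pooled], ignore_index=True)


def write_global_ces(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
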