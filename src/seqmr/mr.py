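"""Per-region Mendelian randomization: Wald-ratio baseline and MR-Egger.

Each sequence region contributes a set of filtered instruments (point
mutations with exposure/outcome effect sizes and standard errors) and
yields one local causal effect estimate with a standard error:

* ``wald_baseline`` — the mean of the per-instrument Wald ratios
  beta_Y / beta_X, with the sample SD of the ratios as the interval basis.
* ``mr_egger`` — regression of outcome effects on exposure effects with
  an intercept (the directional-pleiotropy term), instruments oriented so
  beta_X >= 0 and weighted by 1 / se_Y² (NO-Measurement-Error convention:
  exposure-side error is not propagated into the weights).  By default
  the fit is a robust Huber M-estimate, giving some protection against
  invalid instruments; plain weighted least squares is available via
  ``robust=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

MIN_INSTRUMENTS_EGGER = 3
_SE_FLOOR = 1e-10


class SingularFitError(ValueError):
    """No spread in exposure effects after orientation; MR-Egger undefined."""


@dataclass
class LocalCE:
    """One sequence-region causal effect (one 'study' for meta-analysis)."""

    region_id: str
    method: str  # "baseline" | "egger"
    estimate: float
    se: float
    n_instruments: int
    intercept: float | None = None
    intercept_se: float | None = None


def _instrument_arrays(instruments: pd.DataFrame):
    bx = instruments["beta_X"].to_numpy(dtype=float)
    by = instruments["beta_Y"].to_numpy(dtype=float)
    sy = instruments["se_Y"].to_numpy(dtype=float)
    return bx, by, sy


def wald_baseline(
    instruments: pd.DataFrame, region_id: str = "region", sd_of_mean: bool = False
) -> LocalCE:
    """Average of per-instrument Wald ratios beta_Y / beta_X.

    The reported standard error is the sample SD of the ratios (a
    deliberately conservative interval basis); ``sd_of_mean=True``
    divides by sqrt(k) instead.  Instruments with beta_X = 0 are dropped
    with a log message; with a single usable instrument the SD is
    undefined and the se is NaN.
    """
    bx, by, _ = _instrument_arrays(instruments)
    usable = bx != 0
    if np.sum(~usable):
        logger.info(
            "%s: dropped %d instruments with zero exposure effect",
            region_id,
            int(np.sum(~usable)),
        )
    bx, by = bx[usable], by[usable]
    if bx.size == 0:
        raise ValueError(f"{region_id}: no usable instruments for Wald baseline")
    ratios = by / bx
    estimate = float(ratios.mean())
    if ratios.size > 1:
        se = float(ratios.std(ddof=1))
        if sd_of_mean:
            se /= np.sqrt(ratios.size)
    else:
        se = float("nan")
    return LocalCE(
        region_id=region_id,
        method="baseline",
        estimate=estimate,
        se=se,
        n_instruments=int(bx.size),
    )


def mr_egger(
    instruments: pd.DataFrame, region_id: str = "region", robust: bool = True
) -> LocalCE:
    """MR-Egger: intercept + slope regression of beta_Y on beta_X.

    Instruments are first oriented so all exposure effects are
    nonnegative (both betas flipped together), the standard convention
    that makes the pleiotropy intercept meaningful.  The slope is the
    causal-effect estimate.  With ``robust=True`` (default) the weighted
    regression is fit by a Huber M-estimator (tuning constant 1.345)
    with robust standard errors; otherwise plain WLS.
    """
    bx, by, sy = _instrument_arrays(instruments)
    if bx.size < MIN_INSTRUMENTS_EGGER:
        raise ValueError(
            f"{region_id}: MR-Egger needs >= {MIN_INSTRUMENTS_EGGER} instruments, "
            f"got {bx.size}"
        )
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    if np.ptp(bx) < 1e-12:
        raise SingularFitError(
            f"{region_id}: no spread in oriented exposure effects"
        )
    w = 1.0 / np.maximum(sy, _SE_FLOOR) ** 2
    sqw = np.sqrt(w)
    exog = np.column_stack([sqw, bx * sqw])  # [intercept, slope] in weighted space
    endog = by * sqw
    if robust:
        fit = sm.RLM(endog, exog, M=sm.robust.norms.HuberT(t=1.345)).fit()
    else:
        fit = sm.OLS(endog, exog).fit()
    return LocalCE(
        region_id=region_id,
        method="egger",
        estimate=float(fit.params[1]),
        se=float(fit.bse[1]),
        n_instruments=int(bx.size),
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
    )


def region_causal_effects(
    effects: pd.DataFrame,
    methods: tuple[str, ...] = ("egger", "baseline"),
    robust: bool = True,
    sd_of_mean: bool = False,
) -> pd.DataFrame:
    """Run the requested MR methods on every region of an effects table.

    ``effects`` is the mutagenesis TSV (already filtered or carrying a
    ``kept`` flag).  Regions that cannot support a method (too few
    instruments, singular fit) are skipped with a log message.
    """
    rows = []
    kept = effects[effects["kept"]] if "kept" in effects.columns else effects
    for region_id, group in kept.groupby("region_id", sort=False):
        for method in methods:
            try:
                if method == "egger":
                    ce = mr_egger(group, region_id=str(region_id), robust=robust)
                elif method == "baseline":
                    ce = wald_baseline(
                        group, region_id=str(region_id), sd_of_mean=sd_of_mean
                    )
                else:
                    raise ValueError(f"unknown MR method {method!r}")
            except (ValueError, SingularFitError) as e:
                logger.info("skipping %s/%s: %s", region_id, method, e)
                continue
            rows.append(ce.__dict__)
    return pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "method",
            "estimate",
            "se",
            "n_instruments",
            "intercept",
            "intercept_se",
        ],
    )


def write_local_ces(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_local_ces(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
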