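"""Simulation-study evaluation: accuracy and coverage across rounds.

A study runs the whole pipeline for ``n_rounds`` independent simulation
rounds of one confounding scenario — fresh alpha/gamma draws, a fresh
CNN ensemble, mutagenesis of exposure-bearing test regions, both MR
methods and the meta-analysis — and scores the estimates against the
simulation's exhaustive-mutation ground truth:

* global accuracy: R² between estimated and true global causal effects
  across rounds (squared Pearson correlation by default);
* global coverage: fraction of rounds whose mean ± 2·tau interval
  captures the round's true global CE;
* local coverage: per-round fraction of regions whose 95% CI
  (estimate ± 1.96·se) contains the region's true CE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .meta import GlobalCE
from .model import EnsembleSpec
from .pipeline import run_pipeline
from .pwm import PWM, bundled_motifs
from .simulate import ScenarioConfig, generate_dataset, true_ce_table

logger = logging.getLogger(__name__)

METHODS = ("egger", "baseline")


@dataclass
class StudyProtocol:
    """Sizes and hyperparameters of one simulation study."""

    n_rounds: int = 10
    n_train: int = 4000
    n_test: int = 400
    n_members: int = 3
    max_epochs: int = 40
    patience: int = 8
    batch_size: int = 128
    z_threshold: float = 2.0
    max_regions: int | None = None  # cap on mutagenized regions per round
    calibrate_uncertainty: bool = True
    master_seed: int = 0


@dataclass
class RoundResult:
    round_id: int
    scenario: str
    alpha: float
    gamma: float
    true_global: float
    validation_r2: dict[str, float]
    global_ces: dict[str, GlobalCE]
    locals_with_truth: pd.DataFrame = field(repr=False)
    # diagnostics: fraction of kept instruments inside the exposure implant,
    # and fraction of regions whose Egger pleiotropy intercept is within 3 se
    instrument_in_implant: float = float("nan")
    egger_intercept_near_zero: float = float("nan")

    def local_coverage(self, method: str, z_crit: float = 1.96) -> float:
        sub = self.locals_with_truth[self.locals_with_truth["method"] == method]
        if len(sub) == 0:
            return float("nan")
        se = sub["se"].to_numpy(dtype=float)
        est = sub["estimate"].to_numpy(dtype=float)
        truth = sub["true_ce"].to_numpy(dtype=float)
        ok = np.isfinite(se)
        if not ok.any():
            return float("nan")
        covered = np.abs(est[ok] - truth[ok]) <= z_crit * se[ok]
        return float(covered.mean())


def round_seed(master_seed: int, round_id: int) -> int:
    """Deterministic per-round seed derived from the master seed."""
    return int(
        np.random.SeedSequence([master_seed, round_id]).generate_state(1)[0] % (2**31)
    )


def run_round(
    scenario: str,
    round_id: int,
    protocol: StudyProtocol,
    pwms: dict[str, PWM] | None = None,
) -> RoundResult:
    pwms = pwms or bundled_motifs()
    seed = round_seed(protocol.master_seed, round_id)
    config = ScenarioConfig.for_scenario(
        scenario, seed=seed, n_train=protocol.n_train, n_test=protocol.n_test
    )
    dataset = generate_dataset(config, pwms)
    regions = [r for r in dataset.test if r.has_exposure]
    truths = true_ce_table(regions, pwms, dataset.config)
    if protocol.max_regions is not None:
        truths = truths.iloc[: protocol.max_regions]
    defined = set(truths["region_id"])
    regions = [r for r in regions if r.region_id in defined]
    spec = EnsembleSpec(
        n_members=protocol.n_members,
        max_epochs=protocol.max_epochs,
        patience=protocol.patience,
        batch_size=protocol.batch_size,
        seed=seed,
    )
    result = run_pipeline(
        dataset,
        spec=spec,
        regions=regions,
        z_threshold=protocol.z_threshold,
        calibrate_uncertainty=protocol.calibrate_uncertainty,
    )
    locals_with_truth = result.local_ces.merge(truths, on="region_id", how="inner")
    kept = result.effects[result.effects["kept"]]
    spans = {
        r.region_id: (r.implant_for("exposure").start, r.implant_for("exposure").end)
        for r in regions
    }
    in_implant = float(
        np.mean(
            [
                spans[rid][0] - 1 <= pos <= spans[rid][1]
                for rid, pos in zip(kept["region_id"], kept["position"])
            ]
        )
        if len(kept)
        else np.nan
    )
    egger = locals_with_truth.query("method == 'egger'").dropna(
        subset=["intercept", "intercept_se"]
    )
    intercept_ok = (
        float(
            np.mean(
                np.abs(egger["intercept"]) < 3.0 * egger["intercept_se"]
            )
        )
        if len(egger)
        else float("nan")
    )
    return RoundResult(
        round_id=round_id,
        scenario=scenario,
        alpha=dataset.alpha,
        gamma=dataset.gamma,
        true_global=float(truths["true_ce"].mean()),
        validation_r2=result.validation_r2,
        global_ces=result.global_ces,
        locals_with_truth=locals_with_truth,
        instrument_in_implant=in_implant,
        egger_intercept_near_zero=intercept_ok,
    )


def run_study(
    scenario: str,
    protocol: StudyProtocol,
    pwms: dict[str, PWM] | None = None,
) -> list[RoundResult]:
    """All rounds of one scenario; failed rounds are logged and excluded."""
    rounds: list[RoundResult] = []
    for i in range(protocol.n_rounds):
        try:
            rounds.append(run_round(scenario, i, protocol, pwms=pwms))
            logger.info(
                "%s round %d: gamma=%.2f true=%.3f",
                scenario,
                i,
                rounds[-1].gamma,
                rounds[-1].true_global,
            )
        except FloatingPointError as e:
            logger.warning("%s round %d failed: %s", scenario, i, e)
    if len(rounds) < protocol.n_rounds:
        logger.warning(
            "%s: %d/%d rounds completed",
            scenario,
            len(rounds),
            protocol.n_rounds,
        )
    return rounds


# ---------------------------------------------------------------------------
# metrics


def _round_arrays(rounds: list[RoundResult], method: str):
    ok = [r for r in rounds if method in r.global_ces]
    est = np.array([r.global_ces[method].mean for r in ok])
    tau = np.array([r.global_ces[method].tau for r in ok])
    truth = np.array([r.true_global for r in ok])
    return est, tau, truth


def global_accuracy(
    rounds: list[RoundResult], method: str = "egger", convention: str = "pearson"
) -> float:
    """R² of estimated vs true global CEs across rounds.

    ``convention="pearson"`` (default) is the squared Pearson
    correlation; ``"regression"`` is the coefficient of determination of
    the estimates against the truths.  Undefined (NaN) when the truths
    have zero variance or fewer than 3 rounds are available.
    """
    est, _, truth = _round_arrays(rounds, method)
    if est.size < 3 or np.var(truth) == 0:
        return float("nan")
    if convention == "pearson":
        return float(pearsonr(est, truth)[0] ** 2)
    if convention == "regression":
        return float(1.0 - np.sum((truth - est) ** 2) / np.sum((truth - truth.mean()) ** 2))
    raise ValueError(f"unknown R² convention {convention!r}")


def global_coverage(rounds: list[RoundResult], method: str = "egger") -> float:
    """Fraction of rounds whose mean ± 2·tau interval captures the truth."""
    est, tau, truth = _round_arrays(rounds, method)
    if est.size == 0:
        return float("nan")
    return float(np.mean(np.abs(truth - est) <= 2.0 * tau))


def local_coverage(
    rounds: list[RoundResult], method: str = "egger"
) -> tuple[float, np.ndarray]:
    """Mean and per-round distribution of local 95% CI coverage."""
    per_round = np.array([r.local_coverage(method) for r in rounds])
    per_round = per_round[np.isfinite(per_round)]
    return float(per_round.mean()) if per_round.size else float("nan"), per_round


def summarize(rounds_by_scenario: dict[str, list[RoundResult]]) -> pd.DataFrame:
    """Study summary: accuracy and coverage per scenario and MR method."""
    rows = []
    for scenario, rounds in rounds_by_scenario.items():
        row: dict = {"scenario": scenario, "n_rounds": len(rounds)}
        for method in METHODS:
            row[f"global_accuracy_{method}"] = global_accuracy(rounds, method)
            row[f"global_coverage_{method}"] = global_coverage(rounds, method)
            row[f"local_coverage_{method}"] = local_coverage(rounds, method)[0]
        rows.append(row)
    return pd.DataFrame(rows)


def rounds_long_table(rounds: list[RoundResult]) -> pd.DataFrame:
    """Per-round long table (one row per round × method) for plotting."""
    rows = []
    for r in rounds:
        for method, g in r.global_ces.items():
            rows.append(
                {
                    "round_id": r.round_id,
                    "scenario": r.scenario,
                    "method": method,
                    "gamma": r.gamma,
                    "estimate": g.mean,
                    "sigma": g.sigma,
                    "tau": g.tau,
                    "true_global": r.true_global,
                    "local_coverage": r.local_coverage(method),
                }
            )
    return pd.DataFrame(rows)
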