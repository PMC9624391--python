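"""Saturation in-silico mutagenesis: per-mutation effects and standard errors.

Every single-base substitution of a reference sequence (L × 3 mutants for
the 4-letter alphabet) is scored against the ensemble.  For each task the
effect size is the difference of ensemble-mean predictions between mutant
and reference; its variance is the population variance across members of
the paired per-member differences

    var[beta] = var_m + var_r - 2 cov(m, r)
              = Var_i[ f(m, theta_i) - f(r, theta_i) ],

which corrects the naive sum-of-variances for the strong dependence of
mutant and reference predictions on the shared member weights.  Filtered
on the exposure z-score, these records are the MR instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CalibrationMap, EnsembleLike, one_hot
from .pwm import ALPHABET

logger = logging.getLogger(__name__)

EFFECT_COLUMNS = [
    "region_id",
    "position",
    "ref_base",
    "alt_base",
    "beta_X",
    "se_X",
    "beta_Y",
    "se_Y",
    "z_X",
    "kept",
]


@dataclass
class Mutant:
    position: int  # 0-based
    ref_base: str
    alt_base: str
    sequence: str


def enumerate_mutants(reference: str) -> list[Mutant]:
    """All L × 3 single-base substitutions of an ACGT reference sequence."""
    bad = set(reference.upper()) - set(ALPHABET)
    if bad:
        raise ValueError(f"non-ACGT characters in reference: {sorted(bad)}")
    ref = reference.upper()
    mutants = []
    for pos, base in enumerate(ref):
        for alt in ALPHABET:
            if alt == base:
                continue
            mutants.append(
                Mutant(
                    position=pos,
                    ref_base=base,
                    alt_base=alt,
                    sequence=ref[:pos] + alt + ref[pos + 1 :],
                )
            )
    return mutants


def variant_effects(
    ensemble: EnsembleLike,
    reference: str,
    region_id: str = "region",
    calibration: CalibrationMap | None = None,
    mutants: list[Mutant] | None = None,
) -> pd.DataFrame:
    """Effect sizes and covariance-corrected standard errors per mutation.

    Returns one row per (position, alt base) with columns beta_X / se_X
    (exposure), beta_Y / se_Y (outcome) and the exposure z-score.  The
    ``kept`` column is filled in later by `filter_instruments`.
    """
    mutants = mutants if mutants is not None else enumerate_mutants(reference)
    X = one_hot([reference] + [m.sequence for m in mutants])
    member = ensemble.member_predictions(X)  # (N, 1 + M, T)
    n_members = member.shape[0]
    if n_members < 2:
        raise ValueError(
            "variant-effect standard errors require an ensemble with >= 2 members"
        )
    diffs = member[:, 1:, :] - member[:, :1, :]  # paired per-member differences
    beta = diffs.mean(axis=0)  # (M, T)
    var = diffs.var(axis=0)  # population variance of the member differences
    n_clamped = int(np.sum(var < 0))
    if n_clamped:  # defensive: the difference form is nonnegative by construction
        logger.warning("clamped %d negative effect variances to 0", n_clamped)
    se = np.sqrt(np.maximum(var, 0.0))
    if calibration is not None:
        for t, task in enumerate(ensemble.tasks):
            se[:, t] = calibration.scale_se(se[:, t], task)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_x = np.where(se[:, 0] > 0, beta[:, 0] / se[:, 0], np.inf * np.sign(beta[:, 0]))
    return pd.DataFrame(
        {
            "region_id": region_id,
            "position": [m.position for m in mutants],
            "ref_base": [m.ref_base for m in mutants],
            "alt_base": [m.alt_base for m in mutants],
            "beta_X": beta[:, 0],
            "se_X": se[:, 0],
            "beta_Y": beta[:, 1],
            "se_Y": se[:, 1],
            "z_X": z_x,
            "kept": False,
        }
    )


def filter_instruments(records: pd.DataFrame, z_threshold: float = 2.0) -> pd.DataFrame:
    """Keep mutations strongly associated with the exposure: |z_X| >= threshold.

    Zero-standard-error records are kept only when their effect is
    nonzero (an "infinitely strong" instrument); the outcome columns are
    never consulted.  Returns a copy with the ``kept`` flag set.
    """
    if z_threshold < 0:
        raise ValueError("z_threshold must be nonnegative")
    out = records.copy()
    zero_se = out["se_X"] == 0
    keep = np.where(
        zero_se, out["beta_X"] != 0, np.abs(out["z_X"]) >= z_threshold
    )
    out["kept"] = keep
    return out


def write_effects(records: pd.DataFrame, path: str | Path) -> None:
    records[EFFECT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_effects(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
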