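"""Synthetic TF-binding simulation with a known causal structure.

Random DNA sequences carry optionally-implanted motifs for an exposure TF,
an outcome TF and (in the confounded scenarios) a confounder TF.  Binding
probabilities come from convolving each PWM over the sequence and combining
per-window match scores with a soft-or.  Affinities are linear (exposure)
and multiplicative (outcome) functions of the binding probabilities::

    c_e = alpha * p_e                 + eta * p_c + tau * z + 1
    c_o = alpha * gamma * p_o * p_e   + nu  * p_c + tau * z + 1

so the exposure gates the outcome entirely: with no exposure binding there
is no outcome binding above baseline.  Observed counts are Poisson with
mean equal to the affinity, and models are trained on Anscombe-transformed
counts, whose noise variance is approximately stabilized at 1.

Four confounding scenarios are expressed through two flags: a sequence
confounder (the confounder TF motif, weights ``eta``/``nu``) and a
sequence-independent binary confounder ``z ~ Bernoulli(0.5)`` with weight
``tau_conf``.  The causal coefficient ``gamma`` acts in raw count space;
the *true* local causal effect is defined in Anscombe space and computed by
an exhaustive-mutation oracle (`true_local_ce`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pwm import ALPHABET, PWM, encode, reverse_complement

SCENARIOS = ("unconfounded", "random", "sequence", "both")

# order in which motifs are implanted; later implants overwrite earlier bases
IMPLANT_ORDER = ("confounder", "exposure", "outcome")


class DegenerateRegionError(ValueError):
    """Raised when no exposure-motif mutation perturbs the exposure."""


@dataclass
class ScenarioConfig:
    """Parameters of one simulation scenario.

    ``alpha`` (scale) and ``gamma`` (causal coefficient, raw count space)
    are normally drawn once per simulation run (`draw_run_coefficients`);
    set them explicitly for deterministic unit-scale experiments.
    """

    seed: int
    L: int = 100
    alpha: float | None = None
    gamma: float | None = None
    eta: float = 20.0
    nu: float = 30.0
    tau_conf: float = 25.0
    insertion_prob: float = 0.5
    confound_sequence: bool = False
    confound_random: bool = False
    n_train: int = 10000
    n_test: int = 1000
    scan_reverse: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.insertion_prob <= 1.0:
            raise ValueError("insertion_prob must be in [0, 1]")
        for name in ("eta", "nu", "tau_conf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.alpha is not None and self.alpha < 0:
            raise ValueError("alpha must be nonnegative")

    @property
    def scenario(self) -> str:
        return {
            (False, False): "unconfounded",
            (False, True): "random",
            (True, False): "sequence",
            (True, True): "both",
        }[(self.confound_sequence, self.confound_random)]

    @classmethod
    def for_scenario(cls, scenario: str, seed: int, **kwargs) -> "ScenarioConfig":
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
        return cls(
            seed=seed,
            confound_sequence=scenario in ("sequence", "both"),
            confound_random=scenario in ("random", "both"),
            **kwargs,
        )

    def validate_motifs(self, pwms: dict[str, PWM]) -> None:
        widest = max(p.width for p in pwms.values())
        if self.L < widest:
            raise ValueError(
                f"sequence length L={self.L} shorter than widest motif ({widest})"
            )


@dataclass
class Implant:
    tf: str
    start: int  # 0-based, half-open [start, start + len(subsequence))
    subsequence: str

    @property
    def end(self) -> int:
        return self.start + len(self.subsequence)


@dataclass
class SimulatedRegion:
    region_id: str
    sequence: str
    implants: list[Implant]
    p_e: float
    p_o: float
    p_c: float
    z: int
    c_e: float
    c_o: float
    counts_e: int
    counts_o: int
    y_e: float
    y_o: float

    def implant_for(self, tf: str) -> Implant | None:
        for imp in self.implants:
            if imp.tf == tf:
                return imp
        return None

    @property
    def has_exposure(self) -> bool:
        return self.implant_for("exposure") is not None


@dataclass
class TrueCE:
    """Ground-truth local causal effect (Anscombe-space slope)."""

    region_id: str
    value: float
    n_instruments: int


@dataclass
class Dataset:
    config: ScenarioConfig
    alpha: float
    gamma: float
    train: list[SimulatedRegion]
    test: list[SimulatedRegion]


def sample_gamma(rng: np.random.Generator) -> float:
    """Causal coefficient: equal mixture of N(10, 0.5) and N(1, 0.5).

    The two components create two well-separated clusters of causal
    effects across simulation runs.
    """
    mean = 10.0 if rng.random() < 0.5 else 1.0
    return float(rng.normal(mean, np.sqrt(0.5)))


def sample_alpha(rng: np.random.Generator) -> float:
    """Scale coefficient: one draw from N(100, 3) (variance 3)."""
    return float(rng.normal(100.0, np.sqrt(3.0)))


def draw_run_coefficients(config: ScenarioConfig) -> ScenarioConfig:
    """Fill in alpha/gamma (one draw per run each) if not set explicitly."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0EF]))
    updates = {}
    if config.alpha is None:
        updates["alpha"] = sample_alpha(rng)
    if config.gamma is None:
        updates["gamma"] = sample_gamma(rng)
    return dataclasses.replace(config, **updates) if updates else config


def sample_sequence(
    config: ScenarioConfig, pwms: dict[str, PWM], rng: np.random.Generator
) -> tuple[str, list[Implant]]:
    """One background sequence with independently implanted motifs.

    Background bases are i.i.d. uniform; each TF independently implants a
    PWM-sampled subsequence with probability ``insertion_prob`` at a
    uniform valid start.  Implants are placed in the fixed order
    confounder, exposure, outcome, with later implants overwriting
    overlapping bases.  The confounder draw is always consumed from the
    RNG stream (so scenarios nest reproducibly) but only applied when
    sequence confounding is on.
    """
    config.validate_motifs(pwms)
    seq = list(rng.choice(list(ALPHABET), size=config.L))
    implants: list[Implant] = []
    for tf in IMPLANT_ORDER:
        pwm = pwms[tf]
        coin = rng.random() < config.insertion_prob
        start = int(rng.integers(0, config.L - pwm.width + 1))
        sub = pwm.sample(rng)
        if not coin:
            continue
        if tf == "confounder" and not config.confound_sequence:
            continue
        seq[start : start + pwm.width] = list(sub)
        implants.append(Implant(tf=tf, start=start, subsequence=sub))
    return "".join(seq), implants


def binding_probability(
    sequence: str,
    pwm: PWM,
    background: float = 0.25,
    scan_reverse: bool = False,
    prior: float | None = 0.5,
) -> float:
    """Soft-or binding probability of a TF anywhere on the sequence.

    Each window w is scored with the likelihood ratio
    ``LR_w = P(w | PWM) / P(w | background)`` mapped to [0, 1] as
    ``s_w = q·LR_w / (1 + q·LR_w)``, and the windows combine as the
    probabilistic union (soft-or) ``p = 1 - prod_w (1 - s_w)``.

    With per-window prior odds ``q = prior / n_windows`` (default prior
    0.5, the motif implantation rate) each ``s_w`` is the posterior
    probability that the motif sits at window w, so ``p`` approximates
    the posterior probability of the TF binding *anywhere* on the
    sequence.  ``prior=None`` selects the un-normalized convention
    ``s_w = LR_w / (1 + LR_w)``, which saturates on long sequences and
    is kept only for comparison.
    """
    scores = window_scores(sequence, pwm, background, prior=prior)
    if scan_reverse:
        scores = np.concatenate(
            [
                scores,
                window_scores(
                    reverse_complement(sequence), pwm, background, prior=prior
                ),
            ]
        )
    scores = np.minimum(scores, 1.0)
    if scores.max(initial=0.0) >= 1.0:
        return 1.0
    return float(-np.expm1(np.log1p(-scores).sum()))


def window_scores(
    sequence: str,
    pwm: PWM,
    background: float = 0.25,
    prior: float | None = 0.5,
) -> np.ndarray:
    """Per-window match scores s_w in [0, 1] (see `binding_probability`)."""
    loglik = pwm.log_likelihoods(sequence)
    logbg = pwm.width * np.log(background)
    n_windows = loglik.size
    log_q = 0.0 if prior is None else np.log(prior / n_windows)
    # s = qLR / (1 + qLR) = sigmoid(log q + log LR), numerically stable
    from scipy.special import expit

    return expit(log_q + loglik - logbg)


def _confounder_weights(config: ScenarioConfig) -> tuple[float, float, float]:
    eta = config.eta if config.confound_sequence else 0.0
    nu = config.nu if config.confound_sequence else 0.0
    tau = config.tau_conf if config.confound_random else 0.0
    return eta, nu, tau


def exposure_affinity(
    p_e: float, p_c: float, z: int, config: ScenarioConfig
) -> float:
    """c_e = alpha*p_e + eta*p_c + tau*z + 1 (confounder terms per scenario)."""
    if config.alpha is None or config.alpha < 0:
        raise ValueError("config.alpha must be set and nonnegative")
    eta, _, tau = _confounder_weights(config)
    return config.alpha * p_e + eta * p_c + tau * z + 1.0


def outcome_affinity(
    p_o: float, p_e: float, p_c: float, z: int, config: ScenarioConfig
) -> float:
    """c_o = alpha*gamma*p_o*p_e + nu*p_c + tau*z + 1.

    The multiplicative ``p_o * p_e`` term means exposure binding gates
    outcome binding entirely.  The binding term is floored at zero: the
    causal coefficient's low mixture component occasionally draws gamma
    slightly below zero, and binding cannot subtract counts below the
    confounder-plus-baseline level.
    """
    if config.alpha is None or config.gamma is None:
        raise ValueError("config.alpha and config.gamma must be set")
    if config.alpha < 0:
        raise ValueError("alpha must be nonnegative")
    _, nu, tau = _confounder_weights(config)
    return max(config.alpha * config.gamma * p_o * p_e, 0.0) + nu * p_c + tau * z + 1.0


def sample_counts(affinity: float, rng: np.random.Generator) -> int:
    """Poisson experimental noise with mean equal to the affinity."""
    if affinity < 0:
        raise ValueError("affinity must be nonnegative")
    return int(rng.poisson(affinity))


def anscombe(count):
    """Variance-stabilizing transform y = 2*sqrt(x + 3/8) for Poisson counts."""
    x = np.asarray(count, dtype=float)
    if np.any(x < 0):
        raise ValueError("anscombe requires nonnegative input")
    out = 2.0 * np.sqrt(x + 0.375)
    return float(out) if out.ndim == 0 else out


def _probabilities(
    sequence: str, pwms: dict[str, PWM], scan_reverse: bool = False
) -> tuple[float, float, float]:
    p_e = binding_probability(sequence, pwms["exposure"], scan_reverse=scan_reverse)
    p_o = binding_probability(sequence, pwms["outcome"], scan_reverse=scan_reverse)
    p_c = binding_probability(sequence, pwms["confounder"], scan_reverse=scan_reverse)
    return p_e, p_o, p_c


def make_region(
    region_id: str,
    config: ScenarioConfig,
    pwms: dict[str, PWM],
    rng_seq: np.random.Generator,
    rng_noise: np.random.Generator,
) -> SimulatedRegion:
    sequence, implants = sample_sequence(config, pwms, rng_seq)
    p_e, p_o, p_c = _probabilities(sequence, pwms, config.scan_reverse)
    z = int(rng_noise.random() < 0.5)  # Bernoulli(0.5), always drawn
    c_e = exposure_affinity(p_e, p_c, z, config)
    c_o = outcome_affinity(p_o, p_e, p_c, z, config)
    counts_e = sample_counts(c_e, rng_noise)
    counts_o = sample_counts(c_o, rng_noise)
    return SimulatedRegion(
        region_id=region_id,
        sequence=sequence,
        implants=implants,
        p_e=p_e,
        p_o=p_o,
        p_c=p_c,
        z=z,
        c_e=c_e,
        c_o=c_o,
        counts_e=counts_e,
        counts_o=counts_o,
        y_e=anscombe(counts_e),
        y_o=anscombe(counts_o),
    )


def generate_dataset(config: ScenarioConfig, pwms: dict[str, PWM]) -> Dataset:
    """Generate reproducible train/test collections of simulated regions.

    alpha and gamma are drawn once for the whole run and shared by the
    train and test splits.  Each region has its own RNG stream keyed on
    (seed, split, index), so datasets are bit-identical under a fixed
    seed and scenarios nest: flipping a confounder flag changes only
    confounder-dependent fields of each region.
    """
    config = draw_run_coefficients(config)
    config.validate_motifs(pwms)
    splits: dict[str, list[SimulatedRegion]] = {}
    for split_tag, split, n in (("train", 1, config.n_train), ("test", 2, config.n_test)):
        regions = []
        for i in range(n):
            rng_seq = np.random.default_rng(
                np.random.SeedSequence([config.seed, split, i, 0])
            )
            rng_noise = np.random.default_rng(
                np.random.SeedSequence([config.seed, split, i, 1])
            )
            regions.append(
                make_region(f"{split_tag}_{i}", config, pwms, rng_seq, rng_noise)
            )
        splits[split_tag] = regions
    return Dataset(
        config=config,
        alpha=config.alpha,
        gamma=config.gamma,
        train=splits["train"],
        test=splits["test"],
    )


def noiseless_anscombe_signals(
    sequence: str, z: int, config: ScenarioConfig, pwms: dict[str, PWM]
) -> tuple[float, float]:
    """Anscombe-transformed noiseless affinities (A(c_e), A(c_o))."""
    p_e, p_o, p_c = _probabilities(sequence, pwms, config.scan_reverse)
    c_e = exposure_affinity(p_e, p_c, z, config)
    c_o = outcome_affinity(p_o, p_e, p_c, z, config)
    return anscombe(c_e), anscombe(c_o)


def true_local_ce(
    region: SimulatedRegion, pwms: dict[str, PWM], config: ScenarioConfig
) -> TrueCE:
    """Ground-truth local causal effect by exhaustive exposure-motif mutation.

    Every point mutation to a base inside the exposure implant (width × 3
    mutations) is applied to the region's sequence; noiseless affinities
    are recomputed and Anscombe transformed; the true CE is the slope of
    the no-intercept least-squares regression of the outcome deltas on
    the exposure deltas.  Defined only for regions carrying the exposure
    motif; the no-intercept convention reflects that both deltas are
    exactly zero at the unmutated reference.
    """
    imp = region.implant_for("exposure")
    if imp is None:
        raise ValueError(
            f"region {region.region_id}: true CE defined only for regions "
            "containing the exposure motif"
        )
    y0_e, y0_o = noiseless_anscombe_signals(region.sequence, region.z, config, pwms)
    dx, dy = [], []
    seq = region.sequence
    for pos in range(imp.start, imp.end):
        for alt in ALPHABET:
            if alt == seq[pos]:
                continue
            mutated = seq[:pos] + alt + seq[pos + 1 :]
            ye, yo = noiseless_anscombe_signals(mutated, region.z, config, pwms)
            dx.append(ye - y0_e)
            dy.append(yo - y0_o)
    dx_arr = np.array(dx)
    dy_arr = np.array(dy)
    ssx = float(dx_arr @ dx_arr)
    if ssx == 0.0:
        raise DegenerateRegionError(
            f"region {region.region_id}: no exposure-motif mutation changes "
            "the exposure signal"
        )
    slope = float(dx_arr @ dy_arr) / ssx
    return TrueCE(
        region_id=region.region_id, value=slope, n_instruments=len(dx)
    )


# ---------------------------------------------------------------------------
# dataset serialization


def regions_to_frame(regions: list[SimulatedRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append(
            {
                "region_id": r.region_id,
                "implants": ";".join(
                    f"{i.tf}:{i.start}:{i.subsequence}" for i in r.implants
                ),
                "p_e": r.p_e,
                "p_o": r.p_o,
                "p_c": r.p_c,
                "z": r.z,
                "c_e": r.c_e,
                "c_o": r.c_o,
                "counts_e": r.counts_e,
                "counts_o": r.counts_o,
                "y_e": r.y_e,
                "y_o": r.y_o,
            }
        )
    return pd.DataFrame(rows)


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA sequences plus per-region annotation TSVs."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for split in ("train", "test"):
        regions = getattr(dataset, split)
        fasta = out / f"{split}.fasta"
        records = [
            SeqRecord(Seq(r.sequence), id=r.region_id, description="")
            for r in regions
        ]
        seqio_write(records, str(fasta), "fasta")
        tsv = out / f"{split}_regions.tsv"
        regions_to_frame(regions).to_csv(tsv, sep="\t", index=False)
        paths[f"{split}_fasta"] = fasta
        paths[f"{split}_regions"] = tsv
    return paths


def true_ce_table(
    regions: list[SimulatedRegion], pwms: dict[str, PWM], config: ScenarioConfig
) -> pd.DataFrame:
    """True local CEs for all exposure-bearing, non-degenerate regions."""
    rows = []
    for r in regions:
        if not r.has_exposure:
            continue
        try:
            t = true_local_ce(r, pwms, config)
        except DegenerateRegionError:
            continue
        rows.append(
            {
                "region_id": t.region_id,
                "true_ce": t.value,
                "n_instruments": t.n_instruments,
            }
        )
    return pd.DataFrame(rows, columns=["region_id", "true_ce", "n_instruments"])
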