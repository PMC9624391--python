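"""Deep ensemble of small multi-task CNNs, implemented directly in numpy.

Each member maps a one-hot DNA sequence to the Anscombe-transformed
exposure and outcome counts jointly: three same-padded convolutional
layers (15 filters, width 7, ReLU), a global max-pool, two hidden dense
layers of width 30 and a linear two-task head, trained with Adam (lr 1e-3)
on an MSE loss with early stopping on a held-out split.  Members differ
only by their random initialization (and shuffling) seed; the spread of
member predictions is the model's predictive uncertainty.

The convolutions are computed as im2col matrix products and the backward
pass is written out by hand; for networks this small that is fast enough
on a single CPU and keeps the package free of any deep-learning framework
dependency.  Any external model exposing per-member predictions for the
named tasks can stand in for this ensemble downstream (see
`EnsembleLike`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.isotonic import IsotonicRegression

from .pwm import encode

TASKS = ("exposure", "outcome")


def one_hot(sequences: Sequence[str]) -> np.ndarray:
    """One-hot encode ACGT sequences to an array of shape (B, L, 4)."""
    idx = np.stack([encode(s) for s in sequences])
    return np.eye(4, dtype=np.float32)[idx]


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    from sklearn.metrics import r2_score

    return float(r2_score(np.asarray(y_true), np.asarray(y_pred)))


@dataclass
class EnsembleSpec:
    """Architecture and training hyperparameters shared by all members."""

    n_members: int = 5
    n_filters: int = 15
    filter_width: int = 7
    n_conv_layers: int = 3
    hidden: tuple[int, ...] = (30, 30)
    n_tasks: int = 2
    max_epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 128
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


class EnsembleLike(Protocol):
    """Adapter contract for external multi-task ensembles.

    Anything that can produce per-member predictions for the named tasks
    on one-hot sequences (e.g. a BPNet-style ensemble) can replace the
    built-in CNN throughout the pipeline.
    """

    tasks: tuple[str, ...]

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        """Return array (n_members, n_sequences, n_tasks)."""
        ...


@dataclass
class PredictiveDistribution:
    """Per-member predictions plus ensemble mean and population variance."""

    member: np.ndarray  # (N, B, T)
    tasks: tuple[str, ...] = TASKS

    @property
    def n_members(self) -> int:
        return self.member.shape[0]

    @property
    def mean(self) -> np.ndarray:  # (B, T)
        return self.member.mean(axis=0)

    @property
    def var(self) -> np.ndarray:  # (B, T) population variance across members
        return self.member.var(axis=0)

    def task_index(self, task: str) -> int:
        return self.tasks.index(task)


class _CNN:
    """One ensemble member; weights in a flat dict, Adam state internal."""

    def __init__(self, spec: EnsembleSpec, seed: int):
        self.spec = spec
        self.seed = seed
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(seed))
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def _init_params(self, rng: np.random.Generator) -> None:
        s = self.spec
        c_in = 4
        for i in range(s.n_conv_layers):
            fan_in = s.filter_width * c_in
            self.params[f"Wc{i}"] = (
                rng.standard_normal((fan_in, s.n_filters)) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            self.params[f"bc{i}"] = np.zeros(s.n_filters, dtype=np.float32)
            c_in = s.n_filters
        d_in = s.n_filters
        for i, width in enumerate(s.hidden):
            self.params[f"Wd{i}"] = (
                rng.standard_normal((d_in, width)) * np.sqrt(2.0 / d_in)
            ).astype(np.float32)
            self.params[f"bd{i}"] = np.zeros(width, dtype=np.float32)
            d_in = width
        self.params["Wout"] = (
            rng.standard_normal((d_in, s.n_tasks)) * np.sqrt(1.0 / d_in)
        ).astype(np.float32)
        self.params["bout"] = np.zeros(s.n_tasks, dtype=np.float32)

    # -- forward / backward ------------------------------------------------

    def _conv_cols(self, X: np.ndarray) -> np.ndarray:
        """im2col: (B, L, C) -> (B, L, K*C) with same padding."""
        k = self.spec.filter_width
        pad = k // 2
        Xp = np.pad(X, ((0, 0), (pad, pad - (1 - k % 2)), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(Xp, k, axis=1)
        # win: (B, L, C, K) -> (B, L, K, C) -> (B, L, K*C)
        B, L = X.shape[0], X.shape[1]
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, L, -1)

    def forward(self, X: np.ndarray, want_cache: bool = False):
        s = self.spec
        cache: dict = {"inputs": [], "cols": [], "acts": []}
        h = X.astype(np.float32, copy=False)
        for i in range(s.n_conv_layers):
            cols = self._conv_cols(h)
            z = cols @ self.params[f"Wc{i}"] + self.params[f"bc{i}"]
            a = np.maximum(z, 0.0)
            if want_cache:
                cache["cols"].append(cols)
                cache["acts"].append(a)
                cache["inputs"].append(h.shape)
            h = a
        # global max pool over sequence positions
        pool_idx = h.argmax(axis=1)  # (B, F)
        pooled = np.take_along_axis(h, pool_idx[:, None, :], axis=1)[:, 0, :]
        cache["pool_idx"] = pool_idx
        cache["pool_in_shape"] = h.shape
        d = pooled
        dense_acts = []
        for i in range(len(s.hidden)):
            z = d @ self.params[f"Wd{i}"] + self.params[f"bd{i}"]
            a = np.maximum(z, 0.0)
            dense_acts.append((d, a))
            d = a
        out = d @ self.params["Wout"] + self.params["bout"]
        if not want_cache:
            return out
        cache["pooled"] = pooled
        cache["dense_acts"] = dense_acts
        cache["last_hidden"] = d
        return out, cache

    def backward(self, dout: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        s = self.spec
        grads: dict[str, np.ndarray] = {}
        grads["Wout"] = cache["last_hidden"].T @ dout
        grads["bout"] = dout.sum(axis=0)
        dh = dout @ self.params["Wout"].T
        for i in reversed(range(len(s.hidden))):
            d_in, a = cache["dense_acts"][i]
            dz = dh * (a > 0)
            grads[f"Wd{i}"] = d_in.T @ dz
            grads[f"bd{i}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"Wd{i}"].T
        # un-pool: gradient flows to the argmax position per filter
        B, L, F = cache["pool_in_shape"]
        dpool = np.zeros((B, L, F), dtype=np.float32)
        np.put_along_axis(dpool, cache["pool_idx"][:, None, :], dh[:, None, :], axis=1)
        dh3 = dpool
        k = s.filter_width
        pad = k // 2
        for i in reversed(range(s.n_conv_layers)):
            a = cache["acts"][i]
            cols = cache["cols"][i]
            dz = dh3 * (a > 0)
            dz2 = dz.reshape(-1, dz.shape[-1])
            grads[f"Wc{i}"] = cols.reshape(dz2.shape[0], -1).T @ dz2
            grads[f"bc{i}"] = dz2.sum(axis=0)
            if i > 0:
                dcols = (dz @ self.params[f"Wc{i}"].T).reshape(B, L, k, -1)
                C = dcols.shape[-1]
                dXp = np.zeros((B, L + k - 1, C), dtype=np.float32)
                for j in range(k):
                    dXp[:, j : j + L, :] += dcols[:, :, j, :]
                dh3 = dXp[:, pad : pad + L, :]
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        self._adam_t += 1
        lr, b1, b2, eps = self.spec.learning_rate, 0.9, 0.999, 1e-8
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            v = self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray) -> dict:
        s = self.spec
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 1]))
        n = X.shape[0]
        n_val = max(1, int(round(s.val_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, Ytr = X[tr_idx], Y[tr_idx]
        Xval, Yval = X[val_idx], Y[val_idx]
        best_val = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        stall = 0
        history = []
        for epoch in range(s.max_epochs):
            order = rng.permutation(Xtr.shape[0])
            for start in range(0, Xtr.shape[0], s.batch_size):
                bidx = order[start : start + s.batch_size]
                xb, yb = Xtr[bidx], Ytr[bidx]
                out, cache = self.forward(xb, want_cache=True)
                diff = out - yb
                loss = float(np.mean(diff**2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss in member seed={self.seed}"
                    )
                dout = (2.0 / diff.size) * diff.astype(np.float32)
                self._adam_step(self.backward(dout, cache))
            val_mse = float(np.mean((self.predict(Xval) - Yval) ** 2))
            history.append(val_mse)
            if val_mse < best_val - 1e-6:
                best_val = val_mse
                best_params = {k: v.copy() for k, v in self.params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= s.patience:
                    break
            # early stopping restores the best-validation weights below
        self.params = best_params
        return {"val_mse": best_val, "epochs": len(history), "history": history}

    def predict(self, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        outs = [
            self.forward(X[i : i + batch_size])
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)


class DeepEnsemble:
    """N identically-specified CNNs trained from different initializations."""

    tasks = TASKS

    def __init__(self, spec: EnsembleSpec):
        self.spec = spec
        self.members: list[_CNN] = []
        self.train_info: list[dict] = []

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "DeepEnsemble":
        self.members = []
        self.train_info = []
        for i in range(self.spec.n_members):
            member_seed = int(
                np.random.SeedSequence([self.spec.seed, 7919 + i]).generate_state(1)[0]
                % (2**31)
            )
            m = _CNN(self.spec, seed=member_seed)
            self.train_info.append(m.fit(X, Y))
            self.members.append(m)
        return self

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        if not self.members:
            raise RuntimeError("ensemble is not trained")
        return np.stack([m.predict(X) for m in self.members])

    def predict(self, sequences_or_X) -> PredictiveDistribution:
        X = (
            one_hot(sequences_or_X)
            if isinstance(sequences_or_X[0], str)
            else np.asarray(sequences_or_X, dtype=np.float32)
        )
        return PredictiveDistribution(member=self.member_predictions(X))

    # -- persistence -------------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "spec": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.spec.__dict__.items()
            },
            "member_seeds": [m.seed for m in self.members],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for i, m in enumerate(self.members):
            np.savez(out / f"member_{i}.npz", **m.params)

    @classmethod
    def load(cls, in_dir: str | Path) -> "DeepEnsemble":
        src = Path(in_dir)
        manifest = json.loads((src / "manifest.json").read_text())
        spec_kwargs = manifest["spec"]
        spec_kwargs["hidden"] = tuple(spec_kwargs["hidden"])
        ens = cls(EnsembleSpec(**spec_kwargs))
        for i, seed in enumerate(manifest["member_seeds"]):
            m = _CNN(ens.spec, seed=seed)
            with np.load(src / f"member_{i}.npz") as data:
                m.params = {k: data[k] for k in data.files}
            ens.members.append(m)
        return ens


def train_ensemble(
    train_regions, spec: EnsembleSpec | None = None
) -> DeepEnsemble:
    """Train a deep ensemble on simulated regions (Anscombe targets)."""
    spec = spec or EnsembleSpec()
    X = one_hot([r.sequence for r in train_regions])
    Y = np.array([[r.y_e, r.y_o] for r in train_regions], dtype=np.float32)
    return DeepEnsemble(spec).fit(X, Y)


def predictions_table(dist: PredictiveDistribution, sequence_ids) -> "pd.DataFrame":
    """Long-format per-member prediction table (id, task, member, prediction)."""
    import pandas as pd

    n, b, t = dist.member.shape
    ids = list(sequence_ids)
    if len(ids) != b:
        raise ValueError("sequence_ids length does not match predictions")
    rows = {
        "sequence_id": np.repeat(ids, n * t),
        "task": np.tile(np.repeat(list(dist.tasks), n), b),
        "member": np.tile(np.arange(n), b * t),
        "prediction": dist.member.transpose(1, 2, 0).reshape(-1),
    }
    return pd.DataFrame(rows)


def validation_r2(ensemble: DeepEnsemble, regions) -> dict[str, float]:
    """Held-out R² of the ensemble-mean prediction per task."""
    dist = ensemble.predict([r.sequence for r in regions])
    y = np.array([[r.y_e, r.y_o] for r in regions])
    return {
        task: r_squared(y[:, t], dist.mean[:, t]) for t, task in enumerate(TASKS)
    }


# ---------------------------------------------------------------------------
# uncertainty recalibration


class CalibrationMap:
    """Quantile recalibration of ensemble uncertainty via isotonic regression.

    On validation data the probability integral transform values
    ``u = Phi((y - mean) / se)`` should be uniform if the predictive
    distribution is calibrated.  An isotonic fit of the empirical CDF on
    the predicted CDF values captures any miscalibration; from it a
    per-task standard-error multiplier is derived so that recalibrated
    central 95% intervals achieve nominal empirical coverage.  The
    identity map (factor 1) is used when calibration is disabled.
    """

    MIN_POINTS = 50

    def __init__(self, enabled: bool = True):
        self.enabled = enabled
        self.factors: dict[str, float] = {t: 1.0 for t in TASKS}
        self._iso: dict[str, IsotonicRegression] = {}

    def fit(self, dist: PredictiveDistribution, y_val: np.ndarray) -> "CalibrationMap":
        if not self.enabled:
            return self
        y_val = np.asarray(y_val, dtype=float)
        if y_val.shape[0] < self.MIN_POINTS:
            raise ValueError(
                f"calibration needs at least {self.MIN_POINTS} validation "
                f"points, got {y_val.shape[0]}"
            )
        se = np.sqrt(np.maximum(dist.var, 1e-20))
        for t, task in enumerate(dist.tasks):
            u = norm.cdf((y_val[:, t] - dist.mean[:, t]) / se[:, t])
            order = np.argsort(u)
            emp = (np.arange(1, u.size + 1) - 0.5) / u.size
            iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
            iso.fit(u[order], emp)
            self._iso[task] = iso
            # se multiplier from the empirical central 95% interval of the
            # standardized residuals (the isotonic map's inverse at
            # 0.025/0.975, computed directly on the quantiles)
            z = (y_val[:, t] - dist.mean[:, t]) / se[:, t]
            z_lo, z_hi = np.quantile(z, [0.025, 0.975])
            width = z_hi - z_lo
            self.factors[task] = float(max(width / (2 * norm.ppf(0.975)), 1e-6))
        return self

    def cdf_map(self, u: np.ndarray, task: str) -> np.ndarray:
        """Recalibrated CDF level for predicted CDF values u."""
        if not self.enabled or task not in self._iso:
            return np.asarray(u, dtype=float)
        return self._iso[task].predict(np.asarray(u, dtype=float))

    def scale_se(self, se: np.ndarray, task: str) -> np.ndarray:
        return np.asarray(se, dtype=float) * self.factors.get(task, 1.0)


def calibrate(
    ensemble: EnsembleLike, validation_regions, enabled: bool = True
) -> CalibrationMap:
    """Fit a calibration map from an ensemble and validation regions."""
    cal = CalibrationMap(enabled=enabled)
    if not enabled:
        return cal
    X = one_hot([r.sequence for r in validation_regions])
    dist = PredictiveDistribution(member=ensemble.member_predictions(X))
    y = np.array([[r.y_e, r.y_o] for r in validation_regions])
    return cal.fit(dist, y)
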