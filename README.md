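# seqmr

**Causal effects between genomic marks learned by multi-task sequence
models, via in-silico mutagenesis and Mendelian randomization.**

Multi-task sequence-to-function models (e.g. CNNs predicting the binding
of several transcription factors from DNA sequence) may implicitly learn
how their output marks influence one another. `seqmr` extracts and
quantifies that knowledge: it treats single-base in-silico mutations as
*instruments* Z, one model output as the *exposure* X and another as the
*outcome* Y, and estimates the (assumed linear) causal effect of X on Y —
locally for each sequence region and globally across regions.

For a region of length L, every one of the L×3 single-base substitutions
is scored against a deep ensemble, giving per-mutation effect sizes

    β̂_ZX = E[X | Z=mutant] − E[X | Z=reference]

(and likewise β̂_ZY), with standard errors from the across-member variance
of the paired prediction differences. Mutations strongly associated with
the exposure (|β̂_ZX/se| ≥ z-threshold) become instruments for MR:

* **Wald-ratio baseline** — local effect = mean of β̂_ZY/β̂_ZX, interval
  from the SD of the ratios;
* **MR-Egger** — intercept+slope regression of β̂_ZY on β̂_ZX (robust
  Huber fit, instruments oriented to β̂_ZX ≥ 0); the slope is the causal
  effect and the intercept absorbs directional pleiotropy.

Local effects are pooled with a DerSimonian–Laird random-effects
meta-analysis into a global effect with standard error σ and
between-region SD τ.

The package ships a transcription-factor binding simulation with a known
causal structure (PWM implanting, soft-or binding probabilities, Poisson
counts, Anscombe transform; exposure GATA → outcome TAL1, optional SOX2
sequence confounder and a random non-sequence confounder) that serves as
the validation harness, plus a small numpy CNN deep ensemble to model it.
External ensembles (e.g. a BPNet-style model) plug in through a minimal
adapter: any object exposing per-member predictions for the named tasks.

## Worked example

```python
from seqmr import ScenarioConfig, generate_dataset, run_pipeline, bundled_motifs
from seqmr.model import EnsembleSpec

pwms = bundled_motifs()
config = ScenarioConfig.for_scenario("unconfounded", seed=11, n_train=3000, n_test=250)
dataset = generate_dataset(config, pwms)          # draws alpha, gamma for the run
result = run_pipeline(
    dataset,
    spec=EnsembleSpec(n_members=3, max_epochs=30, seed=11),
    calibrate_uncertainty=True,
)
print({k: round(v, 2) for k, v in result.validation_r2.items()})
for method, g in result.global_ces.items():
    print(f"{method}: {g.mean:.3f} (sigma {g.sigma:.3f}, tau {g.tau:.3f}, "
          f"{g.n_regions} regions)")
```

Output from this exact invocation:

```
{'exposure': 0.95, 'outcome': 0.94}
egger: 0.637 (sigma 0.050, tau 0.511, 110 regions)
baseline: 0.672 (sigma 0.063, tau 0.518, 114 regions)
```

This run drew γ ≈ 1.76 (the low cluster of the causal-coefficient
mixture); the true global causal effect in Anscombe space, computed by
the exhaustive-mutation oracle over the same regions, is 0.707. Both MR
methods land within one between-region SD (τ) of the truth, and the ±2τ
interval — the honest uncertainty statement for a new region — easily
covers it. Across repeated simulation rounds the cross-round R² between
estimated and true global effects exceeds 0.9 (see `seqmr study`).

The same pipeline is scriptable from the shell:

```bash
seqmr simulate --config scenario.yaml --out data/       # FASTA + TSVs
seqmr run      --config scenario.yaml --out results/    # end-to-end
seqmr study    --scenario unconfounded --rounds 10 --seed 0 --out study/
```

where `scenario.yaml` at minimum sets a `seed` and optionally scenario
(`unconfounded` / `random` / `sequence` / `both`), sizes and motif paths.

## Layout

- `seqmr.pwm` — PWM parsing (MEME minimal + plain 4-column), bundled
  synthetic GATA/TAL1/SOX2 motif fixtures
- `seqmr.simulate` — the generator and the exhaustive-mutation
  ground-truth oracle
- `seqmr.model` — numpy CNN deep ensemble + isotonic uncertainty
  recalibration
- `seqmr.mutagenesis` — saturation mutagenesis, effect sizes, instrument
  filtering
- `seqmr.mr` — Wald baseline and (robust) MR-Egger per region
- `seqmr.meta` — DerSimonian–Laird random-effects pooling
- `seqmr.evaluate` — multi-round study harness and metrics
- `seqmr.cli` — `seqmr` command-line interface

See `docs/methods.md` for the model, its assumptions and limitations.
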