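import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqmr import simulate as sim
from seqmr.pwm import ALPHABET, PWM
from seqmr.simulate import (
    DegenerateRegionError,
    ScenarioConfig,
    anscombe,
    binding_probability,
    exposure_affinity,
    generate_dataset,
    outcome_affinity,
    sample_counts,
    sample_gamma,
    sample_sequence,
    true_local_ce,
    window_scores,
)


def _config(**kw):
    kw.setdefault("seed", 7)
    kw.setdefault("alpha", 100.0)
    kw.setdefault("gamma", 10.0)
    return ScenarioConfig(**kw)


class TestGammaMixture:
    def test_moments_match_mixture_closed_form(self):
        rng = np.random.default_rng(0)
        draws = np.array([sample_gamma(rng) for _ in range(100_000)])
        # mixture mean (10+1)/2; variance 0.5 + (10-1)^2/4 = 20.75
        se_mean = math.sqrt(20.75 / draws.size)
        assert abs(draws.mean() - 5.5) < 3 * se_mean
        assert abs(draws.var() - 20.75) < 0.5

    def test_two_clusters_present(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_gamma(rng) for _ in range(200)])
        low, high = draws[draws < 5.5], draws[draws >= 5.5]
        assert len(low) > 50 and len(high) > 50
        assert abs(low.mean() - 1.0) < 0.3 and abs(high.mean() - 10.0) < 0.3


class TestSequenceSampling:
    def test_no_insertion_when_probability_zero(self, pwms):
        cfg = _config(insertion_prob=0.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq, implants = sample_sequence(cfg, pwms, rng)
            assert implants == []
            assert len(seq) == cfg.L == 100

    def test_implant_frequency_is_binomial(self, pwms):
        cfg = _config(insertion_prob=0.5)
        rng = np.random.default_rng(3)
        n = 4000
        hits = sum(
            any(i.tf == "exposure" for i in sample_sequence(cfg, pwms, rng)[1])
            for _ in range(n)
        )
        se = math.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * se

    def test_implanted_subsequence_lands_at_recorded_position(self, pwms):
        cfg = _config(insertion_prob=1.0, confound_sequence=False)
        rng = np.random.default_rng(5)
        seq, implants = sample_sequence(cfg, pwms, rng)
        # the outcome implant is placed last, so it is always intact
        imp = [i for i in implants if i.tf == "outcome"][0]
        assert seq[imp.start : imp.end] == imp.subsequence

    def test_motif_wider_than_sequence_rejected(self, pwms):
        cfg = _config(L=5)
        with pytest.raises(ValueError, match="shorter than widest motif"):
            sample_sequence(cfg, pwms, np.random.default_rng(0))


class TestBindingProbability:
    def test_soft_or_identities(self, toy_pwm, monkeypatch):
        zeros = lambda *a, **k: np.zeros(4)
        monkeypatch.setattr(sim, "window_scores", zeros)
        assert binding_probability("ACGACG", toy_pwm) == 0.0
        one_hit = lambda *a, **k: np.array([0.0, 1.0, 0.0, 0.0])
        monkeypatch.setattr(sim, "window_scores", one_hit)
        assert binding_probability("ACGACG", toy_pwm) == pytest.approx(1.0)

    def test_matches_bruteforce_window_enumeration(self, toy_pwm):
        seq = "ACGTAC"
        p = binding_probability(seq, toy_pwm, prior=0.5)
        # independent enumeration over all 4 windows
        q = 0.5 / 4
        prod = 1.0
        for w in range(4):
            lik = 1.0
            for j, base in enumerate(seq[w : w + 3]):
                lik *= toy_pwm.matrix[j, ALPHABET.index(base)]
            lr = lik / 0.25**3
            prod *= 1.0 - (q * lr) / (1.0 + q * lr)
        assert p == pytest.approx(1.0 - prod, abs=1e-12)

    def test_sequence_shorter_than_motif_errors(self, toy_pwm):
        with pytest.raises(ValueError):
            binding_probability("AC", toy_pwm)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_soft_or_bounded_for_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        width = int(rng.integers(3, 9))
        raw = rng.dirichlet(np.ones(4), size=width)
        pwm = PWM(name="rand", matrix=raw)
        seq = "".join(rng.choice(list(ALPHABET), size=int(rng.integers(width, 60))))
        p = binding_probability(seq, pwm)
        assert 0.0 <= p <= 1.0


class TestAffinities:
    def test_exposure_substitutions(self):
        cfg = _config(alpha=100.0)
        assert exposure_affinity(1.0, 0.0, 0, cfg) == 101.0
        assert exposure_affinity(0.0, 0.0, 0, cfg) == 1.0
        both = _config(alpha=100.0, confound_sequence=True, confound_random=True)
        assert exposure_affinity(0.5, 1.0, 1, both) == pytest.approx(96.0)

    def test_outcome_gated_by_exposure(self):
        cfg = _config(alpha=100.0, gamma=10.0)
        # no exposure binding -> baseline regardless of the outcome motif
        for p_o in (0.0, 0.5, 1.0):
            assert outcome_affinity(p_o, 0.0, 0.0, 0, cfg) == 1.0
        assert outcome_affinity(1.0, 1.0, 0.0, 0, cfg) == 1001.0
        both = _config(alpha=100.0, gamma=10.0, confound_sequence=True)
        assert outcome_affinity(0.0, 0.0, 1.0, 0, both) == pytest.approx(31.0)

    def test_confounder_terms_zero_when_flags_off(self):
        cfg = _config(confound_sequence=False, confound_random=False)
        assert exposure_affinity(0.0, 1.0, 1, cfg) == 1.0
        assert outcome_affinity(0.0, 0.0, 1.0, 1, cfg) == 1.0

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(seed=1, eta=-1.0)
        cfg = _config()
        object.__setattr__ if False else setattr(cfg, "alpha", -5.0)
        with pytest.raises(ValueError):
            exposure_affinity(0.5, 0.0, 0, cfg)


class TestCountsAndAnscombe:
    def test_poisson_moments(self):
        rng = np.random.default_rng(2)
        draws = np.array([sample_counts(101.0, rng) for _ in range(100_000)])
        se = math.sqrt(101.0 / draws.size)
        assert abs(draws.mean() - 101.0) < 3 * se
        assert abs(draws.var() / 101.0 - 1.0) < 0.05

    def test_zero_affinity_degenerate(self):
        rng = np.random.default_rng(0)
        assert all(sample_counts(0.0, rng) == 0 for _ in range(20))

    def test_anscombe_closed_form_and_monotone(self):
        assert anscombe(0) == pytest.approx(2 * math.sqrt(0.375))
        assert anscombe(1) == pytest.approx(2 * math.sqrt(1.375))
        values = anscombe(np.arange(1001))
        assert np.all(np.diff(values) > 0)
        with pytest.raises(ValueError):
            anscombe(-1)

    @pytest.mark.parametrize("lam", [20.0, 100.0, 500.0])
    def test_anscombe_stabilizes_poisson_variance(self, lam):
        rng = np.random.default_rng(int(lam))
        counts = rng.poisson(lam, size=20_000)
        assert abs(np.var(anscombe(counts)) - 1.0) < 0.2


def _bruteforce_true_ce(region, pwms, config):
    """Independent oracle: explicit window/mutation loops + closed-form slope."""

    def prob(seq, pwm):
        n_win = len(seq) - pwm.width + 1
        q = 0.5 / n_win
        prod = 1.0
        for w in range(n_win):
            lik = 1.0
            for j in range(pwm.width):
                lik *= pwm.matrix[j, ALPHABET.index(seq[w + j])]
            lr = lik / 0.25**pwm.width
            s = q * lr / (1 + q * lr)
            prod *= 1 - s
        return 1 - prod

    def signals(seq):
        p_e, p_o, p_c = (
            prob(seq, pwms["exposure"]),
            prob(seq, pwms["outcome"]),
            prob(seq, pwms["confounder"]),
        )
        eta = config.eta if config.confound_sequence else 0.0
        nu = config.nu if config.confound_sequence else 0.0
        tau = config.tau_conf if config.confound_random else 0.0
        c_e = config.alpha * p_e + eta * p_c + tau * region.z + 1
        c_o = (
            config.alpha * config.gamma * p_o * p_e + nu * p_c + tau * region.z + 1
        )
        return 2 * math.sqrt(c_e + 0.375), 2 * math.sqrt(c_o + 0.375)

    imp = region.implant_for("exposure")
    x0, y0 = signals(region.sequence)
    num = den = 0.0
    count = 0
    for pos in range(imp.start, imp.end):
        for alt in ALPHABET:
            if alt == region.sequence[pos]:
                continue
            seq = region.sequence[:pos] + alt + region.sequence[pos + 1 :]
            x, y = signals(seq)
            num += (x - x0) * (y - y0)
            den += (x - x0) ** 2
            count += 1
    return num / den, count


class TestTrueLocalCE:
    def test_matches_bruteforce_oracle_on_many_regions(self, pwms):
        cfg = ScenarioConfig.for_scenario(
            "unconfounded", seed=99, alpha=100.0, gamma=10.0, n_train=120, n_test=0
        )
        ds = generate_dataset(cfg, pwms)
        checked = 0
        for region in ds.train:
            if not region.has_exposure:
                continue
            try:
                t = true_local_ce(region, pwms, ds.config)
            except DegenerateRegionError:
                continue
            expected, count = _bruteforce_true_ce(region, pwms, ds.config)
            assert t.value == pytest.approx(expected, abs=1e-10)
            assert t.n_instruments == count == pwms["exposure"].width * 3
            checked += 1
        assert checked >= 40

    def test_requires_exposure_implant(self, pwms, small_dataset):
        region = next(r for r in small_dataset.test if not r.has_exposure)
        with pytest.raises(ValueError, match="exposure motif"):
            true_local_ce(region, pwms, small_dataset.config)

    def test_zero_gamma_means_zero_slope(self, pwms):
        cfg = ScenarioConfig.for_scenario(
            "unconfounded", seed=13, alpha=100.0, gamma=0.0, n_train=40, n_test=0
        )
        ds = generate_dataset(cfg, pwms)
        for region in ds.train:
            if region.has_exposure:
                t = true_local_ce(region, pwms, ds.config)
                assert t.value == pytest.approx(0.0, abs=1e-12)
                break


class TestGenerateDataset:
    def test_same_seed_is_bit_identical(self, pwms):
        cfg = lambda: ScenarioConfig.for_scenario(
            "unconfounded", seed=5, n_train=25, n_test=10
        )
        d1, d2 = generate_dataset(cfg(), pwms), generate_dataset(cfg(), pwms)
        assert d1.alpha == d2.alpha and d1.gamma == d2.gamma
        for r1, r2 in zip(d1.train + d1.test, d2.train + d2.test):
            assert r1.sequence == r2.sequence
            assert r1.counts_e == r2.counts_e and r1.counts_o == r2.counts_o

    def test_sizes_and_run_coefficients(self, pwms, small_dataset):
        assert len(small_dataset.train) == 150
        assert len(small_dataset.test) == 60
        # alpha ~ N(100, 3), gamma from the two-component mixture
        assert 90 < small_dataset.alpha < 110
        assert -2 < small_dataset.gamma < 13

    def test_affinity_floor(self, small_dataset):
        assert min(r.c_e for r in small_dataset.train + small_dataset.test) >= 1.0
        assert min(r.c_o for r in small_dataset.train + small_dataset.test) >= 1.0

    def test_unconfounded_scenario_ignores_confounder_machinery(self, small_dataset):
        for r in small_dataset.train:
            assert r.c_e == pytest.approx(small_dataset.alpha * r.p_e + 1.0)

    def test_scenario_nesting_changes_only_confounder_fields(self, pwms):
        base = generate_dataset(
            ScenarioConfig.for_scenario("unconfounded", seed=8, n_train=30, n_test=0),
            pwms,
        )
        rand = generate_dataset(
            ScenarioConfig.for_scenario("random", seed=8, n_train=30, n_test=0), pwms
        )
        seqc = generate_dataset(
            ScenarioConfig.for_scenario("sequence", seed=8, n_train=30, n_test=0), pwms
        )
        for b, r in zip(base.train, rand.train):
            assert b.sequence == r.sequence  # z-confounding never touches sequence
            assert b.z == r.z
            assert r.c_e == pytest.approx(b.c_e + rand.config.tau_conf * r.z)
        for b, s in zip(base.train, seqc.train):
            # sequences may differ only inside a confounder implant
            diff = [i for i, (x, y) in enumerate(zip(b.sequence, s.sequence)) if x != y]
            if diff:
                imp = s.implant_for("confounder")
                assert imp is not None
                assert all(imp.start <= i < imp.end for i in diff)
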