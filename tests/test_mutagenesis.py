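import numpy as np
import pandas as pd
import pytest

from seqmr.model import one_hot
from seqmr.mutagenesis import (
    Mutant,
    enumerate_mutants,
    filter_instruments,
    variant_effects,
)


class TestEnumerateMutants:
    def test_count_is_three_per_position(self):
        seq = "A" * 100
        assert len(enumerate_mutants(seq)) == 300

    def test_single_base_exhaustive(self):
        muts = enumerate_mutants("A")
        assert sorted(m.sequence for m in muts) == ["C", "G", "T"]

    def test_mutants_distinct_and_hamming_one(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=50))
        muts = enumerate_mutants(seq)
        assert len({m.sequence for m in muts}) == 150
        for m in muts:
            diff = [i for i, (a, b) in enumerate(zip(seq, m.sequence)) if a != b]
            assert diff == [m.position]
            assert m.ref_base == seq[m.position] and m.alt_base == m.sequence[m.position]

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            enumerate_mutants("ACGN")


class TwoMemberEnsemble:
    """Hand-set predictions: reference then mutants, per member."""

    tasks = ("exposure", "outcome")

    def __init__(self, table):
        self.table = np.asarray(table, dtype=float)  # (N, B, T)

    def member_predictions(self, X):
        assert X.shape[0] == self.table.shape[1]
        return self.table


class TestVariantEffects:
    def test_mutant_identical_to_reference_has_zero_effect(self, linear_ensemble):
        seq = "ACGTACGT"
        fake_mutants = [Mutant(position=0, ref_base="A", alt_base="A", sequence=seq)]
        eff = variant_effects(linear_ensemble, seq, mutants=fake_mutants)
        assert eff.loc[0, "beta_X"] == 0.0
        assert eff.loc[0, "se_X"] == 0.0

    def test_hand_arithmetic_two_members(self):
        # member predictions: reference {1, 1}, mutant {3, 5} (exposure task)
        table = [
            [[1.0, 0.0], [3.0, 0.0]],
            [[1.0, 0.0], [5.0, 0.0]],
        ]
        ens = TwoMemberEnsemble(table)
        eff = variant_effects(
            ens, "AA", mutants=[Mutant(position=0, ref_base="A", alt_base="C", sequence="CA")]
        )
        assert eff.loc[0, "beta_X"] == 3.0
        # var = var_m + var_r - 2cov = 1 + 0 - 0 = 1
        assert eff.loc[0, "se_X"] == pytest.approx(1.0)

    def test_variance_equals_member_difference_variance(self, rng):
        n_members, n_mut = 4, 50
        table = rng.normal(size=(n_members, n_mut + 1, 2))
        ens = TwoMemberEnsemble(table)
        muts = [
            Mutant(position=i, ref_base="A", alt_base="C", sequence="A" * (n_mut + 1))
            for i in range(n_mut)
        ]
        eff = variant_effects(ens, "A" * (n_mut + 1), mutants=muts)
        diffs = table[:, 1:, 0] - table[:, :1, 0]
        # var(A - B) = var A + var B - 2 cov(A, B), all across members
        var_direct = diffs.var(axis=0)
        var_formula = (
            table[:, 1:, 0].var(axis=0)
            + table[:, :1, 0].var(axis=0)
            - 2
            * (
                (table[:, 1:, 0] * table[:, :1, 0]).mean(axis=0)
                - table[:, 1:, 0].mean(axis=0) * table[:, :1, 0].mean(axis=0)
            )
        )
        np.testing.assert_allclose(var_direct, var_formula, atol=1e-8)
        np.testing.assert_allclose(eff["se_X"] ** 2, var_direct, atol=1e-8)

    def test_beta_antisymmetric_under_role_swap(self, rng):
        table = rng.normal(size=(3, 2, 2))
        ens_fwd = TwoMemberEnsemble(table)
        ens_rev = TwoMemberEnsemble(table[:, ::-1, :])
        mut = [Mutant(position=0, ref_base="A", alt_base="C", sequence="C")]
        fwd = variant_effects(ens_fwd, "A", mutants=mut)
        rev = variant_effects(ens_rev, "A", mutants=mut)
        assert fwd.loc[0, "beta_X"] == pytest.approx(-rev.loc[0, "beta_X"])
        assert fwd.loc[0, "se_X"] == pytest.approx(rev.loc[0, "se_X"])

    def test_single_member_rejected(self):
        ens = TwoMemberEnsemble(np.zeros((1, 2, 2)))
        with pytest.raises(ValueError, match=">= 2 members"):
            variant_effects(
                ens, "A", mutants=[Mutant(0, "A", "C", "C")]
            )

    def test_record_count_per_region(self, linear_ensemble):
        seq = "ACGTACGTACGT"
        eff = variant_effects(linear_ensemble, seq)
        assert len(eff) == len(seq) * 3


class TestFilterInstruments:
    def _records(self, z_values, se=1.0):
        z = np.asarray(z_values, dtype=float)
        return pd.DataFrame(
            {
                "region_id": "r",
                "position": np.arange(z.size),
                "ref_base": "A",
                "alt_base": "C",
                "beta_X": z * se,
                "se_X": se,
                "beta_Y": np.linspace(-1, 1, z.size),
                "se_Y": 1.0,
                "z_X": z,
                "kept": False,
            }
        )

    def test_zero_threshold_keeps_all_finite(self):
        out = filter_instruments(self._records([0.1, -5.0, 2.0]), z_threshold=0.0)
        assert out["kept"].all()

    def test_threshold_counting(self):
        out = filter_instruments(self._records([1.5, 2.5, -3.0]), z_threshold=2.0)
        assert out["kept"].sum() == 2

    def test_zero_se_rules(self):
        rec = self._records([0.0, 0.0])
        rec.loc[:, "se_X"] = 0.0
        rec.loc[0, "beta_X"] = 0.0  # exactly no effect: drop
        rec.loc[1, "beta_X"] = 0.5  # infinitely strong: keep
        out = filter_instruments(rec, z_threshold=2.0)
        assert not out.loc[0, "kept"] and out.loc[1, "kept"]

    def test_outcome_columns_never_consulted(self, rng):
        rec = self._records(rng.normal(scale=3, size=40))
        shuffled = rec.copy()
        shuffled["beta_Y"] = rng.permutation(shuffled["beta_Y"].to_numpy())
        a = filter_instruments(rec, 2.0)["kept"]
        b = filter_instruments(shuffled, 2.0)["kept"]
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_instruments(self._records([1.0]), z_threshold=-1.0)
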