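"""Spawning: fecundity, batch partitioning, forcing, and recruitment."""

import numpy as np
import pytest

from batchspawn.genetics import Genotype
from batchspawn.life_history import Individual, weight_from_length
from batchspawn.reproduction import (
    SpawningOutcome,
    SpawningParams,
    batch_survival_prob,
    fecundity,
    n_batches,
    produce_recruits,
    spawn,
    spawn_season,
)


def _female(length=60.0, mature=True, ident=0):
    geno = Genotype(np.ones(20, dtype=np.uint8))
    return Individual(
        id=ident, birth_year=0, age=10, genotype=geno, linf=100.0, k=0.08,
        length=length, mature=mature,
    )


class TestFecundity:
    def test_zero_weight_floor(self):
        # even a weightless female: (0.48*0.37^1.45 + 0.12)e6 ≈ 233,520 eggs
        assert fecundity(0.0) == round((0.48 * 0.37**1.45 + 0.12) * 1e6)
        assert abs(fecundity(0.0) - 233_536) <= 1

    def test_value_at_78cm_fish(self):
        w = weight_from_length(78.0)
        assert fecundity(w) == pytest.approx(3.956e6, rel=1e-3)

    def test_monotone_in_weight(self):
        w = np.linspace(0, 15, 200)
        assert (np.diff(fecundity(w)) > 0).all()

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            fecundity(-0.5)


class TestBatchNumber:
    def test_logistic_midpoint_rounds_half_up(self):
        # raw value at the midpoint is half the asymptote: 10.578 → 11
        assert n_batches(55.014, "MBS") == 11

    def test_asymptote(self):
        assert n_batches(1000.0, "MBS") == 21

    def test_floor_of_one(self):
        assert n_batches(0.0, "MBS") == 1

    def test_sbs_always_one(self):
        for length in (0.0, 55.0, 120.0):
            assert n_batches(length, "SBS") == 1


class TestBatchSurvival:
    def test_first_batch_no_cost(self):
        p = SpawningParams(strategy="MBS", env_forcing=0.0)
        assert batch_survival_prob(1, p) == 1.0

    def test_last_batch_cost_near_011(self):
        p = SpawningParams(strategy="MBS", env_forcing=0.0)
        assert batch_survival_prob(21, p) == pytest.approx(0.8954)

    def test_forcing_scales_survival(self):
        p = SpawningParams(strategy="MBS", env_forcing=0.30)
        assert batch_survival_prob(1, p) == pytest.approx(0.70)

    def test_sbs_pays_no_cost(self):
        p = SpawningParams(strategy="SBS", env_forcing=0.2)
        assert batch_survival_prob(1, p) == pytest.approx(0.8)


class TestSpawn:
    def test_immature_female_rejected(self, rng):
        with pytest.raises(ValueError):
            spawn(_female(mature=False), SpawningParams(), rng)

    def test_sbs_without_forcing_keeps_all_eggs(self, rng):
        p = SpawningParams(strategy="SBS", env_forcing=0.0)
        out = spawn(_female(), p, rng)
        assert out.n_batches == 1
        assert out.eggs_surviving == out.eggs_produced

    def test_outcome_invariants_enforced(self):
        with pytest.raises(ValueError):
            SpawningOutcome(100, 2, 3, 50, 10)
        with pytest.raises(ValueError):
            SpawningOutcome(100, 2, 2, 150, 10)

    def test_sbs_season_failure_probability_equals_forcing(self, rng):
        p = SpawningParams(strategy="SBS", env_forcing=0.25)
        lengths = np.full(20000, 60.0)
        out = spawn_season(lengths, weight_from_length(lengths), p, rng)
        failed = (out["batches_survived"] == 0).mean()
        assert failed == pytest.approx(0.25, abs=0.01)

    def test_mbs_variance_reduction_law(self, rng):
        # equal split over n batches at zero cost: Var = Var_SBS / n
        length = 55.014  # 11 batches
        n = 11
        p = SpawningParams(strategy="MBS", env_forcing=0.3, cost_slope=0.0)
        lengths = np.full(40000, length)
        out = spawn_season(lengths, weight_from_length(lengths), p, rng)
        assert (out["n_batches"] == n).all()
        eggs = out["eggs"][0]
        var_sbs = eggs**2 * 0.3 * 0.7
        observed = out["eggs_surviving"].var()
        assert observed == pytest.approx(var_sbs / n, rel=0.05)

    def test_mbs_cost_orders_expected_survival(self, rng):
        # with no forcing, expected surviving eggs under MBS (with costs)
        # fall below SBS; equality only when one batch is shed
        lengths = np.full(20000, 70.0)
        w = weight_from_length(lengths)
        mbs = spawn_season(lengths, w, SpawningParams("MBS", 0.0), rng)
        sbs = spawn_season(lengths, w, SpawningParams("SBS", 0.0), rng)
        assert mbs["eggs_surviving"].mean() < sbs["eggs_surviving"].mean()
        assert sbs["eggs_surviving"].mean() == mbs["eggs"].mean()

    def test_degenerate_mbs_is_distributionally_sbs(self):
        # an MBS fish small enough to shed one batch, with zero cost, is
        # bit-identical to SBS under the same stream
        lengths = np.full(500, 20.0)
        w = weight_from_length(lengths)
        out_m = spawn_season(
            lengths, w, SpawningParams("MBS", 0.2, cost_slope=0.0),
            np.random.default_rng(99),
        )
        out_s = spawn_season(
            lengths, w, SpawningParams("SBS", 0.2), np.random.default_rng(99)
        )
        for key in out_m:
            np.testing.assert_array_equal(out_m[key], out_s[key])


class TestRecruitment:
    def test_no_surviving_eggs_no_recruits(self, rng):
        out = SpawningOutcome(100, 1, 0, 0, 0)
        dam = _female()
        assert produce_recruits(out, dam, [dam], rng) == []

    def test_expected_recruits_binomial_mean(self, rng):
        p = SpawningParams(strategy="SBS", env_forcing=0.0)
        lengths = np.full(30000, 78.0)
        out = spawn_season(lengths, weight_from_length(lengths), p, rng)
        # E[recruits] = eggs * 1.13e-6 ≈ 4.47 per season for a 78 cm fish
        expected = out["eggs"][0] * 1.13e-6
        assert expected == pytest.approx(4.47, abs=0.02)
        assert out["recruits"].mean() == pytest.approx(expected, rel=0.02)

    def test_parent_credits_double_count_recruits(self, rng):
        dam, sire = _female(ident=0), _female(ident=1)
        out = SpawningOutcome(10000, 1, 1, 10000, 7)
        kids = produce_recruits(out, dam, [dam, sire], rng, birth_year=3, next_id=10)
        assert len(kids) == 7
        assert dam.lifetime_recruits + sire.lifetime_recruits == 2 * 7
        for kid in kids:
            assert kid.age == 0 and kid.length == 0.0 and kid.birth_year == 3
            assert kid.genotype.value == 20  # both parents homozygous-1
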