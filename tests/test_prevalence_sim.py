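from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from cgcp import (
    N_TRIPLES,
    CausalFrequencySet,
    SimModelConfig,
    generate_populations,
    mean_triple_frequency,
    population_prevalence,
    run_simulation,
    slope_sign_summary,
    triple_frequencies,
)


def _random_set(rng):
    return CausalFrequencySet(tuple(rng.uniform(1e-6, 1 - 1e-6, size=15)))


def test_prevalence_closed_form():
    s = CausalFrequencySet(tuple([0.5] * 15))
    assert population_prevalence(s) == pytest.approx(0.5 ** 4 + 0.5 ** 5 + 0.5 ** 6)
    # a vanishing genotype frequency sends its group's term to zero
    vals = [0.5] * 15
    vals[0] = 1e-12
    s0 = CausalFrequencySet(tuple(vals))
    assert population_prevalence(s0) == pytest.approx(0.5 ** 5 + 0.5 ** 6, rel=1e-6)


def test_prevalence_matches_independent_product_oracle(rng):
    import math
    for _ in range(25):
        s = _random_set(rng)
        expect = (math.prod(s.a) + math.prod(s.b) + math.prod(s.c))
        assert population_prevalence(s) == pytest.approx(expect, abs=1e-15)


def test_triple_inventory_is_34():
    s = CausalFrequencySet(tuple([0.3] * 15))
    t = triple_frequencies(s)
    assert len(t) == 34 == N_TRIPLES
    np.testing.assert_allclose(t, 0.3 ** 3)


def test_triples_match_brute_force_subset_enumeration(rng):
    s = _random_set(rng)
    v = np.asarray(s.values)
    groups = [range(0, 4), range(4, 9), range(9, 15)]
    expect = [v[list(t)].prod() for g in groups for t in combinations(g, 3)]
    np.testing.assert_allclose(triple_frequencies(s), expect, rtol=1e-14)


def test_frequency_set_validation():
    with pytest.raises(ValueError, match="15"):
        CausalFrequencySet((0.5,) * 14)
    with pytest.raises(ValueError, match="strictly"):
        CausalFrequencySet((0.0,) + (0.5,) * 14)


def test_generation_is_deterministic_per_seed():
    cfg = SimModelConfig(model="complete_random", n_populations=20, seed=42)
    a = generate_populations(cfg)
    b = generate_populations(cfg)
    assert a.populations == b.populations
    c = generate_populations(SimModelConfig(model="complete_random",
                                            n_populations=20, seed=43))
    assert a.populations != c.populations


def test_constrained_zero_fluctuation_collapses_to_reference():
    cfg = SimModelConfig(model="constrained", n_populations=10, fluctuation=0.0,
                         seed=3)
    draw = generate_populations(cfg)
    ref = draw.populations[0]
    assert all(p == ref for p in draw.populations)
    # downstream: every test degenerate, surfaced not masked
    res = run_simulation(SimModelConfig(model="constrained", n_populations=10,
                                        n_tests=20, fluctuation=0.0, seed=3))
    assert res.n_degenerate == 20 and res.n_valid == 0
    assert res.prop_p_lt_05 == 0.0


def test_constrained_draws_stay_within_fluctuation_band():
    cfg = SimModelConfig(model="constrained", n_populations=667, fluctuation=0.2,
                         seed=11)
    draw = generate_populations(cfg)  # 666 x 15 ~ 10^4 constrained draws
    ref = np.asarray(draw.populations[0].values)
    others = np.stack([np.asarray(p.values) for p in draw.populations[1:]])
    ratio = others / ref
    assert ratio.min() >= 0.8 - 1e-9
    assert ratio.max() <= 1.2 + 1e-9


def test_lost_model_removes_a_shared_subset_from_xbar():
    cfg = SimModelConfig(model="constrained_lost", n_populations=5,
                         lost_fraction=0.2, seed=7)
    draw = generate_populations(cfg)
    assert draw.lost_triples.size == int(0.2 * 34) == 6
    x = mean_triple_frequency(draw)
    keep = np.setdiff1d(np.arange(34), draw.lost_triples)
    for i, pop in enumerate(draw.populations):
        assert x[i] == pytest.approx(triple_frequencies(pop)[keep].mean())
        # prevalence is untouched by the loss
        assert population_prevalence(pop) > 0


def test_mixed_model_fakes_enter_xbar_but_not_prevalence():
    cfg = SimModelConfig(model="constrained_lost_mixed", n_populations=5,
                         lost_fraction=0.2, mixed_fraction=0.1, seed=7)
    draw = generate_populations(cfg)
    n_fake = int(0.1 * 34)
    assert draw.fake_frequencies.shape == (5, n_fake)
    x = mean_triple_frequency(draw)
    keep = np.setdiff1d(np.arange(34), draw.lost_triples)
    for i, pop in enumerate(draw.populations):
        expect = np.concatenate(
            [triple_frequencies(pop)[keep], draw.fake_frequencies[i]]).mean()
        assert x[i] == pytest.approx(expect)


def test_mixed_model_reduces_to_constrained_when_fractions_zero():
    base = SimModelConfig(model="constrained", n_populations=8, seed=99)
    mixed = SimModelConfig(model="constrained_lost_mixed", n_populations=8,
                           lost_fraction=0.0, mixed_fraction=0.0, seed=99)
    a, b = generate_populations(base), generate_populations(mixed)
    assert a.populations == b.populations
    assert b.lost_triples.size == 0 and b.fake_frequencies.shape[1] == 0


def test_xbar_equals_mean_of_all_34_without_loss_or_mixing(rng):
    cfg = SimModelConfig(model="complete_random", n_populations=6, seed=5)
    draw = generate_populations(cfg)
    x = mean_triple_frequency(draw)
    for i, pop in enumerate(draw.populations):
        assert x[i] == pytest.approx(triple_frequencies(pop).mean(), rel=1e-12)


def test_config_rejects_model_inappropriate_fractions():
    with pytest.raises(ValueError, match="lost_fraction"):
        SimModelConfig(model="complete_random", n_populations=10, lost_fraction=0.2)
    with pytest.raises(ValueError, match="mixed_fraction"):
        SimModelConfig(model="constrained_lost", n_populations=10,
                       lost_fraction=0.2, mixed_fraction=0.1)
    with pytest.raises(ValueError, match="unknown model"):
        SimModelConfig(model="bogus", n_populations=10)


def test_constrained_slopes_are_positive():
    res = run_simulation(SimModelConfig(model="constrained", n_populations=20,
                                        n_tests=300, seed=8))
    assert slope_sign_summary(res) > 0.95


def test_slope_sign_summary_on_fabricated_records():
    df = pd.DataFrame({"slope": [-1.0, -1.0], "intercept": 0.0,
                       "r_squared": 0.9, "p_value": 0.01, "degenerate": False})
    assert slope_sign_summary(df) == 0.0
    df2 = pd.DataFrame({"slope": [1.0, -1.0], "intercept": 0.0,
                        "r_squared": 0.9, "p_value": 0.01, "degenerate": False})
    assert slope_sign_summary(df2) == 0.5


def test_aggregates_consistent_with_records():
    res = run_simulation(SimModelConfig(model="complete_random", n_populations=15,
                                        n_tests=200, seed=21))
    rec = res.records
    assert res.prop_p_lt_05 == pytest.approx((rec["p_value"] < 0.05).mean())
    assert res.prop_r2_gt_05 == pytest.approx((rec["r_squared"] > 0.5).mean())
    assert 0.0 <= res.prop_p_lt_05 <= 1.0 and 0.0 <= res.prop_r2_gt_05 <= 1.0
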