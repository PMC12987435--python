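from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgcp import (
    CgcpConfig,
    GenotypeKey,
    GenotypeMatrix,
    PlantSpec,
    canonical_keys,
    carriers_of,
    count_total_combinations,
    enumerate_specific_combinations,
    enumerate_specific_combinations_naive,
    estimate_population_frequency,
    lambda_from_prevalence,
    make_case_control,
    passes_boundary,
)

from conftest import random_matrix


# ---------------------------------------------------------------------------
# arithmetic primitives
# ---------------------------------------------------------------------------

def _brute_force_pattern_count(n, r):
    """Enumerate every genotype-assigned r-subset of n variants and count."""
    return sum(1 for _ in product(*[range(3)] * r) for __ in combinations(range(n), r))


@pytest.mark.parametrize("n,r,expected", [(3, 3, 27), (1, 1, 3), (5, 3, 270)])
def test_count_total_combinations(n, r, expected):
    assert count_total_combinations(n, r) == expected
    assert count_total_combinations(n, r) == _brute_force_pattern_count(n, r)


def test_count_total_combinations_domain():
    with pytest.raises(ValueError):
        count_total_combinations(2, 3)


def test_lambda_values():
    assert lambda_from_prevalence(0.5) == pytest.approx(1.0)
    assert lambda_from_prevalence(0.0047) == pytest.approx(211.76595744680852)
    assert lambda_from_prevalence(1 - 1e-9) == pytest.approx(0.0, abs=1e-8)
    with pytest.raises(ValueError):
        lambda_from_prevalence(0.0)
    with pytest.raises(ValueError):
        lambda_from_prevalence(1.0)


def test_population_frequency_estimator():
    assert estimate_population_frequency(0.3, 0.3, 0.123) == pytest.approx(0.3)
    assert estimate_population_frequency(1.0, 0.0, 0.5) == pytest.approx(0.5)
    # (0.10 + lambda*0.01) / (1 + lambda) with lambda = (1-0.0047)/0.0047
    assert estimate_population_frequency(0.10, 0.01, 0.0047) == pytest.approx(
        0.010423, abs=1e-6)
    with pytest.raises(ValueError):
        estimate_population_frequency(1.2, 0.0, 0.5)


@given(alpha=st.floats(0, 1), beta=st.floats(0, 1))
@settings(deadline=None, derandomize=True)
def test_estimator_between_alpha_and_beta_and_monotone_in_p(alpha, beta):
    grid = np.linspace(0.001, 0.999, 41)
    vals = [estimate_population_frequency(alpha, beta, p) for p in grid]
    lo, hi = min(alpha, beta), max(alpha, beta)
    assert all(lo - 1e-12 <= v <= hi + 1e-12 for v in vals)
    # F moves from beta (P -> 0) towards alpha (P -> 1): monotone in P
    diffs = np.diff(vals)
    if alpha > beta:
        assert (diffs >= -1e-12).all()
    elif alpha < beta:
        assert (diffs <= 1e-12).all()


def test_boundary_is_strict():
    P = 0.0047
    assert not passes_boundary(P, P, 0.01)            # upper edge excluded
    assert not passes_boundary(0.001 * P, P, 0.01)    # below lower edge
    assert not passes_boundary(0.01 * P, P, 0.01)     # lower edge excluded
    assert passes_boundary(0.1 * P, P, 0.01)


# ---------------------------------------------------------------------------
# carrier queries
# ---------------------------------------------------------------------------

def test_carriers_of_conventions(rng):
    m = random_matrix(rng, 10, 10, 6)
    n_case, n_ctrl, ids = carriers_of(m, [])
    assert (n_case, n_ctrl) == (10, 10) and ids == m.sample_ids

    mono = GenotypeMatrix(
        ["a", "b"], ["v1"], np.array([[1], [1]], dtype=np.int8),
        np.array(["case", "control"], dtype=object))
    assert carriers_of(mono, [GenotypeKey("v1", 1)])[:2] == (1, 1)


def test_carriers_of_matches_naive_scan(rng):
    m = random_matrix(rng, 10, 10, 6)
    for _ in range(20):
        vids = rng.choice(m.variant_ids, size=3, replace=False)
        keys = [GenotypeKey(v, int(rng.integers(3))) for v in vids]
        n_case, n_ctrl, ids = carriers_of(m, keys)
        expect = [
            s for i, s in enumerate(m.sample_ids)
            if all(m.genotypes[i, m.variant_index(k.variant_id)] == k.genotype_code
                   for k in keys)
        ]
        assert ids == expect
        assert n_case + n_ctrl == len(expect)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def _as_comparable(combos):
    return {
        (c.keys, c.case_carriers, c.control_carriers,
         tuple(round(x, 12) for x in c.alpha),
         tuple(round(x, 12) for x in c.beta),
         round(c.fhat_product, 14))
        for c in combos
    }


@pytest.mark.parametrize("seed", range(12))
def test_bitset_enumeration_equals_naive_oracle(seed):
    rng = np.random.default_rng(seed)
    m = random_matrix(rng, int(rng.integers(10, 31)), int(rng.integers(10, 31)),
                      int(rng.integers(4, 13)), missing_rate=0.1)
    cfg = CgcpConfig(r=3, prevalence=0.02, min_case_carriers=2)
    fast = enumerate_specific_combinations(m, m.variant_ids, cfg)
    naive = enumerate_specific_combinations_naive(m, m.variant_ids, cfg)
    assert _as_comparable(fast) == _as_comparable(naive)


def test_enumeration_visits_all_patterns(rng):
    for n in (4, 6, 8):
        m = random_matrix(rng, 12, 12, n)
        stats = {}
        enumerate_specific_combinations(m, m.variant_ids,
                                        CgcpConfig(min_case_carriers=1),
                                        stats_out=stats)
        assert stats["visited"] == count_total_combinations(n, 3)


def test_planted_combination_recovered_with_exact_count():
    # het keys: at background maf 0.05 each F-hat is ~0.1, so the product
    # ~1e-3 sits inside the default prevalence band (4.7e-5, 4.7e-3)
    keys = (GenotypeKey("p1", 1), GenotypeKey("p2", 1), GenotypeKey("p3", 1))
    m, truth = make_case_control(
        50, 50, 5, [PlantSpec(keys=keys, case_carrier_freq=12 / 50)], seed=3)
    assert truth.plants[0].case_carriers == 12
    combos = enumerate_specific_combinations(m, m.variant_ids, CgcpConfig())
    match = [c for c in combos if c.keys == canonical_keys(keys)]
    assert len(match) == 1
    assert match[0].case_carriers == 12
    assert match[0].control_carriers == 0
    assert passes_boundary(match[0].fhat_product, 0.0047, 0.01)


def test_single_control_carrier_destroys_exclusivity():
    keys = (GenotypeKey("p1", 1), GenotypeKey("p2", 1), GenotypeKey("p3", 1))
    m, _ = make_case_control(
        50, 50, 5,
        [PlantSpec(keys=keys, case_carrier_freq=12 / 50,
                   control_carrier_freq=1 / 50)],
        seed=4)
    combos = enumerate_specific_combinations(m, m.variant_ids, CgcpConfig())
    assert all(c.keys != canonical_keys(keys) for c in combos)


def test_min_case_carriers_above_cohort_yields_nothing(rng):
    m = random_matrix(rng, 8, 8, 5)
    cfg = CgcpConfig(min_case_carriers=9)
    assert enumerate_specific_combinations(m, m.variant_ids, cfg) == []


def test_r_exceeding_candidates_is_domain_error(rng):
    m = random_matrix(rng, 8, 8, 2)
    with pytest.raises(ValueError, match="exceeds"):
        enumerate_specific_combinations(m, m.variant_ids, CgcpConfig(r=3))
    with pytest.raises(ValueError, match="exceeds"):
        enumerate_specific_combinations_naive(m, m.variant_ids, CgcpConfig(r=3))


def test_missing_never_matches_a_key():
    geno = np.array([[1, 1, 1], [-1, 1, 1], [0, 0, 0], [0, 0, 0]], dtype=np.int8)
    m = GenotypeMatrix(["c1", "c2", "k1", "k2"], ["v1", "v2", "v3"], geno,
                       np.array(["case", "case", "control", "control"], dtype=object))
    n_case, n_ctrl, ids = carriers_of(
        m, [GenotypeKey("v1", 1), GenotypeKey("v2", 1), GenotypeKey("v3", 1)])
    assert (n_case, n_ctrl, ids) == (1, 0, ["c1"])


def test_combination_canonical_form_and_distinct_variants():
    keys = (GenotypeKey("b", 2), GenotypeKey("a", 1), GenotypeKey("c", 0))
    assert canonical_keys(keys)[0].variant_id == "a"
    with pytest.raises(ValueError, match="distinct"):
        canonical_keys((GenotypeKey("a", 1), GenotypeKey("a", 2)))


def test_missing_policy_changes_denominators():
    # one case missing at v1: alpha denominator 1 under "exclude", 2 under "carrier_only"
    geno = np.array([[1, 1, 1], [-1, 1, 1], [0, 0, 0], [2, 2, 2]], dtype=np.int8)
    m = GenotypeMatrix(["c1", "c2", "k1", "k2"], ["v1", "v2", "v3"], geno,
                       np.array(["case", "case", "control", "control"], dtype=object))
    cfg_ex = CgcpConfig(min_case_carriers=1, prevalence=0.5, lower_factor=0.0)
    cfg_co = CgcpConfig(min_case_carriers=1, prevalence=0.5, lower_factor=0.0,
                        missing_policy="carrier_only")
    combo_ex = [c for c in enumerate_specific_combinations(m, m.variant_ids, cfg_ex)
                if c.keys[0].variant_id == "v1"]
    combo_co = [c for c in enumerate_specific_combinations(m, m.variant_ids, cfg_co)
                if c.keys[0].variant_id == "v1"]
    assert combo_ex and combo_co
    assert combo_ex[0].alpha[0] == pytest.approx(1.0)   # 1 of 1 called case
    assert combo_co[0].alpha[0] == pytest.approx(0.5)   # 1 of 2 cases
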