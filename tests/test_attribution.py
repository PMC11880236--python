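"""VIF screen, surrogate contract, and the Shapley engine (exact + sampled)."""

import numpy as np
import pandas as pd
import pytest

from degradiag import attribution


# ---------------------------------------------------------------------------
# VIF


def test_vif_orthonormal_features():
    rng = np.random.default_rng(0)
    q, _ = np.linalg.qr(rng.normal(size=(200, 5)))
    X = pd.DataFrame(q, columns=list("abcde"))
    v = attribution.vif_screen(X)
    assert np.allclose(v["vif"], 1.0, atol=0.2)
    assert v["passed"].all()


def test_vif_duplicated_feature_fails():
    rng = np.random.default_rng(1)
    X = pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100)})
    X["c"] = X["a"]
    v = attribution.vif_screen(X).set_index("feature")
    assert np.isinf(v.loc["a", "vif"]) and not v.loc["a", "passed"]
    assert np.isinf(v.loc["c", "vif"])


def test_vif_constant_column_raises():
    X = pd.DataFrame({"a": np.arange(100.0), "b": np.ones(100)})
    with pytest.raises(attribution.DegenerateDesignError):
        attribution.vif_screen(X)


def test_vif_synthetic_defaults_pass(county):
    X = county.drivers.set_index("unit_id")[list(attribution.DRIVER_NAMES)]
    v = attribution.vif_screen(X)
    assert v["passed"].all(), v.to_string()


# ---------------------------------------------------------------------------
# surrogate


def test_surrogate_recovers_linear_signal():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(size=(1500, 4)), columns=list("abcd"))
    y = 3 * X["a"] - 2 * X["c"]
    s = attribution.fit_surrogate(X, y, seed=0)
    assert s.holdout_r2 > 0.95
    assert not s.low_signal


def test_surrogate_deterministic_given_seed():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(300, 3)), columns=list("abc"))
    y = X["a"] + rng.normal(scale=0.1, size=300)
    p1 = attribution.fit_surrogate(X, y, seed=5).predict(np.asarray(X))
    p2 = attribution.fit_surrogate(X, y, seed=5).predict(np.asarray(X))
    assert np.array_equal(p1, p2)


def test_surrogate_null_model_on_shuffled_target():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(rng.normal(size=(1000, 4)), columns=list("abcd"))
    y = rng.permutation((3 * X["a"]).to_numpy())
    s = attribution.fit_surrogate(X, y, seed=0)
    assert s.holdout_r2 < 0.1


def test_surrogate_zero_variance_warns_not_raises():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
    with pytest.warns(UserWarning):
        s = attribution.fit_surrogate(X, np.zeros(200), seed=0)
    assert s.low_signal


# ---------------------------------------------------------------------------
# Shapley engine on abstract value functions


def _random_value_function(n, seed):
    rng = np.random.default_rng(seed)
    table = {}

    def v(s):
        key = frozenset(s)
        if key not in table:
            table[key] = float(rng.normal())
        return table[key]

    # materialise all subsets deterministically (ordered enumeration)
    from itertools import combinations

    for size in range(n + 1):
        for c in combinations(range(n), size):
            v(c)
    return v


def test_exact_matches_permutation_enumeration():
    """Weighted-subset sum equals the full 720-permutation average at |K|=6."""
    for seed in (0, 1, 2):
        v = _random_value_function(6, seed)
        phi = attribution.shapley_exact(v, 6)
        oracle = attribution.shapley_permutation_oracle(v, 6)
        assert np.max(np.abs(phi - oracle)) < 1e-12


def test_additive_value_function_gives_weights():
    w = np.array([1.5, -2.0, 0.25, 3.0])
    phi = attribution.shapley_exact(lambda s: sum(w[i] for i in s), 4)
    assert np.allclose(phi, w, atol=1e-12)


def test_symmetry_axiom_two_player():
    v = lambda s: 1.0 if len(s) == 2 else 0.0
    assert np.allclose(attribution.shapley_exact(v, 2), [0.5, 0.5])


def test_axioms_on_random_value_functions():
    """Efficiency, symmetry, dummy and linearity at |K| = 8."""
    n = 8
    v = _random_value_function(n, 10)
    w = _random_value_function(n, 11)
    phi_v = attribution.shapley_exact(v, n)
    phi_w = attribution.shapley_exact(w, n)

    # efficiency
    full = frozenset(range(n))
    assert phi_v.sum() == pytest.approx(v(full) - v(frozenset()), abs=1e-9)

    # linearity: phi(2v + 3w) = 2 phi(v) + 3 phi(w)
    phi_mix = attribution.shapley_exact(lambda s: 2 * v(s) + 3 * w(s), n)
    assert np.allclose(phi_mix, 2 * phi_v + 3 * phi_w, atol=1e-9)

    # dummy: a feature the function ignores gets phi = 0
    v_dummy = lambda s: v(frozenset(i for i in s if i != 3))
    assert attribution.shapley_exact(v_dummy, n)[3] == pytest.approx(0.0, abs=1e-12)

    # symmetry: swapping two interchangeable features preserves phi
    swap = {0: 1, 1: 0}
    v_sym = lambda s: v(frozenset(swap.get(i, i) for i in s))
    phi_sym = attribution.shapley_exact(v_sym, n)
    assert phi_sym[0] == pytest.approx(phi_v[1], abs=1e-12)
    assert phi_sym[1] == pytest.approx(phi_v[0], abs=1e-12)


def test_exact_guard_on_large_k():
    with pytest.raises(ValueError):
        attribution.shapley_exact(lambda s: 0.0, 16)


def test_sampled_within_three_se_of_exact():
    v = _random_value_function(6, 20)
    exact = attribution.shapley_exact(v, 6)
    phi, se = attribution.shapley_sampled(v, 6, n_perm=2000, seed=0)
    assert np.all(np.abs(phi - exact) <= 3 * se + 1e-12)


def test_sampled_se_shrinks_with_sqrt_n():
    v = _random_value_function(6, 21)
    _, se1 = attribution.shapley_sampled(v, 6, n_perm=500, seed=1)
    _, se2 = attribution.shapley_sampled(v, 6, n_perm=1000, seed=1)
    ratio = se2.mean() / se1.mean()
    assert 0.6 < ratio < 0.82  # ~ 1/sqrt(2)


def test_sampled_dummy_feature_near_zero():
    v = _random_value_function(6, 22)
    v_dummy = lambda s: v(frozenset(i for i in s if i != 2))
    phi, se = attribution.shapley_sampled(v_dummy, 6, n_perm=2000, seed=2)
    assert abs(phi[2]) <= 3 * se[2] + 1e-12


def test_sampled_reproducible():
    v = _random_value_function(5, 23)
    a = attribution.shapley_sampled(v, 5, n_perm=50, seed=9)
    b = attribution.shapley_sampled(v, 5, n_perm=50, seed=9)
    assert np.array_equal(a[0], b[0])


# ---------------------------------------------------------------------------
# marginalised instance attribution + ranking


def _toy_surrogate(fn, names):
    return attribution.Surrogate(
        predict=lambda A: fn(np.asarray(A, dtype=float)),
        feature_names=tuple(names),
        holdout_r2=1.0,
        n_train=100,
        seed=0,
    )


def test_attribute_exact_linear_model_closed_form():
    """For a linear model, phi_i = beta_i * (x_i - mean(background_i))."""
    rng = np.random.default_rng(30)
    beta = np.array([2.0, -1.0, 0.5])
    sur = _toy_surrogate(lambda A: A @ beta, ["a", "b", "c"])
    X = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
    bg = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
    res = attribution.attribute_exact(sur, X, bg)
    expected = beta * (np.asarray(X) - np.asarray(bg).mean(axis=0))
    assert np.allclose(res.phi, expected, atol=1e-10)
    assert np.max(res.efficiency_gap()) < 1e-9


def test_attribute_sampled_agrees_with_exact():
    rng = np.random.default_rng(31)
    beta = np.array([1.0, 0.0, -2.0, 0.5])
    sur = _toy_surrogate(lambda A: A @ beta + 0.3 * A[:, 0] * A[:, 2], list("abcd"))
    X = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
    bg = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
    exact = attribution.attribute_exact(sur, X, bg)
    samp = attribution.attribute_sampled(sur, X, bg, n_perm=800, seed=0)
    assert np.all(np.abs(samp.phi - exact.phi) <= 3 * samp.se + 1e-9)
    assert np.max(samp.efficiency_gap()) < 1e-9  # telescoping sum is exact


def test_rank_drivers_recovers_planted_driver():
    """A single strong driver ranks first with the right direction in >= 90%
    of seeded runs."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        X = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("abcde"))
        beta = np.array([0.1, 0.0, 3.0, 0.1, 0.0])  # c dominates, mitigating
        sur = _toy_surrogate(lambda A: A @ beta, list("abcde"))
        res = attribution.attribute_sampled(
            sur, X.iloc[:40], X.iloc[40:120], n_perm=30, seed=seed
        )
        rank = attribution.rank_drivers(res)
        if rank.iloc[0]["feature"] == "c" and rank.iloc[0]["direction"] == 1:
            hits += 1
    assert hits >= 18


def test_rank_drivers_flags_all_noise():
    rng = np.random.default_rng(40)
    sur = _toy_surrogate(lambda A: np.full(len(A), 1.23), list("abc"))
    X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
    res = attribution.attribute_exact(sur, X.iloc[:10], X.iloc[10:])
    rank = attribution.rank_drivers(res)
    assert rank["low_signal"].all()
    assert (rank["direction"] == 0).all()
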