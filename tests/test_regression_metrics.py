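"""Regression validation statistics: hand-computed values and invariants."""

import numpy as np
import pytest

import qsarchance as qc
from qsarchance.errors import ContractError, DomainError, FitError
from tests.conftest import naive_q2_loo


# ---------------------------------------------------------------------------
# r_squared
# ---------------------------------------------------------------------------

def test_r2_perfect_and_null():
    y = np.array([1.0, 2.0, 3.0])
    assert qc.r_squared(y, y) == 1.0
    assert qc.r_squared(y, np.full(3, y.mean())) == 0.0


def test_r2_hand_computed():
    # SSres = 0.01+0.01+0.04+0.04 = 0.1, SStot = 5 -> 0.98
    y = [1, 2, 3, 4]
    yhat = [1.1, 1.9, 3.2, 3.8]
    assert qc.r_squared(y, yhat) == pytest.approx(0.98)


def test_r2_length_mismatch():
    with pytest.raises(ContractError):
        qc.r_squared([1, 2], [1, 2, 3])


# ---------------------------------------------------------------------------
# q_squared_cv
# ---------------------------------------------------------------------------

def test_q2_exact_linear_is_one():
    x = np.arange(8.0)
    assert qc.q_squared_cv(x[:, None], 1 + 2 * x, m=1) == pytest.approx(1.0)


def test_q2_loo_matches_naive_refit_oracle_on_quadratic_toy():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    y = x**2  # linear model misfit: q2 well below 1
    fast = qc.q_squared_cv(x[:, None], y, m=1)
    assert fast == pytest.approx(naive_q2_loo(x[:, None], y), abs=1e-12)


def test_q2_lmo_matches_naive_refit_oracle(rng):
    """Exhaustive leave-3-out via block deletion vs per-fold refitting."""
    from itertools import combinations

    X = rng.standard_normal((9, 2))
    y = X @ [1.0, -1.0] + rng.standard_normal(9)
    fast = qc.q_squared_cv(X, y, m=3)

    n = 9
    sq = np.zeros(n)
    cnt = np.zeros(n)
    for fold in combinations(range(n), 3):
        idx = np.array(fold)
        mask = np.ones(n, bool)
        mask[idx] = False
        Z = np.column_stack([np.ones(mask.sum()), X[mask]])
        b = np.linalg.lstsq(Z, y[mask], rcond=None)[0]
        err = y[idx] - (b[0] + X[idx] @ b[1:])
        sq[idx] += err**2
        cnt[idx] += 1
    naive = 1 - np.sum(sq / cnt) / np.sum((y - y.mean()) ** 2)
    assert fast == pytest.approx(naive, abs=1e-12)


def test_q2_below_r2_on_random_data():
    """Cross-validation penalizes overfit: q2 < r2 in >= 95% of replicates."""
    wins = 0
    reps = 200
    for seed in range(reps):
        rng = qc.make_stream(seed)
        X = rng.standard_normal((21, 3))
        y = rng.standard_normal(21)
        fit = qc.fit_ols(X, y)
        wins += qc.q_squared_cv(X, y, m=1) < fit.r2_train
    assert wins >= 0.95 * reps


def test_q2_custom_fitter_forces_naive_path(rng):
    X = rng.standard_normal((10, 2))
    y = rng.standard_normal(10)

    def fitter(Xt, yt):
        Z = np.column_stack([np.ones(len(yt)), Xt])
        b = np.linalg.lstsq(Z, yt, rcond=None)[0]
        return lambda Xn: b[0] + np.asarray(Xn) @ b[1:]

    assert qc.q_squared_cv(X, y, m=1, fitter=fitter) == pytest.approx(
        qc.q_squared_cv(X, y, m=1), abs=1e-12
    )


# ---------------------------------------------------------------------------
# origin regression + Golbraikh–Tropsha
# ---------------------------------------------------------------------------

def test_origin_regression_identity_and_proportionality():
    y = np.array([1.0, 2.0, 3.0])
    k, r0 = qc.origin_regression(y, y)
    assert (k, r0) == (pytest.approx(1.0), pytest.approx(1.0))
    k2, _ = qc.origin_regression(2 * y, y)
    assert k2 == pytest.approx(2.0)


def test_origin_regression_all_zero_predictions():
    with pytest.raises(DomainError):
        qc.origin_regression([1.0, 2.0], [0.0, 0.0])


def test_r0_never_exceeds_free_intercept_r2():
    """Algebraic property checked numerically across 1000 random vectors."""
    rng = qc.make_stream(42)
    for _ in range(1000):
        y = rng.standard_normal(10)
        f = rng.standard_normal(10)
        _, r0 = qc.origin_regression(y, f)
        # free-intercept, free-slope fit of y on f
        b = np.polyfit(f, y, 1)
        r2 = qc.r_squared(y, np.polyval(b, f))
        assert r0 <= r2 + 1e-10


def test_golbraikh_tropsha_thresholds():
    ok = qc.golbraikh_tropsha(q2=0.805, R2=0.732, R0_2=0.70, k=1.0)
    assert ok.q2_ok and ok.r2_ok and ok.ratio_ok and ok.slope_ok and ok.overall
    assert not qc.golbraikh_tropsha(0.4, 0.732, 0.70, 1.0).q2_ok
    # boundaries are strict for q2/R2, inclusive for the slope band
    assert not qc.golbraikh_tropsha(0.5, 0.7, 0.7, 1.0).q2_ok
    assert not qc.golbraikh_tropsha(0.8, 0.6, 0.55, 1.0).r2_ok
    assert qc.golbraikh_tropsha(0.8, 0.7, 0.7, 0.85).slope_ok
    assert qc.golbraikh_tropsha(0.8, 0.7, 0.7, 1.15).slope_ok
    assert not qc.golbraikh_tropsha(0.8, 0.7, 0.7, 1.16).slope_ok
    zero = qc.golbraikh_tropsha(0.8, 0.0, 0.0, 1.0)
    assert not zero.ratio_ok and zero.reason


# ---------------------------------------------------------------------------
# cRp² and rm²
# ---------------------------------------------------------------------------

def test_crp2_reference_values():
    assert qc.c_rp2(0.811, 0.669) == pytest.approx(0.339, abs=5e-4)
    assert qc.c_rp2(0.784, 0.669) == pytest.approx(0.300, abs=5e-4)
    assert qc.c_rp2(0.64, 0.0) == pytest.approx(0.64)  # Rr²=0 limit


def test_crp2_domain():
    with pytest.raises(DomainError):
        qc.c_rp2(1.2, 0.1)
    with pytest.raises(DomainError):
        qc.c_rp2(0.5, -0.1)
    with pytest.warns(RuntimeWarning):
        assert np.isnan(qc.c_rp2(0.3, 0.5))


def test_rm2_hand_computed():
    assert qc.rm2_test(0.81, 0.77) == pytest.approx(0.648)  # sqrt(0.04)=0.2
    assert qc.rm2_test(0.64, 0.55) == pytest.approx(0.448)  # sqrt(0.09)=0.3
    assert qc.rm2_test(0.7, 0.7) == pytest.approx(0.7)      # zero gap


def test_crp2_monotone_in_r2_and_rm2_monotone_in_r0():
    """cRp² grows with the model r² at a fixed chance baseline; rm² grows as
    R0² approaches R² (a shrinking gap means better absolute predictions).
    Note rm² is *not* monotone in R² at fixed R0²: the widening gap's
    penalty outpaces the R² factor."""
    r = np.linspace(0.5, 0.95, 20)
    crp = [qc.c_rp2(v, 0.4) for v in r]
    assert all(a < b for a, b in zip(crp, crp[1:]))
    r0 = np.linspace(0.1, 0.8, 20)
    rm = [qc.rm2_test(0.8, v) for v in r0]
    assert all(a < b for a, b in zip(rm, rm[1:]))


# ---------------------------------------------------------------------------
# permutation intercepts
# ---------------------------------------------------------------------------

def test_flat_line_intercept():
    pairs = [(0.1, 0.3), (0.5, 0.3), (0.9, 0.3)]
    r_int, q_int = qc.randomization_intercepts(pairs, pairs, true_r2=0.3, true_q2=0.3)
    assert r_int == pytest.approx(0.3)
    assert q_int == pytest.approx(0.3)


def test_planted_line_intercept_recovered():
    xs = np.array([0.05, 0.2, 0.4, 0.6, 0.8])
    r_pairs = [(x, 0.1 + 0.8 * x) for x in xs]
    q_pairs = [(x, 0.02 + 0.9 * x) for x in xs]
    r_int, q_int = qc.randomization_intercepts(
        r_pairs, q_pairs, true_r2=0.1 + 0.8, true_q2=0.02 + 0.9
    )
    assert r_int == pytest.approx(0.1, abs=1e-12)
    assert q_int == pytest.approx(0.02, abs=1e-12)


def test_identical_x_values_is_fit_error():
    pairs = [(0.5, 0.1), (0.5, 0.2), (0.5, 0.3)]
    with pytest.raises(FitError):
        qc.randomization_intercepts(pairs, pairs, 0.5, 0.5)


def test_wold_experiment_on_strong_signal_passes_thresholds():
    """A genuine model's permutation intercepts fall below 0.4 / 0.05."""
    t = qc.make_regression_fixture(
        qc.FixtureSpec(n=21, p=3, signal_descriptors=(0, 1, 2),
                       beta=(2.0, 1.5, 1.0), noise_sd=0.7, seed=8)
    )
    X = t.values
    y = t.activity_column("activity")
    r_int, q_int = qc.wold_intercept_experiment(X, y, n_perm=25, seed=3)
    assert r_int < 0.4
    assert q_int < 0.05
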