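"""Validation statistics for regression QSAR models.

Implements the full desk set used when auditing a model against chance:
training r², cross-validated q² (leave-one-out and exhaustive leave-m-out),
external R², regression through the origin (R0², slope k), the
Golbraikh–Tropsha predictive-power criteria, the non-randomness parameter
cRp², the absolute-response metric rm(test)², and the Wold response-
permutation intercepts R²int / Q²int.

Conventions (documented because the literature varies):

* q² uses the PRESS form ``1 − PRESS / Σ(y − ȳ_all)²`` with the
  full-training-set mean in the denominator.
* Leave-m-out enumerates **all** C(n, m) held-out groups; each point's
  squared prediction errors are averaged over the groups containing it
  before summation into PRESS.
* The permutation-intercept plot puts |Pearson corr(y, y_perm)| on the
  x-axis and includes the unpermuted anchor point (1, true statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .errors import ContractError, DomainError, FitError

__all__ = [
    "r_squared",
    "q_squared_cv",
    "origin_regression",
    "golbraikh_tropsha",
    "GolbraikhTropsha",
    "c_rp2",
    "rm2_test",
    "randomization_intercepts",
    "wold_intercept_experiment",
    "ValidationReport",
]


def r_squared(y_obs: Sequence[float], y_pred: Sequence[float]) -> float:
    """Coefficient of determination ``1 − SS_res/SS_tot``.

    Returns 0 with a warning when the observed response is constant
    (SS_tot = 0), so null pipelines on degenerate scrambles do not crash.
    """
    y = np.asarray(y_obs, dtype=float).ravel()
    f = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != f.shape:
        raise ContractError("y_obs and y_pred have different lengths")
    if y.size < 2:
        raise ContractError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant response: r^2 defined as 0", RuntimeWarning)
        return 0.0
    return 1.0 - float(np.sum((y - f) ** 2)) / ss_tot


def _ols_predictor(X: np.ndarray, y: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    Z = np.column_stack([np.ones(X.shape[0]), X])
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < Z.shape[1]:
        raise FitError("rank-deficient design in cross-validation refit")
    return lambda Xnew: beta[0] + np.asarray(Xnew) @ beta[1:]


def q_squared_cv(
    X: np.ndarray,
    y: Sequence[float],
    m: int = 1,
    fitter: Callable[[np.ndarray, np.ndarray], Callable] | None = None,
) -> float:
    """Cross-validated q² = 1 − PRESS / Σ(y − ȳ_all)² with leave-m-out.

    With the default OLS fitter and ``m == 1`` the exact closed form via
    deleted residuals ``e_i / (1 − h_ii)`` is used; for ``m > 1`` every
    C(n, m) group is held out using the exact block-deletion identity
    ``ê_T = (I − H_TT)⁻¹ e_T``, and each point's squared errors are averaged
    over the groups containing it before summation.  A custom ``fitter``
    (taking ``(X_train, y_train)`` and returning a predictor) forces naive
    refitting per fold.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if m < 1 or n <= m:
        raise ContractError("need 1 <= m < n")
    if n - m <= k + 1:
        raise ContractError(
            f"n - m must exceed the predictor count + 1 (n={n}, m={m}, k={k})"
        )
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant response: q^2 defined as 0", RuntimeWarning)
        return 0.0

    if fitter is not None:
        sq_sum = np.zeros(n)
        sq_cnt = np.zeros(n)
        for fold in combinations(range(n), m):
            idx = np.array(fold)
            mask = np.ones(n, dtype=bool)
            mask[idx] = False
            try:
                pred = fitter(X[mask], y[mask])
            except FitError as exc:
                raise FitError(f"fold {fold}: {exc}") from exc
            err = y[idx] - np.asarray(pred(X[idx])).ravel()
            sq_sum[idx] += err**2
            sq_cnt[idx] += 1
        press = float(np.sum(sq_sum / sq_cnt))
        return 1.0 - press / ss_tot

    Z = np.column_stack([np.ones(n), X])
    G = Z.T @ Z
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        raise FitError("rank-deficient design in cross-validation") from None
    H = Z @ Ginv @ Z.T
    e = y - H @ y
    if m == 1:
        d = 1.0 - np.diag(H)
        if np.any(d <= 1e-12):
            raise FitError("leverage 1 point: leave-one-out undefined")
        press = float(np.sum((e / d) ** 2))
        return 1.0 - press / ss_tot

    sq_sum = np.zeros(n)
    sq_cnt = np.zeros(n)
    eye = np.eye(m)
    for fold in combinations(range(n), m):
        idx = np.array(fold)
        M = eye - H[np.ix_(idx, idx)]
        try:
            ehat = np.linalg.solve(M, e[idx])
        except np.linalg.LinAlgError:
            raise FitError(f"fold {fold}: deleted design is rank deficient") from None
        sq_sum[idx] += ehat**2
        sq_cnt[idx] += 1
    press = float(np.sum(sq_sum / sq_cnt))
    return 1.0 - press / ss_tot


def origin_regression(
    y_obs: Sequence[float], y_pred: Sequence[float]
) -> tuple[float, float]:
    """Slope ``k`` and determination ``R0²`` of the observed-vs-predicted
    regression forced through the origin:
    ``k = Σ(y·ŷ)/Σŷ²``, ``R0² = 1 − Σ(y − kŷ)²/Σ(y − ȳ)²``.
    """
    y = np.asarray(y_obs, dtype=float).ravel()
    f = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != f.shape:
        raise ContractError("y_obs and y_pred have different lengths")
    denom = float(f @ f)
    if denom == 0.0:
        raise DomainError("all-zero predictions: origin regression undefined")
    k = float(y @ f) / denom
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant response: R0^2 defined as 0", RuntimeWarning)
        return k, 0.0
    r0 = 1.0 - float(np.sum((y - k * f) ** 2)) / ss_tot
    return k, r0


@dataclass(frozen=True)
class GolbraikhTropsha:
    """Outcome of the four external-predictivity criteria."""

    q2_ok: bool          # q² > 0.5
    r2_ok: bool          # R² > 0.6
    ratio_ok: bool       # (R² − R0²)/R² < 0.1
    slope_ok: bool       # 0.85 ≤ k ≤ 1.15
    reason: str = ""

    @property
    def overall(self) -> bool:
        return self.q2_ok and self.r2_ok and self.ratio_ok and self.slope_ok


def golbraikh_tropsha(q2: float, R2: float, R0_2: float, k: float) -> GolbraikhTropsha:
    """Evaluate the widely used predictive-power criteria: ``q² > 0.5``,
    ``R² > 0.6`` (strict), ``(R² − R0²)/R² < 0.1`` and ``0.85 ≤ k ≤ 1.15``."""
    reason = ""
    if R2 == 0.0:
        ratio_ok = False
        reason = "R^2 is zero: ratio criterion undefined, reported as failed"
    else:
        ratio_ok = (R2 - R0_2) / R2 < 0.1
    return GolbraikhTropsha(
        q2_ok=q2 > 0.5,
        r2_ok=R2 > 0.6,
        ratio_ok=ratio_ok,
        slope_ok=0.85 <= k <= 1.15,
        reason=reason,
    )


def c_rp2(r2: float, rr2_random: float) -> float:
    """Non-randomness parameter ``cRp² = √(r² · (r² − Rr²))`` where ``Rr²``
    is the mean r² of models trained on randomized data.

    Returns NaN with a warning when ``Rr² > r²`` (the model is worse than
    its own chance baseline)."""
    if not 0.0 <= r2 <= 1.0:
        raise DomainError("r2 must lie in [0, 1]")
    if rr2_random < 0.0:
        raise DomainError("rr2_random must be non-negative")
    if rr2_random > r2:
        warnings.warn(
            "mean randomized r^2 exceeds the model r^2: cRp^2 undefined",
            RuntimeWarning,
        )
        return float("nan")
    return float(np.sqrt(r2) * np.sqrt(r2 - rr2_random))


def rm2_test(R2: float, R0_2: float) -> float:
    """Absolute-response metric ``rm² = R² · (1 − √(R² − R0²))``.

    Implemented in the single observed-vs-predicted orientation; requires
    ``R² ≥ R0² ≥ 0`` (else NaN with a warning)."""
    for name, v in (("R2", R2), ("R0_2", R0_2)):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name} must lie in [0, 1]")
    if R0_2 > R2:
        warnings.warn("R0^2 exceeds R^2: rm^2 undefined", RuntimeWarning)
        return float("nan")
    return float(R2 * (1.0 - np.sqrt(R2 - R0_2)))


def _intercept(xs: np.ndarray, ys: np.ndarray) -> float:
    if np.ptp(xs) == 0.0:
        raise FitError("identical x-values: intercept line undefined")
    slope, intercept = np.polyfit(xs, ys, 1)
    return float(intercept)


def randomization_intercepts(
    r2_corr_pairs: Sequence[tuple[float, float]],
    q2_corr_pairs: Sequence[tuple[float, float]],
    true_r2: float,
    true_q2: float,
) -> tuple[float, float]:
    """Wold-style permutation intercepts.

    Each pair is ``(|corr(y, y_perm)|, statistic of the refitted model)``.
    The pairs are augmented with the unpermuted anchor ``(1, true value)``,
    an ordinary least-squares line is fitted, and the intercept at zero
    correlation is returned for r² and q².  Models are conventionally judged
    valid when ``R²int < 0.4`` and ``Q²int < 0.05``.
    """
    if len(r2_corr_pairs) < 3 or len(q2_corr_pairs) < 3:
        raise ContractError("need at least 3 permutation pairs")
    for pairs in (r2_corr_pairs, q2_corr_pairs):
        xs = np.array([p[0] for p in pairs], dtype=float)
        if np.ptp(xs) == 0.0:
            raise FitError(
                "all permutation correlations identical: intercept line "
                "would be determined by the anchor point alone"
            )
    r_pts = np.array(list(r2_corr_pairs) + [(1.0, true_r2)], dtype=float)
    q_pts = np.array(list(q2_corr_pairs) + [(1.0, true_q2)], dtype=float)
    return _intercept(r_pts[:, 0], r_pts[:, 1]), _intercept(q_pts[:, 0], q_pts[:, 1])


def wold_intercept_experiment(
    X: np.ndarray,
    y: Sequence[float],
    n_perm: int = 25,
    seed: int = 0,
) -> tuple[float, float]:
    """Run the full permutation-intercept experiment for a fixed OLS model.

    Permutes ``y`` ``n_perm`` times, refits the model on each permuted
    response, collects (|corr|, r²) and (|corr|, q²) pairs plus the
    unpermuted anchor, and returns (R²int, Q²int).
    """
    from .randomize import make_stream, scramble_column

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = make_stream(seed)
    pred = _ols_predictor(X, y)
    true_r2 = r_squared(y, pred(X))
    true_q2 = q_squared_cv(X, y, m=1)
    r_pairs, q_pairs = [], []
    for _ in range(n_perm):
        yp = scramble_column(y, rng)
        c = abs(float(np.corrcoef(y, yp)[0, 1]))
        pp = _ols_predictor(X, yp)
        r_pairs.append((c, r_squared(yp, pp(X))))
        q_pairs.append((c, q_squared_cv(X, yp, m=1)))
    return randomization_intercepts(r_pairs, q_pairs, true_r2, true_q2)


@dataclass
class ValidationReport:
    """All scalar regression-validation statistics for one model."""

    r2: float
    q2_loo: float
    q2_lmo: float | None = None
    R2_ext: float | None = None
    R0_2: float | None = None
    slope_k: float | None = None
    gt: GolbraikhTropsha | None = None
    c_rp2: float | None = None
    rm2_test: float | None = None
    r2_int: float | None = None
    q2_int: float | None = None

    def rounded(self, ndigits: int = 3) -> dict:
        out = {}
        for k_, v in self.__dict__.items():
            if isinstance(v, float):
                out[k_] = round(v, ndigits)
            elif isinstance(v, GolbraikhTropsha):
                out[k_] = v.overall
            else:
                out[k_] = v
        return out
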