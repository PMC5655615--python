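"""Model engines for the chance harness.

The randomization audit needs model *search*, not just a single fit: the
whole point of mhr²-style thresholds is that searching a descriptor pool
inflates the best chance score far above the single-model null.  This module
provides

* :func:`reduce_descriptor_pool` — constant/near-constant removal and the
  |r| > 0.90 intercorrelation filter applied before model training;
* :func:`fit_ols` — ordinary least squares with coefficient standard errors;
* :func:`search_linear_models` — best-subset search over linear models of up
  to ``max_vars`` descriptors, either exhaustively or by a genetic algorithm
  (a stand-in for GFA-style evolutionary model selection);
* :func:`fit_tree` — a depth-limited CART classification tree (Gini
  impurity) with fully deterministic tie-breaking.

The subset search is vectorized through the cross-product algebra: with
centered descriptors ``Xc`` and response ``yc``, the training r² of the OLS
model on subset ``S`` is ``c_y[S]ᵀ C[S,S]⁻¹ c_y[S] / (ycᵀyc)`` where
``C = XcᵀXc`` and ``c_y = Xcᵀyc``.  All C(p,k) systems of size k ≤ 3 are
solved in a single batched call, which keeps exhaustive search over
p = 89 descriptors (≈125k subsets) in tens of milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np

from .errors import ConfigError, ContractError, EmptyPoolError, FitError
from .table import DescriptorTable

__all__ = [
    "FitResult",
    "TreeModel",
    "GAConfig",
    "SubsetScorer",
    "reduce_descriptor_pool",
    "fit_ols",
    "search_linear_models",
    "fit_tree",
    "predict",
]

EXHAUSTIVE_CAP = 200_000


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A fitted linear model with its training statistics."""

    selected_descriptors: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    r2_train: float
    fitted_values: np.ndarray
    q2_loo: float | None = None
    std_errors: dict[str, float] = field(default_factory=dict)
    intercept_se: float | None = None

    def equation(self, ndigits: int = 3) -> str:
        terms = [f"{round(self.intercept, ndigits)}"]
        for name in self.selected_descriptors:
            c = round(self.coefficients[name], ndigits)
            terms.append(f"{'+' if c >= 0 else '-'} {abs(c)} × {name}")
        return " ".join(terms)


@dataclass
class _TreeNode:
    feature: int
    threshold: float
    left: "object"
    right: "object"


@dataclass
class _TreeLeaf:
    label: int
    n: int
    counts: tuple[int, int]


@dataclass
class TreeModel:
    """A binary CART classification tree of bounded depth."""

    root: object
    max_depth: int
    feature_names: tuple[str, ...] | None = None

    def depth(self) -> int:
        def d(node):
            if isinstance(node, _TreeLeaf):
                return 0
            return 1 + max(d(node.left), d(node.right))

        return d(self.root)


# ---------------------------------------------------------------------------
# Pool reduction
# ---------------------------------------------------------------------------

def reduce_descriptor_pool(
    table: DescriptorTable,
    corr_threshold: float = 0.90,
    rng: np.random.Generator | None = None,
    near_constant_frac: float = 0.95,
) -> DescriptorTable:
    """Remove constant/near-constant descriptors, then thin intercorrelated
    pairs.

    A column is near-constant when its most frequent value occupies more than
    ``near_constant_frac`` of the rows or its sample variance is below 1e-12.
    Remaining pairs with |Pearson r| above ``corr_threshold`` lose one member
    at random (via ``rng``) until no offending pair remains.  Activities are
    untouched.
    """
    if table.n_descriptors < 1:
        raise ContractError("table has no descriptors")
    if rng is None:
        rng = np.random.Generator(np.random.MT19937(0))

    X = table.values
    n = X.shape[0]
    keep: list[int] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if col.size > 1 and col.var(ddof=1) < 1e-12:
            continue
        _, counts = np.unique(col, return_counts=True)
        if counts.max() > near_constant_frac * n:
            continue
        keep.append(j)
    if not keep:
        raise EmptyPoolError("pool reduction removed every descriptor")

    alive = list(keep)
    while True:
        Xa = X[:, alive]
        with np.errstate(invalid="ignore"):
            R = np.corrcoef(Xa, rowvar=False)
        if R.ndim == 0:  # single survivor
            break
        np.fill_diagonal(R, 0.0)
        removed_any = False
        dead: set[int] = set()
        for a in range(len(alive)):
            if a in dead:
                continue
            for b in range(a + 1, len(alive)):
                if b in dead:
                    continue
                if abs(R[a, b]) > corr_threshold:
                    dead.add(a if rng.integers(0, 2) == 0 else b)
                    removed_any = True
                    break  # member of this pair gone; rescan row
        alive = [alive[i] for i in range(len(alive)) if i not in dead]
        if not alive:
            raise EmptyPoolError("intercorrelation filter removed every descriptor")
        if not removed_any:
            break
    return table.select_descriptors([table.descriptor_names[j] for j in alive])


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

def _r2_of(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant response: r^2 defined as 0", RuntimeWarning)
        return 0.0
    return 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot


def fit_ols(
    X: np.ndarray,
    y: np.ndarray,
    descriptor_names: Sequence[str] | None = None,
) -> FitResult:
    """Ordinary least squares with intercept and classical standard errors.

    Raises :class:`FitError` identifying the linearly dependent column(s) on
    a rank-deficient design.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if y.shape[0] != n:
        raise ContractError("X and y have different lengths")
    if n <= k + 1:
        raise ContractError(f"need n > k + 1 observations (n={n}, k={k})")
    if descriptor_names is None:
        descriptor_names = tuple(f"x{j + 1}" for j in range(k))
    descriptor_names = tuple(descriptor_names)

    Z = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < k + 1:
        from scipy.linalg import qr

        _, _, piv = qr(Z, pivoting=True, mode="economic")
        dependent = sorted(piv[rank:].tolist())
        names = [
            "intercept" if j == 0 else descriptor_names[j - 1] for j in dependent
        ]
        raise FitError(f"rank-deficient design; dependent column(s): {names}")

    fitted = Z @ beta
    resid = y - fitted
    dof = n - k - 1
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(Z.T @ Z)
    se = np.sqrt(np.diag(cov))
    return FitResult(
        selected_descriptors=descriptor_names,
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(descriptor_names, beta[1:])},
        r2_train=_r2_of(y, fitted),
        fitted_values=fitted,
        std_errors={name: float(s) for name, s in zip(descriptor_names, se[1:])},
        intercept_se=float(se[0]),
    )


# ---------------------------------------------------------------------------
# Batched subset scoring
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _subsets_upto(p: int, max_vars: int) -> tuple[np.ndarray, ...]:
    """Index arrays of all subsets of sizes 1..max_vars from a pool of p."""
    out = []
    for k in range(1, max_vars + 1):
        if k > p:
            break
        out.append(
            np.array(list(combinations(range(p), k)), dtype=np.intp).reshape(-1, k)
        )
    return tuple(out)


def n_subsets_upto(p: int, max_vars: int) -> int:
    from math import comb

    return sum(comb(p, k) for k in range(1, min(max_vars, p) + 1))


class SubsetScorer:
    """Batched training-r² (and leave-one-out q²) over descriptor subsets."""

    def __init__(self, X: np.ndarray, y: np.ndarray) -> None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self.n, self.p = X.shape
        self.Xc = X - X.mean(axis=0)
        self.yc = y - y.mean()
        self.C = self.Xc.T @ self.Xc
        self.cy = self.Xc.T @ self.yc
        self.syy = float(self.yc @ self.yc)
        self.degenerate = self.syy == 0.0

    def score_many(self, subsets: np.ndarray) -> np.ndarray:
        """Training r² for each subset row; singular subsets score -inf,
        a constant response scores 0 everywhere."""
        subsets = np.atleast_2d(np.asarray(subsets, dtype=np.intp))
        m, k = subsets.shape
        if self.degenerate:
            return np.zeros(m)
        A = self.C[subsets[:, :, None], subsets[:, None, :]]
        b = self.cy[subsets]
        if k == 1:
            diag = A[:, 0, 0]
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = b[:, 0] ** 2 / (diag * self.syy)
            r2[~np.isfinite(r2)] = -np.inf
            return r2
        sol = _solve_batched(A, b)
        with np.errstate(invalid="ignore"):
            r2 = np.einsum("mk,mk->m", sol, b) / self.syy
        r2[~np.isfinite(sol).all(axis=1)] = -np.inf
        return np.clip(r2, -np.inf, 1.0)

    def loo_q2_many(self, subsets: np.ndarray, chunk: int = 20_000) -> np.ndarray:
        """Exact leave-one-out q² for each subset, via deleted residuals
        ``e_i / (1 - h_ii)`` (PRESS denominator uses the full-sample mean)."""
        subsets = np.atleast_2d(np.asarray(subsets, dtype=np.intp))
        m, k = subsets.shape
        if self.degenerate:
            return np.zeros(m)
        out = np.empty(m)
        for s in range(0, m, chunk):
            sub = subsets[s : s + chunk]
            A = self.C[sub[:, :, None], sub[:, None, :]]
            b = self.cy[sub]
            try:
                Ainv = np.linalg.inv(A)
            except np.linalg.LinAlgError:
                Ainv = np.linalg.pinv(A)
            sol = np.einsum("mkl,ml->mk", Ainv, b)
            G = self.Xc[:, sub]                      # (n, mc, k)
            G = np.moveaxis(G, 0, 1)                 # (mc, n, k)
            e = self.yc[None, :] - np.einsum("mnk,mk->mn", G, sol)
            h = 1.0 / self.n + np.einsum("mnk,mkl,mnl->mn", G, Ainv, G)
            with np.errstate(divide="ignore", invalid="ignore"):
                press = np.sum((e / (1.0 - h)) ** 2, axis=1)
            q2 = 1.0 - press / self.syy
            q2[~np.isfinite(q2)] = -np.inf
            out[s : s + chunk] = q2
        return out


def _solve_batched(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.empty_like(b)
        for i in range(A.shape[0]):
            try:
                out[i] = np.linalg.solve(A[i], b[i])
            except np.linalg.LinAlgError:
                out[i] = np.nan
        return out


# ---------------------------------------------------------------------------
# Subset search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for subset search (evolutionary model
    selection over descriptor index sets; fitness is training r²; model size
    is capped at ``max_vars`` so no parsimony penalty is needed)."""

    population: int = 100
    generations: int = 200
    tournament: int = 3
    mutation_rate: float = 0.1
    elitism: int = 5


def search_linear_models(
    table: DescriptorTable,
    activity: str,
    max_vars: int = 3,
    method: str = "exhaustive",
    top_k: int = 1,
    rng: np.random.Generator | None = None,
    ga: GAConfig | None = None,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> list[FitResult]:
    """Best-subset search over linear models of up to ``max_vars`` variables.

    ``method='exhaustive'`` enumerates every non-empty subset of size ≤
    ``max_vars`` (refusing above ``exhaustive_cap`` subsets); ``'genetic'``
    runs a GA over fixed-size subsets (r² is monotone in added variables, so
    the optimum always uses the full budget).  Results are the ``top_k``
    refitted models sorted by descending training r².
    """
    if top_k < 1:
        raise ContractError("top_k must be >= 1")
    if max_vars < 1:
        raise ContractError("max_vars must be >= 1")
    p = table.n_descriptors
    if p < max_vars:
        raise ContractError(f"pool size {p} smaller than max_vars={max_vars}")
    y = table.activity_column(activity)
    scorer = SubsetScorer(table.values, y)

    if method == "exhaustive":
        if n_subsets_upto(p, max_vars) > exhaustive_cap:
            raise ConfigError(
                f"{n_subsets_upto(p, max_vars)} subsets exceed the exhaustive cap "
                f"({exhaustive_cap}); use method='genetic'"
            )
        best: list[tuple[float, tuple[int, ...]]] = []
        for subs in _subsets_upto(p, max_vars):
            scores = scorer.score_many(subs)
            take = np.argsort(scores)[::-1][: top_k]
            best.extend((float(scores[i]), tuple(subs[i])) for i in take)
        best.sort(key=lambda t: -t[0])
        chosen = best[:top_k]
    elif method == "genetic":
        chosen = _genetic_search(scorer, max_vars, top_k, rng, ga or GAConfig())
    else:
        raise ConfigError(f"unknown search method {method!r}")

    results = []
    for score, subset in chosen:
        names = tuple(table.descriptor_names[j] for j in subset)
        if scorer.degenerate or not np.isfinite(score):
            fitted = np.full(table.n_records, float(y.mean()))
            results.append(
                FitResult(
                    selected_descriptors=names,
                    intercept=float(y.mean()),
                    coefficients={nm: 0.0 for nm in names},
                    r2_train=0.0,
                    fitted_values=fitted,
                )
            )
        else:
            results.append(fit_ols(table.values[:, list(subset)], y, names))
    results.sort(key=lambda r: -r.r2_train)
    return results


def _genetic_search(
    scorer: SubsetScorer,
    max_vars: int,
    top_k: int,
    rng: np.random.Generator | None,
    cfg: GAConfig,
) -> list[tuple[float, tuple[int, ...]]]:
    if rng is None:
        rng = np.random.Generator(np.random.MT19937(0))
    p = scorer.p
    k = min(max_vars, p)
    pop = np.array(
        [rng.choice(p, size=k, replace=False) for _ in range(cfg.population)],
        dtype=np.intp,
    )
    archive: dict[tuple[int, ...], float] = {}

    def evaluate(P: np.ndarray) -> np.ndarray:
        scores = scorer.score_many(P)
        for row, s in zip(P, scores):
            key = tuple(sorted(int(j) for j in row))
            if key not in archive or s > archive[key]:
                archive[key] = float(s)
        return scores

    fitness = evaluate(pop)
    for _ in range(cfg.generations):
        order = np.argsort(fitness)[::-1]
        elite = pop[order[: cfg.elitism]]
        children = [row.copy() for row in elite]
        while len(children) < cfg.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population, size=cfg.tournament)
                parents.append(pop[contenders[np.argmax(fitness[contenders])]])
            child = _crossover(parents[0], parents[1], rng)
            if rng.random() < cfg.mutation_rate:
                child = _mutate(child, p, rng)
            children.append(child)
        pop = np.array(children, dtype=np.intp)
        fitness = evaluate(pop)

    ranked = sorted(archive.items(), key=lambda kv: -kv[1])
    return [(score, subset) for subset, score in ranked[:top_k]]


def _crossover(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    k = a.shape[0]
    child: list[int] = []
    for i in range(k):
        gene = int(a[i] if rng.integers(0, 2) == 0 else b[i])
        child.append(gene)
    # repair duplicates from the union of parents, then at random
    pool = [int(g) for g in np.concatenate([a, b]) if int(g) not in child]
    seen: set[int] = set()
    for i, g in enumerate(child):
        if g in seen:
            child[i] = pool.pop() if pool else -1
        seen.add(child[i])
    out = np.array(child, dtype=np.intp)
    return out


def _mutate(child: np.ndarray, p: int, rng: np.random.Generator) -> np.ndarray:
    out = child.copy()
    slot = int(rng.integers(0, out.shape[0]))
    used = set(int(g) for g in out)
    candidates = [j for j in range(p) if j not in used]
    if candidates:
        out[slot] = candidates[int(rng.integers(0, len(candidates)))]
    return out


# ---------------------------------------------------------------------------
# CART classification tree
# ---------------------------------------------------------------------------

def _gini(pos: float, n: float) -> float:
    if n == 0:
        return 0.0
    q = pos / n
    return 1.0 - q * q - (1.0 - q) ** 2


def _best_split(X: np.ndarray, y: np.ndarray) -> tuple[int, float, float] | None:
    """Exhaustive best (feature, threshold) by weighted Gini.

    Candidate thresholds are midpoints of consecutive sorted unique values.
    Ties break on lowest feature index, then lowest threshold.
    """
    n, p = X.shape
    best: tuple[float, int, float] | None = None
    for j in range(p):
        order = np.argsort(X[:, j], kind="mergesort")
        xs = X[order, j]
        ys = y[order]
        boundary = np.flatnonzero(xs[1:] > xs[:-1])
        if boundary.size == 0:
            continue
        cum_pos = np.cumsum(ys)
        total_pos = cum_pos[-1]
        nl = boundary + 1.0
        nr = n - nl
        pl = cum_pos[boundary]
        pr = total_pos - pl
        with np.errstate(invalid="ignore", divide="ignore"):
            gl = 1.0 - (pl / nl) ** 2 - ((nl - pl) / nl) ** 2
            gr = 1.0 - (pr / nr) ** 2 - ((nr - pr) / nr) ** 2
        weighted = (nl * gl + nr * gr) / n
        i = int(np.argmin(weighted))  # first minimum = lowest threshold
        cand = (float(weighted[i]), j, float((xs[boundary[i]] + xs[boundary[i] + 1]) / 2))
        if best is None or cand[0] < best[0] - 1e-15:
            best = cand
    if best is None:
        return None
    return best[1], best[2], best[0]


def _grow(X: np.ndarray, y: np.ndarray, depth: int, max_depth: int):
    n = y.shape[0]
    pos = int(y.sum())
    counts = (n - pos, pos)
    majority = 1 if pos > n - pos else 0  # tie -> lower label
    parent_gini = _gini(pos, n)
    if depth >= max_depth or parent_gini == 0.0:
        return _TreeLeaf(majority, n, counts)
    split = _best_split(X, y)
    if split is None:
        return _TreeLeaf(majority, n, counts)
    j, thr, weighted = split
    if weighted >= parent_gini - 1e-12:  # no impurity decrease
        return _TreeLeaf(majority, n, counts)
    mask = X[:, j] <= thr
    return _TreeNode(
        feature=j,
        threshold=thr,
        left=_grow(X[mask], y[mask], depth + 1, max_depth),
        right=_grow(X[~mask], y[~mask], depth + 1, max_depth),
    )


def fit_tree(
    X: np.ndarray,
    labels: Sequence[int],
    max_depth: int = 3,
    feature_names: Sequence[str] | None = None,
) -> TreeModel:
    """Greedy binary CART tree on Gini impurity, depth ≤ ``max_depth``.

    Deterministic: tie-breaking prefers the lowest feature index, then the
    lowest threshold; thresholds are midpoints of consecutive sorted unique
    values; the left branch takes ``value <= threshold``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1}:
        raise ContractError(f"labels must be binary 0/1, got {sorted(uniq)}")
    if max_depth > 0 and len(uniq) < 2:
        raise ContractError("both classes must be present to train a tree")
    y = y.astype(int)
    root = _grow(X, y, 0, max_depth)
    return TreeModel(
        root=root,
        max_depth=max_depth,
        feature_names=None if feature_names is None else tuple(feature_names),
    )


def _tree_predict_one(node, row: np.ndarray) -> int:
    while isinstance(node, _TreeNode):
        node = node.left if row[node.feature] <= node.threshold else node.right
    return node.label


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(
    model: FitResult | TreeModel,
    X: np.ndarray | DescriptorTable,
    descriptor_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Predict with a linear model (intercept + Σ coefficient·value) or a
    tree (root-to-leaf routing, left branch when value ≤ threshold).

    ``X`` may be a raw matrix (with ``descriptor_names`` giving its column
    names for linear models / named trees) or a :class:`DescriptorTable`.
    """
    if isinstance(X, DescriptorTable):
        table = X
        if isinstance(model, FitResult):
            M = table.descriptor_matrix(model.selected_descriptors)
            return model.intercept + M @ np.array(
                [model.coefficients[n] for n in model.selected_descriptors]
            )
        if model.feature_names is not None:
            M = table.descriptor_matrix(model.feature_names)
        else:
            M = table.values
        return np.array([_tree_predict_one(model.root, row) for row in M])

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if isinstance(model, FitResult):
        if descriptor_names is not None:
            names = list(descriptor_names)
            missing = [n for n in model.selected_descriptors if n not in names]
            if missing:
                raise ContractError(f"missing descriptor column(s): {missing}")
            idx = [names.index(n) for n in model.selected_descriptors]
            X = X[:, idx]
        elif X.shape[1] != len(model.selected_descriptors):
            raise ContractError(
                "X column count does not match the model's descriptors; "
                "pass descriptor_names to map columns"
            )
        coef = np.array([model.coefficients[n] for n in model.selected_descriptors])
        return model.intercept + X @ coef
    return np.array([_tree_predict_one(model.root, row) for row in X])
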