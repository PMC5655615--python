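"""The chance-correlation audit: fit models on every randomized set and
summarize the best scores as mean + k·SD thresholds.

For each of the plan's ``n_sets`` randomized tables the configured engine's
search is run exactly as it would be on the real data (same pool reduction,
same variable budget, per-set seeded RNG), the per-set best training r² (and
that model's q²) is recorded, and the collection is summarized as
``mh ± k·SD`` for k ∈ {1, 2.3, 3}.  Under normality mean + 2.3 SD sits near
the 99th percentile of the chance distribution, which is why it is the
customary "better than chance" bar; the empirical percentile of the real
model within the chance scores is always reported alongside.

Classification engines record the six confusion-derived metrics per set
instead of r²/q², summarized identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import METRIC_NAMES, classification_metrics, confusion
from .errors import ConfigError, ContractError
from .models import (
    GAConfig,
    SubsetScorer,
    fit_tree,
    predict,
    reduce_descriptor_pool,
    search_linear_models,
)
from .randomize import RandomizationPlan, make_stream, randomize_once, fit_distribution_params
from .regression import q_squared_cv, r_squared
from .table import DescriptorTable

__all__ = [
    "EngineConfig",
    "SummaryRow",
    "ChanceSummary",
    "Verdict",
    "summarize",
    "run_chance_test",
    "compare_to_chance",
]

THRESHOLD_KS = (1.0, 2.3, 3.0)


@dataclass(frozen=True)
class EngineConfig:
    """How models are trained on each randomized set.

    ``kind``:
      * ``"mlr-subset"`` — best-subset linear search of up to ``max_vars``
        variables (``method`` exhaustive or genetic);
      * ``"fixed-ols"`` — a single OLS fit on ``fixed_descriptors`` (no
        search; the textbook single-model null);
      * ``"tree"`` — a depth-limited CART classifier on all descriptors.

    ``corr_filter`` enables the |r| > threshold pool reduction per set;
    ``collect`` chooses whether the recorded q² is that of the best-r² model
    (default) or the set's maximum q² (exhaustive search only);
    ``compute_q2`` can be switched off when only r² is audited.
    """

    kind: str = "mlr-subset"
    max_vars: int = 3
    method: str = "exhaustive"
    corr_filter: float | None = None
    fixed_descriptors: tuple[str, ...] = ()
    max_depth: int = 3
    collect: str = "q2-of-best"
    compute_q2: bool = True
    top_k: int = 1
    ga: GAConfig = field(default_factory=GAConfig)

    def __post_init__(self) -> None:
        if self.kind not in ("mlr-subset", "fixed-ols", "tree"):
            raise ConfigError(f"unknown engine kind {self.kind!r}")
        if self.collect not in ("q2-of-best", "max-q2"):
            raise ConfigError(f"unknown collect policy {self.collect!r}")
        if self.collect == "max-q2" and self.kind == "mlr-subset" and self.method != "exhaustive":
            raise ConfigError(
                "collect='max-q2' requires the exhaustive search method"
            )


@dataclass(frozen=True)
class SummaryRow:
    """Mean, sample SD and mean + k·SD thresholds of one score collection."""

    mean: float
    sd: float
    thresholds: dict[float, float]


def summarize(best_scores: Sequence[float], ks: Sequence[float] = THRESHOLD_KS) -> SummaryRow:
    """Mean, sample SD (n−1 denominator) and ``mean + k·SD`` thresholds."""
    x = np.asarray(best_scores, dtype=float)
    if x.size < 2:
        raise ContractError("need at least 2 scores to summarize")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return SummaryRow(mean=mean, sd=sd, thresholds={float(k): mean + k * sd for k in ks})


@dataclass
class ChanceSummary:
    """Per-set best scores of a chance run plus their threshold table."""

    mode: str
    family: str
    n_sets: int
    scores: dict[str, np.ndarray]

    def row(self, stat: str) -> SummaryRow:
        return summarize(self.scores[stat])

    @property
    def best_r2(self) -> np.ndarray:
        return self.scores["r2"]

    @property
    def best_q2(self) -> np.ndarray:
        return self.scores["q2"]

    @property
    def mhr2(self) -> float:
        return self.row("r2").mean

    @property
    def sd_r2(self) -> float:
        return self.row("r2").sd

    @property
    def mhq2(self) -> float:
        return self.row("q2").mean

    @property
    def sd_q2(self) -> float:
        return self.row("q2").sd

    def threshold(self, stat: str, k: float = 2.3) -> float:
        r = self.row(stat)
        return r.mean + k * r.sd

    def table(self):
        """Threshold table, one row per statistic (the report layout:
        mean, SD, +1 SD, +2.3 SD, +3 SD)."""
        import pandas as pd

        rows = {}
        for stat in self.scores:
            r = self.row(stat)
            rows[stat] = {
                "mean": r.mean,
                "SD": r.sd,
                "+1 SD": r.thresholds[1.0],
                "+2.3 SD": r.thresholds[2.3],
                "+3 SD": r.thresholds[3.0],
            }
        return pd.DataFrame(rows).T


@dataclass(frozen=True)
class Verdict:
    """Comparison of a real-data statistic against a chance threshold."""

    stat: str
    real_value: float
    k: float
    threshold: float
    better_than_chance: bool  # strict inequality
    margin: float
    empirical_percentile: float


def compare_to_chance(
    real_stat: float,
    summary: ChanceSummary,
    k: float = 2.3,
    stat: str = "r2",
) -> Verdict:
    """Is ``real_stat`` strictly above the chance ``mean + k·SD`` bar?

    Also reports the empirical percentile of the real value within the
    per-set best scores (the distribution-free counterpart of the
    normal-theory threshold)."""
    thr = summary.threshold(stat, k)
    scores = summary.scores[stat]
    pct = 100.0 * float(np.mean(scores < real_stat))
    return Verdict(
        stat=stat,
        real_value=float(real_stat),
        k=float(k),
        threshold=thr,
        better_than_chance=bool(real_stat > thr),
        margin=float(real_stat - thr),
        empirical_percentile=pct,
    )


def _regression_set_scores(
    table: DescriptorTable,
    activity: str,
    engine: EngineConfig,
    rng: np.random.Generator,
) -> tuple[float, float]:
    if engine.corr_filter is not None:
        table = reduce_descriptor_pool(table, engine.corr_filter, rng)
    y = table.activity_column(activity)
    if np.ptp(y) == 0.0:
        warnings.warn("degenerate scramble (constant y): scored as 0", RuntimeWarning)
        return 0.0, 0.0

    if engine.kind == "fixed-ols":
        X = table.descriptor_matrix(engine.fixed_descriptors)
        from .models import fit_ols

        fit = fit_ols(X, y, engine.fixed_descriptors)
        q2 = q_squared_cv(X, y, m=1) if engine.compute_q2 else float("nan")
        return fit.r2_train, q2

    if engine.collect == "max-q2":
        from .models import _subsets_upto

        scorer = SubsetScorer(table.values, y)
        best_r2 = -np.inf
        best_q2 = -np.inf
        for subs in _subsets_upto(table.n_descriptors, engine.max_vars):
            best_r2 = max(best_r2, float(scorer.score_many(subs).max()))
            best_q2 = max(best_q2, float(scorer.loo_q2_many(subs).max()))
        return best_r2, best_q2

    results = search_linear_models(
        table,
        activity,
        max_vars=engine.max_vars,
        method=engine.method,
        top_k=1,
        rng=rng,
        ga=engine.ga,
    )
    best = results[0]
    q2 = float("nan")
    if engine.compute_q2:
        X = table.descriptor_matrix(best.selected_descriptors)
        q2 = q_squared_cv(X, y, m=1)
    return best.r2_train, q2


def run_chance_test(
    table: DescriptorTable,
    plan: RandomizationPlan,
    engine: EngineConfig,
    activity: str | None = None,
) -> ChanceSummary:
    """Run the full audit: randomize, refit, collect per-set best scores.

    ``activity`` names the response column trained against (defaults to the
    scrambled activity for y-scrambling, or the table's single activity).
    Set ``i`` draws its permutation/pseudo-descriptor values *and* any
    engine randomness (GA, random intercorrelation exclusions) from one
    MT19937 stream seeded ``master_seed + i``, so the whole run is a pure
    function of (table, plan, engine).  The input table is never mutated.
    """
    plan.validate_against(table)
    if activity is None:
        if plan.mode == "y_scramble" and len(plan.target_fields) == 1:
            activity = plan.target_fields[0]
        elif len(table.activity_names) == 1:
            activity = table.activity_names[0]
        else:
            raise ConfigError("ambiguous response: pass activity explicitly")
    table.activity_index(activity)  # validate

    specs = None
    if plan.mode == "pseudo" and plan.family != "original":
        specs = {
            name: fit_distribution_params(table.descriptor_column(name), plan.family)
            for name in plan.target_fields
        }

    if engine.kind == "tree":
        per_metric: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
        for i in range(plan.n_sets):
            rng = make_stream(plan.master_seed + i)
            t_i = randomize_once(table, plan, rng, specs)
            work = (
                reduce_descriptor_pool(t_i, engine.corr_filter, rng)
                if engine.corr_filter is not None
                else t_i
            )
            labels = work.activity_column(activity).astype(int)
            tree = fit_tree(
                work.values,
                labels,
                max_depth=engine.max_depth,
                feature_names=tuple(work.descriptor_names),
            )
            pred = predict(tree, work.values)
            m = classification_metrics(confusion(labels, pred))
            for name, value in zip(METRIC_NAMES, m.as_array()):
                per_metric[name].append(float(value))
        scores = {k: np.asarray(v) for k, v in per_metric.items()}
        return ChanceSummary(plan.mode, plan.family, plan.n_sets, scores)

    best_r2 = np.empty(plan.n_sets)
    best_q2 = np.empty(plan.n_sets)
    for i in range(plan.n_sets):
        rng = make_stream(plan.master_seed + i)
        t_i = randomize_once(table, plan, rng, specs)
        r2_i, q2_i = _regression_set_scores(t_i, activity, engine, rng)
        best_r2[i] = r2_i
        best_q2[i] = q2_i
    scores = {"r2": best_r2}
    if engine.compute_q2:
        scores["q2"] = best_q2
    return ChanceSummary(plan.mode, plan.family, plan.n_sets, scores)
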