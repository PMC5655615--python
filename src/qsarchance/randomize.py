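"""Randomized-data generation: y-scrambling, x-scrambling, pseudo-descriptors.

Three null models are supported:

* **y-scrambling** — each target activity column is replaced by a uniformly
  random permutation of itself; descriptors are left intact.
* **x-scrambling** — each target descriptor column is independently permuted,
  preserving its marginal distribution; activities are left intact.
* **pseudo-descriptors** — each target descriptor column is replaced by i.i.d.
  draws from a chosen family (uniform, normal, binomial, Poisson or
  exponential) with parameters fitted to the original column; choosing the
  ``original`` family keeps the empirical distribution, which is exactly
  x-scrambling.

All randomness flows through MT19937 (Mersenne Twister) streams.  Replicate
``i`` of a plan uses a stream seeded with ``master_seed + i``, so a run is a
pure function of (table, plan) and replicates are mutually independent.
Permutations use an explicit Fisher–Yates shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, ContractError, DomainError
from .table import DescriptorTable

__all__ = [
    "MODES",
    "FAMILIES",
    "DistributionSpec",
    "RandomizationPlan",
    "make_stream",
    "scramble_column",
    "fit_distribution_params",
    "sample_pseudo",
    "generate_sets",
]

MODES = ("y_scramble", "x_scramble", "pseudo")
FAMILIES = ("uniform", "normal", "binomial", "poisson", "exponential", "original")


def make_stream(seed: int) -> np.random.Generator:
    """An MT19937-backed generator stream for the given seed."""
    if seed < 0:
        raise ContractError("seed must be non-negative")
    return np.random.Generator(np.random.MT19937(int(seed)))


@dataclass(frozen=True)
class DistributionSpec:
    """A parameterized sampling family for pseudo-descriptors.

    Parameter conventions: uniform ``(lower, upper)``; normal ``(mean, sd)``;
    binomial ``(trials, success_prob)``; poisson ``(rate,)`` — the mean count;
    exponential ``(rate,)`` — the inverse mean.
    """

    family: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES or self.family == "original":
            raise ContractError(f"unknown sampling family {self.family!r}")
        p = self.parameters
        try:
            if self.family == "uniform" and not p["lower"] <= p["upper"]:
                raise DomainError("uniform requires lower <= upper")
            if self.family == "normal" and p["sd"] < 0:
                raise DomainError("normal requires sd >= 0")
            if self.family == "binomial":
                if p["trials"] < 1:
                    raise DomainError("binomial requires trials >= 1")
                if not 0.0 <= p["success_prob"] <= 1.0:
                    raise DomainError("binomial requires 0 <= success_prob <= 1")
            if self.family in ("poisson", "exponential") and p["rate"] <= 0:
                raise DomainError(f"{self.family} requires rate > 0")
        except KeyError as exc:
            raise ContractError(
                f"{self.family} spec missing parameter {exc.args[0]!r}"
            ) from None


@dataclass(frozen=True)
class RandomizationPlan:
    """What to randomize, how, how many replicate sets, from which seed.

    ``mode`` selects the null model; ``target_fields`` are activity columns
    for y-scrambling and descriptor columns otherwise; ``family`` applies to
    pseudo mode only (``original`` degenerates to per-column permutation,
    i.e. x-scrambling).
    """

    mode: str
    target_fields: tuple[str, ...]
    n_sets: int = 300
    master_seed: int = 0
    family: str = "original"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}")
        if self.n_sets < 1:
            raise ConfigError("n_sets must be >= 1")
        if self.master_seed < 0:
            raise ConfigError("master_seed must be non-negative")
        object.__setattr__(self, "target_fields", tuple(self.target_fields))
        if not self.target_fields:
            raise ConfigError("target_fields must be non-empty")

    def validate_against(self, table: DescriptorTable) -> None:
        if self.mode == "y_scramble":
            known = set(table.activity_names)
            role = "activity"
        else:
            known = set(table.descriptor_names)
            role = "descriptor"
        missing = [f for f in self.target_fields if f not in known]
        if missing:
            raise ConfigError(f"plan targets unknown {role} column(s): {missing}")


def scramble_column(column: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """Uniformly random permutation of ``column`` by Fisher–Yates shuffle.

    The multiset of values is conserved exactly; identity permutations are
    allowed (rejecting them would bias the null distribution).
    """
    out = np.array(column, dtype=float)
    n = out.shape[0]
    if n < 1:
        raise ContractError("cannot scramble an empty column")
    for i in range(n - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        out[i], out[j] = out[j], out[i]
    return out


def fit_distribution_params(column: Sequence[float], family: str) -> DistributionSpec:
    """Method-of-moments parameters for ``family`` fitted to ``column``.

    uniform → (min, max); normal → (mean, sample SD with n−1 denominator);
    poisson → rate = mean; exponential → rate = 1/mean; binomial →
    trials = round(max) clamped to ≥1, success_prob = mean/trials clamped
    to [0, 1].
    """
    x = np.asarray(column, dtype=float)
    if x.size == 0:
        raise ContractError("cannot fit a distribution to an empty column")
    if family in ("poisson", "exponential", "binomial") and np.any(x < 0):
        raise DomainError(f"{family} requires all values >= 0")
    if family == "uniform":
        params = {"lower": float(x.min()), "upper": float(x.max())}
    elif family == "normal":
        sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
        params = {"mean": float(x.mean()), "sd": sd}
    elif family == "poisson":
        rate = float(x.mean())
        if rate <= 0:
            raise DomainError("poisson fit requires a positive mean")
        params = {"rate": rate}
    elif family == "exponential":
        mean = float(x.mean())
        if mean <= 0:
            raise DomainError("exponential fit requires a positive mean")
        params = {"rate": 1.0 / mean}
    elif family == "binomial":
        trials = max(1, int(round(float(x.max()))))
        p = float(np.clip(x.mean() / trials, 0.0, 1.0))
        params = {"trials": trials, "success_prob": p}
    else:
        raise ContractError(f"cannot fit parameters for family {family!r}")
    return DistributionSpec(family=family, parameters=params)


def sample_pseudo(
    spec: DistributionSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` independent draws from ``spec`` on an MT19937 stream."""
    if n < 1:
        raise ContractError("n must be >= 1")
    p = spec.parameters
    if spec.family == "uniform":
        return rng.uniform(p["lower"], p["upper"], size=n)
    if spec.family == "normal":
        return rng.normal(p["mean"], p["sd"], size=n)
    if spec.family == "binomial":
        return rng.binomial(p["trials"], p["success_prob"], size=n).astype(float)
    if spec.family == "poisson":
        return rng.poisson(p["rate"], size=n).astype(float)
    if spec.family == "exponential":
        return rng.exponential(1.0 / p["rate"], size=n)
    raise ContractError(f"cannot sample family {spec.family!r}")


def randomize_once(
    table: DescriptorTable,
    plan: RandomizationPlan,
    rng: np.random.Generator,
    specs: dict[str, DistributionSpec] | None = None,
) -> DescriptorTable:
    """Produce one randomized copy of ``table`` using draws from ``rng``.

    ``specs`` caches fitted pseudo-descriptor parameters (always fitted to
    the *original* columns, never chained through previous replicates).
    """
    out = table.copy()
    if plan.mode == "y_scramble":
        for name in plan.target_fields:
            j = out.activity_index(name)
            out.activities[:, j] = scramble_column(table.activities[:, j], rng)
        return out
    use_perm = plan.mode == "x_scramble" or plan.family == "original"
    for name in plan.target_fields:
        j = out.descriptor_index(name)
        if use_perm:
            out.values[:, j] = scramble_column(table.values[:, j], rng)
        else:
            spec = specs[name] if specs is not None else fit_distribution_params(
                table.values[:, j], plan.family
            )
            out.values[:, j] = sample_pseudo(spec, table.n_records, rng)
    return out


def generate_sets(
    table: DescriptorTable, plan: RandomizationPlan
) -> list[DescriptorTable]:
    """Produce ``plan.n_sets`` randomized copies of ``table``.

    Replicate ``i`` (0-based) draws from an MT19937 stream seeded with
    ``master_seed + i``; repeat calls are bit-identical.
    """
    plan.validate_against(table)
    specs: dict[str, DistributionSpec] | None = None
    if plan.mode == "pseudo" and plan.family != "original":
        specs = {
            name: fit_distribution_params(table.descriptor_column(name), plan.family)
            for name in plan.target_fields
        }
    return [
        randomize_once(table, plan, make_stream(plan.master_seed + i), specs)
        for i in range(plan.n_sets)
    ]
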