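"""Synthetic descriptor tables and toy SD files with controllable signal.

These generators emulate the *shapes* of realistic QSAR data — e.g. a
21-compound training set searched against an 89-descriptor pool, or a
100-active : 3600-decoy (1:36) screening deck — with a planted linear or
class-separation signal whose strength is known exactly.  Every fixture
carries its generating truth (signal subset, coefficients, population R²,
class shift) in ``table.metadata`` so parameter-recovery tests are
self-describing.  Generation is deterministic per seed.

They make no attempt to imitate real molecular-descriptor marginals:
descriptors are standard normal (optionally in equicorrelated blocks), so
conclusions about real, heavy-tailed or discrete descriptor sets require the
pseudo-descriptor families of :mod:`qsarchance.randomize`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, ContractError
from .io import format_value, parse_sdf_text
from .randomize import make_stream
from .table import DescriptorTable

__all__ = [
    "FixtureSpec",
    "make_regression_fixture",
    "make_classification_fixture",
    "make_toy_sdf",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic descriptor table.

    ``beta`` gives the linear coefficients (regression) or the active-class
    mean shifts (classification) on ``signal_descriptors``; ``noise_sd`` is
    the residual SD of the response; ``correlation_blocks = (size, rho)``
    arranges descriptors in equicorrelated blocks to exercise the
    intercorrelation filter; ``class_ratio = (n_active, n_decoy)`` switches
    to a classification deck.
    """

    n: int = 21
    p: int = 89
    signal_descriptors: tuple[int, ...] = ()
    beta: tuple[float, ...] = ()
    noise_sd: float = 1.0
    correlation_blocks: tuple[int, float] | None = None
    class_ratio: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.p < 1:
            raise ConfigError("n and p must be positive")
        if len(self.signal_descriptors) != len(self.beta):
            raise ConfigError("signal_descriptors and beta must have equal length")
        if any(j >= self.p or j < 0 for j in self.signal_descriptors):
            raise ConfigError("signal descriptor index out of range")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.correlation_blocks is not None:
            size, rho = self.correlation_blocks
            if size < 1:
                raise ConfigError("block size must be >= 1")
            if not -1.0 / max(size - 1, 1) < rho < 1.0:
                raise ConfigError(
                    f"block correlation {rho} gives a non-positive-definite block"
                )


def _covariance(spec: FixtureSpec) -> np.ndarray:
    sigma = np.eye(spec.p)
    if spec.correlation_blocks is not None:
        size, rho = spec.correlation_blocks
        for start in range(0, spec.p, size):
            stop = min(start + size, spec.p)
            sigma[start:stop, start:stop] = rho
            np.fill_diagonal(sigma[start:stop, start:stop], 1.0)
    return sigma


def _draw_descriptors(spec: FixtureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    sigma = _covariance(spec)
    if spec.correlation_blocks is None:
        return rng.standard_normal((n, spec.p))
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise ConfigError("correlation blocks give a non-positive-definite matrix")
    return rng.standard_normal((n, spec.p)) @ L.T


def population_r2(spec: FixtureSpec) -> float:
    """The R² implied by (beta, noise_sd) under the fixture's covariance."""
    if not spec.beta:
        return 0.0
    sigma = _covariance(spec)
    idx = list(spec.signal_descriptors)
    b = np.asarray(spec.beta, dtype=float)
    var_signal = float(b @ sigma[np.ix_(idx, idx)] @ b)
    total = var_signal + spec.noise_sd**2
    return var_signal / total if total > 0 else 0.0


def make_regression_fixture(spec: FixtureSpec) -> DescriptorTable:
    """Standard-normal descriptors (optionally correlated in blocks) with
    ``y = Σ beta·x_signal + N(0, noise_sd²)``."""
    rng = make_stream(spec.seed)
    X = _draw_descriptors(spec, spec.n, rng)
    y = np.zeros(spec.n)
    for j, b in zip(spec.signal_descriptors, spec.beta):
        y += b * X[:, j]
    if spec.noise_sd > 0:
        y += rng.normal(0.0, spec.noise_sd, size=spec.n)
    names = [f"d{j + 1}" for j in range(spec.p)]
    return DescriptorTable(
        record_ids=[f"cpd{i + 1}" for i in range(spec.n)],
        descriptor_names=names,
        values=X,
        activity_names=["activity"],
        activities=y[:, None],
        metadata={
            "signal_descriptors": tuple(names[j] for j in spec.signal_descriptors),
            "beta": tuple(spec.beta),
            "noise_sd": spec.noise_sd,
            "population_r2": population_r2(spec),
            "seed": spec.seed,
        },
    )


def make_classification_fixture(spec: FixtureSpec) -> DescriptorTable:
    """An actives/decoys deck: decoys ~ N(0, I); actives shifted by ``beta``
    on the signal descriptors.  Labels (1 = active) land in a binary
    ``active`` column."""
    if spec.class_ratio is None:
        raise ConfigError("class_ratio must be set for a classification fixture")
    n_active, n_decoy = spec.class_ratio
    if n_active < 1 or n_decoy < 1:
        raise ConfigError("both classes need at least one member")
    rng = make_stream(spec.seed)
    n = n_active + n_decoy
    X = _draw_descriptors(spec, n, rng)
    for j, shift in zip(spec.signal_descriptors, spec.beta):
        X[:n_active, j] += shift
    labels = np.concatenate([np.ones(n_active), np.zeros(n_decoy)])
    order = rng.permutation(n)
    names = [f"d{j + 1}" for j in range(spec.p)]
    return DescriptorTable(
        record_ids=[f"cpd{i + 1}" for i in range(n)],
        descriptor_names=names,
        values=X[order],
        activity_names=["active"],
        activities=labels[order][:, None],
        metadata={
            "signal_descriptors": tuple(names[j] for j in spec.signal_descriptors),
            "class_shift": tuple(spec.beta),
            "n_active": n_active,
            "n_decoy": n_decoy,
            "prevalence": n_active / n,
            "seed": spec.seed,
        },
    )


_MOLBLOCK = (
    "{title}\n"
    "  qsarchance\n"
    "\n"
    "  1  0  0  0  0  0  0  0  0  0999 V2000\n"
    "    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
    "M  END\n"
)


def make_toy_sdf(n: int, fields: Sequence[str], seed: int = 0) -> str:
    """Syntactically valid V2000 SD-file text with ``n`` single-carbon
    records carrying uniform(0, 1) numeric data items named ``fields``."""
    if n < 1:
        raise ContractError("n must be >= 1")
    rng = make_stream(seed)
    chunks = []
    for i in range(1, n + 1):
        chunks.append(_MOLBLOCK.format(title=f"mol{i}"))
        for name in fields:
            chunks.append(f">  <{name}>\n{format_value(rng.uniform(0.0, 1.0))}\n\n")
        chunks.append("$$$$\n")
    text = "".join(chunks)
    parse_sdf_text(text)  # generated output must be parseable
    return text
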