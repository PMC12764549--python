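"""Permutation feature importance, its correlation-adjusted variant, VIP.

Plain permutation importance underestimates the contribution of a
variable whose information is duplicated in a correlated partner: the
partner compensates for the shuffle and the score barely drops. The
adjusted variant therefore co-shuffles, per sample, every other variable
q with probability r'_{p,q}, where r' is the lower Fisher-z confidence
bound of |r| (zero when the interval spans zero, so incidental
correlations do not trigger co-shuffling). Co-shuffled values follow the
same permutation as the primary variable, so r' = 1 degenerates to
jointly permuting the pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.compose import TransformedTargetRegressor
from sklearn.metrics import r2_score
from sklearn.pipeline import Pipeline


class ImportanceError(ValueError):
    """Raised on ill-posed importance computations."""


@dataclass(frozen=True)
class CorrelationShrinkage:
    """|r| matrix shrunk to the lower bound of its Fisher-z CI."""

    r_matrix: np.ndarray
    z_matrix: np.ndarray
    ci_alpha: float
    sample_size: int
    r_prime: np.ndarray  # zero diagonal; zero where the CI spans 0

    @property
    def d(self) -> int:
        return self.r_prime.shape[0]


@dataclass(frozen=True)
class ImportanceTable:
    """Per-component permutation importances (baseline minus shuffled score)."""

    component_ids: tuple[str, ...]
    baseline_score: float
    mean_shuffled_score: np.ndarray
    importance: np.ndarray
    n_repeats: int
    method: str  # "plain" | "adjusted"

    @property
    def ranks(self) -> np.ndarray:
        """Rank per component, 1 = most important; ties broken by index."""
        order = np.argsort(-self.importance, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, len(order) + 1)
        return ranks

    def top_components(self, count: int) -> tuple[str, ...]:
        order = np.argsort(-self.importance, kind="stable")[:count]
        return tuple(self.component_ids[i] for i in order)


def _score(model, x, y) -> float:
    return float(r2_score(y, np.ravel(model.predict(x))))


def _resolve_ids(component_ids, d) -> tuple[str, ...]:
    if component_ids is None:
        return tuple(f"c{j}" for j in range(d))
    component_ids = tuple(str(c) for c in component_ids)
    if len(component_ids) != d:
        raise ImportanceError("component_ids length does not match X width")
    return component_ids


def pfi(
    model,
    x,
    y,
    j_repeats: int = 10,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    component_ids: Sequence[str] | None = None,
) -> ImportanceTable:
    """Plain permutation feature importance on a held-out set.

    importance_i = baseline R² - mean over J repeats of the R² obtained
    after independently permuting column i.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = x.shape
    if n < 2:
        raise ImportanceError("permutation importance needs at least 2 samples")
    if j_repeats < 1:
        raise ImportanceError("j_repeats must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    bs = _score(model, x, y)
    mean_shuffled = np.empty(d)
    for i in range(d):
        scores = np.empty(j_repeats)
        for j in range(j_repeats):
            perm = rng.permutation(n)
            xs = x.copy()
            xs[:, i] = x[perm, i]
            scores[j] = _score(model, xs, y)
        mean_shuffled[i] = scores.mean()
    return ImportanceTable(
        component_ids=_resolve_ids(component_ids, d),
        baseline_score=bs,
        mean_shuffled_score=mean_shuffled,
        importance=bs - mean_shuffled,
        n_repeats=j_repeats,
        method="plain",
    )


def shrunk_correlations(
    x, ci_alpha: float = 0.05, effective_sample_size: int | None = None
) -> CorrelationShrinkage:
    """Shrink |r| to the lower bound of its Fisher-z confidence interval.

    z = arctanh(|r|) is treated as normal with variance 1/(m - 3); the
    interval is back-transformed and r' = 0 whenever it spans zero
    (incidental correlation), otherwise r' = the lower bound.

    ``m`` defaults to the number of rows of ``x``. In a blending design
    the rows are not independent draws of the components — every
    condition is a mixture of the same small set of mother media, and
    replicates repeat the composition exactly — so the caller can pass
    the number of mother media as ``effective_sample_size``. The wide
    interval then zeroes moderate correlations and retains co-shuffling
    only for strongly correlated groups.
    """
    x = np.asarray(x, dtype=float)
    m = effective_sample_size if effective_sample_size is not None else x.shape[0]
    if m > x.shape[0]:
        raise ImportanceError("effective_sample_size cannot exceed the row count")
    if m <= 3:
        raise ImportanceError("need more than 3 rows for the Fisher-z variance 1/(m-3)")
    r = np.abs(np.corrcoef(x, rowvar=False))
    r = np.clip(r, 0.0, 1.0 - 1e-12)
    z = np.arctanh(r)
    half = stats.norm.ppf(1.0 - ci_alpha / 2.0) / math.sqrt(m - 3)
    lower = np.tanh(z - half)
    upper = np.tanh(z + half)
    r_prime = np.where((lower < 0.0) & (upper > 0.0), 0.0, lower)
    r_prime = np.clip(r_prime, 0.0, 1.0 - 1e-12)
    np.fill_diagonal(r_prime, 0.0)
    return CorrelationShrinkage(
        r_matrix=r, z_matrix=z, ci_alpha=ci_alpha, sample_size=m, r_prime=r_prime
    )


def adjusted_pfi(
    model,
    x,
    y,
    shrink: CorrelationShrinkage,
    j_repeats: int = 10,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    component_ids: Sequence[str] | None = None,
) -> ImportanceTable:
    """Correlation-adjusted permutation importance.

    When shuffling variable p, each sample of every other variable q is
    co-shuffled (following the same permutation) with probability
    r'_{p,q}, drawn fresh per sample per repeat.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = x.shape
    if n < 2:
        raise ImportanceError("permutation importance needs at least 2 samples")
    if shrink.r_prime.shape != (d, d):
        raise ImportanceError(
            f"shrinkage matrix is {shrink.r_prime.shape}, expected ({d}, {d})"
        )
    if j_repeats < 1:
        raise ImportanceError("j_repeats must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    bs = _score(model, x, y)
    mean_shuffled = np.empty(d)
    for p in range(d):
        probs = shrink.r_prime[p].copy()
        probs[p] = 1.0  # the primary variable is always shuffled
        scores = np.empty(j_repeats)
        for j in range(j_repeats):
            perm = rng.permutation(n)
            u = rng.random((n, d))
            mask = u < probs[None, :]
            mask[:, p] = True  # guard against u == 1 boundary
            xs = np.where(mask, x[perm, :], x)
            scores[j] = _score(model, xs, y)
        mean_shuffled[p] = scores.mean()
    return ImportanceTable(
        component_ids=_resolve_ids(component_ids, d),
        baseline_score=bs,
        mean_shuffled_score=mean_shuffled,
        importance=bs - mean_shuffled,
        n_repeats=j_repeats,
        method="adjusted",
    )


@dataclass(frozen=True)
class ConsensusResult:
    members: tuple[str, ...]
    per_model_top: dict[str, tuple[str, ...]]
    tier_membership: dict[float, tuple[str, ...]]
    top_fraction: float


def consensus_components(
    tables: Mapping[str, ImportanceTable],
    top_fraction: float = 0.25,
    tiers: Sequence[float] = (0.05, 0.10, 0.15, 0.20, 0.25),
) -> ConsensusResult:
    """Components in the top fraction of every model's importance ranking.

    Also reports tiered membership (components common to all models within
    each smaller top fraction).
    """
    if not tables:
        raise ImportanceError("need at least one importance table")
    if not 0.0 < top_fraction <= 1.0:
        raise ImportanceError("top_fraction must lie in (0, 1]")
    d = len(next(iter(tables.values())).component_ids)
    per_model_top = {
        name: tab.top_components(math.ceil(top_fraction * d))
        for name, tab in tables.items()
    }
    members = set.intersection(*(set(t) for t in per_model_top.values()))
    order = next(iter(tables.values())).component_ids
    tier_membership = {}
    for tier in tiers:
        count = math.ceil(tier * d)
        common = set.intersection(
            *(set(tab.top_components(count)) for tab in tables.values())
        )
        tier_membership[float(tier)] = tuple(c for c in order if c in common)
    return ConsensusResult(
        members=tuple(c for c in order if c in members),
        per_model_top=per_model_top,
        tier_membership=tier_membership,
        top_fraction=top_fraction,
    )


def vip_scores(pls_model, component_ids: Sequence[str] | None = None) -> np.ndarray:
    """Variable importance in projection of a fitted PLS regression.

    VIP_j = sqrt(d * sum_a w̃²_{ja} s_a / sum_a s_a) with w̃ the normalized
    x-weights and s_a the y-variance explained by component a; squared
    VIPs average to exactly 1.
    """
    if isinstance(pls_model, TransformedTargetRegressor):
        pls_model = pls_model.regressor_
    if isinstance(pls_model, Pipeline):
        pls_model = pls_model[-1]
    if not isinstance(pls_model, PLSRegression):
        raise ImportanceError("VIP scores are defined only for PLS regression models")
    w = pls_model.x_weights_  # (d, a)
    t = pls_model.x_scores_  # (n, a)
    q = pls_model.y_loadings_  # (targets, a)
    d = w.shape[0]
    ssy = np.sum(t**2, axis=0) * np.sum(q**2, axis=0)
    w_norm2 = (w / np.linalg.norm(w, axis=0, keepdims=True)) ** 2
    vip = np.sqrt(d * (w_norm2 @ ssy) / ssy.sum())
    return vip
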