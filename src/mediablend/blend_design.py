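"""Blend enumeration, PCA projection, and D-optimal condition selection.

Blending ``m`` mother media in integer dispense units creates a finite
candidate set of media compositions. With fewer mother media than
components (m < d) the component-space Gram matrix of any selected design
is rank deficient and its determinant is identically zero, so the
D-optimality criterion det(E'ᵀE') is evaluated in the PCA score space of
the standardized composition matrix, where it is well defined and where
maximizing it is equivalent to maximizing diversity in the non-redundant
part of the component space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement
from math import comb

import numpy as np

from .composition import CorrelationSummary, StandardizedMatrix, correlation_summary


class BlendDesignError(ValueError):
    """Raised on infeasible or ill-posed design requests."""


@dataclass(frozen=True)
class BlendEnumeration:
    """All weak compositions of ``total_units`` dispense units over m media."""

    units: np.ndarray  # (k, m) nonnegative integers, rows sum to total_units
    total_units: int
    unit_volume: float = 200.0

    @property
    def k(self) -> int:
        return self.units.shape[0]

    @property
    def m(self) -> int:
        return self.units.shape[1]

    def volumes(self) -> np.ndarray:
        """Dispense plan in volume units (units x unit_volume, e.g. µL)."""
        return self.units * self.unit_volume


@dataclass(frozen=True)
class PCAProjection:
    """Loadings V_p, scores B = A'V_p and explained variance of the PCA."""

    loadings: np.ndarray  # (d, p), orthonormal columns
    scores: np.ndarray  # (m, p)
    explained_variance_ratio: np.ndarray  # (p,)
    cumulative_evr: float
    p: int


@dataclass(frozen=True)
class DesignDiagnostics:
    correlation: CorrelationSummary
    vif: np.ndarray
    max_vif: float


@dataclass(frozen=True)
class DesignSelection:
    """Result of the random D-optimal search over blend combinations."""

    indices: np.ndarray  # (n,) sorted row indices into the enumeration
    scores: np.ndarray  # E' = E[indices]
    gram_det: float
    search_trace: np.ndarray  # determinant of every iteration
    dispense: np.ndarray | None = None  # D' (n, m) integer units
    diagnostics: DesignDiagnostics | None = None
    worst_indices: np.ndarray | None = None
    worst_det: float | None = None

    @property
    def n(self) -> int:
        return self.indices.shape[0]


def enumerate_blends(
    m: int,
    total_units: int,
    unit_volume: float = 200.0,
    max_combinations: int = 10_000_000,
) -> BlendEnumeration:
    """Enumerate every way to split ``total_units`` units across m media.

    The row count is the stars-and-bars number C(m + total_units - 1,
    total_units); rows are emitted in the deterministic order induced by
    ``itertools.combinations_with_replacement`` over medium indices.
    """
    if m < 1 or total_units < 1:
        raise BlendDesignError("m and total_units must both be >= 1")
    k = comb(m + total_units - 1, total_units)
    if k > max_combinations:
        raise BlendDesignError(
            f"enumeration would produce {k} rows (> {max_combinations}); "
            "use coarser dispense units"
        )
    units = np.zeros((k, m), dtype=np.int64)
    for row, chosen in zip(units, combinations_with_replacement(range(m), total_units)):
        row[:] = np.bincount(chosen, minlength=m)
    return BlendEnumeration(units=units, total_units=total_units, unit_volume=unit_volume)


def pca_project(a_std: StandardizedMatrix, var_threshold: float = 0.99) -> PCAProjection:
    """Project the standardized composition matrix onto its leading PCs.

    ``p`` is the smallest dimension whose cumulative explained variance
    reaches ``var_threshold``. Signs follow the convention that the
    largest-magnitude loading of each PC is positive, making the output
    deterministic.
    """
    if not 0.0 < var_threshold <= 1.0:
        raise BlendDesignError("var_threshold must lie in (0, 1]")
    x = np.asarray(a_std.values, dtype=float)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise BlendDesignError("standardized matrix has no variance")
    evr = var / total
    cum = np.cumsum(evr)
    rank = int(np.sum(s > s[0] * 1e-12))
    p = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    p = min(p, rank)
    loadings = vt[:p].T.copy()
    for j in range(p):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = x @ loadings
    return PCAProjection(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=evr[:p],
        cumulative_evr=float(cum[p - 1]),
        p=p,
    )


def blend_space(d, b) -> np.ndarray:
    """E = D B: locations of every blend combination in PC space."""
    d_mat = d.units if isinstance(d, BlendEnumeration) else np.asarray(d, dtype=float)
    b_mat = b.scores if isinstance(b, PCAProjection) else np.asarray(b, dtype=float)
    if d_mat.shape[1] != b_mat.shape[0]:
        raise BlendDesignError(
            f"shape mismatch: D has {d_mat.shape[1]} media, B has {b_mat.shape[0]} rows"
        )
    return d_mat.astype(float) @ b_mat


def _standardize_columns(e: np.ndarray) -> np.ndarray:
    mu = e.mean(axis=0)
    sd = e.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (e - mu) / sd
    z[:, sd == 0.0] = 0.0  # constant column: no direction, Gram det collapses to 0
    return z


def gram_determinant(e_sel, standardize_columns: bool = False) -> float:
    """det(E'ᵀE') of a selected score matrix, clamped to be nonnegative.

    The Gram matrix is positive semidefinite, so tiny negative values are
    numerical noise and are clamped to zero.
    """
    e_sel = np.asarray(e_sel, dtype=float)
    n, p = e_sel.shape
    if n < p:
        raise BlendDesignError(f"need at least as many rows ({n}) as columns ({p})")
    if standardize_columns:
        e_sel = _standardize_columns(e_sel)
    det = float(np.linalg.det(e_sel.T @ e_sel))
    return max(det, 0.0) + 0.0  # + 0.0 normalizes -0.0


def _sample_subsets(rng: np.random.Generator, k: int, n: int, count: int) -> np.ndarray:
    """Draw ``count`` uniform n-subsets of range(k) (Floyd's algorithm)."""
    sel = np.empty((count, n), dtype=np.int64)
    member = np.zeros((count, k), dtype=bool)
    rows = np.arange(count)
    for i, j in enumerate(range(k - n, k)):
        t = rng.integers(0, j + 1, size=count)
        t = np.where(member[rows, t], j, t)
        member[rows, t] = True
        sel[:, i] = t
    return sel


def _batch_gram_dets(e_sel: np.ndarray, standardize_columns: bool) -> np.ndarray:
    """Determinants of E'ᵀE' for a (count, n, p) stack of selections."""
    n = e_sel.shape[1]
    if standardize_columns:
        # det(Z'ᵀZ') = n^p · det(corr): normalize the centered Gram instead
        # of materializing a standardized copy of the whole stack
        centered = e_sel - e_sel.mean(axis=1, keepdims=True)
        gram = centered.transpose(0, 2, 1) @ centered
        diag = np.diagonal(gram, axis1=1, axis2=2)
        denom = np.sqrt(diag[:, :, None] * diag[:, None, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = gram / denom
        corr = np.nan_to_num(corr, nan=0.0)  # constant column -> singular
        dets = float(n) ** e_sel.shape[2] * np.linalg.det(corr)
    else:
        gram = e_sel.transpose(0, 2, 1) @ e_sel
        dets = np.linalg.det(gram)
    return np.maximum(dets, 0.0)


def doptimal_search(
    e: np.ndarray,
    n: int,
    iters: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    enumeration: BlendEnumeration | None = None,
    standardize_columns: bool = True,
    compute_diagnostics: bool = True,
    chunk_size: int = 2048,
) -> DesignSelection:
    """Random-subset D-optimal search: maximize det(E'ᵀE') over n-row subsets.

    Each iteration draws n distinct rows of ``e`` uniformly at random and
    evaluates the Gram determinant; the first-encountered maximum wins.
    By default the columns of each candidate E' are standardized before
    the determinant (det = n^p · det(correlation matrix), directly
    penalizing inter-PC correlation); set ``standardize_columns=False``
    to rank subsets by the raw-score Gram volume instead. The full
    per-iteration determinant trace is returned (the histogram of the
    search), together with the worst selection seen, which is useful for
    before/after collinearity comparisons.
    """
    e = np.asarray(e, dtype=float)
    k, p = e.shape
    if n > k:
        raise BlendDesignError(f"cannot select {n} conditions from {k} candidates")
    if n < p:
        raise BlendDesignError(f"need n >= p ({p}) rows for a nonsingular Gram matrix")
    if iters < 1:
        raise BlendDesignError("iters must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    trace = np.empty(iters, dtype=float)
    best_det, best_idx = -np.inf, None
    worst_det, worst_idx = np.inf, None
    pos = 0
    while pos < iters:
        c = min(chunk_size, iters - pos)
        sel = _sample_subsets(rng, k, n, c)
        dets = _batch_gram_dets(e[sel], standardize_columns)
        trace[pos : pos + c] = dets
        i_max = int(np.argmax(dets))
        if dets[i_max] > best_det:
            best_det, best_idx = float(dets[i_max]), sel[i_max]
        i_min = int(np.argmin(dets))
        if dets[i_min] < worst_det:
            worst_det, worst_idx = float(dets[i_min]), sel[i_min]
        pos += c

    indices = np.sort(best_idx)
    e_sel = e[indices]
    diagnostics = None
    if compute_diagnostics and n >= p + 1 and p >= 2:
        diagnostics = design_diagnostics(e_sel)
    return DesignSelection(
        indices=indices,
        scores=e_sel,
        gram_det=best_det,
        search_trace=trace,
        dispense=enumeration.units[indices] if enumeration is not None else None,
        diagnostics=diagnostics,
        worst_indices=np.sort(worst_idx),
        worst_det=worst_det,
    )


def design_diagnostics(e_sel) -> DesignDiagnostics:
    """Collinearity diagnostics of a selected design: pairwise |r| and VIF.

    VIF_j = 1/(1 - R²_j) from regressing score column j on the others,
    computed as the diagonal of the inverse correlation matrix. Perfectly
    collinear columns yield an infinite VIF sentinel with a warning.
    """
    e_sel = np.asarray(e_sel, dtype=float)
    n, p = e_sel.shape
    if n < p + 1:
        raise BlendDesignError("diagnostics require n >= p + 1 rows")
    corr = correlation_summary(e_sel, thresholds=(0.7, 0.9))
    r = np.corrcoef(e_sel, rowvar=False)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0 or logdet < np.log(1e-12):
        warnings.warn("perfectly collinear design columns; VIF set to inf", stacklevel=2)
        vif = np.full(p, np.inf)
    else:
        vif = np.diag(np.linalg.inv(r)).copy()
    return DesignDiagnostics(correlation=corr, vif=vif, max_vif=float(np.max(vif)))
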