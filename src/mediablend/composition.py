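"""Mother-media composition matrices: loading, validation, profiling.

The composition matrix ``A`` holds the relative concentration of each
medium component (columns) in each mother medium (rows). Because media
blending creates every experimental medium as a nonnegative mixture of
the mother media, everything downstream — the blend enumeration, the PCA
projection, the D-optimal condition selection — consumes this matrix or
a per-column standardization of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage


class ValidationError(ValueError):
    """Raised when an input matrix violates a structural precondition."""


@dataclass(frozen=True)
class CompositionMatrix:
    """Nonnegative m (media) x d (components) relative-concentration matrix."""

    media_ids: tuple[str, ...]
    component_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "media_ids", tuple(str(x) for x in self.media_ids))
        object.__setattr__(
            self, "component_ids", tuple(str(x) for x in self.component_ids)
        )
        if values.ndim != 2:
            raise ValidationError("composition values must be a 2-D matrix")
        m, d = values.shape
        if m != len(self.media_ids) or d != len(self.component_ids):
            raise ValidationError(
                f"label/shape mismatch: {m} x {d} values vs "
                f"{len(self.media_ids)} media and {len(self.component_ids)} components"
            )
        if m < 2:
            raise ValidationError("at least 2 mother media are required")
        if d < 1:
            raise ValidationError("at least 1 component is required")
        for kind, labels in (("media", self.media_ids), ("component", self.component_ids)):
            dupes = _duplicates(labels)
            if dupes:
                raise ValidationError(f"duplicate {kind} labels: {sorted(dupes)}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("composition values must be finite")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative concentration at medium {self.media_ids[i]!r}, "
                f"component {self.component_ids[j]!r}: {values[i, j]}"
            )

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=list(self.media_ids), columns=list(self.component_ids)
        )
        df.index.name = "medium_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CompositionMatrix":
        return cls(
            media_ids=tuple(map(str, df.index)),
            component_ids=tuple(map(str, df.columns)),
            values=df.to_numpy(dtype=float),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass(frozen=True)
class StandardizedMatrix:
    """Column z-scored composition matrix A' (population standard deviation)."""

    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    dropped_components: tuple[str, ...]
    media_ids: tuple[str, ...] = ()
    component_ids: tuple[str, ...] = ()

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CorrelationSummary:
    """Pairwise |r| profile over the columns of a matrix."""

    pairwise_abs_r: np.ndarray
    max_abs_r: float
    mean_abs_r: float
    frac_above: dict[float, float]
    n_pairs: int
    column_ids: tuple[str, ...] = ()

    def count_above(self, threshold: float) -> int:
        return int(round(self.frac_above[threshold] * self.n_pairs))


def _duplicates(labels: Sequence[str]) -> set[str]:
    seen, dupes = set(), set()
    for lab in labels:
        if lab in seen:
            dupes.add(lab)
        seen.add(lab)
    return dupes


def load_composition(path, rows_are_media: bool = True) -> CompositionMatrix:
    """Read a composition CSV (first column = medium label by default).

    Set ``rows_are_media=False`` when the CSV is transposed (components as
    rows); the matrix is flipped back to the rows-are-media convention.
    """
    # peek at the raw header: pandas silently renames duplicate columns
    raw_header = pd.read_csv(path, header=None, nrows=1).iloc[0, 1:]
    header_dupes = _duplicates([str(x) for x in raw_header])
    if header_dupes:
        raise ValidationError(f"duplicate labels in {path}: {sorted(header_dupes)}")
    if hasattr(path, "seek"):
        path.seek(0)
    df = pd.read_csv(path, index_col=0)
    if not rows_are_media:
        df = df.T
    for kind, labels in (("media", df.index), ("component", df.columns)):
        dupes = _duplicates([str(x) for x in labels])
        if dupes:
            raise ValidationError(f"duplicate {kind} labels in {path}: {sorted(dupes)}")
    try:
        values = df.apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    df = pd.DataFrame(values, index=df.index, columns=df.columns)
    return CompositionMatrix.from_frame(df)


def standardize(a: CompositionMatrix) -> StandardizedMatrix:
    """Z-score each component column of ``a`` (population sd).

    Zero-variance components carry no information for the design and would
    produce undefined z-scores; they are dropped with a warning and listed
    in ``dropped_components``.
    """
    values = a.values
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=0)
    keep = sds > 0.0
    if not np.any(keep):
        raise ValidationError("all components have zero variance across media")
    dropped = tuple(c for c, k in zip(a.component_ids, keep) if not k)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance component(s): {list(dropped)}",
            stacklevel=2,
        )
    z = (values[:, keep] - means[keep]) / sds[keep]
    return StandardizedMatrix(
        values=z,
        column_means=means[keep],
        column_sds=sds[keep],
        dropped_components=dropped,
        media_ids=a.media_ids,
        component_ids=tuple(c for c, k in zip(a.component_ids, keep) if k),
    )


def correlation_summary(
    x,
    thresholds: Sequence[float] = (0.7, 0.9),
    column_ids: Sequence[str] | None = None,
) -> CorrelationSummary:
    """Pearson |r| summary over all column pairs of ``x``.

    Needs at least 3 rows; constant columns (undefined r) are excluded with
    a warning. ``frac_above`` maps each threshold to the fraction of
    off-diagonal pairs whose |r| exceeds it.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValidationError("expected a 2-D matrix")
    if x.shape[0] < 3:
        raise ValidationError("correlation summary requires at least 3 rows")
    sds = x.std(axis=0, ddof=0)
    keep = sds > 0.0
    if column_ids is not None:
        column_ids = tuple(str(c) for c in column_ids)
        if len(column_ids) != x.shape[1]:
            raise ValidationError("column_ids length does not match matrix width")
    if not np.all(keep):
        warnings.warn(
            f"excluding {int((~keep).sum())} constant column(s) from correlations",
            stacklevel=2,
        )
        x = x[:, keep]
        if column_ids is not None:
            column_ids = tuple(c for c, k in zip(column_ids, keep) if k)
    d = x.shape[1]
    if d < 2:
        raise ValidationError("need at least 2 non-constant columns")
    r = np.abs(np.corrcoef(x, rowvar=False))
    np.clip(r, 0.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    iu = np.triu_indices(d, k=1)
    off = r[iu]
    frac = {float(t): float(np.mean(off > t)) for t in thresholds}
    return CorrelationSummary(
        pairwise_abs_r=r,
        max_abs_r=float(off.max()),
        mean_abs_r=float(off.mean()),
        frac_above=frac,
        n_pairs=d * (d - 1) // 2,
        column_ids=column_ids or (),
    )


def cluster_media(a: CompositionMatrix, use_standardized: bool = True) -> np.ndarray:
    """Ward/Euclidean hierarchical clustering of the mother media.

    Returns the scipy linkage matrix. Standardized concentrations are used
    by default so that high-abundance components do not dominate the
    distances; pass ``use_standardized=False`` to cluster raw values.
    """
    x = standardize(a).values if use_standardized else a.values
    return linkage(x, method="ward", metric="euclidean")
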