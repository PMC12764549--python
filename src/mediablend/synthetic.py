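"""Synthetic composition matrices and culture responses.

The compositions of the commercial media in the motivating case study
are proprietary, so this module generates stand-in data with the same
statistical fingerprints: a mother-media matrix whose component pairs
are highly correlated (|r| > 0.7) at a configurable rate (~12% for
commercial media), and a viable-cell-concentration-like response whose
between-condition variance accounts for ~80% of the total, with the
remainder coming from replicate noise. Correlation structure is induced
by a small number of latent factors shared between components — the
simplest mechanism producing the mixed correlation profile of real
media, where some component groups co-vary across products and the rest
vary independently.

Ground-truth labels (which components truly drive the response) are
returned in a separate object and never enter the analysis path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import CompositionMatrix
from .regression import CultureDataset


class SyntheticError(ValueError):
    """Raised when a generation target cannot be met."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Targets for the synthetic composition / response generators."""

    m: int = 11
    d: int = 67
    target_high_corr_fraction: float = 0.12
    corr_tolerance: float = 0.05
    n_factors: int = 5
    factor_tied_fraction: float = 0.8  # fraction of components tied to a latent factor
    loading_low: float = 0.72
    loading_high: float = 0.95
    planted_max_abs_r: float = 0.6  # planted components stay mutually distinguishable
    planted_max_partner_r: float = 0.8  # planted have no near-duplicate partner
    k_true: int = 12
    effect_low: float = 0.9
    effect_high: float = 1.1
    replicates: int = 3
    ssb_target: float = 0.80  # between-condition share of total response variance
    ssb_band: tuple[float, float] = (0.75, 0.85)
    condition_noise_fraction: float = 0.05  # condition-level noise vs signal variance
    response_mean: float = 12.6e6  # cells/mL, centre of the emulated VCC range
    response_sd: float = 3.4e6  # cells/mL, spread of the emulated VCC range
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.target_high_corr_fraction < 1.0:
            raise ValueError("target_high_corr_fraction must lie in [0, 1)")
        if self.k_true > self.d:
            raise ValueError("k_true cannot exceed d")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted; for scoring recovery only."""

    planted_indices: tuple[int, ...]
    planted_components: tuple[str, ...]
    effects: np.ndarray
    ssb_ratio: float


def _high_corr_fraction(values: np.ndarray, threshold: float = 0.7) -> float:
    r = np.abs(np.corrcoef(values, rowvar=False))
    iu = np.triu_indices(r.shape[1], k=1)
    return float(np.mean(r[iu] > threshold))


def synth_composition(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    max_retries: int = 200,
) -> tuple[CompositionMatrix, float]:
    """Draw a nonnegative m x d composition with a target |r| > 0.7 rate.

    Factor-tied components load on one of ``n_factors`` latent media
    profiles (loading ~ U(loading_low, loading_high), random sign); untied
    components are independent. With few media (m ~ 11) a sizable share of the high-|r|
    pairs comes from small-sample noise on top of the factor structure,
    mirroring how commercial media correlate: graded co-variation rather
    than exact duplicates. Columns are shifted to be nonnegative and rescaled by a
    random positive factor, which leaves every |r| unchanged. Candidates
    are redrawn until the achieved fraction of |r| > 0.7 pairs falls
    within ``corr_tolerance`` of the target.

    Returns ``(composition, achieved_fraction)``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    target = spec.target_high_corr_fraction
    tied_fraction = spec.factor_tied_fraction if target > 0 else 0.0
    best_gap, best = np.inf, None
    for _ in range(max_retries):
        factors = rng.standard_normal((spec.m, spec.n_factors))
        z = rng.standard_normal((spec.m, spec.d))
        n_tied = int(round(tied_fraction * spec.d))
        tied = rng.choice(spec.d, size=n_tied, replace=False)
        assignment = rng.integers(0, spec.n_factors, size=n_tied)
        loading = rng.uniform(spec.loading_low, spec.loading_high, size=n_tied) * rng.choice([-1.0, 1.0], size=n_tied)
        z[:, tied] = loading * factors[:, assignment] + np.sqrt(1 - loading**2) * z[:, tied]
        # positive-affine map to nonnegative relative concentrations (|r|-preserving)
        scale = rng.lognormal(mean=0.0, sigma=1.0, size=spec.d)
        values = (z - z.min(axis=0)) * scale
        achieved = _high_corr_fraction(values)
        gap = abs(achieved - target)
        if gap < best_gap:
            best_gap, best = gap, (values, achieved)
        if gap <= spec.corr_tolerance:
            break
    else:
        raise SyntheticError(
            f"could not reach |r|>0.7 fraction {target:.3f} +/- {spec.corr_tolerance}; "
            f"best achieved {best[1]:.3f}"
        )
    values, achieved = best
    comp = CompositionMatrix(
        media_ids=tuple(f"medium_{i:02d}" for i in range(spec.m)),
        component_ids=tuple(f"comp_{j:03d}" for j in range(spec.d)),
        values=values,
    )
    return comp, achieved


def _ssb_ratio(y: np.ndarray, condition_id: np.ndarray) -> float:
    """Between-condition share of the total sum of squares."""
    grand = y.mean()
    tss = np.sum((y - grand) ** 2)
    ssb = 0.0
    for cid in np.unique(condition_id):
        sub = y[condition_id == cid]
        ssb += len(sub) * (sub.mean() - grand) ** 2
    return float(ssb / tss)


def _choose_planted(x: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Plant effects on mutually distinguishable components.

    Active components are drawn at random subject to two identifiability
    caps computed on the condition-level design matrix: their pairwise
    |r| (mutual distinguishability) and their maximum |r| with any other
    component (no near-duplicate partner). In a blending design the
    condition matrix has rank at most m, so a component inside a tightly
    correlated group is unidentifiable by construction — any method can
    only recover the group as a set — and using one as ground truth
    would make the benchmark unscorable. Both caps are relaxed in 0.05
    steps if the design is too collinear to satisfy them.
    """
    d = x.shape[1]
    sds = x.std(axis=0, ddof=0)
    r = np.abs(np.corrcoef(x + 1e-12 * rng.standard_normal(x.shape), rowvar=False))
    r_off = r.copy()
    np.fill_diagonal(r_off, 0.0)
    max_partner = r_off.max(axis=0)
    mutual_cap, partner_cap = spec.planted_max_abs_r, spec.planted_max_partner_r
    while mutual_cap <= 0.9 + 1e-9:
        eligible = np.flatnonzero((sds > 0) & (max_partner <= partner_cap))
        for _ in range(50):
            chosen: list[int] = []
            for j in rng.permutation(eligible):
                if all(r[j, c] <= mutual_cap for c in chosen):
                    chosen.append(int(j))
                if len(chosen) == spec.k_true:
                    return np.sort(np.array(chosen))
        mutual_cap += 0.05
        partner_cap = min(partner_cap + 0.05, 1.0)
    raise SyntheticError(
        f"could not find {spec.k_true} mutually distinguishable components"
    )


def synth_response(
    x_conditions: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    component_ids=None,
    noise: bool = True,
    max_retries: int = 20,
) -> tuple[CultureDataset, GroundTruth]:
    """Simulate a VCC-like response over designed condition compositions.

    ``x_conditions`` is the condition-level component matrix (one row per
    blending condition). The response is linear in ``k_true`` randomly
    planted components (on their standardized scale), plus condition-level
    and replicate-level Gaussian noise with scales solved so that the
    between-condition share of total variance lands in ``ssb_band``.
    Output units emulate viable cell concentration in cells/mL.
    """
    x = np.asarray(x_conditions, dtype=float)
    n_cond, d = x.shape
    if d != spec.d:
        raise SyntheticError(f"x has {d} components, spec expects {spec.d}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ids = (
        tuple(str(c) for c in component_ids)
        if component_ids is not None
        else tuple(f"comp_{j:03d}" for j in range(d))
    )

    planted = _choose_planted(x, spec, rng)
    sds = x[:, planted].std(axis=0, ddof=0)
    if np.any(sds == 0):
        raise SyntheticError("planted component is constant across conditions")
    z = (x[:, planted] - x[:, planted].mean(axis=0)) / sds
    effects = rng.uniform(spec.effect_low, spec.effect_high, size=spec.k_true)
    effects *= rng.choice([-1.0, 1.0], size=spec.k_true)
    if np.allclose(effects, 0.0):
        raise SyntheticError("all planted effects are zero; response would be pure noise")
    signal = z @ effects
    var_signal = float(np.var(signal))
    if var_signal == 0.0:
        raise SyntheticError("planted signal has zero variance")

    for _ in range(max_retries):
        if noise:
            var_cond = spec.condition_noise_fraction * var_signal
            between = var_signal + var_cond
            # solve E[SSB/TSS] = t: replicate noise also inflates the
            # between-condition means by var_rep / replicates
            r_count, t = spec.replicates, spec.ssb_target
            if r_count * t > 1.0:
                var_rep = r_count * between * (1.0 - t) / (r_count * t - 1.0)
            else:
                var_rep = 0.0  # single replicate: SSB == TSS identically
            cond_noise = rng.normal(0.0, np.sqrt(var_cond), size=n_cond)
            rep_noise = rng.normal(0.0, np.sqrt(var_rep), size=n_cond * spec.replicates)
        else:
            cond_noise = np.zeros(n_cond)
            rep_noise = np.zeros(n_cond * spec.replicates)
        y_cond = signal + cond_noise
        y = np.repeat(y_cond, spec.replicates) + rep_noise
        # map to the emulated VCC scale (cells/mL)
        sd = y.std(ddof=0)
        y_scaled = spec.response_mean + (y - y.mean()) * (spec.response_sd / sd)
        condition_id = np.repeat(np.arange(n_cond), spec.replicates)
        replicate_id = np.tile(np.arange(spec.replicates), n_cond)
        ratio = _ssb_ratio(y_scaled, condition_id)
        if not noise or spec.ssb_band[0] <= ratio <= spec.ssb_band[1]:
            break
    else:
        raise SyntheticError(
            f"between-condition variance share {ratio:.3f} outside {spec.ssb_band}"
        )

    ds = CultureDataset(
        condition_id=condition_id,
        replicate_id=replicate_id,
        X=np.repeat(x, spec.replicates, axis=0),
        y=y_scaled,
        component_ids=ids,
    )
    truth = GroundTruth(
        planted_indices=tuple(int(i) for i in planted),
        planted_components=tuple(ids[i] for i in planted),
        effects=effects,
        ssb_ratio=ratio,
    )
    return ds, truth
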