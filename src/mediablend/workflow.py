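"""End-to-end screening pipeline glue.

Chains the package stages the way a screening study would run them:
synthesize (or load) a composition matrix, design blending conditions,
culture (here: simulate) the responses, fit the model suite under the
grouped protocol, and extract the adjusted-PFI consensus component set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .blend_design import blend_space, doptimal_search, enumerate_blends, pca_project
from .composition import CompositionMatrix, standardize
from .importance import adjusted_pfi, consensus_components, shrunk_correlations
from .regression import SUPERIOR_CANDIDATES, CultureDataset, run_model_suite
from .synthetic import SyntheticSpec, synth_composition, synth_response


@dataclass
class ScreeningRun:
    composition: CompositionMatrix
    design_indices: np.ndarray
    dataset: CultureDataset
    suite: object
    consensus: object
    truth: object | None = None

    def recovered(self) -> int:
        """Number of planted components present in the consensus set."""
        if self.truth is None:
            raise ValueError("no ground truth attached to this run")
        return len(set(self.consensus.members) & set(self.truth.planted_components))


def design_conditions(
    composition: CompositionMatrix,
    n_conditions: int = 120,
    total_units: int = 6,
    design_iters: int = 10000,
    var_threshold: float = 0.99,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """Standardize -> PCA -> enumerate -> D-optimal search; returns
    (selection, enumeration, projection, condition-level X)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    enumeration = enumerate_blends(composition.m, total_units)
    proj = pca_project(standardize(composition), var_threshold)
    e = blend_space(enumeration, proj)
    sel = doptimal_search(
        e, n_conditions, design_iters, rng=rng, enumeration=enumeration,
        compute_diagnostics=False,
    )
    x_cond = sel.dispense.astype(float) @ composition.values / total_units
    return sel, enumeration, proj, x_cond


def synthetic_screening_run(
    spec: SyntheticSpec,
    seed: int,
    n_conditions: int = 120,
    total_units: int = 6,
    design_iters: int = 10000,
    model_names: Sequence[str] = SUPERIOR_CANDIDATES,
    j_repeats: int = 10,
    ci_alpha: float = 0.05,
    top_fraction: float = 0.25,
    folds: int = 5,
) -> ScreeningRun:
    """One full synthetic screening study with planted ground truth.

    The importance step mirrors the screening protocol: adjusted PFI on
    the held-out test partition for each modeled algorithm, with the
    correlation shrinkage estimated on the training partition, then the
    consensus of the per-model top fractions.
    """
    rng = np.random.default_rng(seed)
    composition, _ = synth_composition(spec, rng=rng)
    sel, _, _, x_cond = design_conditions(
        composition,
        n_conditions=n_conditions,
        total_units=total_units,
        design_iters=design_iters,
        rng=rng,
    )
    dataset, truth = synth_response(
        x_cond, spec, rng=rng, component_ids=composition.component_ids
    )
    suite = run_model_suite(
        dataset, model_names=list(model_names), folds=folds, seed=seed
    )
    # the correlation structure among components originates from the m
    # mother media, not from the (replicated) condition rows
    shrink = shrunk_correlations(
        suite.train.X, ci_alpha=ci_alpha, effective_sample_size=composition.m
    )
    tables = {}
    for name, model in suite.models.items():
        tables[name] = adjusted_pfi(
            model,
            suite.test.X,
            suite.test.y,
            shrink,
            j_repeats=j_repeats,
            rng=rng,
            component_ids=dataset.component_ids,
        )
    consensus = consensus_components(tables, top_fraction=top_fraction)
    return ScreeningRun(
        composition=composition,
        design_indices=sel.indices,
        dataset=dataset,
        suite=suite,
        consensus=consensus,
        truth=truth,
    )
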