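import itertools
import math

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression, Ridge

from mediablend.importance import (
    ImportanceError,
    adjusted_pfi,
    consensus_components,
    pfi,
    shrunk_correlations,
    vip_scores,
)


class _Linear:
    """Deterministic linear model with fixed coefficients."""

    def __init__(self, coef):
        self.coef = np.asarray(coef, dtype=float)

    def predict(self, x):
        return np.asarray(x) @ self.coef


class _IdentityRng:
    """RNG stub whose permutation is the identity (degenerate shuffles)."""

    def permutation(self, n):
        return np.arange(n)

    def random(self, size):
        return np.ones(size)  # no co-shuffling either


class TestPlainPFI:
    def test_unused_feature_near_zero(self, rng):
        x = rng.standard_normal((100, 3))
        y = 2.0 * x[:, 0]
        table = pfi(_Linear([2.0, 0.0, 0.0]), x, y, j_repeats=10, seed=0)
        assert abs(table.importance[1]) < 1e-12
        assert abs(table.importance[2]) < 1e-12
        assert table.importance[0] > 0.5

    def test_identity_permutation_gives_zero(self, rng):
        x = rng.standard_normal((20, 2))
        y = x @ np.array([1.0, -1.0])
        table = pfi(_Linear([1.0, -1.0]), x, y, j_repeats=1, rng=_IdentityRng())
        np.testing.assert_allclose(table.importance, 0.0, atol=1e-12)

    def test_matches_exhaustive_permutation_average(self):
        """y = 2x with a perfect model at n = 5: the mean shuffled R² over
        all 5! permutations is computed by enumeration and compared with a
        large-J Monte-Carlo PFI."""
        x = np.array([[0.5], [1.0], [2.0], [3.5], [4.0]])
        y = 2.0 * x[:, 0]
        model = _Linear([2.0])
        denom = np.sum((y - y.mean()) ** 2)
        scores = []
        for perm in itertools.permutations(range(5)):
            pred = 2.0 * x[list(perm), 0]
            scores.append(1.0 - np.sum((y - pred) ** 2) / denom)
        expected = 1.0 - float(np.mean(scores))
        table = pfi(model, x, y, j_repeats=4000, seed=0)
        assert table.importance[0] == pytest.approx(expected, abs=0.05)

    def test_single_sample_rejected(self):
        with pytest.raises(ImportanceError):
            pfi(_Linear([1.0]), np.ones((1, 1)), [1.0], j_repeats=2, seed=0)

    def test_noise_feature_mean_importance_near_zero(self, rng):
        """Independent noise feature: mean plain PFI over repeats ~ 0."""
        x = rng.standard_normal((120, 2))
        y = x[:, 0] + 0.2 * rng.standard_normal(120)
        model = LinearRegression().fit(x, y)
        vals = [
            pfi(model, x, y, j_repeats=1, seed=s).importance[1] for s in range(50)
        ]
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert abs(np.mean(vals)) < max(2 * se, 1e-3)


class TestShrunkCorrelations:
    def test_fisher_z_closed_form(self, rng):
        x = rng.standard_normal((50, 2))
        shrink = shrunk_correlations(x)
        r = shrink.r_matrix[0, 1]
        assert shrink.z_matrix[0, 1] == pytest.approx(0.5 * math.log((1 + r) / (1 - r)))
        # known closed form: r = 0.5 -> z = 0.5 ln 3 = 0.5493
        assert 0.5 * math.log(3.0) == pytest.approx(0.5493, abs=1e-4)

    def test_zero_correlation_shrinks_to_zero(self, rng):
        # orthogonalized pair: sample r == 0 exactly
        a = rng.standard_normal(40)
        b = rng.standard_normal(40)
        b -= (b - b.mean()) @ (a - a.mean()) / np.sum((a - a.mean()) ** 2) * (a - a.mean())
        shrink = shrunk_correlations(np.column_stack([a, b]))
        assert shrink.r_prime[0, 1] == 0.0

    def test_known_bounds_r09_m144(self):
        """r = 0.9, m = 144: frozen bounds from the back-transform formula,
        cross-checked against a bootstrap CI on bivariate normal data."""
        z = math.atanh(0.9)
        half = 1.959964 / math.sqrt(141)
        lo, hi = math.tanh(z - half), math.tanh(z + half)
        assert lo == pytest.approx(0.8636, abs=1e-4)
        assert hi == pytest.approx(0.9271, abs=1e-4)
        rng = np.random.default_rng(0)
        cov = [[1.0, 0.9], [0.9, 1.0]]
        base = rng.multivariate_normal([0, 0], cov, size=144)
        r_obs = np.corrcoef(base, rowvar=False)[0, 1]
        z_obs = math.atanh(r_obs)
        lo_f, hi_f = math.tanh(z_obs - half), math.tanh(z_obs + half)
        boots = []
        for _ in range(800):
            idx = rng.integers(0, 144, 144)
            boots.append(np.corrcoef(base[idx], rowvar=False)[0, 1])
        lo_b, hi_b = np.percentile(boots, [2.5, 97.5])
        assert lo_f == pytest.approx(lo_b, abs=0.03)
        assert hi_f == pytest.approx(hi_b, abs=0.03)

    def test_monotone_in_sample_size(self, rng):
        x = rng.standard_normal((300, 3))
        x[:, 1] = 0.8 * x[:, 0] + 0.6 * x[:, 1]
        values = [
            shrunk_correlations(x, effective_sample_size=m).r_prime[0, 1]
            for m in (10, 30, 100, 300)
        ]
        assert values == sorted(values)

    def test_invariants(self, rng):
        x = rng.standard_normal((25, 5))
        shrink = shrunk_correlations(x)
        assert np.all(shrink.r_prime >= 0) and np.all(shrink.r_prime < 1)
        assert np.all(np.diag(shrink.r_prime) == 0)
        assert np.all(shrink.r_prime <= shrink.r_matrix + 1e-12)

    def test_too_small_sample(self, rng):
        with pytest.raises(ImportanceError):
            shrunk_correlations(rng.standard_normal((3, 4)))


class TestAdjustedPFI:
    def test_reduces_to_plain_when_r_prime_zero(self, rng):
        """With r' = 0 everywhere, adjusted PFI is plain PFI: the first
        feature (same RNG stream position) matches exactly and the rest
        match within Monte-Carlo noise."""
        x = rng.standard_normal((60, 3))
        y = x @ np.array([1.0, 0.5, 0.0])
        model = _Linear([1.0, 0.5, 0.0])
        shrink = shrunk_correlations(x)
        object.__setattr__(shrink, "r_prime", shrink.r_prime * 0.0)
        plain_tab = pfi(model, x, y, j_repeats=1, seed=42)
        adj_tab = adjusted_pfi(model, x, y, shrink, j_repeats=1, seed=42)
        assert adj_tab.importance[0] == pytest.approx(plain_tab.importance[0], abs=1e-12)
        plain_big = pfi(model, x, y, j_repeats=300, seed=0)
        adj_big = adjusted_pfi(model, x, y, shrink, j_repeats=300, seed=1)
        np.testing.assert_allclose(adj_big.importance, plain_big.importance, atol=0.05)

    def test_r_prime_one_equals_joint_permutation(self, rng):
        """r'_{p,q} = 1 co-shuffles q with p's permutation on every sample."""
        x = rng.standard_normal((40, 2))
        y = x @ np.array([1.0, 1.0])
        model = _Linear([1.0, 1.0])
        shrink = shrunk_correlations(x)
        rp = np.array([[0.0, 1.0 - 1e-15], [1.0 - 1e-15, 0.0]])
        object.__setattr__(shrink, "r_prime", rp)
        adj = adjusted_pfi(model, x, y, shrink, j_repeats=1, seed=9)
        # oracle: replicate the rng consumption, then jointly permute
        oracle_rng = np.random.default_rng(9)
        denom = np.sum((y - y.mean()) ** 2)
        expected = []
        for p in range(2):
            perm = oracle_rng.permutation(40)
            oracle_rng.random((40, 2))  # consumed by the implementation
            pred = model.predict(x[perm])
            score = 1.0 - np.sum((y - pred) ** 2) / denom
            expected.append(adj.baseline_score - score)
        np.testing.assert_allclose(adj.importance, expected, atol=1e-10)

    def test_duplicate_pair_rescued(self, rng):
        """Both members of a perfectly correlated predictive pair get
        substantially higher adjusted than plain importance."""
        base = rng.standard_normal(150)
        x = np.column_stack([base, base, rng.standard_normal((150, 2))])
        y = 2.0 * base + 0.1 * rng.standard_normal(150)
        model = Ridge(alpha=1.0).fit(x, y)
        shrink = shrunk_correlations(x)
        plain_tab = pfi(model, x, y, j_repeats=10, seed=1)
        adj_tab = adjusted_pfi(model, x, y, shrink, j_repeats=10, seed=1)
        for j in (0, 1):
            assert adj_tab.importance[j] > 2.0 * plain_tab.importance[j]
            assert adj_tab.importance[j] > plain_tab.importance[j] + 0.5

    def test_mismatched_variable_sets(self, rng):
        x = rng.standard_normal((30, 4))
        shrink = shrunk_correlations(x[:, :3])
        with pytest.raises(ImportanceError):
            adjusted_pfi(_Linear([1, 0, 0, 0]), x, x[:, 0], shrink, seed=0)


class TestConsensus:
    def _table(self, importance, ids=None):
        from mediablend.importance import ImportanceTable

        importance = np.asarray(importance, dtype=float)
        d = len(importance)
        return ImportanceTable(
            component_ids=tuple(ids or (f"c{j}" for j in range(d))),
            baseline_score=1.0,
            mean_shuffled_score=1.0 - importance,
            importance=importance,
            n_repeats=1,
            method="plain",
        )

    def test_top_set_size_for_case_study(self, rng):
        table = self._table(rng.random(67))
        result = consensus_components({"only": table}, top_fraction=0.25)
        assert len(result.per_model_top["only"]) == 17

    def test_single_model_consensus_is_own_top(self, rng):
        table = self._table(rng.random(8))
        result = consensus_components({"only": table}, top_fraction=0.5)
        assert set(result.members) == set(table.top_components(4))

    def test_disjoint_top_sets_empty(self):
        t1 = self._table([3, 2, 0, 0])
        t2 = self._table([0, 0, 2, 3])
        result = consensus_components({"a": t1, "b": t2}, top_fraction=0.5)
        assert result.members == ()

    def test_tiers_nested(self, rng):
        tables = {f"m{k}": self._table(rng.random(40)) for k in range(3)}
        result = consensus_components(tables, top_fraction=0.25)
        tiers = [set(result.tier_membership[t]) for t in (0.05, 0.10, 0.15, 0.20, 0.25)]
        for small, big in zip(tiers, tiers[1:]):
            assert small <= big


class TestVIP:
    def test_normalization_identity(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        x = rng.standard_normal((50, 7))
        y = x @ rng.standard_normal(7) + 0.1 * rng.standard_normal(50)
        pls = PLSRegression(n_components=3).fit(x, y)
        vip = vip_scores(pls)
        assert np.mean(vip**2) == pytest.approx(1.0, rel=1e-9)

    def test_single_predictor_single_component(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        x = rng.standard_normal((30, 1))
        y = 2.0 * x[:, 0]
        pls = PLSRegression(n_components=1).fit(x, y)
        assert vip_scores(pls)[0] == pytest.approx(1.0)

    def test_non_pls_rejected(self, rng):
        with pytest.raises(ImportanceError):
            vip_scores(Ridge().fit(rng.standard_normal((10, 2)), rng.standard_normal(10)))

    def test_agreement_with_adjusted_pfi_above_chance(self, case_study_pipeline):
        """VIP and adjusted-PFI top-12 sets agree above the ~2-component
        chance level on the shared screening fixture."""
        run = case_study_pipeline
        pls = run.suite.models["plsr"]
        vip = vip_scores(pls)
        vip_top = set(np.argsort(-vip)[:12])
        from mediablend.importance import adjusted_pfi, shrunk_correlations

        shrink = shrunk_correlations(
            run.suite.train.X, effective_sample_size=run.composition.m
        )
        tab = adjusted_pfi(
            pls, run.suite.test.X, run.suite.test.y, shrink, j_repeats=10, seed=11
        )
        adj_top = set(np.argsort(-tab.importance)[:12])
        assert len(vip_top & adj_top) >= 4
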