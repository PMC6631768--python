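import math

import numpy as np
import pytest

from samfc.divergence import (
    BetaConfig,
    beta_weight,
    classify_gene,
    compute_weight_matrix,
    delta_cutoff,
    fit_genome,
    minimum_beta_divergence_estimate,
    unify_estimates,
)
from samfc.experiment import mle_estimate
from samfc.simulation import SimulationConfig, generate


def grid_search_minimum(d, beta, mu_grid, sigma_grid):
    """Independent dense grid search of the weighted-estimating-equation
    criterion -log J, J = sigma^(-beta/(1+beta)) * mean exp(-beta z^2 / 2)."""
    d = np.asarray(d, dtype=float)
    best = (np.inf, None, None)
    for mu in mu_grid:
        z2 = (d - mu) ** 2
        for s in sigma_grid:
            w = np.exp(-beta * z2 / (2 * s * s))
            if w.mean() == 0.0:  # every weight underflowed
                continue
            val = beta / (1 + beta) * math.log(s) - math.log(w.mean())
            if val < best[0]:
                best = (val, mu, s)
    return best


class TestBetaWeight:
    def test_unit_at_center_and_unit_exponent(self):
        assert beta_weight(5.0, 5.0, 2.0, 0.7) == 1.0
        # (d - mu)^2 = 2 sigma^2 / beta  ->  weight = e^-1
        assert beta_weight(
            1.0 + math.sqrt(2 * 4.0 / 0.2), 1.0, 2.0, 0.2
        ) == pytest.approx(math.exp(-1))

    def test_beta_zero_disables_weighting(self):
        assert beta_weight(123.0, 0.0, 1.0, 0.0) == 1.0

    def test_sigma_zero_rejected(self):
        with pytest.raises(ValueError):
            beta_weight(1.0, 0.0, 0.0, 0.2)

    def test_strictly_decreasing_in_residual(self):
        resid = np.linspace(0, 10, 50)
        w = [beta_weight(r, 0.0, 1.5, 0.2) for r in resid]
        assert np.all(np.diff(w) < 0)
        assert all(0 < x <= 1 for x in w)


class TestFixedPoint:
    def test_beta_zero_reduces_to_classical(self, rng, make_diff):
        for _ in range(10):
            d = make_diff(rng.normal(0, 2, 6))
            est = minimum_beta_divergence_estimate(d, BetaConfig(beta=0.0))
            ref = mle_estimate(d)
            assert est.mu == ref.mu and est.sigma == ref.sigma

    def test_symmetric_vector_centres_at_zero(self, make_diff):
        for beta in (0.1, 0.2, 0.5):
            est = minimum_beta_divergence_estimate(
                make_diff([-1.0, 0.0, 1.0]), BetaConfig(beta=beta)
            )
            assert est.mu == pytest.approx(0.0, abs=1e-8)
            assert est.kind == "robust" and est.converged

    def test_contaminated_vector_matches_grid_search(self, make_diff):
        est = minimum_beta_divergence_estimate(
            make_diff([0.9, 1.0, 1.1, 20.0]), BetaConfig(beta=0.2)
        )
        _, mu_star, _ = grid_search_minimum(
            [0.9, 1.0, 1.1, 20.0],
            0.2,
            np.linspace(-2, 22, 600),
            np.geomspace(0.01, 30, 600),
        )
        assert est.mu == pytest.approx(mu_star, abs=0.05)
        assert abs(est.mu - 1.0) < 0.05  # far from the contaminated mean 5.75
        assert est.weights[-1] < 1e-6

    @pytest.mark.parametrize("M", [1e3, 1e6])
    def test_bounded_influence_of_gross_outlier(self, rng, make_diff, M):
        clean = rng.normal(1.0, 0.5, 7)
        d = np.append(clean, M)
        est = minimum_beta_divergence_estimate(make_diff(d), BetaConfig(beta=0.2))
        assert abs(est.mu - clean.mean()) < 3 * clean.std(ddof=1)
        assert mle_estimate(make_diff(d)).mu > M / 10  # classical mean diverges

    def test_all_equal_rejected(self, make_diff):
        with pytest.raises(ValueError, match="degenerate"):
            minimum_beta_divergence_estimate(make_diff([2.0, 2.0, 2.0]))

    def test_objective_at_fixed_point_attains_grid_minimum(self, rng, make_diff):
        """Fixed point vs an independent dense grid search on 20 contaminated
        length-5 vectors: the iteration's criterion value must not exceed the
        grid minimum by more than 1e-6."""
        beta = 0.2
        for _ in range(20):
            d = rng.normal(0.5, 0.4, 5)
            d[rng.integers(5)] += rng.choice([-1, 1]) * rng.uniform(8, 15)
            est = minimum_beta_divergence_estimate(make_diff(d), BetaConfig(beta=beta))
            w = np.exp(-beta * (d - est.mu) ** 2 / (2 * est.sigma**2))
            fp_obj = beta / (1 + beta) * math.log(est.sigma) - math.log(w.mean())
            span = d.max() - d.min()
            grid_obj, _, _ = grid_search_minimum(
                d,
                beta,
                np.linspace(d.min() - 0.5, d.max() + 0.5, 400),
                np.geomspace(0.02, 2 * span, 400),
            )
            assert fp_obj <= grid_obj + 1e-6


class TestDeltaCutoff:
    @pytest.mark.parametrize(
        "pool, expected",
        [
            (np.full(10, 0.9), 0.2),  # cap binds
            ([0.05, 0.5, 0.95], 0.05 + 0.1 * 0.9),
            ([0.0, 0.0], 0.0),
        ],
    )
    def test_formula(self, pool, expected):
        assert delta_cutoff(pool) == pytest.approx(expected)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            delta_cutoff([])


class TestClassifyGene:
    @pytest.mark.parametrize(
        "weights, delta, expected",
        [
            ([0.8, 0.9, 0.7], 0.2, False),
            ([0.8, 0.1, 0.9], 0.2, True),
            ([0.2, 0.9, 0.9], 0.2, True),  # boundary counts as outlier
        ],
    )
    def test_rule(self, weights, delta, expected):
        assert classify_gene(weights, delta) is expected


class TestWeightMatrix:
    def test_tight_gene_has_large_weights(self, make_diff):
        dv = make_diff([0.0, 0.1, -0.1])
        est = minimum_beta_divergence_estimate(dv, BetaConfig(beta=0.2))
        wm = compute_weight_matrix([est], [dv], BetaConfig(beta=0.2))
        assert np.all(wm.weights > 0.5)
        np.testing.assert_allclose(
            wm.weights[0],
            np.exp(-0.2 * (dv.d - est.mu) ** 2 / (2 * est.sigma**2)),
        )

    def test_gene_permutation_permutes_rows(self, rng, make_diff):
        diffs = [make_diff(rng.normal(0, 1, 4), f"g{i}") for i in range(6)]
        cfg = BetaConfig(beta=0.2)
        ests = [minimum_beta_divergence_estimate(dv, cfg) for dv in diffs]
        wm = compute_weight_matrix(ests, diffs, cfg)
        perm = rng.permutation(6)
        wm_p = compute_weight_matrix(
            [ests[i] for i in perm], [diffs[i] for i in perm], cfg
        )
        np.testing.assert_allclose(wm_p.weights, wm.weights[perm])
        assert wm_p.delta == pytest.approx(wm.delta)

    def test_zero_scale_gene_treated_as_clean(self, make_diff):
        from samfc.experiment import LocationScaleEstimate

        good = make_diff([0.0, 0.5, -0.5], "good")
        bad = make_diff([1.0, 1.0, 1.0], "bad")
        ests = [
            minimum_beta_divergence_estimate(good, BetaConfig(beta=0.2)),
            LocationScaleEstimate(1.0, 0.0, "robust", np.ones(3)),
        ]
        with pytest.warns(UserWarning, match="zero robust scale"):
            wm = compute_weight_matrix(ests, [good, bad], BetaConfig(beta=0.2))
        assert np.all(wm.weights[1] == 1.0)


class TestUnifyEstimates:
    def test_branches(self, make_diff):
        dv = make_diff([0.9, 1.0, 1.1, 20.0])
        classical = mle_estimate(dv)
        robust = minimum_beta_divergence_estimate(dv, BetaConfig(beta=0.2))
        clean = unify_estimates(classical, robust, False)
        assert clean.mu == classical.mu and not clean.is_outlying_gene
        cont = unify_estimates(classical, robust, True)
        assert cont.mu == robust.mu and cont.is_outlying_gene

    def test_clean_genome_mostly_classical(self):
        """Without contamination the vast majority of genes must keep the
        classical branch."""
        ds = generate(SimulationConfig(n_genes=2000, n=3, seed=5))
        from samfc.experiment import difference_matrix

        D = difference_matrix(ds.experiment)
        cfg = BetaConfig(beta=0.2)
        mu, sigma, w, conv = fit_genome(D, cfg)
        delta = delta_cutoff(w[sigma > 0], cfg)
        outlying = (w <= delta).any(axis=1) & (sigma > 0)
        assert outlying.mean() < 0.05


class TestFitGenome:
    def test_matches_per_gene_estimates_for_contaminated_rows(self, make_diff):
        D = np.array([[0.9, 1.0, 1.1, 20.0], [-0.2, 0.3, 0.1, -0.15]])
        mu, sigma, w, conv = fit_genome(D, BetaConfig(beta=0.2, start="per_gene"))
        for g in range(2):
            est = minimum_beta_divergence_estimate(
                make_diff(D[g]), BetaConfig(beta=0.2)
            )
            assert mu[g] == pytest.approx(est.mu, rel=1e-6)
            assert sigma[g] == pytest.approx(est.sigma, rel=1e-6)
        assert conv.all()

    def test_constant_rows_degenerate_but_clean(self):
        D = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, -1.0]])
        mu, sigma, w, conv = fit_genome(D, BetaConfig(beta=0.2))
        assert sigma[0] == 0.0 and np.all(w[0] == 1.0) and conv[0]
        assert sigma[1] > 0
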