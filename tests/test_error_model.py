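"""Rate-surface estimation: selection, pooling, pruning, smoothing, fitting."""

import math

import numpy as np
import pytest

from snvgraph.error_model import (
    SUBSTITUTIONS,
    ErrorModel,
    InsufficientDataError,
    ModelConfig,
    RateObservation,
    RateSurface,
    Substitution,
    ci_prune,
    expected_variant_count,
    fill_gaps,
    fit_exponentials,
    observe_rates,
    select_subgraphs,
    smooth,
    weighted_average,
)
from snvgraph.preprocess import UniqueSequence
from snvgraph.variant_graph import Subgraph, build_graph, connected_subgraphs

AC = Substitution("A", "C")
AT = Substitution("A", "T")
GT = Substitution("G", "T")


def binom_quantile_oracle(q, n, p):
    """Smallest k with CDF(k) >= q, by direct pmf summation in log space."""
    log_pmf = math.log(max((1 - p) ** n, 5e-324))
    cdf = math.exp(log_pmf)
    k = 0
    while cdf < q and k < n:
        k += 1
        log_pmf += math.log((n - k + 1) / k) + math.log(p) - math.log(1 - p)
        cdf += math.exp(log_pmf)
    return k


def _sg(n_nodes, a_parent, a_total):
    return Subgraph(list(range(n_nodes)), 0, a_parent, a_total)


class TestSelectSubgraphs:
    @pytest.mark.parametrize(
        "a_parent,a_total,t,kept",
        [(90, 100, 90, True), (89, 100, 90, False), (95, 100, 90, True)],
    )
    def test_parental_ratio_boundary(self, a_parent, a_total, t, kept):
        sg = _sg(45, a_parent, a_total)
        got = select_subgraphs([sg], ModelConfig(), t)
        assert (got == [sg]) == kept

    def test_node_count_threshold(self):
        cfg = ModelConfig(min_subgraph_nodes=40)
        assert select_subgraphs([_sg(39, 99, 100)], cfg, 30) == []
        assert len(select_subgraphs([_sg(40, 99, 100)], cfg, 30)) == 1


class TestObserveRates:
    def test_child_estimate_follows_error_odds(self):
        # P = a_child / (a_child + a_parent), the only definition consistent
        # with N_error = P/(1-P) * N_correct
        g = build_graph([UniqueSequence("AAAA", 1000), UniqueSequence("AATA", 2)])
        (sg,) = connected_subgraphs(g)
        obs = observe_rates(sg, g)
        hit = [o for o in obs if o.estimate > 0]
        assert len(hit) == 1
        o = hit[0]
        assert (o.pos, o.sub, o.weight) == (3, AT, 1000)
        assert o.estimate == pytest.approx(2 / 1002)

    def test_childless_parent_emits_all_zero_observations(self):
        g = build_graph([UniqueSequence("ACGT", 500)])
        (sg,) = connected_subgraphs(g)
        obs = observe_rates(sg, g)
        assert len(obs) == 4 * 3  # every position, every alternative base
        assert all(o.estimate == 0.0 and o.weight == 500 for o in obs)

    def test_cells_cover_only_parent_compatible_substitutions(self):
        g = build_graph([UniqueSequence("AAAA", 10)])
        (sg,) = connected_subgraphs(g)
        assert {o.sub.r1 for o in observe_rates(sg, g)} == {"A"}


class TestWeightedAverage:
    def test_two_graph_pooling(self):
        obs = [
            RateObservation(5, AC, 0.01, 100, 0),
            RateObservation(5, AC, 0.02, 300, 1),
        ]
        assert weighted_average(obs).values[(5, AC)] == pytest.approx(0.0175)

    def test_single_observation_is_identity(self):
        obs = [RateObservation(2, GT, 0.003, 42, 0)]
        assert weighted_average(obs).values[(2, GT)] == 0.003

    def test_equal_estimates_any_weights(self):
        obs = [RateObservation(2, GT, 0.004, w, i) for i, w in enumerate([1, 10, 1000])]
        assert weighted_average(obs).values[(2, GT)] == pytest.approx(0.004)

    def test_bounded_by_input_range(self):
        rng = np.random.default_rng(0)
        obs = [
            RateObservation(3, AC, float(e), int(w), i)
            for i, (e, w) in enumerate(zip(rng.uniform(0, 0.01, 50), rng.integers(1, 9999, 50)))
        ]
        val = weighted_average(obs).values[(3, AC)]
        ests = [o.estimate for o in obs]
        assert min(ests) <= val <= max(ests)


class TestCiPrune:
    def test_outlier_above_binomial_upper_bound_is_pruned(self):
        # pooled rate ~2e-4 dominated by big graphs; a 1% estimate is far
        # above the 97.5th binomial percentile and must go
        obs = [RateObservation(4, AC, 2e-4, 50_000, i) for i in range(5)]
        obs.append(RateObservation(4, AC, 0.01, 10_000, 5))
        surface = weighted_average(obs)
        p = surface.values[(4, AC)]
        bound = binom_quantile_oracle(0.975, 10_000, p) / 10_000
        assert 0.01 > bound
        kept, pruned = ci_prune(obs, surface, ModelConfig())
        assert len(kept) == 5
        assert pruned.values[(4, AC)] == pytest.approx(2e-4)

    def test_observation_at_the_mean_is_retained(self):
        obs = [RateObservation(4, AC, 2e-4, 50_000, i) for i in range(3)]
        kept, _ = ci_prune(obs, weighted_average(obs), ModelConfig())
        assert len(kept) == 3

    def test_homogeneous_observations_are_a_fixed_point(self):
        obs = [RateObservation(p, AC, 1e-3, 20_000, i) for i, p in enumerate(range(1, 9))]
        surface = weighted_average(obs)
        kept, pruned = ci_prune(obs, surface, ModelConfig())
        assert kept == obs
        assert pruned.values == surface.values

    def test_prune_never_increases_cell_values(self):
        rng = np.random.default_rng(1)
        obs = [
            RateObservation(2, GT, float(rng.uniform(0, 2e-3)), int(rng.integers(1000, 99_000)), i)
            for i in range(40)
        ]
        surface = weighted_average(obs)
        _, pruned = ci_prune(obs, surface, ModelConfig())
        for key, val in pruned.values.items():
            assert val <= surface.values[key] + 1e-15


class TestSmooth:
    def test_spike_replaced_by_neighbour_average(self):
        surface = RateSurface({(2, AC): 1e-4, (3, AC): 5e-4, (4, AC): 1.2e-4})
        out = smooth(surface)
        assert out.values[(3, AC)] == pytest.approx(1.1e-4)

    def test_value_within_factor_two_untouched(self):
        surface = RateSurface({(2, AC): 1e-4, (3, AC): 2e-4, (4, AC): 1.2e-4})
        assert smooth(surface).values[(3, AC)] == 2e-4

    def test_flat_surface_is_fixed_point(self):
        surface = RateSurface({(p, GT): 3e-4 for p in range(2, 25)})
        assert smooth(surface).values == surface.values

    def test_smoothing_only_decreases_and_leaves_others_bit_identical(self):
        rng = np.random.default_rng(5)
        vals = {(p, AC): float(v) for p, v in zip(range(2, 25), rng.uniform(1e-5, 1e-3, 23))}
        out = smooth(RateSurface(dict(vals)))
        for key, v in out.values.items():
            assert v <= vals[key]

    def test_elevated_position_one_is_preserved(self):
        # the position-1 spike is a real platform feature, not an outlier
        surface = RateSurface({(1, AC): 2.8e-3, (2, AC): 4.3e-4, (3, AC): 4.6e-4})
        assert smooth(surface).values[(1, AC)] == 2.8e-3


class TestFillGaps:
    def test_highest_threshold_wins(self):
        s90 = RateSurface({(5, AC): 1e-4})
        s70 = RateSurface({(5, AC): 9e-4, (6, AC): 2e-4})
        merged = fill_gaps({90: s90, 70: s70})
        assert merged.values[(5, AC)] == 1e-4
        assert merged.provenance[(5, AC)] == 90
        assert merged.values[(6, AC)] == 2e-4
        assert merged.provenance[(6, AC)] == 70

    def test_cell_absent_everywhere_stays_a_gap(self):
        merged = fill_gaps({90: RateSurface({(5, AC): 1e-4})})
        assert (6, AC) not in merged.values


class TestFitExponentials:
    def test_exact_recovery_on_noiseless_exponential(self):
        A, b = 3.5e-4, 0.10
        surface = RateSurface(
            {(p, GT): A * math.exp(b * p) for p in range(2, 25)} | {(1, GT): 1.5e-3}
        )
        model = fit_exponentials(surface)
        fit = model.fits[GT]
        assert fit.A == pytest.approx(A, rel=1e-10)
        assert fit.b == pytest.approx(b, rel=1e-10)
        assert model.position1[GT] == 1.5e-3

    def test_negative_trend_allowed(self):
        surface = RateSurface({(p, GT): 7.7e-4 * math.exp(-0.13 * p) for p in range(2, 25)})
        assert fit_exponentials(surface).fits[GT].b == pytest.approx(-0.13, rel=1e-10)

    def test_constant_data_gives_flat_fit(self):
        surface = RateSurface({(p, AC): 5e-4 for p in range(2, 25)})
        fit = fit_exponentials(surface).fits[AC]
        assert fit.A == pytest.approx(5e-4, rel=1e-10)
        assert fit.b == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_cells_give_zero_model(self):
        surface = RateSurface({(p, AC): 0.0 for p in range(2, 25)})
        model = fit_exponentials(surface)
        assert model.fits[AC].A == 0.0
        assert model.rate(10, AC) == 0.0

    def test_single_positive_cell_is_insufficient(self):
        surface = RateSurface({(2, AC): 1e-4, (3, AC): 0.0})
        with pytest.raises(InsufficientDataError):
            fit_exponentials(surface)

    def test_model_evaluation_raw_at_one_fitted_beyond(self):
        surface = RateSurface(
            {(1, AC): 1.4e-3} | {(p, AC): 1.4e-4 * math.exp(0.11 * p) for p in range(2, 25)}
        )
        model = fit_exponentials(surface)
        assert model.rate(1, AC) == 1.4e-3
        assert model.rate(10, AC) == pytest.approx(1.4e-4 * math.exp(1.1), rel=1e-9)


class TestModelSerialization:
    def test_json_roundtrip(self, tmp_path, ga_model):
        path = tmp_path / "model.json"
        ga_model.to_json(path)
        back = ErrorModel.from_json(path)
        for sub in SUBSTITUTIONS:
            assert back.position1[sub] == ga_model.position1[sub]
            assert back.fits[sub].A == ga_model.fits[sub].A
            assert back.fits[sub].b == ga_model.fits[sub].b


class TestExpectedVariantCount:
    def test_no_reads_no_variants(self):
        assert expected_variant_count(0, 21, 0.0004) == 0.0

    def test_saturates_at_three_l(self):
        assert expected_variant_count(10**9, 21, 0.0004) == pytest.approx(63.0)

    def test_worked_value_single_read(self):
        assert expected_variant_count(1, 21, 0.0004) == pytest.approx(0.0252)
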