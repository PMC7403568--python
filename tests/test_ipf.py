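import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortcomp import ConvergenceError, MarginalSpec, ValidationError, ipf_fit
from cohortcomp.ipf import disaggregate_ages, group_label, parse_group_label
from cohortcomp.synthetic import generate_grouped_census_seed

from conftest import small_config
from cohortcomp.synthetic import generate_scenario


class TestIpfFit:
    def test_fixed_point_returned_unchanged(self):
        seed = np.array([[30.0, 30.0], [20.0, 20.0]])
        out = ipf_fit(seed, [MarginalSpec(0, [60, 40]), MarginalSpec(1, [50, 50])])
        np.testing.assert_allclose(out, seed, rtol=1e-10)

    def test_uniform_seed_proportional_allocation(self):
        out = ipf_fit(np.ones((2, 2)),
                      [MarginalSpec(0, [60, 40]), MarginalSpec(1, [50, 50])])
        np.testing.assert_allclose(out, [[30, 30], [20, 20]], rtol=1e-9)

    def test_two_by_two_odds_ratio_quadratic_oracle(self):
        # the fit preserves the seed odds ratio 1*4/(2*3) = 2/3; writing the
        # fitted table as [[a, 5-a], [4-a, 1+a]] gives a^2 + 21a - 40 = 0
        a = (-21 + np.sqrt(21 ** 2 + 4 * 40)) / 2
        expected = np.array([[a, 5 - a], [4 - a, 1 + a]])
        out = ipf_fit(np.array([[1.0, 2.0], [3.0, 4.0]]),
                      [MarginalSpec(0, [5, 5]), MarginalSpec(1, [4, 6])])
        np.testing.assert_allclose(out, expected, atol=5e-5)
        np.testing.assert_allclose(out, [[1.7577, 3.2423], [2.2423, 2.7577]],
                                   atol=5e-5)

    def test_structural_zeros_never_revived(self):
        seed = np.array([[0.0, 2.0], [3.0, 4.0]])
        out = ipf_fit(seed, [MarginalSpec(0, [4, 6]), MarginalSpec(1, [5, 5])])
        assert out[0, 0] == 0.0

    def test_infeasible_zero_slice_raises(self):
        seed = np.array([[0.0, 0.0], [3.0, 4.0]])
        with pytest.raises(ConvergenceError, match="marginal 0"):
            ipf_fit(seed, [MarginalSpec(0, [5, 5]), MarginalSpec(1, [4, 6])])

    def test_inconsistent_grand_totals_rejected(self):
        with pytest.raises(ValidationError, match="grand total"):
            ipf_fit(np.ones((2, 2)),
                    [MarginalSpec(0, [5, 5]), MarginalSpec(1, [4, 7])])

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_conservation_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.uniform(0.1, 5.0, size=(3, 4))
        rows = rng.uniform(1.0, 10.0, size=3)
        cols = rng.uniform(1.0, 10.0, size=4)
        cols *= rows.sum() / cols.sum()
        out = ipf_fit(table, [MarginalSpec(0, rows), MarginalSpec(1, cols)])
        assert np.all(out >= 0)
        assert out.sum() == pytest.approx(rows.sum(), rel=1e-8)
        np.testing.assert_allclose(out.sum(axis=1), rows, rtol=1e-7)
        np.testing.assert_allclose(out.sum(axis=0), cols, rtol=1e-7)

    def test_three_axis_marginals(self):
        rng = np.random.default_rng(5)
        truth = rng.uniform(0.5, 3.0, size=(3, 2, 4))
        specs = [MarginalSpec(0, truth.sum(axis=(1, 2))),
                 MarginalSpec(1, truth.sum(axis=(0, 2))),
                 MarginalSpec((0, 2), truth.sum(axis=1))]
        out = ipf_fit(rng.uniform(0.5, 3.0, size=truth.shape), specs)
        np.testing.assert_allclose(out.sum(axis=(1, 2)), truth.sum(axis=(1, 2)),
                                   rtol=1e-7)
        np.testing.assert_allclose(out.sum(axis=1), truth.sum(axis=1), rtol=1e-6)


class TestGroupLabels:
    @pytest.mark.parametrize("label, expected", [
        ("0-4", (0, 4)), ("95-99", (95, 99)), ("100+", (100, None)),
    ])
    def test_round_trip(self, label, expected):
        assert parse_group_label(label) == expected
        assert group_label(*expected) == label


class TestDisaggregateAges:
    def _tables(self, bundle, sigma):
        return generate_grouped_census_seed(bundle, group_width=5, sigma=sigma)

    def test_uniform_seed_splits_group_total_evenly(self):
        import pandas as pd
        seed = pd.DataFrame([("A", "female", str(a), 1.0) for a in range(5)]
                            + [("A", "female", "5+", 1.0)]
                            + [("A", "male", str(a), 1.0) for a in range(5)]
                            + [("A", "male", "5+", 1.0)],
                            columns=["birthplace", "sex", "age", "count"])
        grouped = pd.DataFrame(
            [("A", s, "0-4", 100.0) for s in ("female", "male")]
            + [("A", s, "5+", 20.0) for s in ("female", "male")],
            columns=["birthplace", "sex", "age_group", "count"])
        grid = disaggregate_ages(grouped, seed, reference_year=2016)
        np.testing.assert_allclose(grid.counts[0, :, :5], 20.0, rtol=1e-9)

    def test_single_group_proportional_scaling(self):
        import pandas as pd
        pattern = [10.0, 20.0, 30.0, 20.0, 20.0]
        seed = pd.DataFrame(
            [("A", s, str(a), v) for s in ("female", "male")
             for a, v in enumerate(pattern + [1.0])],
            columns=["birthplace", "sex", "age", "count"])
        grouped = pd.DataFrame(
            [("A", s, "0-4", 200.0) for s in ("female", "male")]
            + [("A", s, "5+", 2.0) for s in ("female", "male")],
            columns=["birthplace", "sex", "age_group", "count"])
        grid = disaggregate_ages(grouped, seed, reference_year=2016)
        np.testing.assert_allclose(grid.counts[0, 0, :5],
                                   [20, 40, 60, 40, 40], rtol=1e-9)

    def test_noiseless_seed_recovers_truth_exactly(self, bundle):
        grouped, seed = self._tables(bundle, sigma=0.0)
        grid = disaggregate_ages(grouped, seed, bundle.jump_off.reference_year)
        truth = bundle.jump_off.counts
        np.testing.assert_allclose(grid.counts, truth, rtol=1e-10, atol=1e-12)

    def test_group_totals_always_honoured(self, bundle):
        grouped, seed = self._tables(bundle, sigma=0.08)
        grid = disaggregate_ages(grouped, seed, bundle.jump_off.reference_year)
        # every 5-year band must sum to the published group total
        truth = bundle.jump_off.counts
        for lo in range(0, bundle.jump_off.top_age, 5):
            np.testing.assert_allclose(
                grid.counts[:, :, lo:lo + 5].sum(axis=2),
                truth[:, :, lo:lo + 5].sum(axis=2), rtol=1e-7)

    def test_recovery_error_bounded_by_noise(self):
        # mean absolute relative error of the IPF-recovered single-year
        # counts stays below the seed noise scale
        sigma = 0.1
        for seed_val in (0, 1, 2):
            bundle = generate_scenario(small_config(seed=seed_val))
            grouped, seed = generate_grouped_census_seed(bundle, 5, sigma)
            grid = disaggregate_ages(grouped, seed,
                                     bundle.jump_off.reference_year)
            truth = bundle.jump_off.counts
            mask = truth > 0
            mare = np.mean(np.abs(grid.counts[mask] - truth[mask]) / truth[mask])
            assert mare <= sigma
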