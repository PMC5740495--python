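import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ntrprox as nx
from ntrprox.iofmt import IntensityMatrix, ProteinRecord
from ntrprox.preprocess import (
    ContractError,
    ImputationError,
    MissingClass,
    classify_missing,
    impute_mar,
    impute_mnar,
    merge_technical,
    merged_runs_for_line,
    prepare_comparison,
    quantile_normalize,
)


def make_matrix(values, design=None, runs=None, uniq=None, scale="log2"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    runs = runs or (design.run_ids if design else
                    [f"r{j}" for j in range(m)])
    proteins = [
        ProteinRecord(group_id=f"P{i}", unique_peptides=(uniq or {}).get(i, 2))
        for i in range(n)
    ]
    return IntensityMatrix(proteins=proteins, runs=runs, values=values,
                           observed=np.isfinite(values), scale=scale)


@pytest.fixture
def two_line_design():
    cfg = nx.SimulationConfig(n_proteins=4, n_ntrs=1, n_controls=1,
                              n_bio=4, n_tech=2, cargo_fraction=0.0,
                              control_fraction=0.0, n_complexes=0,
                              complex_size=0, seed=0)
    return nx.generate_design(cfg)


M = np.nan


class TestFilterIdentifications:
    def test_three_bio_reps_of_one_line_retained(self, two_line_design):
        # observed in bio reps 1-3 of NTR01 (first technical replicate only)
        row = [20, M, 20, M, 20, M, M, M] + [M] * 8
        m = make_matrix([row], design=two_line_design)
        out = nx.filter_identifications(m, two_line_design, min_bio=3)
        assert out.group_ids == ["P0"]

    def test_single_unique_peptide_removed(self, two_line_design):
        row = [20] * 16
        m = make_matrix([row], design=two_line_design, uniq={0: 1})
        out = nx.filter_identifications(m, two_line_design, min_unique=2)
        assert out.group_ids == []

    def test_two_bio_reps_everywhere_removed(self, two_line_design):
        row = [20, 20, 20, 20, M, M, M, M] * 2  # 2 bio reps per line
        m = make_matrix([row], design=two_line_design)
        out = nx.filter_identifications(m, two_line_design, min_bio=3)
        assert out.group_ids == []

    def test_min_bio_beyond_design_is_error(self, two_line_design):
        m = make_matrix([[20] * 16], design=two_line_design)
        with pytest.raises(ContractError):
            nx.filter_identifications(m, two_line_design, min_bio=5)


class TestMergeTechnical:
    def test_mean_of_observed(self, two_line_design):
        row = [10.0, 12.0] + [20.0] * 14
        m = make_matrix([row], design=two_line_design)
        out = merge_technical(m, two_line_design)
        assert out.values[0, 0] == pytest.approx(11.0)

    def test_one_missing_keeps_other(self, two_line_design):
        row = [10.0, M] + [20.0] * 14
        m = make_matrix([row], design=two_line_design)
        out = merge_technical(m, two_line_design)
        assert out.values[0, 0] == pytest.approx(10.0)

    def test_all_missing_stays_missing(self, two_line_design):
        row = [M, M] + [20.0] * 14
        m = make_matrix([row], design=two_line_design)
        out = merge_technical(m, two_line_design)
        assert not out.observed[0, 0]


class TestClassifyMissing:
    @pytest.mark.parametrize("obs_a,obs_b,expected", [
        (4, 0, MissingClass.MNAR),
        (0, 4, MissingClass.MNAR),
        (4, 1, MissingClass.MNAR),
        (3, 1, MissingClass.MNAR),
        (3, 3, MissingClass.MAR),
        (4, 4, MissingClass.COMPLETE),
        (2, 2, MissingClass.EXCLUDED),
        (4, 2, MissingClass.EXCLUDED),
        (4, 3, MissingClass.EXCLUDED),
        (2, 1, MissingClass.EXCLUDED),
    ])
    def test_quadruplicate_rules(self, obs_a, obs_b, expected):
        assert classify_missing(obs_a, obs_b, n_per_group=4) is expected

    @given(a=st.integers(0, 4), b=st.integers(0, 4))
    @settings(deadline=None)
    def test_symmetry(self, a, b):
        assert classify_missing(a, b) is classify_missing(b, a)

    def test_out_of_range_count_is_error(self):
        with pytest.raises(ContractError):
            classify_missing(5, 0, n_per_group=4)

    def test_unequal_groups_reduce_sensibly(self):
        # NTR quadruplicate vs pooled 16-replicate control set
        assert classify_missing(4, 16, 4, 16) is MissingClass.COMPLETE
        assert classify_missing(4, 2, 4, 16) is MissingClass.MNAR
        assert classify_missing(1, 14, 4, 16) is MissingClass.MNAR
        assert classify_missing(3, 15, 4, 16) is MissingClass.MAR
        assert classify_missing(4, 15, 4, 16) is MissingClass.EXCLUDED


class TestImputeMnar:
    def test_column_minimum_used(self):
        vals = np.array([[18.1, 20.0], [20.3, 21.0],
                         [25.0, 22.0], [np.nan, 23.0]])
        obs = np.isfinite(vals)
        targets = ~obs
        out = impute_mnar(vals, obs, targets)
        assert out[3, 0] == pytest.approx(18.1)

    def test_two_cells_same_column_identical(self):
        vals = np.array([[18.1], [np.nan], [np.nan], [20.0]])
        obs = np.isfinite(vals)
        out = impute_mnar(vals, obs, ~obs)
        assert out[1, 0] == out[2, 0] == pytest.approx(18.1)

    def test_imputed_not_above_observed(self, rng):
        vals = rng.normal(20, 2, size=(30, 4))
        obs = rng.random((30, 4)) > 0.2
        vals = np.where(obs, vals, np.nan)
        out = impute_mnar(vals, obs, ~obs)
        for j in range(4):
            assert (out[~obs[:, j], j] <= vals[obs[:, j], j].min() + 1e-12).all()

    def test_empty_column_is_error(self):
        vals = np.array([[np.nan], [np.nan]])
        obs = np.isfinite(vals)
        with pytest.raises(ImputationError):
            impute_mnar(vals, obs, ~obs)


class TestImputeMar:
    def test_identity_neighbour_copied(self):
        vals = np.array([[10.0, 11.0, 12.0, np.nan],
                         [10.0, 11.0, 12.0, 13.0],
                         [30.0, 31.0, 32.0, 40.0]])
        obs = np.isfinite(vals)
        out = impute_mar(vals, obs, ~obs, k=1)
        assert out[0, 3] == pytest.approx(13.0)

    def test_k_saturates_to_all_eligible(self):
        vals = np.array([[10.0, np.nan],
                         [10.0, 20.0],
                         [10.0, 30.0]])
        obs = np.isfinite(vals)
        out = impute_mar(vals, obs, ~obs, k=50)
        assert out[0, 1] == pytest.approx(25.0)

    def test_mask_and_recover_within_two_sigma(self):
        """Deleting observed cells from a complete synthetic matrix and
        re-imputing them lands within 2 sigma_b of the original."""
        sigma_b = 0.5
        rng = np.random.default_rng(42)
        n, n_del = 600, 500
        base = rng.normal(25, 2, size=n)
        vals = base[:, None] + rng.normal(0, sigma_b, size=(n, 8))
        rows = rng.choice(n, size=n_del, replace=False)  # one deletion per row
        cols = rng.integers(0, 8, size=n_del)
        truth_vals = vals[rows, cols].copy()
        masked = vals.copy()
        masked[rows, cols] = np.nan
        obs = np.isfinite(masked)
        out = impute_mar(masked, obs, ~obs, k=10)
        err = out[rows, cols] - truth_vals
        assert np.mean(np.abs(err) <= 2 * sigma_b) > 0.9


class TestQuantileNormalize:
    def test_hand_example(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = quantile_normalize(vals)
        np.testing.assert_allclose(out, [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0])
        vals = np.column_stack([col, col, col])
        np.testing.assert_allclose(quantile_normalize(vals), vals)

    def test_sorted_columns_identical(self, rng):
        vals = rng.normal(size=(50, 6))
        out = quantile_normalize(vals)
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_missing_values_rejected(self):
        vals = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ContractError):
            quantile_normalize(vals)


class TestPrepareComparison:
    def test_no_missing_values_remain(self):
        cfg = nx.SimulationConfig(n_proteins=300, n_ntrs=2, n_controls=1,
                                  n_bio=4, n_tech=2, cargo_fraction=0.1,
                                  control_fraction=0.0, n_complexes=0,
                                  complex_size=0, seed=5)
        design = nx.generate_design(cfg)
        truth = nx.generate_truth(cfg)
        m = nx.generate_intensities(design, truth, cfg)
        merged = merge_technical(m, design)
        comp = prepare_comparison(
            merged, merged_runs_for_line(design, "NTR01"),
            merged_runs_for_line(design, "NTR02"))
        assert np.isfinite(comp.values_a).all()
        assert np.isfinite(comp.values_b).all()
        assert (comp.classes != MissingClass.EXCLUDED).all()
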