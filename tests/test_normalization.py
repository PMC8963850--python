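"""Quantile normalization, median-of-ratios size factors and ΔCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sorasig.cohort import Platform
from sorasig.errors import DataError
from sorasig.normalization import (
    ExpressionMatrix,
    HousekeepingSet,
    delta_ct,
    quantile_normalize,
    size_factor_normalize,
)

from conftest import make_matrix


def _microarray(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return make_matrix(values, genes, samples, Platform.MICROARRAY, normalized=False)


class TestQuantileNormalize:
    def test_two_column_reference(self):
        out = quantile_normalize(_microarray([[1, 4], [2, 5], [3, 6]]))
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.data.to_numpy(), expected)
        assert out.normalized

    def test_identical_columns_fixed_point(self):
        m = _microarray([[1, 1], [5, 5], [3, 3]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.data.to_numpy(), m.data.to_numpy())

    def test_permuted_column_maps_to_same_permutation(self):
        m = _microarray([[1, 3], [2, 1], [3, 2]])
        out = quantile_normalize(m).data.to_numpy()
        # column 1 is a cyclic permutation of column 0; outputs must match it
        np.testing.assert_allclose(np.sort(out[:, 0]), np.sort(out[:, 1]))
        assert out[0, 0] < out[1, 0] < out[2, 0]
        assert out[1, 1] < out[2, 1] < out[0, 1]

    def test_ties_get_mean_of_spanned_reference_values(self):
        # column 0 has a 2-way tie at the two lowest ranks
        out = quantile_normalize(_microarray([[1, 10], [1, 20], [5, 30]]))
        ref = np.array([(1 + 10) / 2, (1 + 20) / 2, (5 + 30) / 2])
        np.testing.assert_allclose(out.data.iloc[:, 0], [ref[:2].mean(), ref[:2].mean(), ref[2]])
        np.testing.assert_allclose(out.data.iloc[:, 1], ref)

    def test_double_normalization_rejected(self):
        with pytest.raises(DataError, match="already normalized"):
            quantile_normalize(quantile_normalize(_microarray([[1, 2], [3, 4]])))

    def test_wrong_platform_rejected(self):
        counts = make_matrix([[1, 2], [3, 4]], ["a", "b"], ["s1", "s2"],
                             Platform.RNASEQ_COUNTS, normalized=False)
        with pytest.raises(DataError, match="microarray"):
            quantile_normalize(counts)

    @given(
        arrays(
            float, (6, 4),
            elements=st.floats(min_value=0.1, max_value=1e4, allow_nan=False),
            unique=True,  # the exact multiset identity holds for tie-free columns
        )
    )
    def test_columns_share_sorted_multiset_and_grand_mean(self, values):
        out = quantile_normalize(_microarray(values)).data.to_numpy()
        cols = [np.sort(out[:, j]) for j in range(out.shape[1])]
        for col in cols[1:]:
            np.testing.assert_allclose(col, cols[0], rtol=1e-12)
        np.testing.assert_allclose(out.mean(), np.asarray(values).mean(), rtol=1e-9)

    def test_grand_mean_preserved_with_ties(self):
        values = np.array([[1.0, 7.0], [1.0, 3.0], [4.0, 3.0], [9.0, 2.0]])
        out = quantile_normalize(_microarray(values)).data.to_numpy()
        # tie groups receive the mean of the spanned reference values, so
        # column sums (hence the grand mean) are still preserved exactly
        np.testing.assert_allclose(out.mean(), values.mean(), rtol=1e-12)


def _counts(values):
    values = np.asarray(values, dtype=float)
    return make_matrix(values, [f"g{i}" for i in range(values.shape[0])],
                       [f"s{j}" for j in range(values.shape[1])],
                       Platform.RNASEQ_COUNTS, normalized=False)


class TestSizeFactors:
    def test_two_sample_hand_computation(self):
        normalized, factors = size_factor_normalize(_counts([[10, 20], [20, 40], [30, 60]]))
        np.testing.assert_allclose(factors, [1 / np.sqrt(2), np.sqrt(2)])
        expected = np.array([10, 20, 30]) * np.sqrt(2)
        np.testing.assert_allclose(normalized.data.iloc[:, 0], expected)
        np.testing.assert_allclose(normalized.data.iloc[:, 1], expected)

    def test_identical_columns_give_unit_factors(self):
        normalized, factors = size_factor_normalize(_counts([[5, 5], [9, 9], [2, 2]]))
        np.testing.assert_allclose(factors, [1.0, 1.0])
        np.testing.assert_allclose(normalized.data.to_numpy(),
                                   [[5, 5], [9, 9], [2, 2]])

    def test_scale_equivariance_is_exact_in_relative_terms(self, rng):
        # scaling one of m samples by λ moves its factor by λ^((m-1)/m)
        # and every other factor by λ^(-1/m): the *ratio* to any other
        # sample scales by exactly λ, and normalized values change only
        # by a common global constant λ^(1/m)
        base = rng.integers(1, 500, size=(30, 4)).astype(float)
        doubled = base.copy()
        doubled[:, 2] *= 2
        norm1, f_base = size_factor_normalize(_counts(base))
        norm2, f_doubled = size_factor_normalize(_counts(doubled))
        ratio_base = f_base.iloc[2] / f_base.iloc[0]
        ratio_doubled = f_doubled.iloc[2] / f_doubled.iloc[0]
        np.testing.assert_allclose(ratio_doubled, 2 * ratio_base, rtol=1e-12)
        np.testing.assert_allclose(f_doubled.iloc[2], 2 ** (3 / 4) * f_base.iloc[2], rtol=1e-12)
        scale = norm2.data.to_numpy() / norm1.data.to_numpy()
        np.testing.assert_allclose(scale, 2 ** (1 / 4), rtol=1e-12)

    def test_zero_heavy_matrix_errors(self):
        with pytest.raises(DataError, match="pseudocount"):
            size_factor_normalize(_counts([[0, 5], [3, 0]]))

    def test_agrees_with_pydeseq2(self, rng):
        from pydeseq2.preprocessing import deseq2_norm

        counts = rng.negative_binomial(10, 0.3, size=(50, 6)).astype(float)
        counts[:5] = 0  # some all-zero genes must be ignored
        counts[5:] += 1  # ensure a positive core
        _, factors = size_factor_normalize(_counts(counts))
        _, ref = deseq2_norm(pd.DataFrame(counts.T))  # pydeseq2 is samples x genes
        np.testing.assert_allclose(factors.to_numpy(), np.asarray(ref), rtol=1e-10)


def _ct(values, genes):
    values = np.asarray(values, dtype=float)
    return make_matrix(values, genes, [f"s{j}" for j in range(values.shape[1])],
                       Platform.PCR_CT, normalized=False)


class TestDeltaCt:
    def test_constant_housekeeping(self):
        ct = _ct([[20.0], [20.0], [18.0]], ["HK1", "HK2", "T"])
        out = delta_ct(ct, ["HK1", "HK2"])
        assert out.data.loc["T"].iloc[0] == pytest.approx(2.0)

    def test_geometric_mean_not_arithmetic(self):
        ct = _ct([[16.0], [25.0], [22.0]], ["HK1", "HK2", "T"])
        out = delta_ct(ct, ["HK1", "HK2"])
        # geometric mean of 16 and 25 is 20, so ΔCt = 20 - 22 = -2
        assert out.data.loc["T"].iloc[0] == pytest.approx(-2.0)

    def test_target_at_reference_level_is_zero(self):
        ct = _ct([[16.0], [25.0], [20.0]], ["HK1", "HK2", "T"])
        assert delta_ct(ct, ["HK1", "HK2"]).data.loc["T"].iloc[0] == pytest.approx(0.0)

    def test_missing_housekeeping_listed(self):
        ct = _ct([[20.0], [18.0]], ["HK1", "T"])
        with pytest.raises(DataError, match="HK9"):
            delta_ct(ct, ["HK1", "HK9"])

    def test_uniform_shift_cancels_only_if_applied_to_all_genes(self, rng):
        genes = ["HK1", "HK2", "HK3", "T1", "T2"]
        values = rng.uniform(18, 28, size=(5, 4))
        base = delta_ct(_ct(values, genes), ["HK1", "HK2", "HK3"])
        shifted_all = delta_ct(_ct(values + 1.7, genes), ["HK1", "HK2", "HK3"])
        # additive shift moves the geometric (not arithmetic) mean by
        # slightly less than the shift, so cancellation is approximate
        np.testing.assert_allclose(
            shifted_all.data.to_numpy(), base.data.to_numpy(), atol=0.06
        )
        shifted_targets = values.copy()
        shifted_targets[3:] += 1.7
        moved = delta_ct(_ct(shifted_targets, genes), ["HK1", "HK2", "HK3"])
        assert np.all(np.abs(moved.data.to_numpy() - base.data.to_numpy()) > 1.0)

    def test_housekeeping_set_validation(self):
        with pytest.raises(DataError):
            HousekeepingSet(())
        with pytest.raises(DataError):
            HousekeepingSet(("ACTB", "ACTB"))


def test_expression_matrix_invariants():
    with pytest.raises(DataError, match="duplicate gene"):
        make_matrix([[1, 2], [3, 4]], ["a", "a"], ["s1", "s2"])
    with pytest.raises(DataError, match="non-negative"):
        make_matrix([[-1, 2]], ["a"], ["s1", "s2"], Platform.RNASEQ_COUNTS, normalized=False)
    with pytest.raises(DataError, match="positive cycle"):
        make_matrix([[0.0, 20.0]], ["a"], ["s1", "s2"], Platform.PCR_CT, normalized=False)
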