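import numpy as np
import pandas as pd
import pytest

from cyclinpair.core_io import CohortError, ExpressionMatrix, ProbeAnnotation
from cyclinpair.preprocess import (
    average_technical_replicates,
    center_batches,
    collapse_probes_to_genes,
    filter_low_expression,
    quantile_normalize,
    size_factor_normalize,
)


def _matrix(data, index=None, columns=None, **kw):
    frame = pd.DataFrame(data, index=index, columns=columns, dtype=float)
    return ExpressionMatrix(frame, **kw)


class TestQuantileNormalize:
    def test_two_sample_hand_calculation(self):
        # sorted means: (1+2)/2 = 1.5, (3+4)/2 = 3.5
        m = _matrix({"A": [1.0, 3.0], "B": [4.0, 2.0]}, index=["f1", "f2"])
        out = quantile_normalize(m)
        assert out.values["A"].tolist() == [1.5, 3.5]
        assert out.values["B"].tolist() == [3.5, 1.5]

    def test_single_sample_unchanged(self):
        m = _matrix({"A": [2.0, 5.0, 3.0]})
        out = quantile_normalize(m)
        np.testing.assert_array_equal(out.values.to_numpy(), m.values.to_numpy())

    def test_sorted_columns_identical_after(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(8, 2, size=(50, 6)))
        out = quantile_normalize(m).values.to_numpy()
        sorted_cols = np.sort(out, axis=0)
        np.testing.assert_allclose(sorted_cols, sorted_cols[:, [0]] @ np.ones((1, 6)))

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(8, 2, size=(40, 5)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-9
        )

    def test_ties_get_mean_of_target_quantiles(self):
        m = _matrix({"A": [1.0, 1.0, 5.0], "B": [2.0, 3.0, 4.0]})
        out = quantile_normalize(m)
        # target = ((1,2,5)... sorted means: (1.5, 2.0, 4.5); A ties share (1.5+2)/2
        a = out.values["A"]
        assert a.iloc[0] == a.iloc[1] == pytest.approx(1.75)

    def test_single_feature_warns_and_passes_through(self):
        m = _matrix({"A": [1.0], "B": [4.0]})
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        np.testing.assert_array_equal(out.values.to_numpy(), m.values.to_numpy())


class TestReplicatesAndCollapse:
    def test_replicate_rows_averaged(self):
        m = _matrix({"s1": [5.0, 7.0, 2.0]}, index=["p1", "p1_r2", "p2"])
        ann = ProbeAnnotation(
            pd.DataFrame(
                {
                    "probe_id": ["p1", "p1_r2", "p2"],
                    "gene_symbol": ["G1", "G1", "G2"],
                    "replicate_group": ["p1", "p1", "p2"],
                }
            )
        )
        out, out_ann = average_technical_replicates(m, ann)
        assert out.values.loc["p1", "s1"] == 6.0
        assert out.values.loc["p2", "s1"] == 2.0  # singleton passthrough
        assert len(out_ann.table) == 2

    def test_three_replicates(self):
        m = _matrix({"s1": [4.0, 5.0, 6.0]}, index=["p1", "p1_r2", "p1_r3"])
        ann = ProbeAnnotation(
            pd.DataFrame(
                {
                    "probe_id": ["p1", "p1_r2", "p1_r3"],
                    "gene_symbol": ["G1"] * 3,
                    "replicate_group": ["p1"] * 3,
                }
            )
        )
        out, _ = average_technical_replicates(m, ann)
        assert out.values.loc["p1", "s1"] == 5.0

    def test_collapse_probes_to_gene_mean(self):
        m = _matrix(
            {"s1": [6.0, 8.0, 3.0], "s2": [1.0, 3.0, 5.0]},
            index=["p1", "p2", "p3"],
        )
        m = ExpressionMatrix(m.values, level="probe")
        ann = ProbeAnnotation(
            pd.DataFrame(
                {
                    "probe_id": ["p1", "p2", "p3"],
                    "gene_symbol": ["G1", "G1", "G2"],
                }
            )
        )
        out = collapse_probes_to_genes(m, ann)
        assert out.level == "gene"
        assert out.values.shape[0] == 2
        assert out.values.loc["G1", "s1"] == 7.0
        assert out.values.loc["G2", "s2"] == 5.0

    def test_unmapped_probes_dropped(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [6.0, 8.0]}, index=["p1", "px"]), level="probe"
        )
        ann = ProbeAnnotation(
            pd.DataFrame({"probe_id": ["p1"], "gene_symbol": ["G1"]})
        )
        out = collapse_probes_to_genes(m, ann)
        assert out.feature_ids == ["G1"]


class TestIntensityFilter:
    @pytest.mark.parametrize(
        "mean,kept", [(4.9, False), (5.0, True), (5.1, True)]
    )
    def test_threshold_boundary(self, mean, kept):
        m = _matrix({"s1": [mean, 9.0], "s2": [mean, 9.0]}, index=["G1", "G2"])
        out, removed = filter_low_expression(m, threshold=5.0)
        assert ("G1" in out.feature_ids) is kept
        assert ("G1" in removed) is not kept

    def test_all_removed_is_error(self):
        m = _matrix({"s1": [1.0], "s2": [2.0]}, index=["G1"])
        with pytest.raises(CohortError):
            filter_low_expression(m, threshold=5.0)

    def test_collapse_then_filter_commutes_for_one_to_one_mapping(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(
            rng.normal(5, 1, size=(20, 4)), index=[f"p{i}" for i in range(20)]
        )
        probes = ProbeAnnotation(
            pd.DataFrame(
                {
                    "probe_id": values.index,
                    "gene_symbol": [f"G{i}" for i in range(20)],
                }
            )
        )
        m = ExpressionMatrix(values, level="probe")
        a, _ = filter_low_expression(collapse_probes_to_genes(m, probes))
        collapsed = collapse_probes_to_genes(m, probes)
        b, _ = filter_low_expression(collapsed)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestSizeFactors:
    def test_identical_samples_have_unit_factors(self):
        m = _matrix({"s1": [10, 20, 30], "s2": [10, 20, 30]}, scale="count")
        out = size_factor_normalize(m)
        np.testing.assert_allclose(out.size_factors_.to_numpy(), [1.0, 1.0])

    def test_doubled_sample_gets_sqrt2_factors(self):
        m = _matrix({"A": [10, 20, 40], "B": [20, 40, 80]}, scale="count")
        out = size_factor_normalize(m)
        np.testing.assert_allclose(
            out.size_factors_.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )
        # depth-normalized values coincide
        pd.testing.assert_series_equal(
            out.values["A"], out.values["B"], check_names=False
        )

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(50, size=(200, 3)).astype(float) + 1
        m = _matrix(counts, scale="count")
        base = size_factor_normalize(m).size_factors_
        scaled = counts.copy()
        scaled[:, 1] *= 5
        m2 = _matrix(scaled, scale="count")
        factors = size_factor_normalize(m2).size_factors_
        ratio = factors.iloc[1] / base.iloc[1]
        # geometric-mean reference moves too: factor ratio is 5 / 5**(1/3)
        assert ratio == pytest.approx(5 / 5 ** (1 / 3), rel=1e-9)

    def test_all_zero_row_sample_is_error(self):
        m = _matrix({"s1": [0, 0], "s2": [3, 0]}, scale="count")
        with pytest.raises(CohortError, match="nonzero"):
            size_factor_normalize(m)


def test_batch_centering_aligns_batch_means():
    values = pd.DataFrame(
        {"s1": [1.0, 2.0], "s2": [3.0, 4.0], "s3": [11.0, 12.0], "s4": [13.0, 14.0]},
        index=["G1", "G2"],
    )
    m = ExpressionMatrix(values)
    batches = pd.Series(["b1", "b1", "b2", "b2"], index=values.columns)
    out = center_batches(m, batches).values
    for gene in ("G1", "G2"):
        assert out.loc[gene, ["s1", "s2"]].mean() == pytest.approx(
            out.loc[gene, ["s3", "s4"]].mean()
        )
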