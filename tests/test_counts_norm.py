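import numpy as np
import pandas as pd
import pytest

from circlife.core_io import CountMatrix, SampleSheet
from circlife.counts_norm import (
    brain_head_ratio,
    circ_linear_ratio,
    combine_matrices,
    count_expressed_isoforms,
    filter_aging_circrnas,
    filter_temperature_circrnas,
    normalize_counts,
    quantile_shares,
    size_factors_median_of_ratios,
)
from circlife.synthetic_data import aging_annotations


def _matrix(values, index=None, columns=None, kind="circ", normalized=False):
    df = pd.DataFrame(values, index=index, columns=columns)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df, kind=kind, normalized=normalized)


class TestSizeFactors:
    def test_hand_example(self):
        sf = size_factors_median_of_ratios(_matrix([[10, 20], [30, 60]]))
        assert sf.iloc[0] == pytest.approx(0.7071, abs=1e-4)
        assert sf.iloc[1] == pytest.approx(1.4142, abs=1e-4)

    def test_identical_samples_give_unit_factors(self):
        sf = size_factors_median_of_ratios(_matrix([[5, 5, 5], [9, 9, 9]]))
        assert np.allclose(sf, 1.0)

    def test_column_scaling_equivariance(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(100, size=(40, 4)) + 1
        sf1 = size_factors_median_of_ratios(_matrix(base))
        scaled = base.astype(float).copy()
        scaled[:, 2] *= 3.0
        sf2 = size_factors_median_of_ratios(
            CountMatrix(pd.DataFrame(scaled, index=[str(i) for i in range(40)]),
                        kind="circ", normalized=True))
        ratio = (sf2 / sf1.to_numpy()).to_numpy()
        assert ratio[2] / ratio[0] == pytest.approx(3.0, rel=1e-9)

    def test_rank_one_matrix_recovers_column_scales(self):
        rng = np.random.default_rng(2)
        reference = rng.uniform(10, 1000, size=200)
        scales = np.array([0.5, 1.0, 2.0, 3.5])
        values = np.outer(reference, scales)
        sf = size_factors_median_of_ratios(
            CountMatrix(pd.DataFrame(values, index=[str(i) for i in range(200)]),
                        kind="circ", normalized=True))
        expected = scales / np.exp(np.mean(np.log(scales)))
        assert np.allclose(sf.to_numpy(), expected, atol=1e-9)

    def test_error_when_no_feature_in_all_samples(self):
        with pytest.raises(ValueError, match="pre-filter"):
            size_factors_median_of_ratios(_matrix([[0, 5], [5, 0]]))

    def test_normalization_divides_by_factors(self):
        m = _matrix([[10, 20], [30, 60]])
        sf = size_factors_median_of_ratios(m)
        norm = normalize_counts(m, sf)
        assert norm.normalized
        assert np.allclose(norm.values.to_numpy()[:, 0] * sf.iloc[0],
                           m.values.to_numpy()[:, 0])

    def test_matches_independent_deseq2_implementation(self):
        """Cross-check against pydeseq2's size-factor computation."""
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(3)
        counts = rng.poisson(rng.uniform(5, 500, size=(60, 1)), size=(60, 6)).T
        meta = pd.DataFrame({"condition": ["a"] * 3 + ["b"] * 3},
                            index=[f"s{i}" for i in range(6)])
        dds = DeseqDataSet(counts=pd.DataFrame(counts, index=meta.index),
                           metadata=meta, design="~condition", quiet=True)
        dds.fit_size_factors()
        mine = size_factors_median_of_ratios(
            _matrix(counts.T, index=[str(i) for i in range(60)], columns=meta.index))
        assert np.allclose(mine.to_numpy(), dds.obs["size_factors"].to_numpy(), rtol=1e-6)


class TestAgingFilter:
    @pytest.fixture
    def sheet(self):
        rows = [
            {"sample_id": f"s{age}_{rep}", "age_days": age, "sex": "female",
             "condition": "aging", "replicate": rep, "tissue": "head"}
            for age in (0, 10, 20) for rep in (1, 2)
        ]
        return SampleSheet(pd.DataFrame(rows))

    def _run(self, counts_rows, lengths, sheet):
        ids = [f"c{i}" for i in range(len(counts_rows))]
        m = _matrix(counts_rows, index=ids, columns=sheet.sample_ids)
        truth = pd.DataFrame({"host_gene": "g"}, index=ids)
        anns = aging_annotations(truth)
        anns = [
            type(a)(**{**a.__dict__, "length_nt": lengths[i]})
            for i, a in enumerate(anns)
        ]
        retained, log = filter_aging_circrnas(m, anns, sheet)
        return retained, log

    def test_short_circrna_removed_regardless_of_counts(self, sheet):
        retained, _ = self._run([[100] * 6], [49], sheet)
        assert retained == []
        retained, _ = self._run([[100] * 6], [50], sheet)
        assert retained == ["c0"]

    def test_single_sample_with_ten_reads_suffices(self, sheet):
        counts = [[0, 0, 0, 0, 0, 10]]
        retained, _ = self._run(counts, [300], sheet)
        assert retained == ["c0"]
        counts = [[0, 0, 0, 0, 0, 9]]
        retained, _ = self._run(counts, [300], sheet)
        assert retained == []

    def test_mean_one_at_every_age_suffices(self, sheet):
        counts = [[1, 1, 1, 1, 1, 1]]  # per-age means all 1.0, max < 10
        retained, _ = self._run(counts, [300], sheet)
        assert retained == ["c0"]
        counts = [[1, 1, 1, 1, 0, 1]]  # one age mean 0.5
        retained, _ = self._run(counts, [300], sheet)
        assert retained == []

    def test_order_invariance(self, sheet):
        counts = [[0, 0, 0, 0, 0, 10], [1, 1, 1, 1, 1, 1], [0, 0, 0, 0, 0, 9]]
        r1, _ = self._run(counts, [300, 300, 300], sheet)
        r2, _ = self._run(counts[::-1], [300, 300, 300], sheet)
        assert set(r1) == {"c0", "c1"}
        # reversed rows: c0<->c2 swap positions but identity follows content
        assert set(r2) == {"c1", "c2"}


class TestTemperatureFilter:
    @pytest.fixture
    def sheet(self):
        rows = [
            {"sample_id": f"{cond}_{rep}", "age_days": 10, "sex": "male",
             "condition": cond, "replicate": rep, "tissue": "head"}
            for cond in ("18C", "29C") for rep in (1, 2, 3)
        ]
        return SampleSheet(pd.DataFrame(rows))

    def test_all_replicates_above_three_in_one_condition(self, sheet):
        m = _matrix([[0, 0, 0, 4, 4, 4]], index=["c0"],
                    columns=[s for s in sheet.sample_ids])
        assert filter_temperature_circrnas(m, sheet) == ["c0"]

    def test_strictly_greater_than_three(self, sheet):
        m = _matrix([[4, 4, 3, 4, 4, 3]], index=["c0"], columns=sheet.sample_ids)
        assert filter_temperature_circrnas(m, sheet) == []

    def test_single_replicate_condition(self):
        sheet = SampleSheet(pd.DataFrame([
            {"sample_id": "only", "age_days": 10, "sex": "male",
             "condition": "29C", "replicate": 1, "tissue": "head"}]))
        m = _matrix([[100]], index=["c0"], columns=["only"])
        assert filter_temperature_circrnas(m, sheet) == ["c0"]


class TestRatios:
    def test_junction_method_zero_linear_returns_circ_count(self, aging_sim_small):
        circ = _matrix([[12.0]], index=["c"], columns=["s"], normalized=True)
        lin = _matrix([[0.0]], index=["c"], columns=["s"],
                      kind="linear_junction", normalized=True)
        from circlife.core_io import CircAnnotation
        ann = [CircAnnotation("c", "chr1", 0, 100, "+", "host", 2, 100)]
        table = circ_linear_ratio(circ, lin, ann, method="junction_reads")
        assert table.loc["c", "s"] == 12.0

    def test_all_reads_simple_ratio(self):
        circ = _matrix([[5.0]], index=["c"], columns=["s"], normalized=True)
        lin = _matrix([[50.0]], index=["host"], columns=["s"],
                      kind="linear", normalized=True)
        from circlife.core_io import CircAnnotation
        ann = [CircAnnotation("c", "chr1", 0, 100, "+", "host", 2, 100)]
        table = circ_linear_ratio(circ, lin, ann, method="all_reads")
        assert table.loc["c", "s"] == pytest.approx(0.1)

    def test_sentinel_hosts_excluded_from_all_reads(self):
        circ = _matrix([[5.0], [7.0]], index=["c1", "c2"], columns=["s"], normalized=True)
        lin = _matrix([[50.0]], index=["host"], columns=["s"],
                      kind="linear", normalized=True)
        from circlife.core_io import CircAnnotation
        ann = [CircAnnotation("c1", "chr1", 0, 100, "+", "host", 2, 100),
               CircAnnotation("c2", "chr1", 0, 100, "+", "ambiguous", 2, 100)]
        table = circ_linear_ratio(circ, lin, ann, method="all_reads")
        assert list(table.index) == ["c1"]


class TestBrainHeadRatio:
    @pytest.mark.parametrize("brain,head,expected", [(7.0, 0.0, 7.0),
                                                     (42.0, 42.0, 1.0),
                                                     (0.0, 10.0, 0.0)])
    def test_substitution_rule(self, brain, head, expected):
        out = brain_head_ratio(pd.Series({"c": brain}), pd.Series({"c": head}))
        assert out["c"] == pytest.approx(expected)


class TestQuantileShares:
    def test_hand_example_top_quartile(self):
        m = _matrix([[100], [50], [30], [20]], columns=["s"], normalized=True)
        table, mean = quantile_shares(m, n_quantiles=4)
        assert table.loc[4, "s"] == pytest.approx(0.5)

    def test_uniform_counts_give_equal_shares(self):
        m = _matrix([[10]] * 8, columns=["s"], normalized=True)
        table, _ = quantile_shares(m, n_quantiles=4)
        assert np.allclose(table["s"], 0.25)

    def test_shares_sum_to_one_and_conserve_totals(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 100, size=(30, 3))
        m = CountMatrix(pd.DataFrame(vals, index=[str(i) for i in range(30)]),
                        kind="circ", normalized=True)
        table, _ = quantile_shares(m, n_quantiles=5)
        assert np.allclose(table.sum(axis=0), 1.0)
        totals = m.values.sum(axis=0)
        recon = (table * totals).sum(axis=0)
        assert np.allclose(recon, totals)


class TestIsoformCounts:
    def test_strictly_positive_counted(self):
        m = _matrix([[0.0], [0.4], [7.0]], columns=["s"], normalized=True)
        assert count_expressed_isoforms(m)["s"] == 2

    def test_zero_rows_do_not_change_counts(self):
        m1 = _matrix([[1.0], [2.0]], columns=["s"], normalized=True)
        m2 = _matrix([[1.0], [2.0], [0.0]], columns=["s"], normalized=True)
        assert count_expressed_isoforms(m1)["s"] == count_expressed_isoforms(m2)["s"]

    def test_all_zero_column(self):
        m = _matrix([[0.0], [0.0]], columns=["s"], normalized=True)
        assert count_expressed_isoforms(m)["s"] == 0


def test_combine_matrices_prefixes_kinds(aging_sim_small):
    combined = combine_matrices(aging_sim_small.circ, aging_sim_small.linear)
    assert combined.shape[0] == (
        aging_sim_small.circ.values.shape[0] + aging_sim_small.linear.values.shape[0]
    )
    assert combined.index[0].startswith("circ:")
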