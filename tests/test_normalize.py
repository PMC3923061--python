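"""Normalization pipeline: stage examples, invariants and the brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_normalize
from strainscan import (
    DataError,
    FitError,
    apply_bias_correction,
    compute_dx_dy,
    compute_log_ratios,
    fit_positional_bias,
    median_over_replicates,
    normalize_experiment,
    percentile_normalize,
    summarize_gene_intensity,
)
from strainscan.normalize import BiasCurve, split_by_condition, to_log2
from strainscan.simulate import generate_probe_intensities, positional_bias


def _probe_rows(values, sample="s1", gene="g1", probe="p1", dx=0):
    return pd.DataFrame(
        {
            "sample_id": sample,
            "strain_id": "st1",
            "condition": "glucose",
            "gene_id": gene,
            "probe_id": probe,
            "placement_index": range(1, len(values) + 1),
            "dx": dx,
            "intensity": values,
            "scale": "linear",
        }
    )


class TestMedianOverReplicates:
    @pytest.mark.parametrize(
        "values,expected",
        [([100.0, 200.0, 300.0], 200.0), ([100.0, 200.0, 300.0, 400.0], 250.0),
         ([7.5], 7.5)],
    )
    def test_placement_median(self, values, expected):
        out = median_over_replicates(_probe_rows(values))
        assert len(out) == 1
        assert out["intensity"].iloc[0] == expected

    def test_empty_table_rejected(self):
        with pytest.raises(DataError):
            median_over_replicates(_probe_rows([]).iloc[:0])


class TestDxDy:
    def test_log2_ratio_to_plast(self):
        table = pd.concat(
            [
                _probe_rows([1024.0], probe="p0", dx=0),
                _probe_rows([512.0], probe="p1", dx=300),
            ]
        )
        pairs = compute_dx_dy(table)
        by_dx = pairs.set_index("dx")["dy"]
        assert by_dx.loc[0] == 0.0
        assert by_dx.loc[300] == pytest.approx(-1.0)

    def test_equal_intensities_give_zero_dy(self):
        table = pd.concat(
            _probe_rows([256.0], probe=f"p{i}", dx=dx)
            for i, dx in enumerate([0, 100, 500])
        )
        pairs = compute_dx_dy(table)
        assert set(zip(pairs["dx"], pairs["dy"])) == {(0, 0.0), (100, 0.0), (500, 0.0)}

    def test_gene_without_plast_skipped_with_warning(self, caplog):
        table = pd.concat(
            [
                _probe_rows([512.0], gene="g1", probe="p1", dx=300),
                _probe_rows([1024.0], gene="g2", probe="p2", dx=0),
            ]
        )
        with caplog.at_level("WARNING"):
            pairs = compute_dx_dy(table)
        assert pairs["gene_id"].tolist() == ["g2"]
        assert "P_last" in caplog.text


class TestBiasCurve:
    def test_noiseless_linear_trend_recovered(self):
        rng = np.random.default_rng(0)
        # dx grids always contain 0: the P_last probe pairs with itself
        dx = np.concatenate(
            [[0], np.sort(rng.choice(np.arange(1, 1000), size=199, replace=False))]
        )
        pairs = pd.DataFrame({"dx": dx, "dy": -0.002 * dx})
        curve = fit_positional_bias(pairs, span=0.3)
        interior = (curve.support > 100) & (curve.support < 900)
        expected = -0.002 * curve.support[interior]
        assert np.max(np.abs(curve.offset[interior] - expected)) < 1e-3
        assert curve(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_flat_data_gives_flat_curve(self):
        pairs = pd.DataFrame({"dx": np.arange(50), "dy": np.zeros(50)})
        curve = fit_positional_bias(pairs)
        assert np.max(np.abs(curve.offset)) < 1e-9

    def test_symmetric_noise_trend_vanishes_with_n(self):
        amplitudes = []
        for n in (100, 3200):
            rng = np.random.default_rng(42)
            dx = rng.uniform(0, 1000, size=n)
            dy = rng.choice([-0.5, 0.5], size=n)
            curve = fit_positional_bias(pd.DataFrame({"dx": dx, "dy": dy}))
            amplitudes.append(np.max(np.abs(curve.offset)))
        assert amplitudes[1] < amplitudes[0] / 3

    def test_too_few_pairs_advises_pooling(self):
        with pytest.raises(FitError, match="pool"):
            fit_positional_bias(pd.DataFrame({"dx": [0, 1], "dy": [0, 0]}))


class TestBiasCorrection:
    def test_subtracting_negative_offset_raises_intensity(self):
        curve = BiasCurve(support=np.array([0.0, 100.0]),
                          offset=np.array([0.0, -1.0]))
        table = _probe_rows([9.0], dx=100)
        table["scale"] = "log2"
        out = apply_bias_correction(table, curve)
        assert out["intensity"].iloc[0] == pytest.approx(10.0)

    def test_plast_probe_unchanged(self):
        curve = BiasCurve(support=np.array([0.0, 100.0]),
                          offset=np.array([0.0, -1.0]))
        table = _probe_rows([9.0], dx=0)
        table["scale"] = "log2"
        out = apply_bias_correction(table, curve)
        assert out["intensity"].iloc[0] == 9.0

    def test_linear_scale_input_rejected(self):
        curve = BiasCurve(support=np.array([0.0]), offset=np.array([0.0]))
        with pytest.raises(DataError):
            apply_bias_correction(_probe_rows([512.0]), curve)

    def test_known_linear_bias_fully_removed(self, small_config):
        from strainscan.simulate import (
            generate_array_design,
            generate_cohort_phenotypes,
            generate_expression,
        )

        cfg = small_config.replace(
            bias_amplitude=1.0, replicate_noise_sd=0.0, probe_noise_sd=0.0
        )
        phen = generate_cohort_phenotypes(cfg)
        expr = generate_expression(cfg, phen)
        design = generate_array_design(cfg)
        probes = to_log2(generate_probe_intensities(expr, design, cfg))
        pairs = compute_dx_dy(probes)
        curve = fit_positional_bias(pairs, span=0.3)
        corrected = apply_bias_correction(probes, curve)
        spread = corrected.groupby(["sample_id", "gene_id"])["intensity"].agg(
            lambda v: v.max() - v.min()
        )
        assert spread.max() < 1e-3


class TestGeneSummary:
    def test_median_of_probe_values(self):
        table = pd.concat(
            _probe_rows([v], probe=f"p{i}", dx=i)
            for i, v in enumerate([10.0, 11.0, 12.0])
        )
        assert summarize_gene_intensity(table).iloc[0, 0] == 11.0

    def test_probe_order_irrelevant(self):
        table = pd.concat(
            _probe_rows([v], probe=f"p{i}", dx=i)
            for i, v in enumerate([10.0, 11.0, 12.0])
        )
        shuffled = table.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(
            summarize_gene_intensity(table), summarize_gene_intensity(shuffled)
        )


class TestPercentileNormalize:
    def test_rank_means_hand_example(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [10.0, 20.0, 30.0]})
        out = percentile_normalize(m)
        assert out["a"].tolist() == [5.5, 11.0, 16.5]
        assert out["b"].tolist() == [5.5, 11.0, 16.5]

    def test_identical_columns_are_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(percentile_normalize(m), m)

    def test_missing_values_preserved_and_excluded(self):
        m = pd.DataFrame({"a": [1.0, np.nan, 3.0, 2.0], "b": [10.0, 20.0, 30.0, 40.0]})
        out = percentile_normalize(m)
        assert np.isnan(out.loc[1, "a"])
        assert out["a"].rank().dropna().tolist() == m["a"].rank().dropna().tolist()

    def test_ties_get_mean_of_spanned_reference(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [10.0, 20.0, 30.0]})
        out = percentile_normalize(m)
        ref = np.sort((np.sort(m["a"]) + np.sort(m["b"])) / 2)
        assert out["a"].iloc[0] == out["a"].iloc[1] == pytest.approx(
            (ref[0] + ref[1]) / 2
        )

    def test_undersized_column_names_sample(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "bad": [np.nan, 2.0]})
        with pytest.raises(DataError, match="bad"):
            percentile_normalize(m)

    @given(
        st.integers(min_value=5, max_value=12).flatmap(
            lambda n: st.lists(
                st.lists(
                    st.floats(-1e6, 1e6, allow_nan=False),
                    min_size=n,
                    max_size=n,
                    unique=True,  # with ties, tie-averaging trades the shared
                    # multiset for equal tied values, as in limma
                ),
                min_size=2,
                max_size=4,
            )
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_equal_length_columns_share_multiset_and_keep_order(self, cols):
        m = pd.DataFrame({f"c{i}": col for i, col in enumerate(cols)})
        out = percentile_normalize(m)
        sorted_cols = [np.sort(out[c].to_numpy()) for c in out.columns]
        for sc in sorted_cols[1:]:
            assert np.allclose(sc, sorted_cols[0])
        # grand-reference mean and weak rank preservation per column
        assert np.allclose(out.mean(axis=0), out.to_numpy().mean())
        for c in out.columns:
            order = np.argsort(m[c].to_numpy(), kind="stable")
            assert np.all(np.diff(out[c].to_numpy()[order]) >= -1e-12)


class TestLogRatios:
    def test_log2_difference_and_missingness(self):
        xyl = pd.DataFrame({"s1": [5.0, 4.0], "s2": [1.0, np.nan]},
                           index=["g1", "g2"])
        glc = pd.DataFrame({"s1": [3.0, 4.0], "s2": [1.0, 2.0]}, index=["g1", "g2"])
        out = compute_log_ratios(xyl, glc)
        assert out.loc["g1", "s1"] == 2.0
        assert out.loc["g2", "s1"] == 0.0
        assert np.isnan(out.loc["g2", "s2"])

    def test_disjoint_strains_rejected(self):
        xyl = pd.DataFrame({"s1": [5.0]}, index=["g1"])
        glc = pd.DataFrame({"s2": [3.0]}, index=["g1"])
        with pytest.raises(DataError):
            compute_log_ratios(xyl, glc)


class TestFullPipeline:
    def test_matches_bruteforce_oracle(self, small_cohort):
        probes = small_cohort["probes"]
        keep = probes["sample_id"].isin(sorted(probes["sample_id"].unique())[:3])
        probes = probes[keep].reset_index(drop=True)
        ours = normalize_experiment(probes, span=0.3)
        theirs = oracle_normalize(probes, span=0.3)
        for gene in ours.index:
            for sample in ours.columns:
                assert ours.loc[gene, sample] == pytest.approx(
                    theirs[gene][sample], abs=1e-9
                )

    def test_recovers_truth_despite_bias_and_noise(self, default_cohort):
        cfg, cohort = default_cohort
        matrix = normalize_experiment(cohort["probes"], span=0.3)
        truth = cohort["expression"]
        for sample in matrix.columns:
            r = np.corrcoef(matrix[sample], truth[sample])[0, 1]
            assert r > 0.99

    def test_residual_positional_trend_small(self, small_config):
        cfg = small_config.replace(
            n_genes=100, group_sizes={}, coupling={}, bias_amplitude=1.0,
            replicate_noise_sd=0.05, probe_noise_sd=0.0,
        )
        from strainscan.simulate import (
            generate_array_design,
            generate_cohort_phenotypes,
            generate_expression,
        )

        phen = generate_cohort_phenotypes(cfg)
        expr = generate_expression(cfg, phen)
        design = generate_array_design(cfg)
        probes = to_log2(
            median_over_replicates(generate_probe_intensities(expr, design, cfg))
        )
        sample = probes["sample_id"].iloc[0]
        probes = probes[probes["sample_id"] == sample]
        pairs = compute_dx_dy(probes)
        curve = fit_positional_bias(pairs, span=0.3)
        corrected = apply_bias_correction(probes, curve)
        residual = fit_positional_bias(compute_dx_dy(corrected), span=0.3)
        injected = positional_bias(
            curve.support, int(design["dx"].max()), cfg.bias_amplitude
        )
        assert np.ptp(residual.offset) < 0.1 * np.ptp(injected)

    def test_rerun_is_identical(self, small_cohort):
        a = normalize_experiment(small_cohort["probes"])
        b = normalize_experiment(small_cohort["probes"])
        pd.testing.assert_frame_equal(a, b)

    def test_split_by_condition_partitions_samples(self, small_cohort):
        matrix = normalize_experiment(small_cohort["probes"])
        parts = split_by_condition(matrix)
        assert set(parts) == {"glucose", "xylulose"}
        total = sum(p.shape[1] for p in parts.values())
        assert total == matrix.shape[1]
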