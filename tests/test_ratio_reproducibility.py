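import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import exprepro as xp
from exprepro.ratio_reproducibility import fold_deviation

from conftest import make_dataset
from oracles import brute_force_between_treatments, brute_force_within_treatment


def dataset_from_nested(data):
    """Build an ExpressionDataset from {treatment: {replicate: [values]}}."""
    columns, layout = {}, {}
    for t in sorted(data):
        for r in sorted(data[t]):
            sample = f"{t}_{r}"
            columns[sample] = data[t][r]
            layout[sample] = (t, r)
    return make_dataset(columns, layout)


class TestFoldDeviation:
    @pytest.mark.parametrize("v,expected", [(0.8, 0.25), (1.25, 0.25), (1.0, 0.0), (2.0, 1.0)])
    def test_symmetric_folding(self, v, expected):
        assert fold_deviation(v) == pytest.approx(expected)

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            fold_deviation(0.0)


class TestBuildRatioPopulations:
    @pytest.mark.parametrize(
        "n_treat,n_rep,expected",
        [(4, 2, 48), (2, 2, 8), (2, 3, 18)],
    )
    def test_population_count_identity(self, n_treat, n_rep, expected):
        cfg = xp.SynthConfig(
            n_genes=5, n_treatments=n_treat, n_replicates=n_rep, sigma_rep=0.1, seed=3
        )
        pops = xp.build_ratio_populations(xp.generate_dataset(cfg))
        assert len(pops) == expected

    def test_single_treatment_is_error(self):
        ds = dataset_from_nested({"T1": {"R1": [1.0, 2.0], "R2": [1.0, 2.0]}})
        with pytest.raises(ValueError, match="2 treatments"):
            xp.build_ratio_populations(ds)

    def test_zero_values_excluded_per_population(self):
        ds = dataset_from_nested(
            {"T1": {"R1": [1.0, 0.0], "R2": [2.0, 3.0]}, "T2": {"R1": [4.0, 5.0], "R2": [6.0, 7.0]}}
        )
        pops = xp.build_ratio_populations(ds)
        by_pair = {(p.source, p.target): p for p in pops}
        assert by_pair[(("T1", "R1"), ("T2", "R1"))].n_genes == 1
        assert by_pair[(("T1", "R2"), ("T2", "R1"))].n_genes == 2

    def test_listwise_filter_drops_gene_everywhere(self):
        ds = dataset_from_nested(
            {"T1": {"R1": [1.0, 0.0], "R2": [2.0, 3.0]}, "T2": {"R1": [4.0, 5.0], "R2": [6.0, 7.0]}}
        )
        pops = xp.build_ratio_populations(ds, gene_filter="listwise")
        assert all(p.n_genes == 1 for p in pops)


class TestCoefficients:
    def test_identical_replicates_give_zero(self):
        ds = dataset_from_nested(
            {
                "T1": {"R1": [1.0, 5.0, 9.0], "R2": [1.0, 5.0, 9.0]},
                "T2": {"R1": [2.0, 3.0, 4.0], "R2": [2.0, 3.0, 4.0]},
            }
        )
        res = xp.reproducibility_coefficients(ds)
        assert res.avg_deviation == 0.0
        assert res.sd_of_deviations == 0.0

    def test_hand_enumerated_micro_example(self, micro_dataset):
        res = xp.reproducibility_coefficients(micro_dataset)
        assert sorted(res.mean_deviations) == pytest.approx([0.0, 0.0, 1.0, 1.0])
        assert res.avg_deviation == pytest.approx(0.5)

    def test_explicit_deviation_lists(self):
        devs = [1.0, 1.0, 0.0, 0.0]
        assert np.mean(devs) == 0.5
        assert np.std(devs, ddof=1) == pytest.approx(0.57735, abs=1e-5)
        assert np.std(devs, ddof=0) == pytest.approx(0.5)

    def test_sample_vs_population_sd_flag(self, micro_dataset):
        sample = xp.reproducibility_coefficients(micro_dataset, sd_convention="sample")
        population = xp.reproducibility_coefficients(micro_dataset, sd_convention="population")
        assert sample.sd_of_deviations == pytest.approx(0.57735, abs=1e-5)
        assert population.sd_of_deviations == pytest.approx(0.5)

    def test_global_scale_invariance(self, rng):
        cfg = xp.SynthConfig(n_genes=30, n_treatments=3, n_replicates=2, sigma_rep=0.4, seed=7)
        ds = xp.generate_dataset(cfg)
        scaled = xp.ExpressionDataset(ds.values * 17.3, dict(ds.layout))
        a = xp.reproducibility_coefficients(ds)
        b = xp.reproducibility_coefficients(scaled)
        assert a.avg_deviation == pytest.approx(b.avg_deviation, rel=1e-12)

    def test_replicate_relabel_swap_symmetry(self):
        ds = dataset_from_nested(
            {
                "T1": {"R1": [1.0, 5.0, 9.0], "R2": [1.5, 4.0, 8.0]},
                "T2": {"R1": [2.0, 3.0, 4.0], "R2": [2.5, 3.5, 5.0]},
            }
        )
        swapped = dataset_from_nested(
            {
                "T1": {"R1": [1.0, 5.0, 9.0], "R2": [1.5, 4.0, 8.0]},
                "T2": {"R2": [2.0, 3.0, 4.0], "R1": [2.5, 3.5, 5.0]},
            }
        )
        a = xp.reproducibility_coefficients(ds)
        b = xp.reproducibility_coefficients(swapped)
        assert a.avg_deviation == pytest.approx(b.avg_deviation, rel=1e-12)

    def test_monotone_in_replicate_noise(self):
        coeffs = []
        for sigma in (0.05, 0.3, 0.8):
            cfg = xp.SynthConfig(
                n_genes=400, n_treatments=4, n_replicates=2, sigma_rep=sigma, seed=11
            )
            coeffs.append(xp.reproducibility_coefficients(xp.generate_dataset(cfg)).avg_deviation)
        assert coeffs[0] < coeffs[1] < coeffs[2]

    def test_all_skipped_is_error(self):
        populations = []
        with pytest.raises(ValueError):
            xp.reproducibility_coefficients(populations)


class TestWithinTreatment:
    def test_identical_replicates(self):
        ds = dataset_from_nested({"T1": {"R1": [1.0, 2.0], "R2": [1.0, 2.0]},
                                  "T2": {"R1": [1.0], "R2": [1.0]}})
        res = xp.within_treatment_deviation(ds, "T1")
        assert res.avg_deviation == 0.0
        assert all(s == 0.0 for s in res.sd_deviations)

    def test_doubled_replicate_pair(self):
        ds = dataset_from_nested(
            {"T1": {"R1": [10.0, 20.0, 30.0], "R2": [20.0, 40.0, 60.0]},
             "T2": {"R1": [1.0, 1.0, 1.0], "R2": [1.0, 1.0, 1.0]}}
        )
        res = xp.within_treatment_deviation(ds, "T1")
        # ordered pairs: M = 0.5 and M = 2, both folding to deviation 1
        assert res.mean_deviations == pytest.approx([1.0, 1.0])
        assert res.avg_deviation == pytest.approx(1.0)

    def test_noise_monotonicity_three_replicates(self):
        devs = []
        for sigma in (0.05, 0.2, 0.6):
            cfg = xp.SynthConfig(
                n_genes=500, n_treatments=2, n_replicates=3, sigma_rep=sigma, seed=5
            )
            ds = xp.generate_dataset(cfg)
            devs.append(xp.within_treatment_deviation(ds, "T1").avg_deviation)
        assert devs[0] < devs[1] < devs[2]

    def test_matches_brute_force(self, rng):
        reps = {f"R{k}": rng.lognormal(1, 0.5, 6).tolist() for k in range(1, 4)}
        ds = dataset_from_nested({"T1": reps, "T2": {"R1": [1.0] * 6, "R2": [1.0] * 6}})
        oracle = brute_force_within_treatment(reps)
        res = xp.within_treatment_deviation(ds, "T1")
        assert res.avg_deviation == pytest.approx(oracle["avg_deviation"], rel=1e-9)

    def test_single_replicate_error(self):
        ds = dataset_from_nested({"T1": {"R1": [1.0]}, "T2": {"R1": [1.0], "R2": [1.0]}})
        with pytest.raises(ValueError):
            xp.within_treatment_deviation(ds, "T1")


@st.composite
def random_designs(draw):
    n = draw(st.integers(2, 3))
    r = draw(st.integers(2, 3))
    g = draw(st.integers(2, 5))
    value = st.floats(0.01, 1000.0, allow_nan=False, allow_infinity=False)
    data = {
        f"T{t}": {f"R{k}": draw(st.lists(value, min_size=g, max_size=g)) for k in range(1, r + 1)}
        for t in range(1, n + 1)
    }
    return data


@settings(max_examples=60, deadline=None, derandomize=True)
@given(random_designs())
def test_matches_brute_force_enumeration(data):
    """Implementation equals a literal enumeration oracle on small designs."""
    ds = dataset_from_nested(data)
    oracle = brute_force_between_treatments(data)
    res = xp.reproducibility_coefficients(ds)
    assert res.n_populations == oracle["n_populations"]
    assert res.skipped == oracle["skipped"]
    np.testing.assert_allclose(
        sorted(res.mean_deviations), sorted(oracle["mean_deviations"]), rtol=1e-9
    )
    np.testing.assert_allclose(
        sorted(res.sd_deviations), sorted(oracle["sd_deviations"]), rtol=1e-9
    )
    assert res.avg_deviation == pytest.approx(oracle["avg_deviation"], rel=1e-9)
    assert res.sd_of_deviations == pytest.approx(oracle["sd_of_deviations"], rel=1e-9, abs=1e-12)
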