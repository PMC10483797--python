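import numpy as np
import pandas as pd
import pytest

from proteoqc import (QuantMatrix, RunMetadata, SENTINEL, SimulationConfig,
                      four_dim_summary, ibaq_to_fot,
                      identification_frequency, intensity_flow,
                      median_cv_by_group, occurrence_bins, overlap_sets,
                      pairwise_correlation, protein_cv, simulate_experiment,
                      assign_intensity_groups)
from proteoqc.qc_metrics import cv_per_protein


def fot_matrix(data, index=None) -> QuantMatrix:
    df = pd.DataFrame(data)
    if index is not None:
        df.index = index
    else:
        df.index = [f"P{i}" for i in range(len(df))]
    return QuantMatrix(df.astype(float), unit_tag="FOT")


class TestProteinCV:
    @pytest.mark.parametrize("values,expected", [
        ((100, 100, 100), 0.0),
        ((1, 2, 3), 50.0),      # mean 2, sample SD 1
    ])
    def test_hand_computed(self, values, expected):
        assert protein_cv(values) == pytest.approx(expected)

    def test_scale_invariance(self):
        vals = [3.0, 5.5, 9.2, 4.4]
        assert protein_cv([v * 1234.5 for v in vals]) == \
            pytest.approx(protein_cv(vals))

    def test_fewer_than_two_values_is_nan_not_error(self):
        assert np.isnan(protein_cv([5.0]))


class TestIdentificationFrequency:
    def test_counts_and_exclusions(self):
        mat = fot_matrix({"r1": [1.0, SENTINEL, 2.0],
                          "r2": [1.0, SENTINEL, np.nan],
                          "r3": [1.0, SENTINEL, 3.0]})
        idf = identification_frequency(mat, ["r1", "r2", "r3"])
        assert idf["P0"] == 3
        assert idf["P2"] == 2          # present in 2 of 3 runs
        assert "P1" not in idf.index   # sentinel everywhere = never present

    def test_saturation(self):
        mat = fot_matrix({"r1": [1, 2], "r2": [3, 4], "r3": [5, 6]})
        idf = identification_frequency(mat, mat.run_ids)
        assert (idf == 3).all()

    def test_fraction_above_one_matches_hand_count(self):
        # 10 proteins: 4 present in all 3 runs, 3 in two, 2 in one, 1 never
        rows = ([[1, 1, 1]] * 4 + [[1, 1, np.nan]] * 3 +
                [[1, np.nan, np.nan]] * 2 + [[np.nan] * 3])
        mat = fot_matrix(pd.DataFrame(rows, columns=["a", "b", "c"]))
        idf = identification_frequency(mat, ["a", "b", "c"])
        assert len(idf) == 9
        assert (idf > 1).mean() == pytest.approx(7 / 9)


class TestOccurrenceBins:
    def test_full_presence_is_the_exact_100_bin(self):
        mat = fot_matrix(np.ones((2, 10)))
        out = occurrence_bins(mat)
        assert (out["bin"] == "100%").all()

    def test_half_presence_lands_in_50_60(self):
        row = [1.0] * 5 + [np.nan] * 5
        mat = fot_matrix(pd.DataFrame([row]))
        out = occurrence_bins(mat)
        assert out["occurrence_frequency"].iloc[0] == pytest.approx(0.5)
        assert out["bin"].iloc[0] == "[50,60%)"

    def test_bin_counts_match_hand_enumeration(self):
        # 20 proteins over 10 runs with presence counts 1..20 capped at 10
        rng = np.random.default_rng(0)
        rows, want = [], {}
        for i in range(20):
            k = (i % 10) + 1
            row = [1.0] * k + [np.nan] * (10 - k)
            rng.shuffle(row)
            rows.append(row)
            label = "100%" if k == 10 else f"[{10 * k},{10 * (k + 1)}%)"
            want[label] = want.get(label, 0) + 1
        out = occurrence_bins(fot_matrix(pd.DataFrame(rows)))
        assert out["bin"].value_counts().to_dict() == want
        # bins partition the observed universe
        assert out.shape[0] == 20


class TestPairwiseCorrelation:
    def test_self_and_scaled_copy_correlate_perfectly(self):
        rng = np.random.default_rng(1)
        x = 10 ** rng.uniform(0, 4, size=30)
        mat = fot_matrix({"r1": x, "r2": 2.0 * x})
        r = pairwise_correlation(mat)
        assert r.loc["r1", "r1"] == 1.0
        assert r.loc["r1", "r2"] == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 10.0, 100.0, 1000.0, 10000.0])
        y = np.array([2.0, 30.0, 50.0, 4000.0, 8000.0])
        mat = fot_matrix({"r1": x, "r2": y})
        lx, ly = np.log10(x), np.log10(y)
        want = (np.sum((lx - lx.mean()) * (ly - ly.mean())) /
                np.sqrt(np.sum((lx - lx.mean()) ** 2) *
                        np.sum((ly - ly.mean()) ** 2)))
        got = pairwise_correlation(mat).loc["r1", "r2"]
        assert got == pytest.approx(want, rel=1e-12)

    def test_constant_column_warns_and_is_nan(self):
        mat = fot_matrix({"r1": [5.0, 5.0, 5.0], "r2": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning):
            r = pairwise_correlation(mat)
        assert np.isnan(r.loc["r1", "r2"])


class TestOverlap:
    def test_subset_overlaps_reference_fully(self):
        res = overlap_sets({"A": {1, 2}, "B": {1, 2, 3}}, reference="B")
        assert res.fraction_of_reference["A"] == pytest.approx(100 * 2 / 3)
        res2 = overlap_sets({"A": {1, 2}, "B": {1, 2, 3}}, reference="A")
        assert res2.fraction_of_reference["B"] == 100.0

    def test_disjoint_sets(self):
        res = overlap_sets({"A": {1}, "B": {2}}, reference="A")
        assert res.intersection == 0
        assert res.specific == {"A": 1, "B": 1}

    def test_three_sets_match_inclusion_exclusion(self):
        a, b, c = {1, 2, 3, 4}, {3, 4, 5}, {4, 5, 6, 7}
        res = overlap_sets({"a": a, "b": b, "c": c}, reference="a")
        assert res.intersection == len(a & b & c) == 1
        assert res.union == len(a | b | c) == 7
        assert res.specific == {"a": 2, "b": 0, "c": 2}


class TestIntensityFlow:
    def _assignment(self, mapping):
        return pd.DataFrame({"group": pd.Series(mapping),
                             "basis_value": 1.0})

    def test_identical_assignments_give_identity_rows(self):
        a = self._assignment({"P1": "low", "P2": "low", "P3": "medium",
                              "P4": "high", "P5": "high"})
        flow = intensity_flow(a, a)
        for g in ("low", "medium", "high"):
            assert flow.loc[g, g] == 100.0
            assert flow.loc[g].sum() == pytest.approx(100.0)

    def test_nothing_detected_in_b(self):
        a = self._assignment({"P1": "low", "P2": "medium", "P3": "high"})
        b = self._assignment({})
        flow = intensity_flow(a, b)
        assert (flow["not_detected"] == 100.0).all()

    def test_nine_protein_fixture_matches_hand_tally(self):
        a = self._assignment({f"P{i}": g for i, g in enumerate(
            ["low"] * 3 + ["medium"] * 3 + ["high"] * 3)})
        b = self._assignment({"P0": "low", "P1": "medium",
                              "P3": "medium", "P4": "medium", "P5": "high",
                              "P6": "high", "P7": "high", "P8": "high"})
        flow = intensity_flow(a, b)
        np.testing.assert_allclose(
            flow.loc["low"], [100 / 3, 100 / 3, 0, 100 / 3])
        np.testing.assert_allclose(
            flow.loc["medium"], [0, 200 / 3, 100 / 3, 0])
        np.testing.assert_allclose(flow.loc["high"], [0, 0, 100, 0])
        assert flow.sum(axis=1).tolist() == pytest.approx([100.0] * 3)


class TestMedianCV:
    def test_simulator_recovers_stratum_ordering(self):
        cfg = SimulationConfig(
            n_proteins=3000, dep_fraction=0.0, specific_fraction=0.0,
            cv_profile={"low": 0.8, "medium": 0.3, "high": 0.15},
            detection_midpoint_log10=-np.inf, seed=21)
        mat, meta, _ = simulate_experiment(cfg)
        fot = ibaq_to_fot(mat)
        assignment = assign_intensity_groups(fot, meta)
        med = median_cv_by_group(fot, meta, assignment)
        assert med["low"] > med["medium"] > med["high"]

    def test_noise_free_simulation_has_zero_cv(self, clean_config):
        mat, meta, _ = simulate_experiment(clean_config)
        fot = ibaq_to_fot(mat)
        assignment = assign_intensity_groups(fot, meta)
        med = median_cv_by_group(fot, meta, assignment)
        assert med[["low", "medium", "high", "global"]].abs().max() < 1e-9

    def test_singleton_group_median_is_that_cv(self):
        mat = fot_matrix({"g1_r1": [1.0, 50.0], "g1_r2": [2.0, 50.0],
                          "g1_r3": [3.0, 50.0]})
        meta = RunMetadata(pd.DataFrame({
            "run_id": mat.run_ids, "group_label": ["G"] * 3,
            "replicate_index": [1, 2, 3], "month": [1] * 3}))
        assignment = pd.DataFrame(
            {"group": ["low", "high"], "basis_value": [2.0, 50.0]},
            index=["P0", "P1"])
        med = median_cv_by_group(mat, meta, assignment)
        assert med["low"] == pytest.approx(50.0)
        assert med["high"] == pytest.approx(0.0)


class TestFourDim:
    def test_ideal_experiment(self, clean_config):
        mat, meta, _ = simulate_experiment(clean_config)
        fd = four_dim_summary(ibaq_to_fot(mat), meta)
        assert fd.reproducibility == pytest.approx(1.0)
        assert fd.mean_pearson_r == pytest.approx(1.0)
        assert fd.median_cv == pytest.approx(0.0, abs=1e-9)
        assert fd.n_proteins_identified == clean_config.n_proteins

    def test_noisier_experiment_scores_worse(self):
        base = dict(n_proteins=500, dep_fraction=0.0, specific_fraction=0.0,
                    detection_midpoint_log10=-np.inf, seed=5)
        quiet = SimulationConfig(
            cv_profile={"low": 0.1, "medium": 0.1, "high": 0.1}, **base)
        loud = SimulationConfig(
            cv_profile={"low": 0.9, "medium": 0.9, "high": 0.9}, **base)
        fd_q = four_dim_summary(ibaq_to_fot(simulate_experiment(quiet)[0]),
                                simulate_experiment(quiet)[1])
        mat_l, meta_l, _ = simulate_experiment(loud)
        fd_l = four_dim_summary(ibaq_to_fot(mat_l), meta_l)
        assert fd_l.mean_pearson_r < fd_q.mean_pearson_r
        assert fd_l.median_cv > fd_q.median_cv

    def test_components_match_independent_computation(self, default_sim):
        mat, meta, _ = default_sim
        fot = ibaq_to_fot(mat)
        fd = four_dim_summary(fot, meta)
        # reproducibility: recompute from per-group IDF
        parts = []
        for g in meta.groups():
            runs = meta.runs_for(group=g)
            idf = identification_frequency(fot, runs)
            parts.append((idf == len(runs)).mean())
        assert fd.reproducibility == pytest.approx(np.mean(parts))
        cvs = cv_per_protein(fot, meta)
        assert fd.median_cv == pytest.approx(cvs.stack().median())
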