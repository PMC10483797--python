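import math

import numpy as np
import pandas as pd
import pytest

from proteoqc import (DegenerateReplicatesError, DesignError,
                      InsufficientDataError, QuantMatrix, RunMetadata,
                      SNREmbedding, ValidationError, classify_snr,
                      compute_snr, derive_snr_threshold, embed_pca,
                      pair_counts)


def brute_force_snr_db(coords, weights, labels):
    """Independent oracle: explicit double loops over every run pair,
    normalized by directly counted pair numbers (no prefactor algebra)."""
    coords = np.asarray(coords, float)
    labels = list(labels)
    inter_sum = intra_sum = 0.0
    inter_n = intra_n = 0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            d2 = sum(w * (a - b) ** 2
                     for w, a, b in zip(weights, coords[i], coords[j]))
            if labels[i] == labels[j]:
                intra_sum += d2
                intra_n += 1
            else:
                inter_sum += d2
                inter_n += 1
    return 10.0 * math.log10((inter_sum / inter_n) / (intra_sum / intra_n))


def embedding(coords, weights, labels):
    return SNREmbedding(coordinates=np.asarray(coords, float),
                        weights=np.asarray(weights, float),
                        group_labels=np.asarray(labels))


class TestPairCounts:
    @pytest.mark.parametrize("m,n,expected", [
        (4, 3, (54, 12)),   # the quartet design: 9*12/2 and 2*3*4/2
        (2, 2, (4, 2)),
        (3, 4, (48, 18)),
    ])
    def test_closed_form(self, m, n, expected):
        assert pair_counts(m, n) == expected

    @pytest.mark.parametrize("m,n", [(1, 3), (4, 1), (0, 0)])
    def test_degenerate_designs_rejected(self, m, n):
        with pytest.raises(DesignError):
            pair_counts(m, n)


class TestComputeSNR:
    def test_two_group_worked_example(self):
        """A={0,1}, B={10,11} on one axis: mean inter 100.5, mean intra 1."""
        emb = embedding([[0, 0], [1, 0], [10, 0], [11, 0]], [1.0, 0.0],
                        ["A", "A", "B", "B"])
        res = compute_snr(emb)
        assert res.signal == pytest.approx(100.5)
        assert res.noise == pytest.approx(1.0)
        assert res.snr_db == pytest.approx(10 * math.log10(100.5), abs=1e-12)
        assert res.category == "excellent"

    def test_ratio_one_design_gives_zero_db(self):
        s = math.sqrt(2)
        emb = embedding([[0, 0], [2, 0], [s, 0], [s + 2, 0]], [1.0, 0.0],
                        ["A", "A", "B", "B"])
        res = compute_snr(emb)
        assert res.snr_db == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_bruteforce_on_random_designs(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            m = int(rng.integers(2, 6))
            n = int(rng.integers(2, 5))
            labels = np.repeat([f"g{k}" for k in range(m)], n)
            coords = rng.normal(size=(m * n, 2)) + \
                10 * rng.normal(size=(m, 2)).repeat(n, axis=0)
            w = rng.uniform(0.05, 1.0, size=2)
            got = compute_snr(embedding(coords, w, labels)).snr_db
            want = brute_force_snr_db(coords, w, labels)
            assert got == pytest.approx(want, rel=1e-9)

    def test_prefactor_identity(self):
        """Averaging by pair counts equals the printed closed-form prefactor
        m*C(n,2)/(C(m,2)*n*n) applied to raw sums."""
        rng = np.random.default_rng(5)
        m, n = 4, 3
        labels = np.repeat(list("ABCD"), n)
        coords = rng.normal(size=(12, 2)) * 3
        w = np.array([0.6, 0.2])
        res = compute_snr(embedding(coords, w, labels))
        inter_pairs, intra_pairs = pair_counts(m, n)
        raw_ratio = (res.signal * inter_pairs) / (res.noise * intra_pairs)
        prefactor = (m * math.comb(n, 2)) / (math.comb(m, 2) * n * n)
        assert res.snr_db == pytest.approx(
            10 * math.log10(prefactor * raw_ratio), rel=1e-12)

    def test_rigid_motion_invariance_with_equal_weights(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(8, 2))
        labels = list("AABBCCDD")
        w = [0.5, 0.5]
        theta = 1.1
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        moved = coords @ rot.T + np.array([3.0, -7.0])
        a = compute_snr(embedding(coords, w, labels)).snr_db
        b = compute_snr(embedding(moved, w, labels)).snr_db
        assert a == pytest.approx(b, rel=1e-9)

    def test_label_shuffle_reduces_snr_on_separated_groups(self):
        rng = np.random.default_rng(13)
        centers = np.array([[0, 0], [20, 0], [0, 20], [20, 20]])
        coords = centers.repeat(3, axis=0) + rng.normal(size=(12, 2))
        labels = np.repeat(list("ABCD"), 3)
        true_snr = compute_snr(embedding(coords, [0.5, 0.5], labels)).snr_db
        shuffled = []
        for _ in range(20):
            perm = rng.permutation(labels)
            shuffled.append(
                compute_snr(embedding(coords, [0.5, 0.5], perm)).snr_db)
        assert np.mean(shuffled) < true_snr
        assert max(shuffled) < true_snr

    def test_snr_nondecreasing_in_group_separation(self):
        rng = np.random.default_rng(17)
        noise = rng.normal(size=(6, 2))
        vals = []
        for sep in (1.0, 3.0, 10.0, 30.0):
            coords = noise.copy()
            coords[3:, 0] += sep
            labels = list("AAABBB")
            vals.append(compute_snr(embedding(coords, [0.7, 0.3],
                                              labels)).snr_db)
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_zero_noise_is_reported_distinctly(self):
        emb = embedding([[0, 0], [0, 0], [5, 0], [5, 0]], [1, 0],
                        ["A", "A", "B", "B"])
        with pytest.raises(DegenerateReplicatesError):
            compute_snr(emb)

    def test_unbalanced_design_rejected(self):
        emb = embedding([[0, 0], [1, 0], [2, 0], [10, 0], [11, 0]], [1, 0],
                        ["A", "A", "A", "B", "B"])
        with pytest.raises(DesignError):
            compute_snr(emb)


class TestClassify:
    @pytest.mark.parametrize("value,category", [
        (0.59, "ineligible"), (17.74, "good"), (23.12, "excellent"),
        (25.18, "excellent"), (-3.0, "ineligible"), (2.0, "average"),
        (10.0, "good"), (20.0, "excellent"), (9.999, "average"),
    ])
    def test_bins(self, value, category):
        assert classify_snr(value) == category

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            classify_snr(float("nan"))


class TestThreshold:
    def test_hand_computed_mean_minus_sample_sd(self):
        assert derive_snr_threshold([10, 12, 14]) == pytest.approx(10.0)

    def test_equal_values_return_the_value(self):
        assert derive_snr_threshold([7.5, 7.5, 7.5]) == pytest.approx(7.5)

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientDataError):
            derive_snr_threshold([12.0])


class TestEmbedPCA:
    def _matrix_meta(self, data, groups):
        runs = [f"r{i}" for i in range(data.shape[1])]
        mat = QuantMatrix(pd.DataFrame(data, columns=runs,
                                       index=[f"P{i}" for i in
                                              range(data.shape[0])]),
                          unit_tag="FOT")
        meta = RunMetadata(pd.DataFrame({
            "run_id": runs, "group_label": groups,
            "replicate_index": [groups[:i + 1].count(groups[i])
                                for i in range(len(groups))],
            "month": [1] * len(groups)}))
        return mat, meta

    def test_full_weight_in_two_dimensions(self):
        rng = np.random.default_rng(1)
        data = 10 ** rng.uniform(0, 2, size=(2, 6))
        mat, meta = self._matrix_meta(data, list("AABBCC"))
        emb = embed_pca(mat, meta, scale=False)
        assert emb.weights.sum() == pytest.approx(1.0)

    def test_duplicating_rows_preserves_distance_ratios(self):
        rng = np.random.default_rng(8)
        data = 10 ** rng.uniform(0, 3, size=(20, 6))
        mat, meta = self._matrix_meta(data, list("AABBCC"))
        mat2 = QuantMatrix(
            pd.concat([mat.values,
                       mat.values.set_axis(
                           [f"dup{i}" for i in range(20)])]), "FOT")
        e1 = embed_pca(mat, meta)
        e2 = embed_pca(mat2, meta)

        def pdist(e):
            c = e.coordinates
            d = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
            return d[np.triu_indices(len(c), 1)]

        d1, d2 = pdist(e1), pdist(e2)
        ratios = d2 / d1
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_run_permutation_is_a_relabeling(self):
        rng = np.random.default_rng(9)
        data = 10 ** rng.uniform(0, 3, size=(15, 6))
        mat, meta = self._matrix_meta(data, list("AABBCC"))
        runs = mat.run_ids
        perm = [runs[i] for i in [3, 1, 5, 0, 2, 4]]
        e1 = embed_pca(mat, meta, runs=runs)
        e2 = embed_pca(mat, meta, runs=perm)
        idx = [perm.index(r) for r in runs]
        d1 = np.abs(e1.coordinates)
        d2 = np.abs(e2.coordinates[idx])
        np.testing.assert_allclose(d1, d2, atol=1e-9)  # up to axis sign

    def test_too_few_runs_rejected(self):
        data = np.ones((4, 2))
        mat, meta = self._matrix_meta(data, list("AB"))
        with pytest.raises(InsufficientDataError):
            embed_pca(mat, meta)

    def test_zero_variance_input_rejected(self):
        data = np.ones((4, 6))
        mat, meta = self._matrix_meta(data, list("AABBCC"))
        with pytest.raises(ValidationError, match="variance"):
            embed_pca(mat, meta)
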