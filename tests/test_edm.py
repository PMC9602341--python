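"""Delay embedding, simplex projection and embedding-dimension choice."""

import numpy as np
import pytest

import micronet as m
from micronet.edm import make_block, simplex_forecast


def brute_force_simplex(x, y, times, k):
    """Independent all-pairs reimplementation of simplex projection.

    Sorting by (distance, row index) reproduces the deterministic
    tie-break; weights exp(-d/d_min) with the equal-weight rule at
    d_min = 0.
    """
    preds = np.empty(len(x))
    for i in range(len(x)):
        cand = [j for j in range(len(x)) if times[j] != times[i]]
        if len(cand) < k:
            raise ValueError("not enough neighbors")
        dist = {j: float(np.sqrt(np.sum((x[j] - x[i]) ** 2))) for j in cand}
        chosen = sorted(cand, key=lambda j: (dist[j], j))[:k]
        d_min = dist[chosen[0]]
        if d_min == 0:
            zeros = [j for j in cand if dist[j] == 0]
            preds[i] = float(np.mean([y[j] for j in zeros]))
        else:
            w = np.array([np.exp(-dist[j] / d_min) for j in chosen])
            preds[i] = float(np.sum(w * np.array([y[j] for j in chosen]))
                             / np.sum(w))
    return preds


class TestStandardize:
    def test_hand_zscore_population_sd(self):
        out = m.standardize({"r1": np.array([1.0, 2.0, 3.0])})
        np.testing.assert_allclose(out["r1"],
                                   [-1.224744871, 0.0, 1.224744871])

    def test_already_standardized_unchanged(self):
        z = np.array([-1.224744871391589, 0.0, 1.224744871391589])
        out = m.standardize({"r1": z})
        np.testing.assert_allclose(out["r1"], z, atol=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            m.standardize({"r1": np.ones(5)})

    def test_pooled_across_replicates(self):
        out = m.standardize({"r1": np.array([0.0, 1.0]),
                             "r2": np.array([2.0, 3.0])})
        pooled = np.concatenate(list(out.values()))
        assert pooled.mean() == pytest.approx(0.0, abs=1e-12)
        assert pooled.std() == pytest.approx(1.0)


class TestMakeBlock:
    def test_enumerated_single_series(self):
        series = {"x": {"r1": np.array([1.0, 2.0, 3.0, 4.0])}}
        block = make_block(series, [("x", 0), ("x", -1)], ("x", 1))
        # valid rows: t=1 -> (2,1) predicting 3; t=2 -> (3,2) predicting 4
        np.testing.assert_array_equal(block.valid, [False, True, True, False])
        np.testing.assert_allclose(block.x[block.valid],
                                   [[2.0, 1.0], [3.0, 2.0]])
        np.testing.assert_allclose(block.y[block.valid], [3.0, 4.0])

    def test_identity_embedding_equals_series(self):
        s = np.array([5.0, 6.0, 7.0])
        block = make_block({"x": {"r1": s}}, [("x", 0)], ("x", 0))
        assert block.valid.all()
        np.testing.assert_allclose(block.x[:, 0], s)
        np.testing.assert_allclose(block.y, s)

    def test_no_row_crosses_replicate_boundary(self):
        series = {"x": {"r1": np.arange(5.0), "r2": 100 + np.arange(5.0)}}
        block = make_block(series, [("x", 0), ("x", -1)], ("x", 1))
        for row, rep, ok in zip(block.x, block.replicate, block.valid):
            if ok:
                vals = set(row)
                assert (vals < set(np.arange(5.0))) or \
                    (vals < set(100 + np.arange(5.0)))


class TestSimplexForecast:
    def test_k1_returns_nearest_neighbor_target(self):
        series = {"x": {"r1": np.array([0.0, 1.0, 0.1, 5.0, 0.9, 2.0])}}
        block = make_block(series, [("x", 0)], ("x", 1))
        preds = simplex_forecast(block, k=1)
        # row t=0 (value 0.0): nearest is t=2 (0.1) -> predicts y[2]=5.0
        assert preds[0] == block.y[2]

    def test_zero_distance_duplicates_predict_their_target(self):
        series = {"x": {"r1": np.array([1.0, 7.0, 1.0, 3.0, 1.0, 3.0])}}
        block = make_block(series, [("x", 0)], ("x", 1))
        preds = simplex_forecast(block, k=2)
        # rows with value 1.0 at t=0: zero-distance copies at t=2 and t=4
        # with targets 3.0 and 3.0 -> exact prediction 3.0
        assert preds[0] == pytest.approx(3.0)

    def test_matches_brute_force_on_random_blocks(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            n = int(rng.integers(12, 30))
            series = {"x": {"r1": rng.normal(size=n)},
                      "y": {"r1": rng.normal(size=n)}}
            block = make_block(series, [("x", 0), ("x", -1), ("y", -1)],
                               ("x", 1))
            k = block.n_coords + 1
            preds = simplex_forecast(block)
            xv, yv, tv = block.valid_rows()
            expect = brute_force_simplex(xv, yv, tv, k)
            np.testing.assert_allclose(preds[block.valid], expect,
                                       rtol=0, atol=0)

    def test_weights_invariant_to_global_rescaling(self):
        rng = np.random.default_rng(12)
        s = rng.normal(size=25)
        for scale in (1.0, 17.3):
            series = {"x": {"r1": scale * s}}
            block = make_block(series, [("x", 0), ("x", -1)], ("x", 1))
            p = simplex_forecast(block)
            if scale == 1.0:
                ref = p
        np.testing.assert_allclose(p[block.valid] / scale, ref[block.valid],
                                   rtol=1e-12)

    def test_too_few_neighbors_names_the_row(self):
        series = {"x": {"r1": np.array([1.0, 2.0, 3.0])}}
        block = make_block(series, [("x", 0)], ("x", 1))
        with pytest.raises(ValueError, match="neighbors"):
            simplex_forecast(block, k=5)


class TestForecastSkill:
    def test_perfect_prediction(self):
        sk = m.forecast_skill(np.array([1.0, 2.0, 3.0]),
                              np.array([1.0, 2.0, 3.0]))
        assert (sk.rho, sk.mse, sk.n_pred) == (pytest.approx(1.0), 0.0, 3)

    def test_anticorrelated(self):
        obs = np.array([-1.0, 0.0, 1.0])
        sk = m.forecast_skill(-obs, obs)
        assert sk.rho == pytest.approx(-1.0)

    def test_hand_computed_pearson_and_mse(self):
        p = np.array([1.0, 2.0, 4.0])
        o = np.array([1.0, 3.0, 3.0])
        sk = m.forecast_skill(p, o)
        assert sk.mse == pytest.approx(2.0 / 3.0)
        assert sk.rho == pytest.approx(np.corrcoef(p, o)[0, 1])

    def test_white_noise_skill_centers_on_zero(self):
        rng = np.random.default_rng(100)
        rhos = []
        for _ in range(100):
            series = {"x": {"r1": rng.normal(size=40)}}
            block = make_block(series, [("x", 0), ("x", -1)], ("x", 1))
            sk = m.forecast_skill(simplex_forecast(block), block.y)
            rhos.append(sk.rho)
        assert abs(np.mean(rhos)) < 0.1


class TestSelectEmbedding:
    def test_singleton_grid_returned(self):
        rng = np.random.default_rng(13)
        s = {"r1": rng.normal(size=30)}
        assert m.select_embedding(s, e_grid=[3]) == 3

    def test_ar1_modal_choice_is_dimension_one(self):
        # a first-order autoregression needs one lag; E=1 is the modal pick
        from collections import Counter
        rng = np.random.default_rng(14)
        counts = Counter()
        for _ in range(30):
            x = np.zeros(25)
            for t in range(24):
                x[t + 1] = 0.8 * x[t] + rng.normal(0, 0.3)
            counts[m.select_embedding({"r1": x}, e_grid=range(1, 5))] += 1
        assert counts.most_common(1)[0][0] == 1

    def test_two_dimensional_map_needs_higher_dimension(self):
        # one observable of the (2-D) Henon map: E >= 2 required
        rng = np.random.default_rng(15)
        picks = []
        for _ in range(10):
            x, y = rng.uniform(-0.1, 0.1, 2)
            xs = np.empty(80)
            for t in range(80):
                xs[t] = x
                x, y = 1 - 1.4 * x * x + y, 0.3 * x
            picks.append(m.select_embedding({"r1": xs}, e_grid=range(1, 6)))
        assert np.median(picks) >= 2
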