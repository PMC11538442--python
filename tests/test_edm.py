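"""Unit and property tests for the delay-embedding / cross-mapping core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causalweb import (
    ConstantSeriesError,
    EmbeddingParams,
    SeriesLengthError,
    UniformSeries,
    ccm_library_sweep,
    ccm_rho,
    ccm_scan,
    cross_map_predict,
    embed,
    max_abs_xcorr,
)
from conftest import coupled_logistic_pair, logistic_map


# ---------------------------------------------------------------- oracle ---

def brute_force_cross_map(target, library, tp):
    """Independent simplex oracle: exhaustive distances, full stable sort.

    Mirrors the published prediction formula directly: for each library row,
    find the E+1 nearest other rows by Euclidean distance (ties broken by
    ascending time), weight them by exp(-d/d1) normalized, and average the
    target at the neighbours' prediction times.
    """
    E = library.params.E
    k = E + 1
    preds, obs, times = [], [], []
    rows = library.vectors
    row_times = library.row_times
    valid = [
        i for i in range(len(rows))
        if not np.isnan(target.value_at(int(row_times[i]) + tp))
    ]
    for qi in valid:
        cands = []
        for i in valid:
            if i == qi:
                continue
            d = float(np.sqrt(np.sum((rows[i] - rows[qi]) ** 2)))
            cands.append((d, int(row_times[i])))
        cands.sort()
        nn = cands[:k]
        d1 = nn[0][0]
        if d1 == 0:
            u = np.array([1.0 if d == 0 else 0.0 for d, _ in nn])
        else:
            u = np.array([np.exp(-d / d1) for d, _ in nn])
        w = u / u.sum()
        pred = sum(
            wi * target.value_at(t + tp) for wi, (_, t) in zip(w, nn)
        )
        preds.append(pred)
        obs.append(target.value_at(int(row_times[qi]) + tp))
        times.append(int(row_times[qi]) + tp)
    return np.array(preds), np.array(obs), np.array(times)


# ----------------------------------------------------------------- embed ---

def test_embed_basic_example():
    s = UniformSeries([1, 2, 3, 4, 5])
    ss = embed(s, EmbeddingParams(E=2, tau=1))
    assert ss.vectors.tolist() == [[2, 1], [3, 2], [4, 3], [5, 4]]
    assert ss.row_times.tolist() == [1, 2, 3, 4]


def test_embed_E1_is_identity():
    s = UniformSeries(np.arange(7.0))
    ss = embed(s, EmbeddingParams(E=1, tau=3))
    assert np.array_equal(ss.vectors[:, 0], s.values)
    assert np.array_equal(ss.row_times, s.time_index)


def test_embed_row_count_and_first_time():
    s = UniformSeries(np.arange(10.0))
    ss = embed(s, EmbeddingParams(E=3, tau=2))
    assert len(ss) == 6
    assert ss.row_times[0] == 4


def test_embed_too_short_raises_with_minimum():
    s = UniformSeries(np.arange(4.0))
    with pytest.raises(SeriesLengthError, match="at least 5"):
        embed(s, EmbeddingParams(E=5, tau=1))


def test_embed_drops_rows_with_missing_values():
    v = np.arange(10.0)
    v[4] = np.nan
    ss = embed(UniformSeries(v), EmbeddingParams(E=2, tau=1))
    # rows at t=4 and t=5 contain the NaN
    assert 4 not in ss.row_times and 5 not in ss.row_times
    assert len(ss) == 9 - 2


@given(
    n=st.integers(8, 60),
    E=st.integers(1, 4),
    tau=st.integers(1, 3),
    seed=st.integers(0, 10_000),
)
@settings(max_examples=60, deadline=None)
def test_embed_shape_invariants(n, E, tau, seed):
    """Row count, first row time and column content follow the defining map."""
    if n <= (E - 1) * tau:
        return
    rng = np.random.default_rng(seed)
    s = UniformSeries(rng.normal(size=n))
    ss = embed(s, EmbeddingParams(E, tau))
    assert len(ss) == n - (E - 1) * tau
    assert ss.row_times[0] == (E - 1) * tau
    t = int(ss.row_times[len(ss) // 2])
    for j in range(E):
        assert ss.vectors[len(ss) // 2, j] == s.values[t - j * tau]


# ----------------------------------------------------- cross_map_predict ---

@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("E,tp", [(2, 0), (3, -1), (2, 1)])
def test_cross_map_matches_brute_force_oracle(seed, E, tp):
    rng = np.random.default_rng(seed)
    n = rng.integers(12, 50)
    target = UniformSeries(rng.normal(size=n), name="T")
    lib_series = UniformSeries(rng.normal(size=n), name="L")
    library = embed(lib_series, EmbeddingParams(E, 1, tp))
    res = cross_map_predict(target, library, tp)
    preds, obs, times = brute_force_cross_map(target, library, tp)
    assert np.allclose(res.predictions, preds, atol=1e-12, rtol=0)
    assert np.array_equal(res.prediction_times, times)
    assert np.allclose(res.observations, obs, atol=1e-12, rtol=0)


def test_self_map_on_noiseless_logistic():
    x = logistic_map(3.8, 500)
    s = UniformSeries(x, name="x")
    res = ccm_rho(s, s, EmbeddingParams(2, 1, 0))
    assert res.rho > 0.99


def test_rho_recomputable_from_stored_vectors(chaotic_series):
    res = ccm_rho(chaotic_series, chaotic_series, EmbeddingParams(2, 1, 0))
    again = np.corrcoef(res.predictions, res.observations)[0, 1]
    assert res.rho == pytest.approx(again, abs=1e-14)
    assert res.n_pred == len(res.predictions) == len(res.observations)


def test_equidistant_neighbors_get_uniform_weights():
    # library embedding with all distances equal: one-hot-like scalar rows
    target = UniformSeries([0.0, 1.0, 2.0, 3.0, 4.0, 5.0], name="T")
    lib = UniformSeries([0.0, 1.0, 0.0, 1.0, 0.0, 1.0], name="L")
    library = embed(lib, EmbeddingParams(1, 1))
    res = cross_map_predict(target, library, 0)
    # for the query at t=0 (value 0), neighbours at distance 0 are t=2, t=4
    # and at distance 1 are t=1, 3, 5; E+1=2 nearest are the two zeros,
    # both at distance 0 -> equal weights -> prediction = mean(target[2,4])
    assert res.predictions[0] == pytest.approx((2.0 + 4.0) / 2)


def test_degenerate_constant_observation_is_flagged():
    target = UniformSeries(np.ones(30), name="T")
    lib = UniformSeries(np.sin(np.arange(30.0)), name="L")
    res = cross_map_predict(target, embed(lib, EmbeddingParams(2, 1)), 0)
    assert res.degenerate and np.isnan(res.rho)


def test_library_too_small_raises():
    target = UniformSeries(np.arange(5.0))
    lib = embed(UniformSeries(np.arange(5.0)), EmbeddingParams(4, 1))
    with pytest.raises(SeriesLengthError):
        cross_map_predict(target, lib, 0)


# --------------------------------------------------------------- ccm_rho ---

def test_affine_invariance_of_rho():
    """Positive affine rescaling of either series leaves rho unchanged."""
    X, Y = coupled_logistic_pair(400, 0.3, seed=5)
    params = EmbeddingParams(3, 1, -1)
    base = ccm_rho(X, Y, params).rho
    X2 = X.with_values(7.5 * X.values + 3.0)
    Y2 = Y.with_values(0.2 * Y.values - 11.0)
    assert ccm_rho(X2, Y, params).rho == pytest.approx(base, abs=1e-10)
    assert ccm_rho(X, Y2, params).rho == pytest.approx(base, abs=1e-10)


def test_directionality_on_unidirectional_coupling():
    """The driver is recovered from the response better than vice versa in
    at least 90% of seeded replicates."""
    params = EmbeddingParams(3, 1, 0)
    wins = 0
    n_rep = 20
    for seed in range(n_rep):
        X, Y = coupled_logistic_pair(1000, 0.35, seed=seed)
        rho_xy = ccm_rho(X, Y, params).rho  # X -> Y: M_Y recovers X
        rho_yx = ccm_rho(Y, X, params).rho
        wins += rho_xy > rho_yx
    assert wins >= 0.9 * n_rep


def test_independent_noise_has_no_skill():
    """|rho| for independent white noise stays below its permutation null."""
    rng = np.random.default_rng(11)
    X = UniformSeries(rng.normal(size=500), name="X")
    Y = UniformSeries(rng.normal(size=500), name="Y")
    params = EmbeddingParams(3, 1, 0)
    actual = abs(ccm_rho(X, Y, params).rho)
    null = []
    for i in range(50):
        perm = rng.permutation(len(X.values))
        null.append(abs(ccm_rho(X.with_values(X.values[perm]), Y, params).rho))
    assert actual < np.quantile(null, 0.95)


def test_length_mismatch_raises():
    with pytest.raises(ValueError, match="lengths differ"):
        ccm_rho(UniformSeries(np.arange(10.0)), UniformSeries(np.arange(9.0)),
                EmbeddingParams(2))


# --------------------------------------------------------- max_abs_xcorr ---

def test_xcorr_identity_and_sign():
    x = UniformSeries(np.sin(np.linspace(0, 20, 200)), name="x")
    neg = x.with_values(-x.values)
    assert max_abs_xcorr(x, x, 5) == pytest.approx(1.0)
    assert max_abs_xcorr(x, neg, 5) == pytest.approx(1.0)


def test_xcorr_finds_shifted_copy():
    base = np.sin(np.linspace(0, 40, 400))
    x = UniformSeries(base[:-3], name="x")
    y = UniformSeries(base[3:], name="y")  # y(t) = x(t+3)
    assert max_abs_xcorr(x, y, 5) == pytest.approx(1.0, abs=1e-6)
    assert max_abs_xcorr(x, y, 1) < 1.0 - 1e-4  # lag 3 out of reach


def test_xcorr_constant_series_raises():
    x = UniformSeries(np.ones(50), name="c")
    y = UniformSeries(np.arange(50.0), name="y")
    with pytest.raises(ConstantSeriesError):
        max_abs_xcorr(x, y, 3)


# -------------------------------------------------------------- ccm_scan ---

def test_scan_singleton_equals_single_call(chaotic_series):
    s = chaotic_series
    best, table = ccm_scan(s, s, [2], tau=1, tp=0)
    single = ccm_rho(s, s, EmbeddingParams(2, 1, 0))
    assert best.rho == pytest.approx(single.rho)
    assert len(table) == 1


def test_scan_table_has_one_row_per_feasible_E():
    X, Y = coupled_logistic_pair(300, 0.3, seed=2)
    best, table = ccm_scan(X, Y, range(1, 6), tau=1, tp=0)
    assert set(table["E"]) == {1, 2, 3, 4, 5}
    assert best.rho == table["rho"].max()


def test_scan_no_feasible_E_raises():
    s = UniformSeries(np.arange(8.0))
    with pytest.raises(SeriesLengthError):
        ccm_scan(s, s, [30, 40], tau=1, tp=0)


# ---------------------------------------------------- ccm_library_sweep ---

def test_sweep_full_library_equals_full_rho():
    X, Y = coupled_logistic_pair(300, 0.3, seed=3)
    params = EmbeddingParams(3, 1, 0)
    full_rows = len(embed(Y, params))
    table = ccm_library_sweep(X, Y, params, [full_rows], n_samples=1, seed=0)
    assert table["mean_rho"].iloc[0] == pytest.approx(
        ccm_rho(X, Y, params).rho
    )


def test_sweep_convergence_on_coupled_pair():
    X, Y = coupled_logistic_pair(600, 0.35, seed=4)
    params = EmbeddingParams(3, 1, 0)
    table = ccm_library_sweep(X, Y, params, [30, 120, 500], n_samples=8, seed=1)
    rhos = table["mean_rho"].to_numpy()
    assert rhos[-1] > rhos[0]  # skill grows with library size


def test_sweep_size_below_minimum_raises():
    X, Y = coupled_logistic_pair(300, 0.3, seed=6)
    with pytest.raises(ValueError, match="below the minimum"):
        ccm_library_sweep(X, Y, EmbeddingParams(3, 1, 0), [3], seed=0)
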