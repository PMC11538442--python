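"""Empirical dynamic modeling core: delay embedding, simplex cross-map
prediction and convergent cross mapping (CCM).

The causal logic of CCM runs "backwards" relative to ordinary prediction: if
a variable X forces a variable Y, then the attractor reconstructed from Y
contains an imprint of X, so the states of Y can be used to recover
contemporaneous (or lagged) values of X.  Skill is measured as the Pearson
correlation rho between cross-map estimates and observations of X; rho
substantially above chance is evidence for an X -> Y causal influence.

Cross-map predictions use the simplex convention: the E+1 nearest library
vectors (Euclidean distance, the query's own time excluded) are combined
with exponential weights ``u_i = exp(-d_i / d_1)`` normalised to sum to one,
where ``d_1`` is the distance to the nearest neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .series import (
    ConstantSeriesError,
    EmbeddingParams,
    SeriesLengthError,
    UniformSeries,
)

# Libraries up to this many rows use exact exhaustive distances with
# deterministic (distance, time) tie-breaking; larger libraries use a k-d
# tree with a candidate surplus, which resolves exact distance ties in the
# tree's deterministic order instead.
_EXACT_PATH_MAX_ROWS = 4000
_KDTREE_SURPLUS = 16


@dataclass(frozen=True)
class StateSpace:
    """Delay-coordinate reconstruction of one series.

    Row ``i`` is the vector ``(x(t), x(t-tau), ..., x(t-(E-1)tau))`` for
    ``t = row_times[i]``; rows that would contain missing values are dropped.
    """

    vectors: np.ndarray
    row_times: np.ndarray
    params: EmbeddingParams

    def __len__(self) -> int:
        return len(self.row_times)


@dataclass(frozen=True)
class CrossMapResult:
    """Outcome of one directed cross-map.

    ``rho`` is the Pearson correlation between cross-map predictions and
    observations of the target.  ``degenerate`` marks results where rho is
    undefined (constant predictions or observations); such results carry
    ``rho = nan`` rather than a silent zero.
    """

    rho: float
    predictions: np.ndarray
    observations: np.ndarray
    prediction_times: np.ndarray
    params: EmbeddingParams
    n_pred: int
    degenerate: bool = False


def embed(x: UniformSeries, params: EmbeddingParams) -> StateSpace:
    """Time-delay embedding of ``x``.

    Returns one row per time ``t`` from ``(E-1)*tau`` (relative to the series
    start) through the end of the series; rows containing NaN are dropped.
    """
    n = len(x)
    if n < params.min_length():
        raise SeriesLengthError(
            f"series {x.name!r} has {n} samples; embedding with E={params.E}, "
            f"tau={params.tau} requires at least {params.min_length()}"
        )
    span = params.span
    cols = [x.values[span - j * params.tau: n - j * params.tau] for j in range(params.E)]
    vectors = np.column_stack(cols)
    row_times = x.time_index[span:]
    ok = ~np.isnan(vectors).any(axis=1)
    return StateSpace(vectors=vectors[ok], row_times=row_times[ok], params=params)


def _knn(
    vectors: np.ndarray,
    row_times: np.ndarray,
    queries: np.ndarray,
    query_times: np.ndarray,
    k: int,
    exclusion_radius: int,
) -> tuple[np.ndarray, np.ndarray]:
    """k nearest library rows per query, excluding rows within
    ``exclusion_radius`` time steps of the query time.

    Returns (distances, indices) arrays of shape (n_queries, k). Ties are
    broken by ascending row time on the exact path.
    """
    n = len(vectors)
    if n <= _EXACT_PATH_MAX_ROWS:
        d = cdist(queries, vectors)
        excl = np.abs(query_times[:, None] - row_times[None, :]) <= exclusion_radius
        d[excl] = np.inf
        # lexsort: primary key distance, secondary ascending row time
        order = np.lexsort((np.broadcast_to(row_times, d.shape), d), axis=1)[:, :k]
        return np.take_along_axis(d, order, axis=1), order
    tree = cKDTree(vectors)
    n_query = k + 2 * exclusion_radius + 1 + _KDTREE_SURPLUS
    n_query = min(n_query, n)
    dist, idx = tree.query(queries, k=n_query, workers=1)
    out_d = np.empty((len(queries), k))
    out_i = np.empty((len(queries), k), dtype=np.int64)
    for q in range(len(queries)):
        cand_i = idx[q]
        cand_d = dist[q]
        keep = np.abs(row_times[cand_i] - query_times[q]) > exclusion_radius
        cand_i, cand_d = cand_i[keep], cand_d[keep]
        order = np.lexsort((row_times[cand_i], cand_d))[:k]
        out_d[q] = cand_d[order]
        out_i[q] = cand_i[order]
    return out_d, out_i


def _simplex_weights(distances: np.ndarray) -> np.ndarray:
    """Exponential simplex weights per query row (rows of ``distances``).

    When the nearest distance is zero, all zero-distance neighbours share
    the weight equally and positive-distance neighbours get none.
    """
    d1 = distances[:, :1]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(d1 > 0, np.exp(-distances / d1), (distances == 0).astype(float))
    return u / u.sum(axis=1, keepdims=True)


def cross_map_predict(
    target: UniformSeries,
    library: StateSpace,
    tp: int,
    n_neighbors: int | None = None,
    exclusion_radius: int = 0,
) -> CrossMapResult:
    """Cross-map ``target`` from the reconstructed states in ``library``.

    For each library row at time ``t`` whose prediction time ``t + tp``
    carries an observed target value, the E+1 nearest library rows (the row
    at time ``t`` itself excluded; a wider Theiler window via
    ``exclusion_radius``) supply the estimate
    ``X_hat(t+tp) = sum_i w_i * target(t_i + tp)``.
    """
    params = library.params
    k = params.E + 1 if n_neighbors is None else n_neighbors
    if len(library) < k + 1:
        raise SeriesLengthError(
            f"library has {len(library)} rows; need at least {k + 1} "
            f"for {k} neighbours plus the query"
        )
    # Neighbours must themselves have an observed target at t_i + tp.
    lib_targets = np.array([target.value_at(t + tp) for t in library.row_times])
    cand = ~np.isnan(lib_targets)
    if cand.sum() < k + 1:
        raise SeriesLengthError(
            "too few library rows with observed target values for "
            f"{k} neighbours"
        )
    cand_vectors = library.vectors[cand]
    cand_times = library.row_times[cand]
    cand_targets = lib_targets[cand]

    # Queries: library rows whose own prediction time is observed — the same
    # validity condition as for neighbours, so the two sets coincide.
    queries = cand_vectors
    query_times = cand_times

    dists, idx = _knn(cand_vectors, cand_times, queries, query_times, k, exclusion_radius)
    weights = _simplex_weights(dists)
    predictions = np.sum(weights * cand_targets[idx], axis=1)
    observations = cand_targets
    prediction_times = query_times + tp

    degenerate = (
        len(predictions) < 2
        or np.std(predictions) == 0
        or np.std(observations) == 0
    )
    if degenerate:
        rho = float("nan")
    else:
        rho = float(np.corrcoef(predictions, observations)[0, 1])
    return CrossMapResult(
        rho=rho,
        predictions=predictions,
        observations=observations,
        prediction_times=prediction_times,
        params=EmbeddingParams(params.E, params.tau, tp),
        n_pred=len(predictions),
        degenerate=bool(degenerate),
    )


def ccm_rho(
    X: UniformSeries,
    Y: UniformSeries,
    params: EmbeddingParams,
    exclusion_radius: int = 0,
) -> CrossMapResult:
    """CCM estimate of the influence of ``X`` on ``Y``.

    Embeds ``Y`` and cross-maps ``X`` from it at offset ``params.tp``.
    High skill means the states of Y recover X, the signature of X forcing Y.
    """
    if len(X) != len(Y):
        raise ValueError(
            f"series lengths differ: {X.name!r} has {len(X)}, {Y.name!r} has {len(Y)}"
        )
    library = embed(Y, params)
    return cross_map_predict(X, library, params.tp, exclusion_radius=exclusion_radius)


def max_abs_xcorr(
    X: UniformSeries,
    Y: UniformSeries,
    max_lag: int,
    lag0_only: bool = False,
) -> float:
    """Maximum absolute lagged Pearson cross-correlation.

    Scans lags ``-max_lag .. +max_lag`` of ``corr(X(t), Y(t+lag))`` over the
    overlapping segment; serves as the linear null that a CCM rho must beat.
    """
    x, y = X.values, Y.values
    n = len(x)
    if len(y) != n:
        raise ValueError("series lengths differ")
    if max_lag >= n / 2:
        raise ValueError(f"max_lag={max_lag} must be < half the series length {n}")
    if np.nanstd(x) == 0 or np.nanstd(y) == 0:
        raise ConstantSeriesError("cross-correlation undefined for a constant series")
    lags = [0] if lag0_only else range(-max_lag, max_lag + 1)
    best = 0.0
    for lag in lags:
        if lag >= 0:
            xa, ya = x[: n - lag], y[lag:]
        else:
            xa, ya = x[-lag:], y[: n + lag]
        ok = ~(np.isnan(xa) | np.isnan(ya))
        if ok.sum() < 3:
            continue
        xa, ya = xa[ok], ya[ok]
        if xa.std() == 0 or ya.std() == 0:
            continue
        r = abs(float(np.corrcoef(xa, ya)[0, 1]))
        best = max(best, r)
    return best


def ccm_scan(
    X: UniformSeries,
    Y: UniformSeries,
    E_range: Iterable[int],
    tau: int = 1,
    tp: int = -1,
    exclusion_radius: int = 0,
) -> tuple[CrossMapResult, pd.DataFrame]:
    """Run :func:`ccm_rho` over a range of embedding dimensions.

    Returns the best (highest-rho, non-degenerate) result and a table with
    one row per attempted E.  Infeasible E (series too short) are skipped;
    if none is feasible a :class:`SeriesLengthError` is raised.
    """
    E_list = sorted(set(int(E) for E in E_range))
    if not E_list:
        raise ValueError("E_range must be non-empty")
    rows = []
    results: list[CrossMapResult] = []
    for E in E_list:
        try:
            res = ccm_rho(X, Y, EmbeddingParams(E, tau, tp), exclusion_radius)
        except SeriesLengthError:
            continue
        results.append(res)
        rows.append({"E": E, "rho": res.rho, "n_pred": res.n_pred,
                     "degenerate": res.degenerate})
    if not results:
        raise SeriesLengthError(
            f"no E in {E_list} is feasible for series of length {len(X)} "
            f"with tau={tau}"
        )
    table = pd.DataFrame(rows)
    usable = [r for r in results if not r.degenerate]
    best = max(usable, key=lambda r: r.rho) if usable else results[0]
    return best, table


def ccm_library_sweep(
    X: UniformSeries,
    Y: UniformSeries,
    params: EmbeddingParams,
    library_sizes: Sequence[int],
    n_samples: int = 10,
    seed: int | None = None,
    exclusion_radius: int = 0,
) -> pd.DataFrame:
    """Convergence diagnostic: mean cross-map skill versus library size.

    For each requested library size, ``n_samples`` random row subsets of the
    full embedding of Y are used as the library; skill that rises with
    library size is the convergence signature of a genuine causal imprint.
    """
    full = embed(Y, params)
    rng = np.random.default_rng(seed)
    k = params.E + 1
    rows = []
    for size in library_sizes:
        if size < k + 1:
            raise ValueError(
                f"library size {size} is below the minimum {k + 1} "
                f"(E+1 neighbours plus the query)"
            )
        if size > len(full):
            raise ValueError(
                f"library size {size} exceeds available rows {len(full)}"
            )
        rhos = []
        for _ in range(n_samples):
            if size == len(full):
                sub = full
            else:
                pick = np.sort(rng.choice(len(full), size=size, replace=False))
                sub = StateSpace(full.vectors[pick], full.row_times[pick], params)
            res = cross_map_predict(X, sub, params.tp,
                                    exclusion_radius=exclusion_radius)
            if not res.degenerate:
                rhos.append(res.rho)
        rows.append({
            "library_size": size,
            "mean_rho": float(np.mean(rhos)) if rhos else float("nan"),
            "n_used": len(rhos),
        })
    return pd.DataFrame(rows)
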