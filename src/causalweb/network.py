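"""Causal-network construction and comparison.

Every ordered pair of series is tested with CCM and one of two null
procedures.  For model data the null is the maximum absolute lagged
cross-correlation: a link is accepted only when the best cross-map skill
over the scanned embedding dimensions exceeds what linear correlation alone
could produce.  For monthly field-like data the null is a set of seasonal
surrogates: the putative driver is reshuffled within calendar months,
preserving seasonality while destroying any other dynamics, and the link is
accepted when the real skill beats at least ``min_exceeded`` of the
``n_surrogates`` surrogate skills.  In both cases acceptance additionally
requires rho > 0: negative cross-map correlation is not causal skill.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .edm import ccm_rho, ccm_scan, max_abs_xcorr
from .series import ConstantSeriesError, EmbeddingParams, SeriesLengthError, UniformSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CausalLink:
    """One tested directed interaction (accepted or not)."""

    source: str
    target: str
    rho: float
    null_value: float
    null_kind: str  # "xcorr" | "seasonal_surrogate"
    accepted: bool
    E_used: int
    tau: int
    tp: int
    degenerate: bool = False
    untestable: bool = False
    note: str = ""


@dataclass
class CausalNetwork:
    """Directed graph of tested links at one analysis timescale."""

    nodes: tuple[str, ...]
    links: tuple[CausalLink, ...]
    scale_label: str = ""

    def __post_init__(self) -> None:
        pairs = [(l.source, l.target) for l in self.links]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (source, target) links")
        known = set(self.nodes)
        for l in self.links:
            if l.source not in known or l.target not in known:
                raise ValueError(f"link endpoint not in nodes: {l.source}->{l.target}")

    def accepted_links(self) -> list[CausalLink]:
        return [l for l in self.links if l.accepted]

    def accepted_edges(self) -> set[tuple[str, str]]:
        return {(l.source, l.target) for l in self.links if l.accepted}

    def get(self, source: str, target: str) -> CausalLink | None:
        for l in self.links:
            if l.source == source and l.target == target:
                return l
        return None

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for l in self.accepted_links():
            g.add_edge(l.source, l.target, rho=l.rho, null_value=l.null_value)
        return g


GroupMap = Mapping[str, str]


def normalize_sqrt(x: UniformSeries) -> UniformSeries:
    """Min-max normalize to [0, 1] then take the square root.

    The square root damps the multi-order-of-magnitude spikes typical of
    abundance data, so no single excursion dominates nearest-neighbour
    distances in the reconstructed state space.
    """
    v = x.values
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        raise ConstantSeriesError(
            f"series {x.name!r} has zero range; normalization undefined"
        )
    return x.with_values(np.sqrt((v - lo) / (hi - lo)))


def minmax(x: UniformSeries) -> UniformSeries:
    """Min-max normalization to [0, 1] (no square root)."""
    v = x.values
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        raise ConstantSeriesError(
            f"series {x.name!r} has zero range; normalization undefined"
        )
    return x.with_values((v - lo) / (hi - lo))


def aggregate_group(
    series: Sequence[UniformSeries], group_name: str
) -> UniformSeries:
    """Sum of min-max-normalized members: every species contributes equally
    to the aggregate regardless of its absolute abundance."""
    if not series:
        raise ValueError(f"group {group_name!r} has no members")
    t0 = series[0].time_index
    for s in series[1:]:
        if len(s) != len(series[0]) or s.start_time != series[0].start_time:
            raise ValueError(
                f"series {s.name!r} is not aligned with {series[0].name!r}"
            )
    total = np.zeros(len(series[0]))
    for s in series:
        total += minmax(s).values
    return UniformSeries(
        total,
        time_index=t0,
        month_labels=series[0].month_labels,
        name=group_name,
    )


def seasonal_surrogates(
    x: UniformSeries, n_surrogates: int = 100, seed: int | None = None
) -> list[UniformSeries]:
    """Surrogate series that shuffle values within each calendar month.

    Each surrogate permutes the observed values only among samples sharing
    a month label, preserving the seasonal profile exactly while destroying
    all other temporal structure.
    """
    if x.month_labels is None:
        raise ValueError(
            f"series {x.name!r} has no month labels; seasonal surrogates "
            "require monthly data"
        )
    rng = np.random.default_rng(seed)
    month_positions = {m: np.where(x.month_labels == m)[0] for m in range(1, 13)}
    out = []
    for i in range(n_surrogates):
        v = x.values.copy()
        for pos in month_positions.values():
            if len(pos) > 1:
                v[pos] = v[pos[rng.permutation(len(pos))]]
        out.append(x.with_values(v, name=f"{x.name}_surr{i}"))
    return out


def surrogate_link_test(
    X: UniformSeries,
    Y: UniformSeries,
    params: EmbeddingParams,
    n_surrogates: int = 100,
    min_exceeded: int = 95,
    seed: int | None = None,
    shuffle_side: str = "driver",
) -> CausalLink:
    """Test the X -> Y link against the seasonal-surrogate null.

    The real CCM skill is compared with the skill obtained after replacing
    the putative driver X (or the recipient Y, if ``shuffle_side="recipient"``)
    by each of its within-month shuffles; the link is accepted when the real
    skill strictly exceeds at least ``min_exceeded`` of the surrogate skills
    and is positive.
    """
    actual = ccm_rho(X, Y, params)
    shuffled = X if shuffle_side == "driver" else Y
    surrs = seasonal_surrogates(shuffled, n_surrogates, seed)
    surr_rhos = []
    n_degenerate = 0
    for s in surrs:
        if shuffle_side == "driver":
            r = ccm_rho(s, Y, params)
        else:
            r = ccm_rho(X, s, params)
        if r.degenerate:
            n_degenerate += 1
        else:
            surr_rhos.append(r.rho)
    n_exceeded = int(np.sum(actual.rho > np.array(surr_rhos))) if surr_rhos else 0
    flagged = actual.degenerate or n_degenerate > 0.1 * n_surrogates
    accepted = (
        not flagged
        and actual.rho > 0
        and n_exceeded >= min_exceeded
    )
    return CausalLink(
        source=X.name,
        target=Y.name,
        rho=actual.rho,
        null_value=float(n_exceeded),
        null_kind="seasonal_surrogate",
        accepted=accepted,
        E_used=params.E,
        tau=params.tau,
        tp=params.tp,
        degenerate=flagged,
        note=f"{n_degenerate} degenerate surrogates" if n_degenerate else "",
    )


def xcorr_link_test(
    X: UniformSeries,
    Y: UniformSeries,
    E_range: Iterable[int],
    tau: int,
    tp: int,
    max_lag: int | None = None,
    lag0_only: bool = False,
) -> CausalLink:
    """Test the X -> Y link against the lagged cross-correlation null.

    The CCM skill is scanned over ``E_range`` and the best value must exceed
    the maximum absolute cross-correlation between the two series (over lags
    up to the embedding span by default) and be positive.
    """
    E_list = sorted(set(int(e) for e in E_range))
    if max_lag is None:
        max_lag = (max(E_list) - 1) * tau
        max_lag = min(max_lag, (len(X) - 1) // 2 - 1)
        max_lag = max(max_lag, 0)
    best, _ = ccm_scan(X, Y, E_list, tau, tp)
    null = max_abs_xcorr(X, Y, max_lag, lag0_only=lag0_only)
    accepted = (not best.degenerate) and best.rho > null and best.rho > 0
    return CausalLink(
        source=X.name,
        target=Y.name,
        rho=best.rho,
        null_value=null,
        null_kind="xcorr",
        accepted=accepted,
        E_used=best.params.E,
        tau=tau,
        tp=tp,
        degenerate=best.degenerate,
    )


def build_network(
    series: Sequence[UniformSeries],
    params: EmbeddingParams,
    null_kind: str = "seasonal_surrogate",
    group_map: GroupMap | None = None,
    n_surrogates: int = 100,
    min_exceeded: int = 95,
    seed: int | None = None,
    E_range: Iterable[int] | None = None,
    scale_label: str = "",
) -> CausalNetwork:
    """Test every ordered pair of series and assemble a network.

    When ``group_map`` is given, series are first pooled into functional-
    group aggregates (sum of min-max-normalized members) and the network is
    built between aggregates.  Every tested link is recorded whether or not
    it is accepted; pairs failing length preconditions are flagged
    untestable rather than dropped.
    """
    if len(series) < 2:
        raise ValueError("need at least two series")
    if group_map is not None:
        by_group: dict[str, list[UniformSeries]] = {}
        for s in series:
            if s.name in group_map:
                by_group.setdefault(group_map[s.name], []).append(s)
        series = [aggregate_group(v, g) for g, v in sorted(by_group.items())]
    series = sorted(series, key=lambda s: s.name)
    names = [s.name for s in series]
    if len(set(names)) != len(names):
        raise ValueError("series names must be unique")

    master = np.random.SeedSequence(seed)
    links = []
    for i, X in enumerate(series):
        for j, Y in enumerate(series):
            if i == j:
                continue
            pair_seed = int(
                np.random.SeedSequence([0 if seed is None else seed, i, j])
                .generate_state(1)[0] % (2**31)
            )
            try:
                if null_kind == "seasonal_surrogate":
                    link = surrogate_link_test(
                        X, Y, params, n_surrogates, min_exceeded, pair_seed
                    )
                elif null_kind == "xcorr":
                    link = xcorr_link_test(
                        X, Y, E_range or [params.E], params.tau, params.tp
                    )
                else:
                    raise ValueError(f"unknown null_kind {null_kind!r}")
            except (SeriesLengthError, ConstantSeriesError) as err:
                logger.warning("pair %s -> %s untestable: %s", X.name, Y.name, err)
                link = CausalLink(
                    source=X.name, target=Y.name, rho=float("nan"),
                    null_value=float("nan"), null_kind=null_kind,
                    accepted=False, E_used=params.E, tau=params.tau,
                    tp=params.tp, untestable=True, note=str(err),
                )
            links.append(link)
    return CausalNetwork(tuple(names), tuple(links), scale_label=scale_label)


def multiscale_compare(
    netA: CausalNetwork, netB: CausalNetwork
) -> dict[str, set[tuple[str, str]]]:
    """Partition accepted links into those in both networks or only one."""
    if set(netA.nodes) != set(netB.nodes):
        only_a = set(netA.nodes) - set(netB.nodes)
        only_b = set(netB.nodes) - set(netA.nodes)
        raise ValueError(
            f"node sets differ: only in A {sorted(only_a)}, only in B {sorted(only_b)}"
        )
    a, b = netA.accepted_edges(), netB.accepted_edges()
    return {"both": a & b, "A_only": a - b, "B_only": b - a}


def fine_scale_connectance(
    species_net: CausalNetwork,
    groupA: Iterable[str],
    groupB: Iterable[str],
) -> float:
    """Fraction of possible directed cross-group species links realized."""
    A, B = set(groupA), set(groupB)
    if not A or not B:
        raise ValueError("groups must be non-empty")
    if A & B:
        raise ValueError(f"groups overlap: {sorted(A & B)}")
    accepted = species_net.accepted_edges()
    n_cross = sum(
        1 for (s, t) in accepted
        if (s in A and t in B) or (s in B and t in A)
    )
    return n_cross / (2 * len(A) * len(B))


@dataclass(frozen=True)
class LinkedUnlinkedResult:
    linked_counts: tuple[int, ...]
    unlinked_counts: tuple[int, ...]
    linked_mean: float
    unlinked_mean: float
    t_statistic: float
    p_value: float  # one-sided, alternative: linked > unlinked
    descriptive_only: bool = False


def linked_vs_unlinked_test(
    aggregate_net: CausalNetwork,
    species_net: CausalNetwork,
    group_map: GroupMap,
) -> LinkedUnlinkedResult:
    """Do causally linked aggregates have more species-level cross links?

    Each ordered pair of functional groups is classed as linked or unlinked
    according to the aggregate network; its species-level cross-link count
    (accepted links from members of the source group to members of the
    target group) is tallied; the two count distributions are compared with
    a one-sided Welch t-test (alternative: linked > unlinked).
    """
    members: dict[str, set[str]] = {}
    for sp, g in group_map.items():
        members.setdefault(g, set()).add(sp)
    groups = sorted(set(aggregate_net.nodes) & set(members))
    accepted_species = species_net.accepted_edges()
    accepted_agg = aggregate_net.accepted_edges()
    linked, unlinked = [], []
    for g1 in groups:
        for g2 in groups:
            if g1 == g2:
                continue
            count = sum(
                1 for (s, t) in accepted_species
                if s in members[g1] and t in members[g2]
            )
            (linked if (g1, g2) in accepted_agg else unlinked).append(count)
    if len(linked) < 2 or len(unlinked) < 2:
        return LinkedUnlinkedResult(
            tuple(linked), tuple(unlinked),
            float(np.mean(linked)) if linked else float("nan"),
            float(np.mean(unlinked)) if unlinked else float("nan"),
            float("nan"), float("nan"), descriptive_only=True,
        )
    t_stat, p = stats.ttest_ind(
        linked, unlinked, equal_var=False, alternative="greater"
    )
    return LinkedUnlinkedResult(
        tuple(linked), tuple(unlinked),
        float(np.mean(linked)), float(np.mean(unlinked)),
        float(t_stat), float(p),
    )


def compare_foodweb(
    causal_net: CausalNetwork,
    trophic_edges: Iterable[tuple[str, str]],
) -> dict[str, set[tuple[str, str]]]:
    """Overlay a causal web on a trophic (who-eats-whom) edge list.

    A trophic edge implies potential causal influence in both directions, so
    an accepted causal link is "causal_and_trophic" when the trophic list
    contains the pair in either orientation; trophic edges with no accepted
    causal link in either orientation are "trophic_only".
    """
    trophic = list(trophic_edges)
    known = set(causal_net.nodes)
    for (a, b) in trophic:
        for node in (a, b):
            if node not in known:
                raise ValueError(f"unknown node in trophic edge list: {node!r}")
    trophic_set = set(trophic)
    trophic_bidir = trophic_set | {(b, a) for (a, b) in trophic_set}
    causal = causal_net.accepted_edges()
    causal_and_trophic = {e for e in causal if e in trophic_bidir}
    causal_only = causal - causal_and_trophic
    trophic_only = {
        e for e in trophic_set
        if e not in causal and (e[1], e[0]) not in causal
    }
    return {
        "causal_and_trophic": causal_and_trophic,
        "causal_only": causal_only,
        "trophic_only": trophic_only,
    }
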