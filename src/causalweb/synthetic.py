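"""Synthetic community generators with the statistical structure of monthly
ecological monitoring data.

Field plankton series have two properties that shape the inference pipeline:
strong seasonal synchrony across taxa (which can fool naive cross mapping)
and, for genuinely interacting taxa, nonlinear dynamic coupling.  The
generators here are seasonally forced logistic maps — nonlinear, bounded and
well studied as cross-mapping benchmarks — sharing a sinusoidal month effect
on the growth rate, with optional unidirectional coupling.  Any generator
family with those two properties would serve; this one is simply the most
transparent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import UniformSeries


@dataclass(frozen=True)
class SeasonalSeriesConfig:
    """Configuration of one seasonally forced coupled pair."""

    n_years: int = 30
    seasonal_amplitude: float = 0.05
    growth_rate: float = 3.7
    growth_rate_y: float = 3.55
    coupling: float = 0.0
    noise_sd: float = 0.02
    process_noise_sd: float = 0.03
    seasonal_envelope: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3")
        if self.seasonal_amplitude < 0 or self.coupling < 0 or self.noise_sd < 0:
            raise ValueError("amplitude, coupling and noise_sd must be >= 0")


def _month_cycle(n: int) -> np.ndarray:
    return (np.arange(n) % 12) + 1


def make_seasonal_pair(
    cfg: SeasonalSeriesConfig,
) -> tuple[UniformSeries, UniformSeries]:
    """Two monthly series sharing a seasonal forcing, X optionally driving Y.

    Updates (months m(t) = 1..12 cycling), with a shared seasonal factor
    ``s(t) = 1 + seasonal_amplitude * sin(2*pi*m(t)/12)``::

        rx(t)  = growth_rate   * s(t)
        ry(t)  = growth_rate_y * s(t)
        x(t+1) = x(t) * (rx(t) - rx(t) * x(t))
        y(t+1) = y(t) * (ry(t) - ry(t) * y(t) - coupling * x(t))

    so both series fluctuate synchronously through the season while only Y
    receives a dynamic imprint of X.  The two base growth rates differ so
    that, absent coupling, the pair shares only the seasonal profile: with
    identical maps the common forcing sweeps both through the same periodic
    windows and genuinely synchronizes their trajectories.  Small dynamical
    (process) noise plays the role of environmental stochasticity and breaks
    deterministic subharmonic entrainment to the seasonal cycle, which would
    otherwise correlate the pair beyond the monthly profile; observation
    noise (sd ``noise_sd``) is added to the recorded values afterwards.

    Recorded abundances are additionally modulated by a shared seasonal
    envelope ``1 + seasonal_envelope * sin(2*pi*m/12)`` — the bloom cycle —
    which is what gives the pair its strong cross-series seasonal synchrony;
    being a deterministic function of the month it is exactly preserved by
    within-month surrogate shuffles.
    """
    n = 12 * cfg.n_years
    rng = np.random.default_rng(cfg.seed)
    months = _month_cycle(n)
    season = 1.0 + cfg.seasonal_amplitude * np.sin(2 * np.pi * months / 12.0)
    rx = cfg.growth_rate * season
    ry = cfg.growth_rate_y * season
    x = np.empty(n)
    y = np.empty(n)
    x[0] = rng.uniform(0.2, 0.8)
    y[0] = rng.uniform(0.2, 0.8)
    pn = cfg.process_noise_sd
    for t in range(n - 1):
        x[t + 1] = x[t] * (rx[t] - rx[t] * x[t]) + pn * rng.normal()
        y[t + 1] = y[t] * (ry[t] - ry[t] * y[t] - cfg.coupling * x[t]) + pn * rng.normal()
        # keep the maps inside their basin
        x[t + 1] = min(max(x[t + 1], 1e-8), 1.0)
        y[t + 1] = min(max(y[t + 1], 1e-8), 1.0)
    envelope = 1.0 + cfg.seasonal_envelope * np.sin(2 * np.pi * months / 12.0)
    x = x * envelope
    y = y * envelope
    if cfg.noise_sd > 0:
        x = np.clip(x + rng.normal(0, cfg.noise_sd, n), 1e-8, None)
        y = np.clip(y + rng.normal(0, cfg.noise_sd, n), 1e-8, None)
    X = UniformSeries(x, month_labels=months, name="X")
    Y = UniformSeries(y, month_labels=months, name="Y")
    return X, Y


def make_two_timescale_system(
    seed: int = 0,
    n_steps: int = 2400,
    slow_lag: int = 24,
) -> tuple[UniformSeries, UniformSeries, UniformSeries]:
    """Three series with one fast and one coarse-scale causal channel.

    A and B are mutually coupled logistic maps (lag-1 channel); C responds
    to B only at a delay of ``slow_lag`` samples, so the B -> C influence is
    invisible to a lag-1 embedding (whose states hold information about B
    that is 24 chaotic iterations stale) but aligns with a tau = ``slow_lag``
    embedding.
    """
    rng = np.random.default_rng(seed)
    n = n_steps
    a = np.empty(n)
    b = np.empty(n)
    c = np.empty(n)
    a[0] = rng.uniform(0.2, 0.8)
    b[0] = rng.uniform(0.2, 0.8)
    c[0] = rng.uniform(0.2, 0.8)
    for t in range(n - 1):
        a[t + 1] = a[t] * (3.8 - 3.8 * a[t] - 0.1 * b[t])
        b[t + 1] = b[t] * (3.6 - 3.6 * b[t] - 0.35 * a[t])
        # C responds to B lagged by slow_lag-1 so that c(t) encodes
        # b(t - slow_lag), aligning with the tau = slow_lag cross-map
        b_lagged = b[max(t - (slow_lag - 1), 0)]
        c[t + 1] = c[t] * (3.8 - 3.8 * c[t] - 0.4 * b_lagged)
        a[t + 1] = min(max(a[t + 1], 1e-8), 1.0)
        b[t + 1] = min(max(b[t + 1], 1e-8), 1.0)
        c[t + 1] = min(max(c[t + 1], 1e-8), 1.0)
    return (
        UniformSeries(a, name="A"),
        UniformSeries(b, name="B"),
        UniformSeries(c, name="C"),
    )


def make_grouped_community(
    n_groups: int = 2,
    species_per_group: int = 5,
    cross_coupling: np.ndarray | None = None,
    seed: int = 0,
    n_years: int = 40,
    coupling_strength: float = 0.35,
    seasonal_amplitude: float = 0.05,
    noise_sd: float = 0.01,
) -> tuple[list[UniformSeries], dict[str, str], np.ndarray]:
    """Block-structured seasonally forced community.

    ``cross_coupling[i, j]`` is the probability that a species of group j
    drives a species of group i (within-group couplings are absent, matching
    the aggregate-model convention).  Returns the series, the species ->
    group map, and the realized directed coupling-density matrix between
    groups (ground truth for fine-scale connectance checks).
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if cross_coupling is None:
        cross_coupling = np.full((n_groups, n_groups), 0.3)
        np.fill_diagonal(cross_coupling, 0.0)
    cross_coupling = np.asarray(cross_coupling, dtype=float)
    rng = np.random.default_rng(seed)
    n_sp = n_groups * species_per_group
    n = 12 * n_years
    months = _month_cycle(n)

    # adjacency: adj[i, j] = 1 if species j drives species i
    adj = np.zeros((n_sp, n_sp))
    realized = np.zeros((n_groups, n_groups))
    group_of = np.repeat(np.arange(n_groups), species_per_group)
    for i in range(n_sp):
        for j in range(n_sp):
            gi, gj = group_of[i], group_of[j]
            if i != j and gi != gj and rng.random() < cross_coupling[gi, gj]:
                adj[i, j] = coupling_strength
                realized[gi, gj] += 1
    realized /= species_per_group**2

    r_base = rng.uniform(3.55, 3.85, n_sp)
    season = 1.0 + seasonal_amplitude * np.sin(2 * np.pi * months / 12.0)
    x = np.empty((n, n_sp))
    x[0] = rng.uniform(0.2, 0.8, n_sp)
    for t in range(n - 1):
        r = r_base * season[t]
        drive = adj @ x[t]
        x[t + 1] = x[t] * (r - r * x[t] - drive)
        x[t + 1] = np.clip(x[t + 1], 1e-8, 1.0)
    if noise_sd > 0:
        x = np.clip(x + rng.normal(0, noise_sd, x.shape), 1e-8, None)

    series = []
    group_map: dict[str, str] = {}
    for j in range(n_sp):
        name = f"g{group_of[j]}_sp{j % species_per_group}"
        series.append(UniformSeries(x[:, j], month_labels=months, name=name))
        group_map[name] = f"group{group_of[j]}"
    return series, group_map, realized
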