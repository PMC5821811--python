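"""Synthetic data with known ground truth.

Four generators cover the downstream stages:

* a Galton-Watson branching simulator whose critical point (branching ratio
  m = 1) carries the mean-field avalanche exponents tau = 1.5, alpha = 2.0,
  gamma = 0.5 — the reference model against which the inference pipeline is
  validated;
* an embedding of an avalanche catalog into a spike raster (the inverse of
  avalanche extraction, for exact round-trip tests);
* avalanche-size sequences with tunable lag persistence, the ground truth
  for the delta-P memory statistic;
* injection of system-size events (quasi-synchronous near-full-network
  bursts) into a raster, to exercise SSE screening.

All generators thread a single seeded numpy Generator and record the seed,
so fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleEmbeddingError, InvalidParameterError, PlacementError
from .extraction import AvalancheCatalog, SpikeRaster
from .powerlaw import TruncatedDiscretePowerLaw

__all__ = [
    "BranchingConfig",
    "SyntheticCatalogTruth",
    "simulate_branching_avalanches",
    "embed_catalog_as_raster",
    "generate_correlated_sizes",
    "inject_sse",
]

MEAN_FIELD_EXPONENTS = {"tau": 1.5, "alpha": 2.0, "gamma": 0.5}


@dataclass(frozen=True)
class BranchingConfig:
    """Parameters of the Galton-Watson avalanche simulator.

    ``m`` is the branching ratio (mean offspring per node, dimensionless);
    m = 1 is the critical point.  ``offspring_law`` is 'poisson' or
    'binomial' (two trials of probability m/2 each, so m <= 2).
    ``size_cap`` is an absorbing cap preventing runaway supercritical
    cascades; capped cascades are flagged and excluded from fitting.
    """

    m: float
    n_avalanches: int
    offspring_law: str = "poisson"
    size_cap: int = 10**6
    seed: int = 0

    def __post_init__(self):
        if self.offspring_law not in ("poisson", "binomial"):
            raise InvalidParameterError("offspring_law must be 'poisson' or 'binomial'")
        if self.m < 0 or (self.m == 0 and self.offspring_law == "poisson"):
            raise InvalidParameterError("branching ratio m must be positive (or 0 for binomial)")
        if self.offspring_law == "poisson" and self.m <= 0:
            raise InvalidParameterError("poisson offspring requires m > 0")
        if self.offspring_law == "binomial" and self.m > 2:
            raise InvalidParameterError("binomial offspring (2 trials) requires m <= 2")
        if self.n_avalanches < 1:
            raise InvalidParameterError("n_avalanches must be >= 1")
        if self.size_cap < 1:
            raise InvalidParameterError("size_cap must be >= 1")


@dataclass
class SyntheticCatalogTruth:
    """A simulated catalog together with its true critical exponents.

    The true exponents are the mean-field values (1.5, 2.0, 0.5) at m = 1
    and None away from the critical point (no pure power law holds there).
    """

    catalog: AvalancheCatalog
    true_tau: float | None
    true_alpha: float | None
    true_gamma: float | None
    config: BranchingConfig


def simulate_branching_avalanches(config: BranchingConfig) -> SyntheticCatalogTruth:
    """Simulate independent Galton-Watson cascades.

    Each avalanche starts from one ancestor; generation g+1 holds the sum
    of independent offspring draws over generation-g nodes (for Poisson
    offspring the generation total is drawn exactly as Poisson(m * Z_g),
    for binomial as Binomial(2 * Z_g, m/2)).  Size S is the total node
    count including the ancestor, duration T the number of non-empty
    generations.  Cascades reaching ``size_cap`` are stopped and flagged.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_avalanches
    sizes = np.ones(n, dtype=np.int64)
    durations = np.ones(n, dtype=np.int64)
    active = np.ones(n, dtype=np.int64)
    capped = np.zeros(n, dtype=bool)

    alive = np.arange(n)
    while alive.size:
        z = active[alive]
        if config.offspring_law == "poisson":
            off = rng.poisson(config.m * z)
        else:
            off = rng.binomial(2 * z, config.m / 2.0)
        sizes[alive] += off
        durations[alive] += off > 0
        active[alive] = off
        hit_cap = sizes[alive] >= config.size_cap
        capped[alive[hit_cap]] = True
        keep = (off > 0) & ~hit_cap
        alive = alive[keep]

    catalog = AvalancheCatalog(
        sizes=sizes, durations=durations, capped=capped,
        meta={"seed": config.seed, "m": config.m, "offspring_law": config.offspring_law,
              "size_cap": config.size_cap},
    )
    critical = config.m == 1.0
    return SyntheticCatalogTruth(
        catalog=catalog,
        true_tau=MEAN_FIELD_EXPONENTS["tau"] if critical else None,
        true_alpha=MEAN_FIELD_EXPONENTS["alpha"] if critical else None,
        true_gamma=MEAN_FIELD_EXPONENTS["gamma"] if critical else None,
        config=config,
    )


def _draw_gaps(gap_law, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inter-avalanche gaps in empty bins (each >= 1)."""
    if isinstance(gap_law, (int, np.integer)):
        if gap_law < 1:
            raise InvalidParameterError("constant gap must be >= 1 empty bin")
        return np.full(n, int(gap_law), dtype=np.int64)
    kind = gap_law[0]
    if kind == "constant":
        return _draw_gaps(int(gap_law[1]), n, rng)
    if kind == "geometric":
        p = float(gap_law[1])
        if not (0 < p <= 1):
            raise InvalidParameterError("geometric gap probability must lie in (0, 1]")
        return rng.geometric(p, n).astype(np.int64)  # support starts at 1
    raise InvalidParameterError(f"unknown gap law {gap_law!r}")


def embed_catalog_as_raster(
    catalog: AvalancheCatalog,
    n_neurons: int,
    bin_dt: float,
    gap_law=1,
    seed: int = 0,
) -> SpikeRaster:
    """Place a catalog's avalanches into a spike raster, bin-exactly.

    Each avalanche occupies exactly T consecutive bins, each holding at
    least one spike, with S spikes total (one spike per bin, the remaining
    S - T distributed uniformly); consecutive avalanches are separated by
    at least one empty bin drawn from ``gap_law``.  Spikes are placed at
    bin centers and neurons assigned uniformly at random, so re-extracting
    with the same bin width recovers the (S, T) sequence exactly.

    The returned raster uses ``frame_dt = bin_dt`` (one frame per bin).
    """
    if n_neurons < 1:
        raise InvalidParameterError("n_neurons must be >= 1")
    if bin_dt <= 0:
        raise InvalidParameterError("bin_dt must be positive")
    rng = np.random.default_rng(seed)
    n_av = len(catalog)
    if n_av == 0:
        return SpikeRaster(neuron_ids=np.empty(0, dtype=np.int64),
                           times=np.empty(0), n_neurons=n_neurons, frame_dt=bin_dt)
    if np.any(catalog.sizes < catalog.durations):
        raise InfeasibleEmbeddingError("an avalanche with S < T cannot be embedded")

    gaps = _draw_gaps(gap_law, n_av, rng)
    all_bins = []
    all_counts = []
    cursor = 0
    for i in range(n_av):
        S, T = int(catalog.sizes[i]), int(catalog.durations[i])
        counts = np.ones(T, dtype=np.int64)
        if S > T:
            counts += rng.multinomial(S - T, np.full(T, 1.0 / T))
        all_bins.append(np.arange(cursor, cursor + T))
        all_counts.append(counts)
        cursor += T + int(gaps[i])
    occ_bins = np.concatenate(all_bins)
    counts = np.concatenate(all_counts)
    bins = np.repeat(occ_bins, counts)
    # distinct, evenly spaced sub-bin offsets: k spikes in a bin sit at
    # (j+1)/(k+1), so no two spikes ever share a timestamp
    within = (_intra_rank(counts) + 1) / (np.repeat(counts, counts) + 1)
    times = bins.astype(np.float64) + within  # frames == bins
    ids = rng.integers(0, n_neurons, bins.size)
    return SpikeRaster(neuron_ids=ids, times=times, n_neurons=n_neurons, frame_dt=bin_dt)


def _intra_rank(counts: np.ndarray) -> np.ndarray:
    """[0..c0-1, 0..c1-1, ...] for a vector of group sizes."""
    total = int(counts.sum())
    starts = np.repeat(np.cumsum(counts) - counts, counts)
    return np.arange(total) - starts


def _marginal_sampler(marginal):
    """Resolve a marginal distribution spec into a draw(rng, n) callable."""
    if callable(marginal):
        return marginal
    kind = marginal[0]
    if kind == "powerlaw":
        _, exponent, lo, hi = marginal
        model = TruncatedDiscretePowerLaw(float(exponent), int(lo), int(hi))
        return lambda rng, n: model.sample(n, rng)
    if kind == "geometric":
        p = float(marginal[1])
        return lambda rng, n: rng.geometric(p, n).astype(np.int64)
    raise InvalidParameterError(f"unknown marginal spec {marginal!r}")


def generate_correlated_sizes(
    n: int,
    marginal=("powerlaw", 1.5, 1, 10**4),
    persist_prob: float = 0.0,
    seed: int = 0,
    jitter_max: float = 1.5,
) -> np.ndarray:
    """Size sequence with tunable lag-1 persistence.

    With probability ``persist_prob`` the next size repeats the previous
    one up to a multiplicative jitter drawn log-uniform in
    [1/jitter_max, jitter_max] (default 1.5, keeping repeats inside the
    similarity window lambda in (1/3, 3)); otherwise it is drawn fresh
    from the marginal.  ``persist_prob = 0`` gives an i.i.d. sequence.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if not (0.0 <= persist_prob < 1.0):
        raise InvalidParameterError("persist_prob must lie in [0, 1)")
    if not (1.0 < jitter_max < 3.0):
        raise InvalidParameterError("jitter_max must lie in (1, 3)")
    rng = np.random.default_rng(seed)
    draw = _marginal_sampler(marginal)
    fresh = draw(rng, n).astype(np.float64)
    repeat = rng.random(n) < persist_prob
    jitter = np.exp(rng.uniform(-np.log(jitter_max), np.log(jitter_max), n))
    sizes = np.empty(n, dtype=np.int64)
    sizes[0] = max(1, int(round(fresh[0])))
    for i in range(1, n):
        if repeat[i]:
            sizes[i] = max(1, int(round(sizes[i - 1] * jitter[i])))
        else:
            sizes[i] = max(1, int(round(fresh[i])))
    return sizes


def inject_sse(
    raster: SpikeRaster,
    n_events: int,
    participation: float = 1.0,
    duration_bins: int = 2,
    seed: int = 0,
    bin_dt: float | None = None,
) -> SpikeRaster:
    """Add system-size events: near-full-network bursts in short windows.

    Each event makes ``ceil(participation * n_neurons)`` distinct neurons
    fire once within ``duration_bins`` consecutive bins (bins assigned
    round-robin so every bin of the window is occupied), placed inside
    empty stretches of the raster with at least one empty bin on each side.
    ``bin_dt`` defaults to the raster's frame interval.
    """
    if not (0.0 < participation <= 1.0):
        raise InvalidParameterError("participation must lie in (0, 1]")
    if duration_bins < 1 or n_events < 0:
        raise InvalidParameterError("duration_bins >= 1 and n_events >= 0 required")
    if n_events == 0:
        return raster
    if bin_dt is None:
        bin_dt = raster.frame_dt
    rng = np.random.default_rng(seed)

    t = np.sort(raster.times_s)
    need = (duration_bins + 2) * bin_dt
    slots = []
    if t.size == 0:
        slots = [k * (need + bin_dt) for k in range(n_events)]
    else:
        # one event per interior empty stretch wide enough for the window
        # plus one empty bin on each side
        for lo, hi in zip(t[:-1], t[1:]):
            if hi - lo > need + bin_dt:
                slots.append(lo + bin_dt)
    if len(slots) < n_events:
        raise PlacementError(
            f"only {len(slots)} empty stretches can hold a {duration_bins}-bin event "
            f"({n_events} requested)"
        )
    chosen = list(slots[:n_events])

    k = int(np.ceil(participation * raster.n_neurons))
    new_ids, new_times = [raster.neuron_ids], [raster.times]
    for start in chosen:
        start_bin = int(np.ceil(start / bin_dt)) + 1  # align to the global bin grid
        neurons = rng.choice(raster.n_neurons, size=k, replace=False)
        bins = np.resize(np.arange(duration_bins), k)
        rng.shuffle(bins)
        times_s = (start_bin + bins + 0.5) * bin_dt
        new_ids.append(neurons.astype(np.int64))
        new_times.append(times_s / raster.frame_dt)
    return SpikeRaster(
        neuron_ids=np.concatenate(new_ids), times=np.concatenate(new_times),
        n_neurons=raster.n_neurons, frame_dt=raster.frame_dt,
    )
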