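"""Avalanche extraction from spike rasters.

A neuronal avalanche is a maximal run of consecutive time bins in which at
least one neuron fires per bin; avalanches are bounded by empty bins.  The
bin width is set from the data itself as the mean inter-spike interval (ISI)
of the merged population spike train, rounded to an integer number of
acquisition frames.  Recordings dominated by system-size events (SSEs,
quasi-synchronous bursts recruiting most of the network) are screened out
before any criticality fit, because SSEs sit far off the power-law cloud in
the (duration, size) plane and bias exponent estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "SpikeRaster",
    "BinningSpec",
    "Avalanche",
    "AvalancheCatalog",
    "compute_isi",
    "choose_bin_width",
    "extract_avalanches",
    "detect_sse",
    "isi_stationarity_cv",
]


@dataclass(frozen=True)
class SpikeRaster:
    """Spike times for a population of neurons on a common frame clock.

    Parameters
    ----------
    neuron_ids : integer array, one entry per spike.
    times : float array, spike times **in frames** (real-valued allowed,
        e.g. after embedding synthetic avalanches mid-bin).
    n_neurons : number of neurons in the field of view; at least the number
        of distinct ids present.
    frame_dt : acquisition frame interval in seconds (default 30 ms).
    """

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    frame_dt: float = 0.030

    def __post_init__(self):
        ids = np.asarray(self.neuron_ids, dtype=np.int64)
        t = np.asarray(self.times, dtype=np.float64)
        if ids.shape != t.shape or ids.ndim != 1:
            raise InvalidParameterError("neuron_ids and times must be 1-D and equal length")
        if t.size and t.min() < 0:
            raise InvalidParameterError("spike times must be non-negative")
        if self.frame_dt <= 0:
            raise InvalidParameterError("frame_dt must be positive")
        if self.n_neurons < 1:
            raise InvalidParameterError("n_neurons must be >= 1")
        if ids.size and ids.max() >= self.n_neurons:
            raise InvalidParameterError("neuron id exceeds declared n_neurons")
        order = np.argsort(t, kind="stable")
        object.__setattr__(self, "neuron_ids", ids[order])
        object.__setattr__(self, "times", t[order])

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def times_s(self) -> np.ndarray:
        """Spike times in seconds."""
        return self.times * self.frame_dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.neuron_ids, "frame": self.times})


@dataclass(frozen=True)
class BinningSpec:
    """Time-bin specification derived from the ISI.

    ``bin_dt = bin_width_frames * frame_dt``; ``subframe_isi`` flags an ISI
    below the frame interval (the recording is too slow to separate events,
    the bin width is clamped to one frame).
    """

    isi: float
    bin_width_frames: int
    bin_dt: float
    subframe_isi: bool = False

    def __post_init__(self):
        if self.bin_width_frames < 1:
            raise InvalidParameterError("bin_width_frames must be >= 1")
        if self.bin_dt <= 0:
            raise InvalidParameterError("bin_dt must be positive")


@dataclass(frozen=True)
class Avalanche:
    start_bin: int
    duration_T: int
    size_S: int
    participation: float

    def __post_init__(self):
        if not (self.size_S >= self.duration_T >= 1):
            raise InvalidParameterError("avalanche must satisfy S >= T >= 1")
        if not (0.0 < self.participation <= 1.0):
            raise InvalidParameterError("participation must lie in (0, 1]")


@dataclass
class AvalancheCatalog:
    """Ordered avalanche sequence (sizes in spikes, durations in bins).

    The central intermediate of the pipeline.  ``capped`` marks synthetic
    cascades truncated at the simulator's absorbing size cap; those are
    excluded from exponent fits.  ``sse_flags`` marks system-size-event
    candidates after screening.
    """

    sizes: np.ndarray
    durations: np.ndarray
    start_bins: np.ndarray | None = None
    participations: np.ndarray | None = None
    capped: np.ndarray | None = None
    sse_flags: np.ndarray | None = None
    binning: BinningSpec | None = None
    n_neurons: int | None = None
    recording_has_sse: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        self.durations = np.asarray(self.durations, dtype=np.int64)
        if self.sizes.shape != self.durations.shape:
            raise InvalidParameterError("sizes and durations must have equal length")
        if self.sizes.size and np.any(self.sizes < self.durations):
            raise InvalidParameterError("every avalanche must satisfy S >= T")
        if self.sizes.size and np.any(self.durations < 1):
            raise InvalidParameterError("durations must be >= 1")
        for name in ("start_bins", "capped", "sse_flags", "participations"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != self.sizes.shape:
                    raise InvalidParameterError(f"{name} must match catalog length")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return int(self.sizes.size)

    @property
    def fit_mask(self) -> np.ndarray:
        """Avalanches admissible for exponent fitting (uncapped cascades).

        SSE screening acts at the recording level (a flagged recording is
        excluded whole), not by dropping individual avalanches.
        """
        mask = np.ones(len(self), dtype=bool)
        if self.capped is not None:
            mask &= ~self.capped.astype(bool)
        return mask

    def to_frame(self) -> pd.DataFrame:
        data = {"index": np.arange(len(self)), "size": self.sizes, "duration": self.durations}
        if self.capped is not None:
            data["capped_flag"] = self.capped.astype(int)
        if self.participations is not None:
            data["participation"] = self.participations
        if self.sse_flags is not None:
            data["sse_flag"] = self.sse_flags.astype(int)
        return pd.DataFrame(data)


def compute_isi(raster: SpikeRaster) -> float:
    """Mean inter-spike interval of the merged population spike train, in seconds.

    All spikes are pooled across neurons and sorted; the ISI is the mean of
    consecutive differences, i.e. ``(t_last - t_first) / (N - 1)``.
    """
    if raster.n_spikes < 2:
        raise InsufficientDataError("ISI requires at least 2 spikes")
    t = np.sort(raster.times_s)
    return float((t[-1] - t[0]) / (t.size - 1))


def choose_bin_width(isi: float, frame_dt: float) -> BinningSpec:
    """Round the ISI to an integer number of frames (half-to-even).

    An ISI below the frame interval cannot be resolved by the acquisition;
    the bin width is clamped to one frame and flagged.
    """
    if isi <= 0 or frame_dt <= 0:
        raise InvalidParameterError("isi and frame_dt must be positive")
    subframe = isi < frame_dt
    if subframe:
        warnings.warn(
            "ISI is below the acquisition frame interval; events may be "
            "under-separated (bin width clamped to 1 frame)",
            stacklevel=2,
        )
    width = max(1, round(isi / frame_dt))
    return BinningSpec(isi=isi, bin_width_frames=width, bin_dt=width * frame_dt,
                       subframe_isi=subframe)


def _bin_indices(raster: SpikeRaster, binning: BinningSpec, bin_offset: float) -> np.ndarray:
    # bin on the native frame clock: seconds-domain division is not exact
    # for frame-locked spike times
    off_frames = bin_offset / raster.frame_dt
    return np.floor((raster.times - off_frames) / binning.bin_width_frames).astype(np.int64)


def extract_avalanches(
    raster: SpikeRaster,
    binning: BinningSpec,
    bin_offset: float = 0.0,
) -> AvalancheCatalog:
    """Segment a raster into avalanches: maximal runs of occupied time bins.

    Bins are half-open ``[k*bin_dt, (k+1)*bin_dt)`` anchored at time zero
    (shiftable via ``bin_offset`` for sensitivity checks).  Size S counts all
    spikes in the run, duration T its bins, participation the fraction of
    neurons firing at least once.  An empty raster yields an empty catalog.
    """
    if raster.n_spikes == 0:
        empty = np.empty(0, dtype=np.int64)
        return AvalancheCatalog(
            sizes=empty, durations=empty.copy(), start_bins=empty.copy(),
            participations=np.empty(0), binning=binning, n_neurons=raster.n_neurons,
        )
    bins = _bin_indices(raster, binning, bin_offset)
    occupied, counts = np.unique(bins, return_counts=True)
    # run boundaries: where consecutive occupied bins are not adjacent
    breaks = np.flatnonzero(np.diff(occupied) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [occupied.size - 1]))

    cum = np.concatenate(([0], np.cumsum(counts)))
    sizes = cum[ends + 1] - cum[starts]
    durations = occupied[ends] - occupied[starts] + 1
    start_bins = occupied[starts]

    # participation: distinct neurons per run; spikes are bin-sorted via argsort
    order = np.argsort(bins, kind="stable")
    ids_sorted = raster.neuron_ids[order]
    participations = np.empty(starts.size, dtype=np.float64)
    for i in range(starts.size):
        sl = ids_sorted[cum[starts[i]]:cum[ends[i] + 1]]
        participations[i] = np.unique(sl).size / raster.n_neurons

    return AvalancheCatalog(
        sizes=sizes, durations=durations, start_bins=start_bins,
        participations=participations, binning=binning, n_neurons=raster.n_neurons,
    )


def detect_sse(
    catalog: AvalancheCatalog,
    participation_threshold: float = 0.75,
    min_events: int = 3,
) -> AvalancheCatalog:
    """Flag system-size-event candidates by participation threshold.

    An avalanche recruiting at least ``participation_threshold`` of the
    network is an SSE candidate; a recording with ``min_events`` or more
    candidates is flagged as SSE-containing and is excluded whole from
    downstream exponent fits unless explicitly overridden.
    """
    if not (0.0 < participation_threshold <= 1.0) and participation_threshold != 0.0:
        raise InvalidParameterError("participation_threshold must lie in [0, 1]")
    if catalog.participations is None:
        raise InvalidParameterError("catalog lacks participation data; re-extract from a raster")
    flags = catalog.participations >= participation_threshold
    out = replace_catalog(catalog, sse_flags=flags)
    out.recording_has_sse = bool(flags.sum() >= min_events) and len(catalog) > 0
    return out


def replace_catalog(catalog: AvalancheCatalog, **changes) -> AvalancheCatalog:
    """Shallow copy of a catalog with selected fields replaced."""
    kwargs = dict(
        sizes=catalog.sizes, durations=catalog.durations, start_bins=catalog.start_bins,
        participations=catalog.participations, capped=catalog.capped,
        sse_flags=catalog.sse_flags, binning=catalog.binning,
        n_neurons=catalog.n_neurons, recording_has_sse=catalog.recording_has_sse,
        meta=dict(catalog.meta),
    )
    kwargs.update(changes)
    return AvalancheCatalog(**kwargs)


def isi_stationarity_cv(raster: SpikeRaster, n_segments: int = 10) -> float:
    """Coefficient of variation of the ISI across equal-duration segments.

    The ISI-derived bin width is only meaningful when the firing rate is
    roughly stationary; a CV above ~0.5 warrants caution.  Segments with
    fewer than 2 spikes are skipped.
    """
    if raster.n_spikes < 2:
        raise InsufficientDataError("stationarity check requires at least 2 spikes")
    t = np.sort(raster.times_s)
    edges = np.linspace(t[0], t[-1] + 1e-12, n_segments + 1)
    isis = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        seg = t[(t >= lo) & (t < hi)]
        if seg.size >= 2:
            isis.append((seg[-1] - seg[0]) / (seg.size - 1))
    if len(isis) < 2:
        return 0.0
    isis = np.asarray(isis)
    return float(isis.std(ddof=1) / isis.mean())
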