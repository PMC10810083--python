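"""High-amplitude event detection on the RMS co-fluctuation series.

Peaks of the RMS series are tested against a pooled null distribution of
peak amplitudes obtained from circularly shifted parcel time series; the
surviving peaks (BH-FDR within subject) are "events". Frames are then
categorized (event / non-event peak / trough / other) and each category's
ability to reconstruct static FC from a small subsample of frames is
quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .edges import (
    EdgeTimeSeries,
    FCMatrix,
    ParcelTimeSeries,
    RMSSeries,
    compute_edge_timeseries,
    compute_rms,
    vectorize_pattern,
)

__all__ = [
    "ExtremaSet",
    "NullPeakDistribution",
    "EventTable",
    "FrameCategories",
    "SimilarityReport",
    "BinningReport",
    "find_local_extrema",
    "build_null_peak_distribution",
    "detect_events",
    "categorize_frames",
    "reconstruct_fc_similarity",
    "bin_frames_by_amplitude",
]

CATEGORY_NAMES = ("event", "non_event_peak", "trough", "other")


@dataclass
class ExtremaSet:
    peak_frames: np.ndarray
    trough_frames: np.ndarray
    peak_amplitudes: np.ndarray
    trough_amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.peak_frames = np.asarray(self.peak_frames, dtype=int)
        self.trough_frames = np.asarray(self.trough_frames, dtype=int)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        self.trough_amplitudes = np.asarray(self.trough_amplitudes, dtype=float)
        if np.intersect1d(self.peak_frames, self.trough_frames).size:
            raise ValueError("peaks and troughs must be disjoint")


@dataclass
class NullPeakDistribution:
    null_peak_amplitudes: np.ndarray
    n_runs: int
    seed: int

    def __post_init__(self) -> None:
        v = np.asarray(self.null_peak_amplitudes, dtype=float)
        if v.size == 0:
            raise ValueError("null peak distribution is empty")
        if (v < 0).any():
            raise ValueError("null peak amplitudes must be non-negative")
        self.null_peak_amplitudes = v


@dataclass
class EventTable:
    """Per-peak statistics: frame, amplitude, p, BH-adjusted q, event flag."""

    frames: np.ndarray
    amplitudes: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    is_event: np.ndarray
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.q_values = np.asarray(self.q_values, dtype=float)
        self.is_event = np.asarray(self.is_event, dtype=bool)

    @property
    def event_frames(self) -> np.ndarray:
        return self.frames[self.is_event]

    @property
    def n_events(self) -> int:
        return int(self.is_event.sum())


@dataclass
class FrameCategories:
    """Per-frame category label; mutually exclusive, covering all T frames."""

    labels: np.ndarray  # length-T array of strings from CATEGORY_NAMES

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(CATEGORY_NAMES)
        if bad:
            raise ValueError(f"unknown frame categories: {bad}")

    def frames_in(self, category: str) -> np.ndarray:
        return np.flatnonzero(self.labels == category)

    def counts(self) -> dict[str, int]:
        return {c: int((self.labels == c).sum()) for c in CATEGORY_NAMES}


@dataclass
class SimilarityReport:
    """Mean/SD over repetitions of corr(mean subsampled pattern, static FC)."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_repetitions: int
    frames_per_sample: int
    sampled_with_replacement: dict[str, bool] = field(default_factory=dict)
    per_repetition: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class BinningReport:
    mode: str
    bin_edges: np.ndarray
    similarity: np.ndarray       # per-bin corr(mean pattern, FC)
    dispersion: np.ndarray       # per-bin mean |gap| between consecutive frames / T
    bin_frames: list[np.ndarray]
    merged_bins: list[int] = field(default_factory=list)


def find_local_extrema(rms: RMSSeries) -> ExtremaSet:
    """Strict local maxima/minima; a plateau run contributes its first frame.

    Only interior runs count: a run touching the first or last frame is never
    an extremum.
    """
    v = rms.values
    if v.size < 3:
        raise ValueError("need at least 3 frames")
    # run-length encode equal-value plateaus
    change = np.flatnonzero(np.diff(v) != 0) + 1
    starts = np.concatenate([[0], change])              # run start indices
    run_vals = v[starts]
    peaks, troughs = [], []
    for k in range(1, len(starts) - 1):
        if run_vals[k] > run_vals[k - 1] and run_vals[k] > run_vals[k + 1]:
            peaks.append(starts[k])
        elif run_vals[k] < run_vals[k - 1] and run_vals[k] < run_vals[k + 1]:
            troughs.append(starts[k])
    peaks = np.asarray(peaks, dtype=int)
    troughs = np.asarray(troughs, dtype=int)
    return ExtremaSet(peaks, troughs, v[peaks], v[troughs])


def _rms_from_standardized(z: np.ndarray) -> np.ndarray:
    # sum_{i<j} (z_i z_j)^2 = ((sum z_i^2)^2 - sum z_i^4) / 2, per frame
    s2 = np.sum(z**2, axis=0)
    s4 = np.sum(z**4, axis=0)
    n = z.shape[0]
    e = n * (n - 1) / 2
    return np.sqrt(np.maximum(s2**2 - s4, 0.0) / (2 * e))


def build_null_peak_distribution(
    ts: ParcelTimeSeries, n_runs: int = 100, seed: int = 0
) -> NullPeakDistribution:
    """Pool RMS peak amplitudes from circularly shifted parcel time series.

    Per run, every parcel row is independently shifted by a uniform offset in
    ``[1, T-1]`` (offset 0 excluded), the RMS series is recomputed, and peak
    amplitudes from all runs are pooled.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not ts.standardized:
        raise ValueError("input must be standardized")
    rng = np.random.default_rng(seed)
    z = ts.values
    n, t = z.shape
    pooled: list[np.ndarray] = []
    cols = np.arange(t)
    for _ in range(n_runs):
        offsets = rng.integers(1, t, size=n)
        shifted = z[np.arange(n)[:, None], (cols[None, :] - offsets[:, None]) % t]
        rms = RMSSeries(_rms_from_standardized(shifted))
        ex = find_local_extrema(rms)
        pooled.append(ex.peak_amplitudes)
    return NullPeakDistribution(np.concatenate(pooled), n_runs=n_runs, seed=seed)


def detect_events(
    extrema: ExtremaSet,
    null: NullPeakDistribution,
    q_threshold: float = 0.05,
) -> EventTable:
    """Flag peaks whose amplitude beats the null, controlling FDR at q.

    p = (1 + #{null >= amplitude}) / (1 + #null), then Benjamini-Hochberg
    across the subject's peaks.
    """
    amps = extrema.peak_amplitudes
    if amps.size == 0:
        z = np.empty(0)
        return EventTable(z, z, z, z, z.astype(bool), q_threshold)
    null_sorted = np.sort(null.null_peak_amplitudes)
    n_null = null_sorted.size
    # #{null >= a} via searchsorted on the sorted null
    n_ge = n_null - np.searchsorted(null_sorted, amps, side="left")
    p = (1.0 + n_ge) / (1.0 + n_null)
    reject, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")[:4]
    return EventTable(extrema.peak_frames, amps, p, q, reject, q_threshold)


def categorize_frames(extrema: ExtremaSet, events: EventTable, n_frames: int) -> FrameCategories:
    """Partition frames into event / non_event_peak / trough / other."""
    labels = np.full(n_frames, "other", dtype=object)
    labels[extrema.trough_frames] = "trough"
    labels[extrema.peak_frames] = "non_event_peak"
    labels[events.event_frames] = "event"
    return FrameCategories(labels)


def _corr_with_fc(mean_vec: np.ndarray, fc_vec: np.ndarray) -> float:
    return float(stats.pearsonr(mean_vec, fc_vec).statistic)


def reconstruct_fc_similarity(
    ets: EdgeTimeSeries,
    categories: FrameCategories,
    fc: FCMatrix,
    n_repetitions: int = 100,
    seed: int = 0,
) -> SimilarityReport:
    """How well does each frame category's mean pattern reproduce static FC?

    Per repetition and category, sample k = #event frames (without
    replacement; with replacement and a flag if the category is smaller than
    k), average the sampled co-fluctuation patterns, and correlate the
    upper-triangle vector with static FC. The event category uses all its
    frames once, so it carries no resampling variance.
    """
    rng = np.random.default_rng(seed)
    event_frames = categories.frames_in("event")
    k = event_frames.size
    if k == 0:
        raise ValueError("no event frames: cannot size the subsamples")
    fc_vec = vectorize_pattern(fc.values)
    mean_out: dict[str, float] = {}
    sd_out: dict[str, float] = {}
    flags: dict[str, bool] = {}
    per_rep: dict[str, np.ndarray] = {}

    ev_mean = ets.values[:, event_frames].mean(axis=1)
    ev_sim = _corr_with_fc(ev_mean, fc_vec)
    mean_out["event"], sd_out["event"] = ev_sim, 0.0
    flags["event"] = False
    per_rep["event"] = np.full(n_repetitions, ev_sim)

    for cat in ("non_event_peak", "trough", "other"):
        pool = categories.frames_in(cat)
        if pool.size == 0:
            continue
        replace = pool.size < k
        sims = np.empty(n_repetitions)
        for r in range(n_repetitions):
            pick = rng.choice(pool, size=k, replace=replace)
            sims[r] = _corr_with_fc(ets.values[:, pick].mean(axis=1), fc_vec)
        mean_out[cat] = float(sims.mean())
        sd_out[cat] = float(sims.std(ddof=1)) if n_repetitions > 1 else 0.0
        flags[cat] = replace
        per_rep[cat] = sims
    return SimilarityReport(mean_out, sd_out, n_repetitions, k, flags, per_rep)


def bin_frames_by_amplitude(
    ets: EdgeTimeSeries,
    rms: RMSSeries,
    extrema: ExtremaSet,
    n_bins: int,
    mode: str = "all_frames",
) -> BinningReport:
    """Bin frames by RMS quantile; report per-bin FC similarity and dispersion.

    ``all_frames`` bins every frame; ``peak_binning`` bins only peak frames.
    Temporal dispersion of a bin is the mean absolute gap between consecutive
    sampled frame indices, normalized by T. Bins emptied by ties are merged
    into their lower neighbor and flagged.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if mode not in ("all_frames", "peak_binning"):
        raise ValueError(f"unknown mode {mode!r}")
    t = rms.n_frames
    if mode == "all_frames":
        frames = np.arange(t)
    else:
        frames = extrema.peak_frames
    amps = rms.values[frames]
    edges = np.quantile(amps, np.linspace(0, 1, n_bins + 1))
    # temporal mean of ALL edge products = static FC off-diagonal (sum/(T-1))
    fc_vec = ets.values.sum(axis=1) / (ets.n_frames - 1)

    bins = np.clip(np.searchsorted(edges, amps, side="right") - 1, 0, n_bins - 1)
    merged: list[int] = []
    members = [frames[bins == b] for b in range(n_bins)]
    for b in range(1, n_bins):
        if members[b].size == 0:
            merged.append(b)
    members = [m for m in members if m.size > 0]
    sims = np.empty(len(members))
    disp = np.empty(len(members))
    for b, fr in enumerate(members):
        mean_vec = ets.values[:, fr].mean(axis=1)
        sims[b] = _corr_with_fc(mean_vec, fc_vec) if fr.size > 0 else np.nan
        fr_sorted = np.sort(fr)
        disp[b] = (
            float(np.mean(np.abs(np.diff(fr_sorted)))) / t if fr_sorted.size > 1 else np.nan
        )
    return BinningReport(mode, edges, sims, disp, members, merged)
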