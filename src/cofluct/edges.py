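"""Edge (co-fluctuation) time series construction.

Standardizes parcel time series, expands them into framewise edge products,
and derives static functional connectivity (FC), per-frame co-fluctuation
patterns, and the global RMS amplitude series.

Conventions fixed here and relied on everywhere else:

* standardization uses the sample standard deviation (denominator ``T - 1``),
  and FC is the ``1/(T-1)`` temporal sum of edge products, so that the
  temporal mean of every edge series equals the Pearson correlation of the
  raw rows exactly;
* edges are ordered row-major over the upper triangle with 0-based node
  indices (``(0,1), (0,2), ..., (N-2,N-1)``);
* the diagonal of a co-fluctuation pattern is excluded from all similarity
  statistics and is stored as exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParcelTimeSeries",
    "EdgeTimeSeries",
    "FCMatrix",
    "CoFluctuationPattern",
    "RMSSeries",
    "edge_index_pairs",
    "standardize_timeseries",
    "compute_edge_timeseries",
    "compute_static_fc",
    "frame_pattern",
    "compute_rms",
    "vectorize_pattern",
    "pattern_from_vector",
]


@dataclass
class ParcelTimeSeries:
    """N x T array of parcel signals with optional standardization flag."""

    values: np.ndarray
    parcel_ids: list[str] | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("parcel time series must be a 2-D (N x T) array")
        n, t = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 parcels, got {n}")
        if t < 3:
            raise ValueError(f"need at least 3 frames, got {t}")
        if not np.isfinite(self.values).all():
            raise ValueError("parcel time series contains non-finite values")
        if self.parcel_ids is None:
            self.parcel_ids = [f"parcel{i}" for i in range(n)]
        elif len(self.parcel_ids) != n:
            raise ValueError("parcel_ids length does not match row count")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class EdgeTimeSeries:
    """E x T framewise products with an explicit (i, j) edge index."""

    values: np.ndarray
    edge_index: np.ndarray  # (E, 2) int array, i < j, row-major upper triangle

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.edge_index = np.asarray(self.edge_index, dtype=int)
        e = self.values.shape[0]
        if self.edge_index.shape != (e, 2):
            raise ValueError("edge_index shape does not match edge count")

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def n_nodes(self) -> int:
        return int(self.edge_index.max()) + 1 if self.n_edges else 0


@dataclass
class FCMatrix:
    """Symmetric correlation matrix with unit diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValueError("FC matrix must be symmetric within 1e-12")
        self.values = v


@dataclass
class CoFluctuationPattern:
    """Symmetric N x N pattern with an exactly-zero diagonal."""

    values: np.ndarray
    source: int | str = "centroid"
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("pattern must be square")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValueError("pattern must be symmetric")
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class RMSSeries:
    """Per-frame global co-fluctuation amplitude (non-negative)."""

    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("RMS series must be 1-D")
        if (v < 0).any():
            raise ValueError("RMS values must be non-negative")
        self.values = v

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def edge_index_pairs(n_nodes: int) -> np.ndarray:
    """Row-major upper-triangle (i, j) pairs with i < j, as an (E, 2) array."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    return np.column_stack([iu, ju])


def standardize_timeseries(ts: ParcelTimeSeries) -> ParcelTimeSeries:
    """Z-score each parcel row using sample moments (denominator T - 1).

    Raises ``ValueError`` naming the parcel if a row is constant.
    """
    x = ts.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(
            f"cannot standardize constant parcel row(s): "
            f"{[ts.parcel_ids[i] for i in bad]}"
        )
    z = (x - mu) / sd
    return ParcelTimeSeries(z, parcel_ids=list(ts.parcel_ids), standardized=True)


def _require_standardized(ts: ParcelTimeSeries) -> None:
    if not ts.standardized:
        raise ValueError("input must be standardized (see standardize_timeseries)")


def compute_edge_timeseries(ts: ParcelTimeSeries) -> EdgeTimeSeries:
    """Framewise products z_i(t) * z_j(t) for all node pairs i < j."""
    _require_standardized(ts)
    z = ts.values
    iu, ju = np.triu_indices(z.shape[0], k=1)
    values = z[iu] * z[ju]
    return EdgeTimeSeries(values, np.column_stack([iu, ju]))


def compute_static_fc(ts: ParcelTimeSeries) -> FCMatrix:
    """Product-moment FC as the 1/(T-1) sum of framewise products."""
    _require_standardized(ts)
    z = ts.values
    t = z.shape[1]
    r = (z @ z.T) / (t - 1)
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(np.clip(r, -1.0, 1.0))


def frame_pattern(ets: EdgeTimeSeries, t: int, subject_id: str = "") -> CoFluctuationPattern:
    """The symmetric N x N co-fluctuation matrix expressed at frame ``t``."""
    if not 0 <= t < ets.n_frames:
        raise IndexError(f"frame {t} out of range [0, {ets.n_frames})")
    n = ets.n_nodes
    m = np.zeros((n, n))
    i, j = ets.edge_index.T
    m[i, j] = ets.values[:, t]
    m[j, i] = ets.values[:, t]
    return CoFluctuationPattern(m, source=t, subject_id=subject_id)


def compute_rms(ets: EdgeTimeSeries) -> RMSSeries:
    """Root mean square over all edges at each frame."""
    return RMSSeries(np.sqrt(np.mean(ets.values**2, axis=0)))


def vectorize_pattern(pattern: CoFluctuationPattern | np.ndarray) -> np.ndarray:
    """Upper-triangle vectorization (row-major, diagonal excluded)."""
    v = pattern.values if isinstance(pattern, CoFluctuationPattern) else np.asarray(pattern)
    iu, ju = np.triu_indices(v.shape[0], k=1)
    return v[iu, ju]


def pattern_from_vector(vec: np.ndarray, n_nodes: int, **kwargs) -> CoFluctuationPattern:
    """Inverse of :func:`vectorize_pattern`."""
    vec = np.asarray(vec, dtype=float)
    m = np.zeros((n_nodes, n_nodes))
    iu, ju = np.triu_indices(n_nodes, k=1)
    if vec.shape != iu.shape:
        raise ValueError("vector length does not match n_nodes*(n_nodes-1)/2")
    m[iu, ju] = vec
    m[ju, iu] = vec
    return CoFluctuationPattern(m, **kwargs)
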