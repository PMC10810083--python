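"""Bipartition-induced modularity on a directed weighted connectome.

An event cluster centroid implies a split of nodes into positively and
negatively co-fluctuating groups. That bipartition is imposed on the
structural connectome's modularity matrix
``B^sc_ij = W^sc_ij - k_in(i) * k_out(j) / 2m`` (built on the FULL
connectome's strengths) and the within-group sums give the induced
modularity, tested against an independent permutation null and a
geometry-preserving null (ring rotation or variogram-matched shuffles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .clustering import consensus_partition, maximize_modularity
from .edges import CoFluctuationPattern, EdgeTimeSeries, RMSSeries, vectorize_pattern

__all__ = [
    "StructuralConnectome",
    "Bipartition",
    "ModularityResult",
    "CouplingSeries",
    "NoValidBipartitionError",
    "structural_modularity_matrix",
    "extract_bipartition",
    "induced_modularity",
    "independent_permutation_null",
    "geometry_preserving_null",
    "gamma_sweep",
    "coupling_timeseries",
]


class NoValidBipartitionError(ValueError):
    """Raised when no anticorrelated pair of communities exists."""


@dataclass
class StructuralConnectome:
    """Directed, weighted, non-negative W^sc with zero diagonal."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectome must be square")
        if (w < 0).any():
            raise ValueError("connectome weights must be non-negative")
        if np.abs(np.diagonal(w)).max() > 0:
            raise ValueError("connectome diagonal must be zero")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def in_strength(self) -> np.ndarray:
        """k_in(i) = sum_j W_ij (row sums)."""
        return self.weights.sum(axis=1)

    @property
    def out_strength(self) -> np.ndarray:
        """k_out(i) = sum_j W_ji (column sums)."""
        return self.weights.sum(axis=0)

    @property
    def total_weight(self) -> float:
        """2m = sum of all weights."""
        return float(self.weights.sum())


@dataclass
class Bipartition:
    """Node labels in {+1, -1, 0}: plus / minus community, or unassigned."""

    labels: np.ndarray
    gamma_used: float = 1.0

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if not set(np.unique(lab)) <= {-1, 0, 1}:
            raise ValueError("labels must be in {-1, 0, 1}")
        self.labels = lab

    @property
    def plus_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)

    @property
    def minus_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.labels == -1)

    @property
    def n_plus(self) -> int:
        return self.plus_nodes.size

    @property
    def n_minus(self) -> int:
        return self.minus_nodes.size


@dataclass
class ModularityResult:
    Q_induced: float
    null_values: np.ndarray
    p_value: float
    null_kind: str
    n_perm: int
    seed: int | None = None


@dataclass
class CouplingSeries:
    """Per-frame rank correlation between pattern and (symmetrized) SC."""

    coupling: np.ndarray
    rms: np.ndarray


def structural_modularity_matrix(sc: StructuralConnectome) -> np.ndarray:
    """B^sc = W^sc - outer(k_in, k_out) / 2m, computed on the full graph."""
    two_m = sc.total_weight
    if two_m == 0:
        raise ValueError("connectome has zero total weight")
    return sc.weights - np.outer(sc.in_strength, sc.out_strength) / two_m


def induced_modularity(sc: StructuralConnectome, bp: Bipartition) -> float:
    """Sum of B^sc over ordered within-plus and within-minus pairs (i != j)."""
    return _induced_from_bsc(structural_modularity_matrix(sc), bp.plus_nodes, bp.minus_nodes)


def _induced_from_bsc(bsc: np.ndarray, plus: np.ndarray, minus: np.ndarray) -> float:
    if plus.size == 0 or minus.size == 0:
        raise ValueError("bipartition has an empty community")
    q = 0.0
    for idx in (plus, minus):
        block = bsc[np.ix_(idx, idx)]
        q += block.sum() - np.trace(block)  # diagonal excluded
    return float(q)


def extract_bipartition(
    centroid: CoFluctuationPattern,
    gamma: float = 1.0,
    n_iter: int = 1000,
    seed: int = 0,
) -> Bipartition:
    """Bipartition implied by a centroid via uniform-null modularity.

    Optimizes B = W - gamma * P, with P the mean off-diagonal centroid value,
    by Louvain + consensus; the two largest communities with a negative mean
    inter-community centroid value become plus/minus (plus is the community
    with the larger mean within-block value); other nodes are labeled 0.
    """
    w = centroid.values
    n = w.shape[0]
    p_const = vectorize_pattern(centroid).mean()
    b = w - gamma * p_const
    np.fill_diagonal(b, 0.0)
    runs = maximize_modularity(b, n_iter=n_iter, seed=seed, description="uniform-null")
    cons = consensus_partition(runs, seed=seed + 1, n_iter=max(10, n_iter // 10))
    assign = cons.assignment
    k = int(assign.max()) + 1
    if k < 2:
        raise NoValidBipartitionError(
            f"no valid bipartition at gamma={gamma}: single community"
        )
    sizes = np.bincount(assign, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    top_two = sorted(sizes[order[:2]], reverse=True)
    # size ties: every pair realizing the two largest sizes is a candidate,
    # and the pair with the most negative inter-community mean wins
    cands = [c for c in range(k) if sizes[c] >= top_two[1]]
    best_pair = None
    best_inter = np.inf
    for ai in range(len(cands)):
        for bi in range(ai + 1, len(cands)):
            ca, cb = cands[ai], cands[bi]
            if sorted([sizes[ca], sizes[cb]], reverse=True) != top_two:
                continue
            ia = np.flatnonzero(assign == ca)
            ib = np.flatnonzero(assign == cb)
            inter = w[np.ix_(ia, ib)].mean()
            if inter < best_inter:
                best_inter = inter
                best_pair = (ca, cb)
    if best_pair is None or best_inter >= 0:
        raise NoValidBipartitionError(
            f"no valid bipartition at gamma={gamma}: "
            "two largest communities are not anticorrelated"
        )
    ca, cb = best_pair
    ia = np.flatnonzero(assign == ca)
    ib = np.flatnonzero(assign == cb)
    mean_a = w[np.ix_(ia, ia)].sum() / max(ia.size * (ia.size - 1), 1)
    mean_b = w[np.ix_(ib, ib)].sum() / max(ib.size * (ib.size - 1), 1)
    labels = np.zeros(n, dtype=int)
    if mean_a >= mean_b:
        labels[ia], labels[ib] = 1, -1
    else:
        labels[ib], labels[ia] = 1, -1
    return Bipartition(labels, gamma_used=gamma)


def independent_permutation_null(
    sc: StructuralConnectome,
    bp: Bipartition,
    n_perm: int = 1000,
    seed: int = 0,
) -> ModularityResult:
    """Null: random disjoint node sets of sizes n_plus and n_minus."""
    n = sc.n_nodes
    n_p, n_m = bp.n_plus, bp.n_minus
    if n_p + n_m > n:
        raise ValueError("bipartition larger than the connectome")
    bsc = structural_modularity_matrix(sc)
    observed = _induced_from_bsc(bsc, bp.plus_nodes, bp.minus_nodes)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(n, size=n_p + n_m, replace=False)
        null[i] = _induced_from_bsc(bsc, pick[:n_p], pick[n_p:])
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return ModularityResult(observed, null, float(p), "independent", n_perm, seed)


def _rotation_order(coordinates: np.ndarray) -> np.ndarray:
    """Cyclic node order for the rotation null.

    Nodes are ordered by angle around the centroid of their coordinates; for
    a ring layout in index order this is the identity ordering.
    """
    xy = np.asarray(coordinates, dtype=float)[:, :2]
    centered = xy - xy.mean(axis=0)
    ang = np.arctan2(centered[:, 1], centered[:, 0])
    return np.argsort(ang, kind="stable")


def _label_variogram(labels: np.ndarray, dist: np.ndarray, bins: np.ndarray) -> np.ndarray:
    """Binned semivariance of the {-1, 0, 1} label indicator vector."""
    iu, ju = np.triu_indices(labels.size, k=1)
    sq = (labels[iu] - labels[ju]).astype(float) ** 2
    d = dist[iu, ju]
    which = np.clip(np.digitize(d, bins) - 1, 0, len(bins) - 2)
    out = np.zeros(len(bins) - 1)
    for b in range(len(bins) - 1):
        mask = which == b
        out[b] = sq[mask].mean() if mask.any() else 0.0
    return out


def geometry_preserving_null(
    sc: StructuralConnectome,
    bp: Bipartition,
    coordinates: np.ndarray,
    n_perm: int = 1000,
    strategy: str = "rotation",
    seed: int = 0,
    variogram_rtol: float = 0.10,
    oversample: int = 50,
) -> ModularityResult:
    """Spatial-autocorrelation-preserving permutation null.

    ``rotation``: the label vector is rotated by a random non-zero offset
    along the cyclic spatial ordering of the nodes, exactly preserving
    community sizes and contiguity. ``variogram``: random label shuffles are
    accepted only when the binned variogram of the shuffled label indicator
    matches the original within ``variogram_rtol`` relative error.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape[0] != sc.n_nodes:
        raise ValueError("coordinates must cover all nodes")
    bsc = structural_modularity_matrix(sc)
    observed = _induced_from_bsc(bsc, bp.plus_nodes, bp.minus_nodes)
    rng = np.random.default_rng(seed)
    n = sc.n_nodes
    null = np.empty(n_perm)

    if strategy == "rotation":
        order = _rotation_order(coordinates)
        lab_ordered = bp.labels[order]
        for i in range(n_perm):
            off = int(rng.integers(1, n))
            rolled = np.roll(lab_ordered, off)
            lab = np.empty(n, dtype=int)
            lab[order] = rolled
            null[i] = _induced_from_bsc(
                bsc, np.flatnonzero(lab == 1), np.flatnonzero(lab == -1)
            )
    elif strategy == "variogram":
        diff = coordinates[:, None, :] - coordinates[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        iu = np.triu_indices(n, k=1)
        bins = np.quantile(dist[iu], np.linspace(0, 1, 11))
        bins[-1] += 1e-9
        target = _label_variogram(bp.labels, dist, bins)
        scale = np.abs(target).max()
        # spatially contiguous proposals: sweep the original label sequence
        # along a random direction (distance-rank-preserving shuffle), then
        # accept only proposals whose label variogram matches the original
        order0 = _rotation_order(coordinates)
        seq = bp.labels[order0]
        accepted = 0
        attempts = 0
        cap = oversample * n_perm
        while accepted < n_perm:
            if attempts >= cap:
                raise RuntimeError(
                    f"variogram null: only {accepted}/{n_perm} surrogates "
                    f"accepted within {cap} attempts"
                )
            attempts += 1
            u = rng.standard_normal(coordinates.shape[1])
            u /= np.linalg.norm(u)
            sweep = np.argsort(coordinates @ u, kind="stable")
            cand = np.roll(seq, int(rng.integers(n)))
            if rng.random() < 0.5:
                cand = cand[::-1]
            lab = np.empty(n, dtype=int)
            lab[sweep] = cand
            if np.array_equal(lab, bp.labels):
                continue
            vg = _label_variogram(lab, dist, bins)
            if np.abs(vg - target).max() <= variogram_rtol * scale:
                null[accepted] = _induced_from_bsc(
                    bsc, np.flatnonzero(lab == 1), np.flatnonzero(lab == -1)
                )
                accepted += 1
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return ModularityResult(observed, null, float(p), strategy, n_perm, seed)


def gamma_sweep(
    centroid: CoFluctuationPattern,
    sc: StructuralConnectome,
    gammas: list[float],
    coordinates: np.ndarray | None = None,
    n_iter: int = 1000,
    n_perm: int = 1000,
    strategy: str = "rotation",
    seed: int = 0,
) -> dict[float, dict]:
    """extract_bipartition + both nulls per gamma; invalid gammas reported."""
    if not gammas:
        raise ValueError("empty gamma list")
    out: dict[float, dict] = {}
    for g in gammas:
        entry: dict = {"gamma": g}
        try:
            bp = extract_bipartition(centroid, gamma=g, n_iter=n_iter, seed=seed)
        except NoValidBipartitionError as exc:
            entry["valid"] = False
            entry["reason"] = str(exc)
            out[g] = entry
            continue
        entry["valid"] = True
        entry["bipartition"] = bp
        entry["independent"] = independent_permutation_null(sc, bp, n_perm, seed)
        if coordinates is not None:
            entry["geometry"] = geometry_preserving_null(
                sc, bp, coordinates, n_perm, strategy, seed
            )
        out[g] = entry
    return out


def coupling_timeseries(
    ets: EdgeTimeSeries,
    sc: StructuralConnectome,
    rms: RMSSeries,
) -> CouplingSeries:
    """Per-frame Spearman correlation between pattern and symmetrized SC."""
    if sc.n_nodes != ets.n_nodes:
        raise ValueError("node count mismatch between edge series and connectome")
    w_sym = 0.5 * (sc.weights + sc.weights.T)
    sc_vec = vectorize_pattern(w_sym)
    if np.ptp(sc_vec) == 0:
        raise ValueError("constant SC vector: coupling undefined")
    sc_rank = stats.rankdata(sc_vec)
    frame_ranks = stats.rankdata(ets.values, axis=0)
    sc_c = sc_rank - sc_rank.mean()
    fr_c = frame_ranks - frame_ranks.mean(axis=0)
    denom = np.sqrt((sc_c**2).sum() * (fr_c**2).sum(axis=0))
    coupling = (sc_c @ fr_c) / denom
    return CouplingSeries(coupling, rms.values.copy())
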