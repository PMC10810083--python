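"""Concordance-based hierarchical clustering of co-fluctuation patterns.

Pairwise similarity between patterns is Lin's concordance (reduces to the
Pearson correlation when means and variances match). The concordance matrix
C is clustered by modularity maximization of B = C - <C> (with <C> the mean
of the upper-triangle entries), using a Louvain-style greedy optimizer that
supports signed modularity matrices, followed by consensus clustering of the
run ensemble. Clusters are recursed only while their modularity contribution
q_c beats a size-preserving label-permutation null, yielding a pruned
hierarchy of statistically supported clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .edges import CoFluctuationPattern, vectorize_pattern

__all__ = [
    "PatternEnsemble",
    "ConcordanceMatrix",
    "Partition",
    "HierarchicalPartition",
    "CentroidSet",
    "lin_concordance",
    "concordance_matrix",
    "modularity_value",
    "community_contributions",
    "maximize_modularity",
    "consensus_partition",
    "hierarchical_cluster_events",
    "compute_centroids",
]


@dataclass
class PatternEnsemble:
    patterns: list[CoFluctuationPattern]
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("pattern ensemble is empty")
        sizes = {p.n_nodes for p in self.patterns}
        if len(sizes) != 1:
            raise ValueError(f"patterns disagree on node count: {sorted(sizes)}")
        if self.subject_ids is None:
            self.subject_ids = [p.subject_id or "" for p in self.patterns]
        elif len(self.subject_ids) != len(self.patterns):
            raise ValueError("subject_ids length mismatch")

    def __len__(self) -> int:
        return len(self.patterns)

    @property
    def n_nodes(self) -> int:
        return self.patterns[0].n_nodes

    def as_vectors(self) -> np.ndarray:
        """(M, E) matrix of upper-triangle vectorized patterns."""
        return np.vstack([vectorize_pattern(p) for p in self.patterns])


@dataclass
class ConcordanceMatrix:
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("concordance matrix must be square")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValueError("concordance matrix must be symmetric")
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 1.0)
        self.values = v

    @property
    def n_items(self) -> int:
        return self.values.shape[0]


@dataclass
class Partition:
    """Community assignment with its modularity under a stated null."""

    assignment: np.ndarray
    Q: float
    B_description: str = ""
    converged: bool = True

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        self.assignment = _canonical_labels(a)
        if not np.isfinite(self.Q):
            raise ValueError("Q must be finite")

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0


@dataclass
class HierarchicalPartition:
    """Nested partitions; level 0 is the single root community."""

    levels: list[Partition]
    parent_map: dict[tuple[int, int], tuple[int, int]]  # (level, comm) -> parent
    q_contributions: list[np.ndarray]    # per level, q_c indexed by community id
    significant: list[np.ndarray]        # per level, boolean per community

    @property
    def depth(self) -> int:
        return len(self.levels)

    def assignment_at(self, level: int) -> np.ndarray:
        return self.levels[level].assignment


@dataclass
class CentroidSet:
    centroids: list[CoFluctuationPattern]
    member_counts: np.ndarray
    member_fractions: np.ndarray


# ---------------------------------------------------------------------------
# concordance


def lin_concordance(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance C = 2 Cov(x,y) / (Var x + Var y + (mu_x - mu_y)^2).

    Sample (n-1) moments throughout. Equals Pearson r when means and
    variances match; otherwise |C| < |r|.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("concordance undefined: both vectors constant with equal means")
    cov = np.dot(x - mx, y - my) / (x.size - 1)
    return float(2.0 * cov / denom)


def _concordance_from_vectors(v: np.ndarray) -> np.ndarray:
    m, e = v.shape
    mu = v.mean(axis=1)
    var = v.var(axis=1, ddof=1)
    centered = v - mu[:, None]
    cov = (centered @ centered.T) / (e - 1)
    denom = var[:, None] + var[None, :] + (mu[:, None] - mu[None, :]) ** 2
    if (denom == 0).any():
        i, j = np.argwhere(denom == 0)[0]
        raise ValueError(f"concordance undefined for pattern pair ({i}, {j})")
    c = 2.0 * cov / denom
    np.fill_diagonal(c, 1.0)
    return 0.5 * (c + c.T)


def concordance_matrix(ensemble: PatternEnsemble) -> ConcordanceMatrix:
    """All pairwise concordances between the ensemble's vectorized patterns."""
    if len(ensemble) < 2:
        raise ValueError("need at least 2 patterns")
    return ConcordanceMatrix(_concordance_from_vectors(ensemble.as_vectors()))


# ---------------------------------------------------------------------------
# modularity machinery (signed-B Louvain + consensus)


def _canonical_labels(a: np.ndarray) -> np.ndarray:
    """Relabel communities contiguously from 0 in order of first appearance."""
    out = np.empty_like(a)
    mapping: dict[int, int] = {}
    for idx, lab in enumerate(a):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[idx] = mapping[lab]
    return out


def modularity_value(B: np.ndarray, assignment: np.ndarray) -> float:
    """Q = sum_ij B_ij delta(sigma_i, sigma_j), diagonal included."""
    q = 0.0
    for c in np.unique(assignment):
        idx = np.flatnonzero(assignment == c)
        q += B[np.ix_(idx, idx)].sum()
    return float(q)


def community_contributions(B: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """Per-community q_c with sum_c q_c == Q; indexed by community id."""
    k = int(assignment.max()) + 1
    q = np.zeros(k)
    for c in range(k):
        idx = np.flatnonzero(assignment == c)
        q[c] = B[np.ix_(idx, idx)].sum()
    return q


def _louvain_once(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One greedy Louvain run on a symmetric (possibly signed) B.

    The diagonal never changes under node moves, so it is ignored during
    optimization; Q values reported elsewhere include it.
    """
    n = B.shape[0]
    node_members: list[list[int]] = [[i] for i in range(n)]
    W = B.copy()
    np.fill_diagonal(W, 0.0)
    while True:
        m = W.shape[0]
        labels = np.arange(m)
        improved_any = False
        improved = True
        while improved:
            improved = False
            for i in rng.permutation(m):
                # sum of W[i, j] into each community
                gains = np.bincount(labels, weights=W[i], minlength=labels.max() + 1)
                own = labels[i]
                best = int(np.argmax(gains))
                if gains[best] > gains[own] + 1e-12:
                    labels[i] = best
                    improved = True
                    improved_any = True
        labels = _canonical_labels(labels)
        k = labels.max() + 1
        if not improved_any or k == m:
            # expand back to original node labels
            out = np.empty(n, dtype=int)
            for super_idx, lab in enumerate(labels):
                for node in node_members[super_idx]:
                    out[node] = lab
            return _canonical_labels(out)
        # aggregate: supernode adjacency, regroup members
        onehot = np.zeros((m, k))
        onehot[np.arange(m), labels] = 1.0
        W = onehot.T @ W @ onehot
        np.fill_diagonal(W, 0.0)
        new_members: list[list[int]] = [[] for _ in range(k)]
        for super_idx, lab in enumerate(labels):
            new_members[lab].extend(node_members[super_idx])
        node_members = new_members


def maximize_modularity(
    B: np.ndarray, n_iter: int = 100, seed: int = 0, description: str = ""
) -> list[Partition]:
    """Run the greedy optimizer ``n_iter`` times; return all local optima."""
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError("B must be square")
    if np.abs(B - B.T).max() > 1e-10:
        raise ValueError("B must be symmetric")
    if not np.isfinite(B).all():
        raise ValueError("B must be finite")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_iter):
        labels = _louvain_once(B, rng)
        out.append(Partition(labels, modularity_value(B, labels), description))
    return out


def _coassignment(partitions: list[Partition]) -> np.ndarray:
    n = partitions[0].assignment.size
    co = np.zeros((n, n))
    for p in partitions:
        co += (p.assignment[:, None] == p.assignment[None, :]).astype(float)
    return co / len(partitions)


def _expected_coassignment(partitions: list[Partition]) -> float:
    """Chance that a random distinct pair is coassigned, given each
    partition's community-size profile, averaged over the ensemble."""
    n = partitions[0].assignment.size
    exp = 0.0
    for p in partitions:
        sizes = np.bincount(p.assignment)
        exp += float((sizes * (sizes - 1)).sum()) / (n * (n - 1))
    return exp / len(partitions)


def consensus_partition(
    partitions: list[Partition],
    seed: int = 0,
    n_iter: int = 100,
    max_rounds: int = 50,
) -> Partition:
    """Iterated consensus clustering of a partition ensemble.

    Builds B_consensus = coassignment - expected coassignment, re-optimizes,
    and repeats until all runs agree up to relabeling. Never raises on
    degenerate input: a non-convergent outcome is returned with
    ``converged=False`` (assignment = modal partition of the last round).
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    n = partitions[0].assignment.size
    if any(p.assignment.size != n for p in partitions):
        raise ValueError("partitions must cover the same items")
    rng = np.random.default_rng(seed)
    ensemble = partitions
    for _ in range(max_rounds):
        keys = {tuple(p.assignment) for p in ensemble}
        if len(keys) == 1:
            a = ensemble[0].assignment
            return Partition(a, ensemble[0].Q, "consensus", converged=True)
        co = _coassignment(ensemble)
        b_cons = co - _expected_coassignment(ensemble)
        np.fill_diagonal(b_cons, 0.0)
        ensemble = maximize_modularity(
            b_cons, n_iter=n_iter, seed=int(rng.integers(2**32)), description="consensus"
        )
    # cap reached: report the modal partition, flagged
    keys_list = [tuple(p.assignment) for p in ensemble]
    modal = max(set(keys_list), key=keys_list.count)
    a = np.asarray(modal, dtype=int)
    return Partition(a, ensemble[keys_list.index(modal)].Q, "consensus:non-convergent",
                     converged=False)


def _consensus_of_matrix(
    B: np.ndarray, n_iter: int, seed: int, description: str
) -> tuple[Partition, float]:
    """Louvain ensemble on B followed by consensus; returns (partition, Q on B)."""
    runs = maximize_modularity(B, n_iter=n_iter, seed=seed, description=description)
    cons = consensus_partition(runs, seed=seed + 1, n_iter=max(10, n_iter // 10))
    q = modularity_value(B, cons.assignment)
    return Partition(cons.assignment, q, description, cons.converged), q


def _prune_significance(
    B: np.ndarray,
    assignment: np.ndarray,
    n_perm: int,
    alpha: float,
    rng: np.random.Generator,
    method: str = "residual_surrogate",
    vectors: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided permutation test of each community's q_c (add-one p).

    ``label_permutation`` permutes community labels preserving sizes. That is
    the literal prescription but it ignores that the partition was optimized
    on this very matrix, so optimizer-found noise structure always passes.
    The surrogate methods therefore rebuild structureless data and
    re-optimize it, using the maximum surrogate community contribution as
    the null: a community is significant only if its q_c beats what
    optimization extracts from data with no alignment structure.
    ``residual_surrogate`` (default; needs ``vectors``) conjugates each
    pattern's residual around the common centroid by an independent random
    node permutation drawn within the sign groups of the centroid's leading
    eigenvector, then recomputes the concordance matrix. Such permutations
    (approximately) fix the centroid itself, so per-pattern noise levels,
    within-pattern edge dependencies, and the shared low-rank subspace are
    all preserved while cross-pattern residual alignment is destroyed -- an
    exchangeability null for "one family plus noise".
    ``optimized_surrogate`` shuffles the off-diagonal entries of B directly.
    Diagonal entries are excluded from the tested contributions (they are
    constant per community size); reported q_c elsewhere keep them.
    """
    q_obs = community_contributions(B, assignment)
    b0 = B.copy()
    np.fill_diagonal(b0, 0.0)
    q_test = community_contributions(b0, assignment)
    k = q_obs.size
    exceed = np.zeros(k)
    if method == "residual_surrogate" and vectors is None:
        method = "optimized_surrogate"
    if method == "label_permutation":
        for _ in range(n_perm):
            perm = rng.permutation(assignment)
            exceed += community_contributions(b0, perm) >= q_test
    elif method == "residual_surrogate":
        m, e = vectors.shape
        n_nodes = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
        eu, ev = np.triu_indices(n_nodes, k=1)
        centroid = vectors.mean(axis=0)
        resid_mat = np.zeros((m, n_nodes, n_nodes))
        resid_mat[:, eu, ev] = vectors - centroid
        resid_mat += resid_mat.transpose(0, 2, 1)
        cent_mat = np.zeros((n_nodes, n_nodes))
        cent_mat[eu, ev] = centroid
        cent_mat += cent_mat.T
        lam, evec = np.linalg.eigh(cent_mat)
        lead = evec[:, np.argmax(np.abs(lam))]
        groups = [np.flatnonzero(lead >= 0), np.flatnonzero(lead < 0)]
        groups = [g for g in groups if g.size > 1]
        iu, ju = np.triu_indices(B.shape[0], k=1)
        v_s = np.empty_like(vectors)
        base = np.arange(n_nodes)
        for _ in range(n_perm):
            for i in range(m):
                perm = base.copy()
                for g in groups:
                    perm[g] = rng.permutation(g)
                v_s[i] = resid_mat[i][np.ix_(perm, perm)][eu, ev]
            v_s += centroid
            c_s = _concordance_from_vectors(v_s)
            b_s = c_s - c_s[iu, ju].mean()
            np.fill_diagonal(b_s, 0.0)
            lab = _louvain_once(b_s, rng)
            exceed += community_contributions(b_s, lab).max() >= q_test
    elif method == "optimized_surrogate":
        n = B.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        vals = b0[iu, ju]
        for _ in range(n_perm):
            s = np.zeros((n, n))
            s[iu, ju] = rng.permutation(vals)
            s += s.T
            lab = _louvain_once(s, rng)
            exceed += community_contributions(s, lab).max() >= q_test
    else:
        raise ValueError(f"unknown pruning method {method!r}")
    p = (1.0 + exceed) / (1.0 + n_perm)
    return q_obs, p < alpha


def hierarchical_cluster_events(
    cm: ConcordanceMatrix,
    n_iter: int = 1000,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_size: int = 3,
    max_depth: int = 10,
    prune_method: str = "residual_surrogate",
    vectors: np.ndarray | None = None,
) -> HierarchicalPartition:
    """Recursive consensus modularity maximization with permutation pruning.

    Level 0 is the single root community. At each step a community's induced
    concordance submatrix is re-centered on its own upper-triangle mean and
    split by consensus modularity maximization; only communities whose q_c
    beats the pruning null (see :func:`_prune_significance`; one-sided
    p < alpha) and have at least ``min_size`` members are recursed. Passing
    the ensemble's vectorized patterns as ``vectors`` enables the default
    residual-surrogate pruning null; without them the entry-shuffle
    surrogate is used.
    """
    c = cm.values
    m = c.shape[0]
    rng = np.random.default_rng(seed)

    root = Partition(np.zeros(m, dtype=int), 0.0, "root")
    levels = [root]
    parent_map: dict[tuple[int, int], tuple[int, int]] = {}
    q_contribs: list[np.ndarray] = [np.array([0.0])]
    significant: list[np.ndarray] = [np.array([True])]

    # communities eligible for subdivision at the current level
    active = {0: np.arange(m)}
    for level in range(1, max_depth + 1):
        new_assignment = levels[-1].assignment.copy()
        next_active: dict[int, np.ndarray] = {}
        split_info: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        any_split = False
        for comm, idx in active.items():
            sub = c[np.ix_(idx, idx)]
            iu, ju = np.triu_indices(idx.size, k=1)
            b = sub - sub[iu, ju].mean()
            part, _ = _consensus_of_matrix(
                b, n_iter, int(rng.integers(2**32)), f"level{level}"
            )
            if part.n_communities < 2:
                continue
            q_c, sig = _prune_significance(
                b, part.assignment, n_perm, alpha, rng, prune_method,
                vectors[idx] if vectors is not None else None,
            )
            if not sig.any():
                # split is wholly consistent with the null: prune the children
                continue
            split_info[comm] = (idx, part.assignment, q_c, sig)
            any_split = True
        if not any_split:
            break
        # assign globally contiguous ids for the new level
        next_id = 0
        level_q: list[float] = []
        level_sig: list[bool] = []
        # communities not split survive unchanged as their own child
        for comm in range(levels[-1].n_communities):
            if comm in split_info:
                idx, sub_assign, q_c, sig = split_info[comm]
                for child in range(int(sub_assign.max()) + 1):
                    members = idx[sub_assign == child]
                    new_assignment[members] = next_id
                    parent_map[(level, next_id)] = (level - 1, comm)
                    level_q.append(float(q_c[child]))
                    level_sig.append(bool(sig[child]))
                    if sig[child] and members.size >= min_size:
                        next_active[next_id] = members
                    next_id += 1
            else:
                members = np.flatnonzero(levels[-1].assignment == comm)
                new_assignment[members] = next_id
                parent_map[(level, next_id)] = (level - 1, comm)
                level_q.append(np.nan)
                level_sig.append(False)
                next_id += 1
        # Q for the level is the sum over split parents' contributions
        levels.append(
            Partition(new_assignment, float(np.nansum(level_q)), f"level{level}")
        )
        q_contribs.append(np.asarray(level_q))
        significant.append(np.asarray(level_sig))
        if not next_active:
            break
        active = next_active

    return HierarchicalPartition(levels, parent_map, q_contribs, significant)


def compute_centroids(ensemble: PatternEnsemble, partition: Partition) -> CentroidSet:
    """Elementwise mean pattern per cluster, with member counts/fractions."""
    a = partition.assignment
    if a.size != len(ensemble):
        raise ValueError("partition does not match ensemble size")
    stack = np.stack([p.values for p in ensemble.patterns])
    centroids = []
    counts = []
    for comm in range(partition.n_communities):
        idx = np.flatnonzero(a == comm)
        centroids.append(
            CoFluctuationPattern(stack[idx].mean(axis=0), source="centroid")
        )
        counts.append(idx.size)
    counts_arr = np.asarray(counts)
    return CentroidSet(centroids, counts_arr, counts_arr / counts_arr.sum())
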