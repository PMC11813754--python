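"""Multiplex dynamics: per-node change between timepoint layers.

Within each enterotype-trajectory group, the w0 and w24 aggregate networks
(|mean ISN| per group, so all weights are non-negative) are stacked into a
two-layer multiplex. Every node is represented once per layer by the visit
profile of seeded random walks with restart on that layer; the 2n profiles
are jointly reduced to a low-dimensional space, and a node's dynamic is the
cosine distance between its two embedded points. Embedding and distances are
repeated R times (walk-sampling seeds differ per repeat); nodes are ranked
per repeat and rank sums compared against a layer-swap permutation null,
with BH correction across nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.decomposition import PCA

from isnkit.diffedges import benjamini_hochberg
from isnkit.lioness import IsnSet


@dataclass
class MultiplexNetwork:
    """Two non-negative weight layers over a shared node set."""

    nodes: list
    layer_a: pd.DataFrame
    layer_b: pd.DataFrame
    group: str = ""
    timepoints: tuple = ("w0", "w24")

    def __post_init__(self):
        for name, layer in (("layer_a", self.layer_a), ("layer_b", self.layer_b)):
            if (layer.values < 0).any():
                raise ValueError(f"{name} has negative weights; layers must be |mean ISN|")
            if list(layer.index) != list(self.nodes):
                raise ValueError(f"{name} node set does not match the multiplex nodes")


def aggregate_layer(isns: IsnSet, samples, taxa) -> pd.DataFrame:
    """|mean ISN| weight matrix over ``samples`` on the ``taxa`` node set."""
    mean_w = isns.weights.loc[samples].mean(axis=0)
    W = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for (ti, tj), label in zip(isns.edge_index, isns.weights.columns):
        if ti in W.index and tj in W.index:
            W.loc[ti, tj] = W.loc[tj, ti] = abs(mean_w[label])
    return W


def aggregate_group_networks(
    isns: IsnSet,
    metadata: pd.DataFrame,
    group: str,
    taxa,
    group_col: str = "trajectory",
    timepoint_col: str = "timepoint",
    timepoints: tuple = ("w0", "w24"),
    min_individuals: int = 3,
    allow_single: bool = False,
) -> MultiplexNetwork:
    """|mean ISN| per timepoint layer for one trajectory group."""
    meta = metadata.loc[isns.samples]
    layers = {}
    for tp in timepoints:
        sel = (meta[group_col] == group) & (meta[timepoint_col] == tp)
        n_ind = meta.loc[sel.values, "individual_id"].nunique() if "individual_id" in meta else int(sel.sum())
        if int(sel.sum()) == 0:
            raise ValueError(f"no samples for group {group!r} at {tp!r}")
        if n_ind < min_individuals and not allow_single:
            raise ValueError(
                f"group {group!r} has {n_ind} individuals at {tp!r}; need >= {min_individuals}")
        layers[tp] = aggregate_layer(isns, isns.samples[sel.values], taxa)
    return MultiplexNetwork(list(taxa), layers[timepoints[0]], layers[timepoints[1]],
                            group=group, timepoints=timepoints)


def _walk_profiles(W: np.ndarray, rng: np.random.Generator, n_walks: int,
                   walk_len: int, restart: float) -> np.ndarray:
    """Visit-frequency profile of random walks with restart from every node.

    Isolated nodes stay put, so their profile is the unit vector at
    themselves in both layers.
    """
    n = W.shape[0]
    row_sum = W.sum(axis=1)
    P = np.where(row_sum[:, None] > 0, W / np.maximum(row_sum[:, None], 1e-300), 0.0)
    cum = np.cumsum(P, axis=1)
    has_nb = row_sum > 0

    starts = np.repeat(np.arange(n), n_walks)
    current = starts.copy()
    visits = np.zeros((n, n))
    np.add.at(visits, (starts, current), 1.0)
    for _ in range(walk_len):
        u = rng.random(len(current))
        do_restart = u < restart
        current = np.where(do_restart, starts, current)
        move = ~do_restart & has_nb[current]
        if move.any():
            r = rng.random(int(move.sum()))
            rows = cum[current[move]]
            nxt = (r[:, None] > rows).sum(axis=1)
            cur = current.copy()
            cur[move] = np.minimum(nxt, n - 1)
            current = cur
        np.add.at(visits, (starts, current), 1.0)
    return visits / visits.sum(axis=1, keepdims=True)


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(1.0 - np.dot(a, b) / (na * nb))


def embed_and_distance(
    mx: MultiplexNetwork,
    dim: int = 5,
    repeats: int = 50,
    seed: int = 0,
    n_walks: int = 20,
    walk_len: int = 10,
    restart: float = 0.5,
) -> pd.DataFrame:
    """Per-node cosine distance between layer embeddings, one column per repeat."""
    n = len(mx.nodes)
    if dim >= n:
        raise ValueError(f"embedding dim {dim} must be < n_nodes {n}")
    A, B = mx.layer_a.values, mx.layer_b.values
    iso_both = (A.sum(axis=1) == 0) & (B.sum(axis=1) == 0)
    if iso_both.any():
        warnings.warn(f"{int(iso_both.sum())} nodes isolated in both layers; distance set to 0")
    seeds = np.random.SeedSequence(seed).spawn(repeats)
    out = np.zeros((n, repeats))
    for r in range(repeats):
        rng = np.random.default_rng(seeds[r])
        prof = np.vstack([
            _walk_profiles(A, rng, n_walks, walk_len, restart),
            _walk_profiles(B, rng, n_walks, walk_len, restart),
        ])
        emb = PCA(n_components=dim, random_state=0).fit_transform(prof)
        for v in range(n):
            out[v, r] = 0.0 if iso_both[v] else cosine_distance(emb[v], emb[n + v])
    return pd.DataFrame(out, index=pd.Index(mx.nodes, name="node"),
                        columns=[f"rep_{r}" for r in range(repeats)])


def _rank_sum(distances: np.ndarray, over: str) -> np.ndarray:
    """Rank sums; ``repeats``: rank nodes within each repeat, sum per node."""
    if over == "repeats":
        ranks = np.apply_along_axis(rankdata, 0, distances)
        return ranks.sum(axis=1)
    if over == "nodes":
        ranks = np.apply_along_axis(rankdata, 1, distances)
        return ranks.sum(axis=1)
    raise ValueError(f"unknown rank_over {over!r}")


@dataclass
class DynamicsResult:
    """Per-node dynamics significance for one trajectory group."""

    table: pd.DataFrame             # mean_distance, rank_sum, p, q, significant
    distances: pd.DataFrame = field(repr=False)
    group: str = ""
    n_perm: int = 0

    @property
    def nodes(self) -> list:
        return list(self.table.index)


def permutation_significance(
    mx: MultiplexNetwork,
    distances: pd.DataFrame,
    n_perm: int = 200,
    seed: int = 0,
    threshold: float = 0.05,
    rank_over: str = "repeats",
    scheme: str = "within_layer",
    **embed_kwargs,
) -> DynamicsResult:
    """Permutation null for per-node rank sums.

    ``within_layer`` (default) shuffles the upper-triangle edge weights of
    each layer independently per permutation, spreading any between-layer
    discrepancy over random edges; because the rank-sum statistic only uses
    relative ranks within a repeat, the null is calibrated under identical
    layers while a genuinely rewired node exceeds it. ``layer_swap``
    exchanges each pair's weight between the two layers with probability
    1/2, which preserves pooled weights but also preserves every edge's
    between-layer difference magnitude — it tests the assignment direction,
    not the amount of change. In both cases
    p = (1 + #{null rank sum >= observed}) / (1 + n_perm), BH across nodes.
    """
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values are coarse below 100")
    if scheme not in ("within_layer", "layer_swap"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    repeats = distances.shape[1]
    obs = _rank_sum(distances.values, rank_over)
    n = len(mx.nodes)
    iu = np.triu_indices(n, k=1)
    A, B = mx.layer_a.values, mx.layer_b.values
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n)
    for pidx in range(n_perm):
        Ap, Bp = np.zeros_like(A), np.zeros_like(B)
        a_vals, b_vals = A[iu].copy(), B[iu].copy()
        if scheme == "within_layer":
            a_new = a_vals[rng.permutation(len(a_vals))]
            b_new = b_vals[rng.permutation(len(b_vals))]
        else:
            swap = rng.random(len(iu[0])) < 0.5
            a_new = np.where(swap, b_vals, a_vals)
            b_new = np.where(swap, a_vals, b_vals)
        Ap[iu], Bp[iu] = a_new, b_new
        Ap[(iu[1], iu[0])], Bp[(iu[1], iu[0])] = a_new, b_new
        mx_p = MultiplexNetwork(mx.nodes,
                                pd.DataFrame(Ap, index=mx.nodes, columns=mx.nodes),
                                pd.DataFrame(Bp, index=mx.nodes, columns=mx.nodes),
                                group=mx.group)
        d_p = embed_and_distance(mx_p, repeats=repeats,
                                 seed=int(rng.integers(2**31 - 1)), **embed_kwargs)
        exceed += _rank_sum(d_p.values, rank_over) >= obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    q = benjamini_hochberg(p)
    table = pd.DataFrame({
        "mean_distance": distances.mean(axis=1).values,
        "rank_sum": obs,
        "p": p,
        "q": q,
        "significant": q < threshold,
    }, index=distances.index)
    return DynamicsResult(table, distances, group=mx.group, n_perm=n_perm)


def contrast_distance_ranks(result_a: DynamicsResult, result_b: DynamicsResult) -> pd.DataFrame:
    """Nodes ranked by |mean distance in A - mean distance in B| (descending)."""
    if set(result_a.nodes) != set(result_b.nodes):
        raise ValueError("the two results cover different node sets")
    a = result_a.table["mean_distance"]
    b = result_b.table["mean_distance"].loc[a.index]
    out = pd.DataFrame({
        "mean_distance_a": a,
        "mean_distance_b": b,
        "abs_difference": (a - b).abs(),
    })
    # descending difference; ties broken by node id (stable sort after index sort)
    out = out.sort_index().sort_values("abs_difference", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def repeat_robustness(mx: MultiplexNetwork, repeats: int = 50, seed_a: int = 1,
                      seed_b: int = 2, **embed_kwargs) -> float:
    """Spearman correlation of per-node mean distances across two runs."""
    da = embed_and_distance(mx, repeats=repeats, seed=seed_a, **embed_kwargs).mean(axis=1)
    db = embed_and_distance(mx, repeats=repeats, seed=seed_b, **embed_kwargs).mean(axis=1)
    return float(spearmanr(da.values, db.values).statistic)
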