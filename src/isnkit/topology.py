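"""Per-node topology metrics on ISN support graphs and the AUC screen.

The ten metrics (degree, average shortest path length, eccentricity,
closeness, betweenness, stress, clustering coefficient, neighbourhood
connectivity, radiality, topological coefficient) follow the NetworkAnalyzer
definitions on the unweighted, undirected support graph of each ISN.
Distances are computed within a node's connected component; cross-component
pairs are excluded rather than treated as infinite. Metrics a definition
cannot produce for a node (clustering for degree < 2, the topological
coefficient for nodes sharing no neighbour with anyone, betweenness on
graphs with fewer than three nodes) are marked missing, and the two
protocols of the screen — zero-fill and node-drop — decide how missing cells
enter the feature matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from isnkit.lioness import IsnSet
from isnkit.predict import compute_auc

METRICS = [
    "degree", "avg_shortest_path", "eccentricity", "closeness", "betweenness",
    "stress", "clustering", "neighbourhood_connectivity", "radiality",
    "topological_coefficient",
]


def _path_counts(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs BFS distances and shortest-path counts via layered DP.

    Returns (d, sigma): d[s, t] is the geodesic distance (-1 if unreachable),
    sigma[s, t] the number of distinct shortest s-t paths.
    """
    n = A.shape[0]
    d = np.full((n, n), -1, dtype=int)
    sigma = np.zeros((n, n))
    neighbors = [np.flatnonzero(A[v]) for v in range(n)]
    for s in range(n):
        d[s, s] = 0
        sigma[s, s] = 1.0
        frontier = [s]
        dist = 0
        while frontier:
            nxt = []
            dist += 1
            for v in frontier:
                for w in neighbors[v]:
                    if d[s, w] == -1:
                        d[s, w] = dist
                        nxt.append(w)
                    if d[s, w] == dist:
                        sigma[s, w] += sigma[s, v]
            frontier = nxt
    return d, sigma


def compute_node_metrics(graph: nx.Graph | pd.DataFrame, min_nodes: int = 4) -> pd.DataFrame:
    """Ten per-node metrics for a single ISN's support graph.

    ``graph`` is a networkx Graph or a symmetric weight DataFrame (non-zero
    entries define edges; only nodes incident to at least one edge enter).
    Graphs with fewer than ``min_nodes`` nodes are rejected.
    """
    if isinstance(graph, pd.DataFrame):
        W = graph.values
        nodes = list(graph.index)
        G = nx.Graph()
        iu, ju = np.nonzero(np.triu(W, k=1))
        G.add_edges_from((nodes[a], nodes[b]) for a, b in zip(iu, ju))
        graph = G
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if n < min_nodes:
        raise ValueError(f"ISN support graph has {n} nodes; fewer than {min_nodes}")
    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None).astype(bool)
    deg = A.sum(axis=1).astype(float)
    d, sigma = _path_counts(A.astype(np.int8))
    reach = d > 0  # same component, excluding self

    out = pd.DataFrame(index=pd.Index(nodes, name="node"), columns=METRICS, dtype=float)
    out["degree"] = deg

    # distances within components
    dd = np.where(reach, d, 0).astype(float)
    n_reach = reach.sum(axis=1)
    asp = np.where(n_reach > 0, dd.sum(axis=1) / np.maximum(n_reach, 1), np.nan)
    out["avg_shortest_path"] = asp
    out["eccentricity"] = np.where(n_reach > 0, dd.max(axis=1), np.nan)
    out["closeness"] = np.where(n_reach > 0, 1.0 / np.where(asp > 0, asp, 1.0), np.nan)

    # betweenness and stress from the sigma matrices (vectorized per node)
    bet = np.zeros(n)
    stress = np.zeros(n)
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    for v in range(n):
        dsv = d[:, v][:, None]
        dvt = d[v, :][None, :]
        on_path = (dsv > 0) & (dvt > 0) & (d > 0) & (dsv + dvt == d) & upper
        on_path[v, :] = False
        on_path[:, v] = False
        if not on_path.any():
            continue
        through = sigma[:, v][:, None] * sigma[v, :][None, :]
        stress[v] = through[on_path].sum()
        bet[v] = (through[on_path] / sigma[on_path]).sum()
    denom = (n - 1) * (n - 2) / 2
    out["betweenness"] = bet / denom if denom > 0 else np.nan
    out["stress"] = stress

    # clustering: missing for degree < 2
    Af = A.astype(float)
    tri = np.einsum("ij,jk,ki->i", Af, Af, Af) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        clust = 2.0 * tri / (deg * (deg - 1))
    out["clustering"] = np.where(deg >= 2, clust, np.nan)

    out["neighbourhood_connectivity"] = np.where(
        deg > 0, (A @ deg) / np.maximum(deg, 1), np.nan)

    # radiality: (diameter_C + 1 - asp) / diameter_C within the component
    comp_label = np.full(n, -1)
    label = 0
    for v in range(n):
        if comp_label[v] == -1:
            members = np.flatnonzero((d[v] >= 0))
            comp_label[members] = label
            label += 1
    radial = np.full(n, np.nan)
    for c in range(label):
        members = np.flatnonzero(comp_label == c)
        if len(members) < 2:
            continue
        sub_d = d[np.ix_(members, members)]
        diam = sub_d.max()
        if diam > 0:
            radial[members] = (diam + 1 - asp[members]) / diam
    out["radiality"] = radial

    # topological coefficient over partners sharing >= 1 neighbour
    shared = (A.astype(int) @ A.astype(int)).astype(float)
    np.fill_diagonal(shared, 0.0)
    J = shared + A  # +1 when also adjacent
    tc = np.full(n, np.nan)
    for v in range(n):
        partners = np.flatnonzero(shared[v] > 0)
        partners = partners[partners != v]
        if len(partners) and deg[v] > 0:
            tc[v] = float(np.mean(J[v, partners] / deg[v]))
    out["topological_coefficient"] = tc
    return out


def metrics_for_isns(isns: IsnSet, taxa, min_nodes: int = 4,
                     weight_threshold: float = 0.0) -> dict:
    """Per-sample metric tables; samples whose graph is too small are skipped.

    ``weight_threshold`` > 0 binarises each ISN at |weight| >= threshold
    before building the support graph; with dense (all-pairs) ISNs every
    entry is technically non-zero and a magnitude cutoff is what makes the
    graphs sample-specific.
    """
    tables, skipped = {}, []
    for s in isns.samples:
        W = isns.edge_matrix(s, taxa)
        if weight_threshold > 0:
            W = W.where(W.abs() >= weight_threshold, 0.0)
        try:
            tables[s] = compute_node_metrics(W, min_nodes=min_nodes)
        except ValueError:
            skipped.append(s)
    return {"tables": tables, "skipped": skipped}


def build_metric_features(tables: dict, protocol: str = "zero_fill") -> pd.DataFrame:
    """Sample x (node, metric) matrix under one missing-value protocol.

    ``zero_fill`` replaces missing metric cells (including whole nodes absent
    from a sample's ISN) with zeros; ``drop_node`` removes any node missing
    any metric in any sample from the feature space entirely.
    """
    if protocol not in ("zero_fill", "drop_node"):
        raise ValueError(f"unknown protocol {protocol!r}")
    wide = {}
    for sample, tab in tables.items():
        stacked = tab.stack(dropna=False)
        stacked.index = [f"{node}|{metric}" for node, metric in stacked.index]
        wide[sample] = stacked
    X = pd.DataFrame(wide).T.sort_index(axis=1)
    X.index.name = "sample"
    if protocol == "zero_fill":
        out = X.fillna(0.0)
    else:
        missing_cols = X.columns[X.isna().any(axis=0)]
        bad_nodes = {c.split("|")[0] for c in missing_cols}
        keep = [c for c in X.columns if c.split("|")[0] not in bad_nodes]
        if not keep:
            raise ValueError(
                f"drop_node removed every node ({len(bad_nodes)} nodes had missing metrics)")
        out = X[keep]
    out.attrs["protocol"] = protocol
    return out


@dataclass
class ScreenInstance:
    name: str
    classifier: str
    auc: float
    significant: bool
    top_features: list


def topo_screen_classify(
    features: dict | pd.DataFrame,
    outcome: pd.Series,
    folds: int = 10,
    top_k: int = 20,
    auc_min: float = 0.75,
    n_trees: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated RF and radial-SVM AUC screen per feature instance.

    ``features`` maps instance name (e.g. "closeness/zero_fill") to a sample
    x feature matrix; a single matrix screens one instance. The RF route
    restricts each training fold to its own top-``top_k`` importance
    features; instances reaching ``auc_min`` are flagged significant.
    """
    if isinstance(features, pd.DataFrame):
        features = {"features": features}
    rows = []
    rng = np.random.default_rng(seed)
    for name, X in features.items():
        y_all = outcome.loc[X.index]
        keep = y_all.notna() & (y_all != "missing")
        Xv = X.loc[keep.values].values
        classes = sorted(pd.unique(y_all[keep.values]))
        y = (y_all[keep.values] == classes[-1]).astype(int).values
        n_folds = min(folds, int(np.bincount(y).min()))
        if n_folds < 2:
            raise ValueError(f"too few samples per class to cross-validate {name!r}")
        for attempt in range(10):
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=int(rng.integers(2**31 - 1)))
            splits = list(skf.split(Xv, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
                break
        else:
            raise RuntimeError("could not draw folds with both classes present")

        rf_scores = np.zeros(len(y))
        svm_scores = np.zeros(len(y))
        top_union: dict = {}
        for tr, te in splits:
            rf = RandomForestClassifier(
                n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1)))
            rf.fit(Xv[tr], y[tr])
            order = np.lexsort((np.arange(Xv.shape[1]), -rf.feature_importances_))
            sel = order[:min(top_k, Xv.shape[1])]
            for f in sel:
                top_union[X.columns[f]] = top_union.get(X.columns[f], 0) + 1
            rf_sel = RandomForestClassifier(
                n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1)))
            rf_sel.fit(Xv[tr][:, sel], y[tr])
            rf_scores[te] = rf_sel.predict_proba(Xv[te][:, sel])[:, 1]

            sd = Xv[tr].std(axis=0)
            usable = np.flatnonzero(sd > 0)
            if len(usable) == 0:
                svm_scores[te] = 0.0  # nothing informative in this fold
                continue
            scaler = StandardScaler().fit(Xv[tr][:, usable])
            svm = SVC(kernel="rbf", C=1.0, gamma="scale")
            svm.fit(scaler.transform(Xv[tr][:, usable]), y[tr])
            svm_scores[te] = svm.decision_function(scaler.transform(Xv[te][:, usable]))

        top_feats = sorted(top_union, key=lambda f: (-top_union[f], f))[:top_k]
        for clf, sc in (("rf", rf_scores), ("svm", svm_scores)):
            auc = compute_auc(sc, y)
            rows.append({"instance": name, "classifier": clf, "auc": auc,
                         "significant": auc >= auc_min,
                         "top_features": top_feats if clf == "rf" else []})
    return pd.DataFrame(rows)
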