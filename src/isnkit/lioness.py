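"""Individual-specific networks via the LIONESS leave-one-out equation.

For an aggregate network estimator e(.) and N samples, the ISN of sample q is

    e^q = N * (e^alpha - e^(alpha-q)) + e^(alpha-q)

where e^alpha is the estimate on all samples and e^(alpha-q) on the N-1
samples excluding q. When the estimator is a mean of per-sample
contributions, e^q recovers sample q's contribution exactly; for non-linear
estimators (the copula graphical model here) it linearly extrapolates the
sample's influence on each edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from isnkit.containers import CountMatrix
from isnkit.popnet import (PopulationNetwork, _glasso_precision,
                           constrained_partial_corr, weights_from_precision)


@dataclass
class IsnSet:
    """Per-sample edge weights over a fixed edge universe."""

    edge_index: list                # [(taxon_i, taxon_j), ...] upper triangle
    weights: pd.DataFrame           # samples x edges; columns "ti|tj"
    provenance: dict = field(default_factory=dict)
    e_alpha: pd.Series | None = None  # the aggregate network the ISNs extrapolate

    @property
    def samples(self) -> pd.Index:
        return self.weights.index

    @property
    def edge_labels(self) -> list:
        return list(self.weights.columns)

    def edge_matrix(self, sample, taxa) -> pd.DataFrame:
        """Square symmetric weight matrix of one sample's ISN."""
        W = pd.DataFrame(0.0, index=taxa, columns=taxa)
        row = self.weights.loc[sample]
        for (ti, tj), label in zip(self.edge_index, self.weights.columns):
            W.loc[ti, tj] = W.loc[tj, ti] = row[label]
        return W


def edge_labels(edge_index) -> list:
    return [f"{a}|{b}" for a, b in edge_index]


def copula_estimator(net: PopulationNetwork, mode: str = "relaxed",
                     support: np.ndarray | None = None):
    """Aggregate estimator reusing the full-data marginal scores and support.

    ``relaxed`` (default) keeps the StARS-selected support fixed and
    computes partial correlations from the support-constrained Gaussian MLE
    of each (leave-one-out) correlation matrix; it is smooth in the data, so
    the leave-one-out extrapolation is well behaved. ``glasso`` re-runs the
    graphical lasso at the fixed rho* instead (edges may flip in and out of
    the support between refits, which makes the extrapolated weights jumpy).
    """
    if mode == "relaxed":
        if support is None:
            support = net.support.values.astype(bool)

        def estimate(Z: np.ndarray) -> np.ndarray:
            return constrained_partial_corr(np.corrcoef(Z, rowvar=False), support)

    elif mode == "glasso":
        rho = net.rho_star

        def estimate(Z: np.ndarray) -> np.ndarray:
            corr = np.corrcoef(Z, rowvar=False)
            return weights_from_precision(_glasso_precision(corr, rho))

    else:
        raise ValueError(f"unknown copula estimator mode {mode!r}")
    estimate.__name__ = f"copula_{mode}"
    return estimate


def product_mean_estimator(Z: np.ndarray) -> np.ndarray:
    """Mean of per-sample outer products: the canonical linear statistic."""
    n = Z.shape[0]
    return (Z.T @ Z) / n


def lioness_isns(
    cm: CountMatrix,
    net: PopulationNetwork,
    estimator=None,
    edge_universe: str = "support",
) -> IsnSet:
    """Compute one ISN per retained sample by leave-one-out extrapolation.

    ``estimator`` maps a samples x taxa score matrix to a symmetric taxa x
    taxa weight matrix; the default is the copula graphical-model estimator
    at the population network's selected penalty, applied to the stored
    normal scores. ``edge_universe`` is the population support by default,
    or "all" for every upper-triangle pair (useful for linearity checks).
    """
    if net.scores is None:
        raise ValueError("population network carries no score matrix; run population_network()")
    Z = net.scores
    samples = list(Z.index)
    N = len(samples)
    if N < 3:
        raise ValueError(f"need N >= 3 samples, got {N}")
    if estimator is None:
        # the estimator's support must cover the requested edge universe
        if edge_universe == "all":
            p = len(net.taxa)
            full = np.ones((p, p), dtype=bool)
            np.fill_diagonal(full, False)
            estimator = copula_estimator(net, support=full)
        else:
            estimator = copula_estimator(net)

    taxa = list(net.taxa)
    sup = net.support.values
    iu, ju = np.triu_indices(len(taxa), k=1)
    if edge_universe == "support":
        mask = sup[iu, ju]
    elif edge_universe == "all":
        mask = np.ones(len(iu), dtype=bool)
    else:
        raise ValueError(f"unknown edge universe {edge_universe!r}")
    ei, ej = iu[mask], ju[mask]
    edge_index = [(taxa[a], taxa[b]) for a, b in zip(ei, ej)]

    Zv = Z.values
    e_alpha = estimator(Zv)[ei, ej]
    rows, kept = [], []
    for q in range(N):
        try:
            e_loo = estimator(np.delete(Zv, q, axis=0))[ei, ej]
        except Exception as exc:  # noqa: BLE001 - flagged and skipped per contract
            warnings.warn(f"leave-one-out refit failed for sample {samples[q]}: {exc}")
            continue
        rows.append(N * (e_alpha - e_loo) + e_loo)
        kept.append(samples[q])

    labels = edge_labels(edge_index)
    weights = pd.DataFrame(np.vstack(rows), index=pd.Index(kept, name="sample"),
                           columns=labels)
    prov = {"rho_star": net.rho_star, "estimator": getattr(estimator, "__name__", "copula"),
            "N": N, "edge_universe": edge_universe}
    return IsnSet(edge_index, weights, prov, e_alpha=pd.Series(e_alpha, index=labels))


def lioness_from_contributions(values: pd.DataFrame, estimator) -> IsnSet:
    """LIONESS over an arbitrary samples x features table with a callable
    estimator returning a square feature x feature weight matrix.

    Exposed separately for estimator-agnostic tests (e.g. the linear
    mean-of-contributions identity).
    """
    X = values.values
    feats = list(values.columns)
    N = X.shape[0]
    iu, ju = np.triu_indices(len(feats), k=1)
    e_alpha = estimator(X)[iu, ju]
    rows = []
    for q in range(N):
        e_loo = estimator(np.delete(X, q, axis=0))[iu, ju]
        rows.append(N * (e_alpha - e_loo) + e_loo)
    edge_index = [(feats[a], feats[b]) for a, b in zip(iu, ju)]
    weights = pd.DataFrame(np.vstack(rows), index=values.index,
                           columns=edge_labels(edge_index))
    return IsnSet(edge_index, weights, {"estimator": getattr(estimator, "__name__", "custom"),
                                        "N": N})


def isn_edge_table(isns: IsnSet, metadata: pd.DataFrame,
                   label_cols=("outcome", "group", "timepoint")) -> pd.DataFrame:
    """Tidy long table: one row per (sample, edge) with outcome/group labels."""
    missing = isns.samples.difference(metadata.index)
    if len(missing):
        raise ValueError(f"samples absent from metadata: {list(missing)[:5]}")
    long = isns.weights.reset_index().melt(
        id_vars="sample", var_name="edge", value_name="weight")
    cols = [c for c in label_cols if c in metadata.columns]
    labels = metadata.loc[isns.samples, cols].reset_index()
    out = long.merge(labels, on="sample", how="left")
    if "outcome" in out.columns:
        out["outcome"] = out["outcome"].fillna("missing")
    return out
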