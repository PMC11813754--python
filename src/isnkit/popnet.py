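"""Population co-abundance network: ZINB-copula Gaussian graphical model.

The estimator follows the MAGMA recipe: each taxon's counts are fit to a
zero-inflated negative binomial regression (log link, per-sample log-depth
offset as size factor, clinical covariates on log-mean), observed counts are
probability-transformed through the fitted discrete CDF into latent normal
scores, and a graphical lasso on the scores' correlation — with the penalty
chosen by StARS stability selection — yields a sparse precision matrix. The
continuous co-abundance weight of an edge is the negative rescaled precision
entry, i.e. the latent partial correlation, on the selected support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

from isnkit.containers import CountMatrix
from isnkit.simulate import standardize_covariates
from isnkit.zinb import ZinbTaxonFit, fit_zinb_regression, normal_scores


def exclude_sparse_overlap_samples(cm: CountMatrix, min_common_taxa: int = 10) -> CountMatrix:
    """Drop samples sharing fewer than ``min_common_taxa`` non-zero taxa with the rest.

    A taxon counts as "common" for a sample when it is non-zero in that sample
    and non-zero in at least one other sample.
    """
    nz = cm.counts.values > 0
    col_nz = nz.sum(axis=0)
    # shared count for sample s: taxa with nz[s] and nz in >= 1 other sample
    shared = ((nz) & ((col_nz[None, :] - nz) >= 1)).sum(axis=1)
    keep = cm.samples[shared >= min_common_taxa]
    if len(keep) < 10:
        raise ValueError(
            f"only {len(keep)} samples share >= {min_common_taxa} common taxa; "
            "too few for network estimation"
        )
    return cm.subset_samples(keep)


def gmpr_size_factors(counts: np.ndarray) -> np.ndarray:
    """Geometric mean of pairwise ratios (GMPR) size factors.

    For each sample pair, take the median of count ratios over taxa non-zero
    in both; a sample's size factor is the geometric mean of its medians.
    Robust to zeros and to single dominant taxa, unlike raw library size,
    whose sampling noise is shared across taxa and would leak a common
    factor into the copula scores.
    """
    n, p = counts.shape
    with np.errstate(divide="ignore"):
        logc = np.where(counts > 0, np.log(counts.astype(float)), np.nan)
    log_sf = np.zeros(n)
    for i in range(n):
        diffs = logc[i][None, :] - logc  # n x p pairwise log ratios
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            med = np.nanmedian(diffs, axis=1)
        med[i] = np.nan
        log_sf[i] = np.nanmean(med)
    if not np.all(np.isfinite(log_sf)):
        raise ValueError("GMPR size factors undefined: samples share no taxa")
    # mean over j != i of (s_i - s_j) equals (n/(n-1)) * (s_i - mean s); undo
    log_sf *= (n - 1) / n
    return np.exp(log_sf - log_sf.mean())


@dataclass
class ZinbFit:
    """Per-taxon marginal fits plus the design they were fit against."""

    fits: dict                      # taxon -> ZinbTaxonFit
    design: np.ndarray | None       # covariate design (without intercept)
    offset: np.ndarray              # per-sample log-depth offset (centred)
    covariates: list
    samples: pd.Index

    def params_table(self) -> pd.DataFrame:
        rows = {}
        for taxon, f in self.fits.items():
            rows[taxon] = {"mu": f.mu, "theta": f.theta, "pi": f.pi,
                           "loglik": f.loglik, "fallback_nb": f.fallback_nb}
        return pd.DataFrame(rows).T


def fit_copula_margins(
    cm: CountMatrix,
    covariates: list | None = None,
    score_method: str = "mid",
    seed: int = 0,
) -> tuple[ZinbFit, pd.DataFrame]:
    """ZINB regression per taxon and covariate-adjusted latent normal scores.

    ``covariates`` names metadata columns (subset of age/gender/duration/
    location); they enter the marginal regressions, so the returned scores Z
    are adjusted for them. Taxa whose ZINB fit fails fall back to a plain NB
    with a warning.
    """
    if not cm.is_integer:
        raise ValueError("copula margins require integer counts (RMP profiles)")
    design = None
    if covariates:
        full = standardize_covariates(cm.metadata.loc[cm.samples])
        name_map = {"age": [0], "gender": [1], "duration": [2], "location": [3, 4]}
        cols = [c for name in covariates for c in name_map[name]]
        design = full[:, cols]
    offset = np.log(gmpr_size_factors(cm.counts.values))

    rng = np.random.default_rng(seed)
    fits, zcols, fallbacks = {}, {}, []
    for taxon in cm.taxa:
        y = cm.counts[taxon].values
        fit = fit_zinb_regression(y, design, offset)
        if fit.fallback_nb:
            fallbacks.append(taxon)
        fits[taxon] = fit
        X = np.column_stack([np.ones(len(y))] + ([design] if design is not None else []))
        mu = np.exp(np.clip(offset + X @ fit.beta, -30.0, 30.0))
        zcols[taxon] = normal_scores(y, mu, fit.theta, fit.pi,
                                     method=score_method, rng=rng)
    if fallbacks:
        warnings.warn(f"ZINB fit fell back to NB for {len(fallbacks)} taxa: {fallbacks[:5]}")
    if all(f.fallback_nb and not f.converged for f in fits.values()):
        raise RuntimeError("every taxon's marginal fit failed")
    Z = pd.DataFrame(zcols, index=cm.samples)[list(cm.taxa)]
    return ZinbFit(fits, design, offset, list(covariates or []), cm.samples), Z


@dataclass
class PopulationNetwork:
    """Sparse continuous co-abundance network over taxa.

    ``weights`` holds the signed partial correlations -Omega_ij/sqrt(Omega_ii
    Omega_jj) on the StARS-selected support (zero elsewhere, zero diagonal);
    ``support`` is the binary simplification (weights != 0).
    """

    weights: pd.DataFrame
    support: pd.DataFrame
    rho_star: float
    rho_path: pd.DataFrame          # rho, instability, monotone instability
    retained_samples: list
    scores: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def taxa(self) -> pd.Index:
        return self.weights.index

    def edge_list(self) -> pd.DataFrame:
        w = self.weights.values
        iu, ju = np.triu_indices(len(self.taxa), k=1)
        mask = w[iu, ju] != 0
        return pd.DataFrame({
            "taxon_i": self.taxa[iu[mask]],
            "taxon_j": self.taxa[ju[mask]],
            "weight": w[iu, ju][mask],
        })


def _glasso_precision(corr: np.ndarray, rho: float) -> np.ndarray:
    # 1e-3 tolerances are ample for support/partial-correlation estimation and
    # avoid dual-gap oscillation near the sparsity phase transition
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            _, prec = graphical_lasso(corr, alpha=rho, max_iter=100,
                                      tol=1e-3, enet_tol=1e-3)
        except FloatingPointError:
            _, prec = graphical_lasso(corr, alpha=rho, max_iter=500, mode="lars")
    return prec


def _support(prec: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    s = np.abs(prec) > tol
    np.fill_diagonal(s, False)
    return s


def weights_from_precision(prec: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(prec))
    w = -prec / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    w[~_support(prec)] = 0.0
    return w


def constrained_precision(S: np.ndarray, support: np.ndarray,
                          max_sweeps: int = 50, tol: float = 1e-8) -> np.ndarray:
    """Gaussian MLE of the precision matrix constrained to a fixed support.

    Classical covariance-selection fitting by node-wise regressions
    (Dempster's problem, solved with the modified-regression algorithm):
    maximises logdet(Omega) - tr(S Omega) subject to Omega_ij = 0 off the
    support. Unlike the lasso fit it is smooth in S, which matters for
    leave-one-out extrapolation, and carries no shrinkage bias on the
    retained edges.
    """
    p = S.shape[0]
    support = np.asarray(support, dtype=bool)
    off_diag = ~np.eye(p, dtype=bool)
    if support[off_diag].all():
        # saturated model: the MLE is the inverse correlation directly
        return np.linalg.pinv(S)
    W = S.copy()
    betas = [None] * p
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            nb = np.flatnonzero(support[j])
            idx = np.delete(np.arange(p), j)
            if len(nb) == 0:
                new = np.zeros(p - 1)
                betas[j] = (nb, np.zeros(0))
            else:
                W11 = W[np.ix_(idx, idx)]
                pos = np.searchsorted(idx, nb)
                beta = np.linalg.solve(W11[np.ix_(pos, pos)], S[nb, j])
                new = W11[:, pos] @ beta
                betas[j] = (nb, beta)
            delta = max(delta, np.abs(W[idx, j] - new).max() if p > 1 else 0.0)
            W[idx, j] = new
            W[j, idx] = new
        if delta < tol:
            break
    # recover Omega from the final regressions
    Omega = np.zeros_like(S)
    for j in range(p):
        idx = np.delete(np.arange(p), j)
        nb, beta = betas[j]
        pos = np.searchsorted(idx, nb)
        w12 = W[idx, j]
        theta_jj = 1.0 / (S[j, j] - (w12[pos] @ beta if len(nb) else 0.0))
        Omega[j, j] = theta_jj
        if len(nb):
            Omega[nb, j] = -beta * theta_jj
    # symmetrise (node-wise recovery is symmetric only at convergence)
    return 0.5 * (Omega + Omega.T)


def constrained_partial_corr(S: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Partial correlations of the support-constrained Gaussian MLE."""
    prec = constrained_precision(S, support)
    d = np.sqrt(np.abs(np.diag(prec)))
    w = -prec / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    w[~support] = 0.0
    return w


def default_rho_grid(corr: np.ndarray, n_rho: int = 15, ratio: float = 15.0) -> np.ndarray:
    """Decreasing log-spaced penalty grid bracketing the correlation range.

    The grid starts above the largest off-diagonal |corr| (so the most
    penalised model is empty even on subsamples, anchoring the instability
    curve at zero) and descends geometrically.
    """
    off = np.abs(corr[~np.eye(corr.shape[0], dtype=bool)])
    rho_max = max(off.max(), 1e-3)
    top = min(1.0, 1.3 * rho_max)
    return np.geomspace(top, rho_max / ratio, n_rho)


def stars_glasso(
    Z: pd.DataFrame | np.ndarray,
    rho_grid: np.ndarray | None = None,
    n_subsamples: int = 20,
    subsample_fraction: float | None = None,
    beta_threshold: float = 0.05,
    seed: int = 0,
) -> PopulationNetwork:
    """Graphical lasso along a penalty path with StARS penalty selection.

    Edge-selection instability at each rho is the mean over edges of
    2*theta*(1-theta), theta being the fraction of random subsamples that
    select the edge; the instability curve is monotonised from the most to
    the least penalised end, and rho* is the smallest rho whose monotone
    instability stays <= ``beta_threshold``.
    """
    if isinstance(Z, pd.DataFrame):
        taxa = Z.columns
        sample_ids = list(Z.index)
        Zv = Z.values
    else:
        Zv = np.asarray(Z)
        taxa = pd.Index([f"v{t}" for t in range(Zv.shape[1])])
        sample_ids = list(range(Zv.shape[0]))
    n, p = Zv.shape
    if n < 20:
        raise ValueError(f"StARS needs >= 20 samples, got {n}")
    corr = np.corrcoef(Zv, rowvar=False)
    if rho_grid is None:
        rho_grid = default_rho_grid(corr)
    rho_grid = np.asarray(rho_grid, dtype=float)
    if len(rho_grid) == 0:
        raise ValueError("empty rho grid")
    if np.any(np.diff(rho_grid) >= 0):
        raise ValueError("rho grid must be strictly decreasing")

    if subsample_fraction is None:
        subsample_fraction = min(0.8, 10.0 * np.sqrt(n) / n)
    b = min(max(int(np.floor(subsample_fraction * n)), 10), n - 1)

    rng = np.random.default_rng(seed)
    sel_freq = np.zeros((len(rho_grid), p, p))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=b, replace=False)
        sub_corr = np.corrcoef(Zv[idx], rowvar=False)
        for k, rho in enumerate(rho_grid):
            sel_freq[k] += _support(_glasso_precision(sub_corr, rho))
    theta = sel_freq / n_subsamples
    iu = np.triu_indices(p, k=1)
    instability = np.array([(2 * theta[k] * (1 - theta[k]))[iu].mean()
                            for k in range(len(rho_grid))])
    monotone = np.maximum.accumulate(instability)  # grid is decreasing in rho

    ok = np.flatnonzero(monotone <= beta_threshold)
    if len(ok) == 0:
        warnings.warn("no rho meets the StARS instability threshold; using the largest rho")
        k_star = 0
    else:
        k_star = int(ok.max())
    rho_star = float(rho_grid[k_star])

    prec = _glasso_precision(corr, rho_star)
    W = weights_from_precision(prec)
    weights = pd.DataFrame(W, index=taxa, columns=taxa)
    support = pd.DataFrame(W != 0, index=taxa, columns=taxa)
    path = pd.DataFrame({"rho": rho_grid, "instability": instability,
                         "monotone_instability": monotone})
    return PopulationNetwork(weights, support, rho_star, path, sample_ids)


def population_network(
    cm: CountMatrix,
    covariates: list | None = None,
    min_common_taxa: int = 10,
    score_method: str = "mid",
    seed: int = 0,
    **stars_kwargs,
) -> tuple[PopulationNetwork, ZinbFit]:
    """Convenience wrapper: sample exclusion -> margins -> StARS glasso."""
    kept = exclude_sparse_overlap_samples(cm, min_common_taxa)
    margins, Z = fit_copula_margins(kept, covariates, score_method, seed)
    net = stars_glasso(Z, seed=seed, **stars_kwargs)
    net.scores = Z
    return net, margins


@dataclass
class FamilyConnectivity:
    """Family-pair normalised summed co-occurrence; loops (A-A) admitted."""

    connectivity: pd.DataFrame      # families x families, symmetric
    taxa_per_family: pd.Series
    omitted: list


def family_connectivity(net: PopulationNetwork, taxonomy: pd.DataFrame) -> FamilyConnectivity:
    """Sum of edge weights between two families' taxa over the number of
    possible pairs (|A||B| across families, |A|(|A|-1)/2 within)."""
    fam = taxonomy.loc[net.taxa, "family"]
    families = sorted(fam.unique())
    omitted = sorted(set(taxonomy["family"].unique()) - set(families))
    W = net.weights.values
    conn = pd.DataFrame(0.0, index=families, columns=families)
    idx = {f: np.flatnonzero((fam == f).values) for f in families}
    for a_i, fa in enumerate(families):
        for fb in families[a_i:]:
            ia, ib = idx[fa], idx[fb]
            if fa == fb:
                n_pairs = len(ia) * (len(ia) - 1) / 2
                total = W[np.ix_(ia, ia)][np.triu_indices(len(ia), k=1)].sum()
            else:
                n_pairs = len(ia) * len(ib)
                total = W[np.ix_(ia, ib)].sum()
            val = total / n_pairs if n_pairs > 0 else 0.0
            conn.loc[fa, fb] = conn.loc[fb, fa] = val
    return FamilyConnectivity(conn, fam.value_counts(), omitted)


def network_summary_metrics(net: PopulationNetwork) -> dict:
    """Average node strength and eigenvector centrality of |W|."""
    A = np.abs(net.weights.values)
    strength = A.sum(axis=1)
    if not np.any(A > 0):
        warnings.warn("empty network: centrality reported as 0")
        centrality = np.zeros(len(strength))
    else:
        vals, vecs = np.linalg.eigh(A)
        v = np.abs(vecs[:, np.argmax(vals)])
        centrality = v / v.max() if v.max() > 0 else v
    return {
        "average_node_strength": float(strength.mean()),
        "average_eigenvector_centrality": float(centrality.mean()),
        "node_strength": pd.Series(strength, index=net.taxa),
        "eigenvector_centrality": pd.Series(centrality, index=net.taxa),
    }
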