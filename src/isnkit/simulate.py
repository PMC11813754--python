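"""Synthetic microbiome cohorts with known latent network structure.

Counts are generated by inverting exactly the model the population-network
estimator assumes: a Gaussian copula over taxa (latent z ~ N(0, Omega^-1)
with a group-specific sparse precision Omega) pushed through per-taxon
zero-inflated negative-binomial marginals, with per-sample sequencing depth
entering as a multiplicative offset on the NB mean and covariates acting
linearly on log-mean. "Planted" edges differ in partial correlation between
groups; outcome labels follow the group, so downstream differential-edge and
classifier stages have a known truth to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from isnkit.containers import CountMatrix
from isnkit.zinb import zinb_ppf

_FAMILIES = [
    "Lachnospiraceae", "Bacteroidaceae", "Ruminococcaceae",
    "Streptococcaceae", "Erysipelotrichaceae", "Bifidobacteriaceae",
]
_LOCATIONS = ["ileal", "colonic", "ileocolonic"]


@dataclass
class SimulationConfig:
    """Generative settings for one synthetic cohort.

    ``planted_edges`` are upper-triangle pairs (i, j, delta): the reference
    group (groups[0]) keeps the base precision; every other group has the
    edge's partial correlation shifted by ``delta`` (precision entry shifted
    by -delta, which equals a +delta partial-correlation shift when the
    precision diagonal is 1).
    """

    n_taxa: int = 30
    n_samples_per_group: int = 40
    groups: tuple = ("non-responder", "responder")
    timepoints: tuple = ("w0",)
    precision_base: np.ndarray | None = None
    planted_edges: list = field(default_factory=list)  # [(i, j, delta), ...]
    mu: np.ndarray | None = None        # per-taxon NB mean scale
    theta: np.ndarray | None = None     # per-taxon dispersion
    pi: np.ndarray | None = None        # per-taxon zero inflation
    depth_lognormal: tuple = (np.log(2e4), 0.5)
    covariate_effects: dict = field(default_factory=dict)  # cov -> scalar or (n_taxa,)
    outcome_by_group: dict | None = None
    seed: int = 0

    def __post_init__(self):
        p = self.n_taxa
        rng = np.random.default_rng(self.seed + 777)
        if self.precision_base is None:
            self.precision_base = np.eye(p)
        self.precision_base = np.asarray(self.precision_base, dtype=float)
        if self.mu is None:
            # lognormal mean scale: a few dominant taxa, a long tail
            self.mu = np.exp(rng.normal(np.log(40.0), 1.0, size=p))
        if self.theta is None:
            self.theta = np.full(p, 1.5)
        if self.pi is None:
            self.pi = rng.uniform(0.05, 0.3, size=p)
        self.mu = np.asarray(self.mu, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.outcome_by_group is None:
            self.outcome_by_group = {
                g: ("remission" if "non" not in g else "no-remission")
                for g in self.groups
            }
        self.check()

    def check(self) -> None:
        if np.any(self.pi < 0) or np.any(self.pi > 1):
            raise ValueError("pi must lie in [0, 1]")
        for i, j, _ in self.planted_edges:
            if not (0 <= i < j < self.n_taxa):
                raise ValueError(f"planted edge ({i},{j}) not in the upper triangle")
        for g in self.groups:
            prec = self.group_precision(g)
            if not np.allclose(prec, prec.T):
                raise ValueError(f"precision for group {g!r} is not symmetric")
            if np.linalg.eigvalsh(prec).min() <= 1e-10:
                raise ValueError(f"precision for group {g!r} is not positive definite")

    def group_precision(self, group: str) -> np.ndarray:
        prec = self.precision_base.copy()
        if group != self.groups[0]:
            for i, j, delta in self.planted_edges:
                prec[i, j] -= delta
                prec[j, i] -= delta
        return prec


@dataclass
class GroundTruth:
    """Latent quantities recorded for recovery tests."""

    latent: pd.DataFrame            # samples x taxa latent Gaussian vectors
    labels: pd.DataFrame            # group / timepoint / outcome per sample
    planted_edges: list             # [(i, j, delta)]
    partial_correlations: dict      # group -> {(i, j): partial r} on planted edges

    def to_json(self) -> str:
        payload = {
            "planted_edges": [[int(i), int(j), float(d)] for i, j, d in self.planted_edges],
            "partial_correlations": {
                g: {f"{i},{j}": float(r) for (i, j), r in d.items()}
                for g, d in self.partial_correlations.items()
            },
            "latent": {"index": list(self.latent.index),
                       "columns": list(self.latent.columns),
                       "values": self.latent.values.tolist()},
            "labels": self.labels.to_dict(orient="index"),
        }
        return json.dumps(payload, indent=1)


def partial_corr_from_precision(prec: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def planted_precision(n_taxa: int, edges, partial_r: float) -> np.ndarray:
    """Identity precision with ``partial_r`` partial correlation on ``edges``."""
    prec = np.eye(n_taxa)
    for i, j in edges:
        prec[i, j] = prec[j, i] = -partial_r
    if np.linalg.eigvalsh(prec).min() <= 1e-10:
        raise ValueError("requested planted edges make the precision indefinite")
    return prec


def default_taxonomy(n_taxa: int, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed + 13)
    taxa = [f"taxon_{t:03d}" for t in range(n_taxa)]
    fam = [_FAMILIES[t % len(_FAMILIES)] for t in range(n_taxa)]
    gen = [f"genus_{t:03d}" for t in range(n_taxa)]
    cn = rng.integers(1, 8, size=n_taxa).astype(float)
    return pd.DataFrame(
        {"family": fam, "genus": gen, "copy_number": cn}, index=pd.Index(taxa, name="taxon")
    )


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame({
        "age": rng.uniform(18, 75, size=n),
        "gender": rng.integers(0, 2, size=n),
        "duration": rng.uniform(0, 20, size=n),
        "location": rng.choice(_LOCATIONS, size=n),
    })


def standardize_covariates(meta: pd.DataFrame) -> np.ndarray:
    """Numeric design for the covariates (age/gender/duration + location dummies).

    Continuous covariates are scaled to their uniform-draw ranges so effect
    sizes on log-mean are comparable across covariates.
    """
    cols = [
        (meta["age"].values - 46.5) / 16.45,
        meta["gender"].values - 0.5,
        (meta["duration"].values - 10.0) / 5.77,
    ]
    for loc in _LOCATIONS[1:]:
        cols.append((meta["location"].values == loc).astype(float))
    return np.column_stack(cols)


_COV_DESIGN_NAMES = ["age", "gender", "duration", "location_colonic", "location_ileocolonic"]


def _covariate_shift(config: SimulationConfig, design: np.ndarray) -> np.ndarray:
    """n x p additive shift on log mu from configured covariate effects."""
    n = design.shape[0]
    shift = np.zeros((n, config.n_taxa))
    for name, coef in config.covariate_effects.items():
        if name not in _COV_DESIGN_NAMES:
            raise ValueError(f"unknown covariate {name!r}")
        col = design[:, _COV_DESIGN_NAMES.index(name)]
        coef = np.broadcast_to(np.asarray(coef, dtype=float), (config.n_taxa,))
        shift += np.outer(col, coef)
    return shift


def _counts_from_latent(config, z, depth, cov_shift):
    """Invert the ZINB CDF at the copula uniforms, depth-scaled."""
    from scipy.stats import norm

    u = norm.cdf(z)
    n = z.shape[0]
    counts = np.zeros_like(z)
    depth_factor = depth / np.exp(config.depth_lognormal[0])
    for t in range(config.n_taxa):
        mu_eff = config.mu[t] * depth_factor * np.exp(cov_shift[:, t])
        counts[:, t] = zinb_ppf(u[:, t], mu_eff, config.theta[t], config.pi[t])
    return counts.astype(np.int64)


def generate_cohort(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a cross-sectional cohort: one sample per individual per group."""
    rng = np.random.default_rng(config.seed)
    rows, zrows, ids = [], [], []
    meta_parts = []
    for g in config.groups:
        prec = config.group_precision(g)
        cov = np.linalg.inv(prec)
        n = config.n_samples_per_group
        z = rng.multivariate_normal(np.zeros(config.n_taxa), cov, size=n, method="cholesky")
        depth = np.exp(rng.normal(*config.depth_lognormal, size=n))
        meta = _draw_covariates(rng, n)
        meta["group"] = g
        meta["outcome"] = config.outcome_by_group[g]
        meta["timepoint"] = config.timepoints[0]
        meta["depth_drawn"] = depth
        design = standardize_covariates(meta)
        cov_shift = _covariate_shift(config, design)
        counts = _counts_from_latent(config, z, depth, cov_shift)
        rows.append(counts)
        zrows.append(z)
        ids.extend(f"{g}_s{k:03d}" for k in range(n))
        meta_parts.append(meta)

    taxa = [f"taxon_{t:03d}" for t in range(config.n_taxa)]
    index = pd.Index(ids, name="sample")
    counts = pd.DataFrame(np.vstack(rows), index=index, columns=taxa)
    metadata = pd.concat(meta_parts, ignore_index=True)
    metadata.index = index
    metadata["cohort"] = "synthetic"
    metadata["disease"] = "CD"
    metadata["therapy"] = "TNF"
    metadata["individual_id"] = [s.rsplit("_", 1)[0] + "_" + s.rsplit("_", 1)[1] for s in ids]

    taxonomy = default_taxonomy(config.n_taxa, config.seed)
    cm = CountMatrix(counts, taxonomy, metadata)

    latent = pd.DataFrame(np.vstack(zrows), index=index, columns=taxa)
    pcs = {
        g: {(i, j): float(partial_corr_from_precision(config.group_precision(g))[i, j])
            for i, j, _ in config.planted_edges}
        for g in config.groups
    }
    labels = metadata[["group", "timepoint", "outcome"]].copy()
    gt = GroundTruth(latent, labels, list(config.planted_edges), pcs)
    return cm, gt


def paired_timepoints(
    config: SimulationConfig,
    precision_by_group_timepoint: dict | None = None,
) -> tuple[CountMatrix, GroundTruth]:
    """Paired-design cohort: each individual sampled at every timepoint.

    Group labels play the role of enterotype trajectories (e.g. Bact2-Bact2 /
    Bact2-Other / Other-Other); ``precision_by_group_timepoint`` maps
    (group, timepoint) to the latent precision of that layer. Latent draws
    are independent across timepoints (no within-individual carry-over).
    """
    if len(config.timepoints) != 2:
        raise ValueError("paired_timepoints requires exactly two timepoints")
    if precision_by_group_timepoint is None:
        precision_by_group_timepoint = {
            (g, tp): config.group_precision(g)
            for g in config.groups for tp in config.timepoints
        }
    for g in config.groups:
        for tp in config.timepoints:
            if (g, tp) not in precision_by_group_timepoint:
                raise ValueError(f"missing precision for group {g!r} at timepoint {tp!r}")

    rng = np.random.default_rng(config.seed)
    rows, zrows, ids, meta_parts = [], [], [], []
    for g in config.groups:
        n = config.n_samples_per_group
        base_meta = _draw_covariates(rng, n)
        depth = np.exp(rng.normal(*config.depth_lognormal, size=(len(config.timepoints), n)))
        for k, tp in enumerate(config.timepoints):
            prec = np.asarray(precision_by_group_timepoint[(g, tp)], dtype=float)
            if np.linalg.eigvalsh(prec).min() <= 1e-10:
                raise ValueError(f"precision for ({g!r}, {tp!r}) is not positive definite")
            cov = np.linalg.inv(prec)
            z = rng.multivariate_normal(np.zeros(config.n_taxa), cov, size=n, method="cholesky")
            meta = base_meta.copy()
            meta["group"] = g
            meta["trajectory"] = g
            meta["outcome"] = config.outcome_by_group[g]
            meta["timepoint"] = tp
            meta["depth_drawn"] = depth[k]
            design = standardize_covariates(meta)
            counts = _counts_from_latent(config, z, depth[k], _covariate_shift(config, design))
            rows.append(counts)
            zrows.append(z)
            ids.extend(f"{g}_i{m:03d}_{tp}" for m in range(n))
            meta["individual_id"] = [f"{g}_i{m:03d}" for m in range(n)]
            meta_parts.append(meta)

    taxa = [f"taxon_{t:03d}" for t in range(config.n_taxa)]
    index = pd.Index(ids, name="sample")
    counts = pd.DataFrame(np.vstack(rows), index=index, columns=taxa)
    metadata = pd.concat(meta_parts, ignore_index=True)
    metadata.index = index
    metadata["cohort"] = "synthetic"
    metadata["disease"] = "CD"
    metadata["therapy"] = "TNF"
    cm = CountMatrix(counts, metadata=metadata, taxonomy=default_taxonomy(config.n_taxa, config.seed))
    latent = pd.DataFrame(np.vstack(zrows), index=index, columns=taxa)
    labels = metadata[["group", "timepoint", "outcome"]].copy()
    gt = GroundTruth(latent, labels, list(config.planted_edges), {})
    return cm, gt


def write_cohort(cm: CountMatrix, gt: GroundTruth | None, out_dir: str | Path) -> None:
    """TSV counts (taxa rows x sample columns), CSV metadata/taxonomy, JSON truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm.counts.T.to_csv(out / "counts.tsv", sep="\t")
    cm.metadata.to_csv(out / "metadata.csv")
    cm.taxonomy.to_csv(out / "taxonomy.csv")
    if gt is not None:
        (out / "ground_truth.json").write_text(gt.to_json())
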