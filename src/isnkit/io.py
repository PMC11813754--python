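"""File formats and pipeline configuration.

Counts travel as TSV (taxa rows x sample columns, the common deposition
layout), metadata and taxonomy as CSV, networks as TSV edge lists (the
canonical machine interface) plus GraphML for desktop graph tools, ground
truth and metrics as JSON, configuration as YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from isnkit.containers import CountMatrix
from isnkit.popnet import PopulationNetwork


def load_profile(counts_path, meta_path, taxonomy_path) -> CountMatrix:
    """Read and validate a counts TSV + metadata CSV + taxonomy CSV triple."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#").T
    counts.index.name = "sample"
    metadata = pd.read_csv(meta_path, index_col=0, comment="#")
    taxonomy = pd.read_csv(taxonomy_path, index_col=0, comment="#")

    extra = counts.index.difference(metadata.index)
    if len(extra):
        raise ValueError(f"samples missing from metadata: {list(extra)[:10]}")
    if counts.columns.duplicated().any():
        dups = sorted(set(counts.columns[counts.columns.duplicated()]))
        raise ValueError(f"duplicate taxon ids in counts: {dups}")
    vals = counts.values
    if not np.allclose(vals, np.round(vals)):
        bad = counts.columns[(~np.isclose(vals, np.round(vals))).any(axis=0)]
        raise ValueError(f"non-integer count cells in taxa: {list(bad)[:5]}")
    counts = counts.astype(np.int64)
    return CountMatrix(counts, taxonomy, metadata.loc[counts.index])


def write_profile(cm: CountMatrix, out_dir, header: str | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_table(cm.counts.T, out / "counts.tsv", sep="\t", header_comment=header)
    cm.metadata.to_csv(out / "metadata.csv")
    cm.taxonomy.to_csv(out / "taxonomy.csv")


def _write_table(df: pd.DataFrame, path, sep=",", header_comment: str | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep)


def write_network(net: PopulationNetwork, out_dir, stem: str = "population_network",
                  header: str | None = None) -> None:
    """TSV edge list + GraphML + penalty path CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_table(net.edge_list().set_index("taxon_i"), out / f"{stem}_edges.tsv",
                 sep="\t", header_comment=header)
    _write_table(net.rho_path, out / f"{stem}_rho_path.csv", header_comment=header)
    G = nx.Graph()
    G.add_nodes_from(net.taxa)
    for _, row in net.edge_list().iterrows():
        G.add_edge(row["taxon_i"], row["taxon_j"], weight=float(row["weight"]))
    nx.write_graphml(G, out / f"{stem}.graphml")


@dataclass
class PipelineConfig:
    """All thresholds and seeds of the end-to-end pipeline, YAML round-trippable."""

    out_dir: str = "results/pipeline"
    # stage toggles
    run_prep: bool = True
    run_popnet: bool = True
    run_isn: bool = True
    run_diff: bool = True
    run_predict: bool = True
    run_topo: bool = True
    run_dynamics: bool = False
    use_qmp: bool = False
    # thresholds
    prevalence_min: float = 0.25
    depth_min: int = 500
    rarefaction_target: int = 10_000
    qmp_min_rarefied: int = 150
    min_common_taxa: int = 10
    covariates: list = field(default_factory=lambda: ["age", "gender", "duration", "location"])
    diff_threshold: float = 0.5
    p_max: float = 0.05
    q_max: float = 0.05
    auc_min: float = 0.75
    top_k: int = 20
    rf_folds: int = 5
    rf_repeats: int = 10
    rf_trees: int = 100
    svm_n_screen: int = 20
    topo_folds: int = 10
    dynamics_repeats: int = 50
    dynamics_n_perm: int = 200
    dynamics_dim: int = 5
    # per-stage seeds
    seed_prep: int = 1
    seed_popnet: int = 2
    seed_predict: int = 3
    seed_topo: int = 4
    seed_dynamics: int = 5

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text)
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def provenance(self, stage: str) -> str:
        return (f"isnkit {stage} | config_sha={self.digest()} | "
                f"seeds prep={self.seed_prep} popnet={self.seed_popnet} "
                f"predict={self.seed_predict} topo={self.seed_topo} "
                f"dynamics={self.seed_dynamics}")


def write_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def convert(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (pd.Series,)):
            return o.to_dict()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=convert))
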