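"""End-to-end orchestrator: prep -> popnet -> isn -> {diff, predict, topo, dynamics}.

Every stage writes its artifacts under the configured output directory with a
provenance header (config hash + stage seeds) and drops a ``<stage>.done``
checkpoint; a rerun skips stages whose checkpoint is present, so a failed run
resumes where it halted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from isnkit.containers import CountMatrix
from isnkit.diffedges import differential_edges
from isnkit.dynamics import (aggregate_group_networks, embed_and_distance,
                             permutation_significance)
from isnkit.io import PipelineConfig, _write_table, write_json, write_network, write_profile
from isnkit.lioness import isn_edge_table, lioness_isns
from isnkit.popnet import population_network
from isnkit.predict import rf_rank_select, svm_loo_predict
from isnkit.profiles import filter_profiles, qmp_transform, rarefy_rmp
from isnkit.topology import build_metric_features, metrics_for_isns, topo_screen_classify

log = logging.getLogger("isnkit.pipeline")


def _done(out: Path, stage: str) -> Path:
    return out / f"{stage}.done"


def run_pipeline(config: PipelineConfig, cm: CountMatrix) -> Path:
    """Run the configured stages over ``cm``; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    state: dict = {"cm": cm}

    if config.run_prep and not _done(out, "prep").exists():
        n0 = (len(cm.samples), len(cm.taxa))
        prepped = filter_profiles(cm, config.prevalence_min, config.depth_min)
        log.info("filter: %s -> %s (samples, taxa)", n0, (len(prepped.samples), len(prepped.taxa)))
        if config.use_qmp:
            prepped = qmp_transform(prepped, config.qmp_min_rarefied, config.seed_prep)
        else:
            target = min(config.rarefaction_target, int(prepped.depths.min()))
            prepped = rarefy_rmp(prepped, target, config.seed_prep)
        write_profile(prepped, out / "prep", header=config.provenance("prep"))
        _done(out, "prep").write_text("ok")
    if config.run_prep:
        from isnkit.io import load_profile
        state["cm"] = load_profile(out / "prep" / "counts.tsv",
                                   out / "prep" / "metadata.csv",
                                   out / "prep" / "taxonomy.csv")

    if config.run_popnet:
        net, margins = population_network(
            state["cm"], covariates=config.covariates,
            min_common_taxa=config.min_common_taxa, seed=config.seed_popnet)
        state["net"] = net
        if not _done(out, "popnet").exists():
            write_network(net, out / "popnet", header=config.provenance("popnet"))
            _write_table(margins.params_table(), out / "popnet" / "zinb_margins.csv",
                         header_comment=config.provenance("popnet"))
            _done(out, "popnet").write_text("ok")

    if config.run_isn:
        isns = lioness_isns(state["cm"], state["net"])
        state["isns"] = isns
        if not _done(out, "isn").exists():
            _write_table(isns.weights, out / "isn" / "isn_weights.tsv", sep="\t",
                         header_comment=config.provenance("isn"))
            _done(out, "isn").write_text("ok")

    meta = state["cm"].metadata

    if config.run_diff and not _done(out, "diff").exists():
        stats = differential_edges(state["isns"], meta["outcome"],
                                   config.diff_threshold, config.p_max, config.q_max)
        _write_table(stats.table, out / "diff" / "edge_stats.csv",
                     header_comment=config.provenance("diff"))
        _done(out, "diff").write_text("ok")

    if config.run_predict and not _done(out, "predict").exists():
        ranking, rf_res = rf_rank_select(
            state["isns"], meta["outcome"], folds=config.rf_folds,
            repeats=config.rf_repeats, top_k=config.top_k,
            n_trees=config.rf_trees, seed=config.seed_predict)
        svm_res = svm_loo_predict(state["isns"], meta["outcome"],
                                  n_screen=config.svm_n_screen, seed=config.seed_predict)
        _write_table(pd.DataFrame({"rf": rf_res.scores, "svm": svm_res.scores}),
                     out / "predict" / "scores.csv",
                     header_comment=config.provenance("predict"))
        write_json({"rf": {"auc": rf_res.auc, "accuracy": rf_res.accuracy,
                           "top_features": ranking.top_k},
                    "svm": {"auc": svm_res.auc, "accuracy": svm_res.accuracy}},
                   out / "predict" / "metrics.json")
        _done(out, "predict").write_text("ok")

    if config.run_topo and not _done(out, "topo").exists():
        res = metrics_for_isns(state["isns"], state["net"].taxa)
        instances = {}
        for protocol in ("zero_fill", "drop_node"):
            try:
                feats = build_metric_features(res["tables"], protocol)
            except ValueError as exc:
                log.warning("protocol %s skipped: %s", protocol, exc)
                continue
            instances[protocol] = feats
            _write_table(feats, out / "topo" / f"features_{protocol}.csv",
                         header_comment=config.provenance("topo"))
        screen = topo_screen_classify(instances, meta["outcome"],
                                      folds=config.topo_folds, top_k=config.top_k,
                                      auc_min=config.auc_min, seed=config.seed_topo)
        _write_table(screen.set_index("instance"), out / "topo" / "screen.csv",
                     header_comment=config.provenance("topo"))
        _done(out, "topo").write_text("ok")

    if config.run_dynamics and not _done(out, "dynamics").exists():
        for group in sorted(meta["trajectory"].dropna().unique()):
            mx = aggregate_group_networks(state["isns"], meta, group, state["net"].taxa)
            dists = embed_and_distance(mx, dim=config.dynamics_dim,
                                       repeats=config.dynamics_repeats,
                                       seed=config.seed_dynamics)
            result = permutation_significance(mx, dists, n_perm=config.dynamics_n_perm,
                                              seed=config.seed_dynamics,
                                              dim=config.dynamics_dim)
            _write_table(result.table, out / "dynamics" / f"{group}_dynamics.csv",
                         header_comment=config.provenance("dynamics"))
        _done(out, "dynamics").write_text("ok")

    return out
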