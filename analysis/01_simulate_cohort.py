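#!/usr/bin/env python
"""Generate the synthetic study cohorts.

Two cohorts are written under results/data/:
* ``cross`` — a two-group (responder / non-responder) cross-sectional cohort
  of 30 taxa x 80 samples whose five planted edges differ in latent partial
  correlation by 0.4 between groups, on top of a shared co-occurrence
  backbone; this drives the population-network, ISN, differential-edge,
  prediction and topology analyses.
* ``paired`` — a paired w0/w24 cohort with three enterotype-trajectory
  groups (Bact2-Bact2, Bact2-Other, Other-Other); in Bact2-Other one taxon's
  latent edges are rewired between timepoints, the planted dynamic the
  multiplex analysis should find.
"""

from pathlib import Path

import numpy as np

from isnkit.simulate import (SimulationConfig, generate_cohort, paired_timepoints,
                             planted_precision, write_cohort)

OUT = Path("results/data")

BASE_EDGES = [(2 * k, 2 * k + 1) for k in range(10, 13)]  # shared backbone
PLANTED = [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)]


def cross_sectional():
    cfg = SimulationConfig(
        n_taxa=30, n_samples_per_group=60,
        groups=("non-responder", "responder"),
        # planted edges flip from partial correlation -0.25 (non-responders)
        # to +0.5 (responders): a strong ISN-level contrast
        planted_edges=[(i, j, 0.75) for i, j in PLANTED],
        depth_lognormal=(np.log(20_000), 0.4),
        covariate_effects={"age": 0.2, "gender": 0.15},
        seed=11,
    )
    cfg.precision_base = planted_precision(30, BASE_EDGES, 0.35)
    for i, j in PLANTED:
        cfg.precision_base[i, j] = cfg.precision_base[j, i] = 0.25
    # library sizes ~20k reads, so the standard 10,000-read rarefaction
    # retains most samples while excluding a shallow tail
    cfg.mu = cfg.mu * (20_000 / cfg.mu.sum())
    cfg.check()
    cm, gt = generate_cohort(cfg)
    write_cohort(cm, gt, OUT / "cross")
    return cm


def paired_trajectories():
    n = 100
    base = planted_precision(20, [(2 * k, 2 * k + 1) for k in range(6)], 0.35)
    # taxon 0 drops its (0,1) edge and re-partners with taxa 13 and 15
    rewired = planted_precision(
        20, [(0, 13), (0, 15)] + [(2 * k, 2 * k + 1) for k in range(1, 6)], 0.45)
    cfg = SimulationConfig(
        n_taxa=20, n_samples_per_group=n,
        groups=("Bact2-Bact2", "Bact2-Other", "Other-Other"),
        timepoints=("w0", "w24"),
        depth_lognormal=(np.log(20_000), 0.4),
        seed=12,
    )
    cfg.mu = cfg.mu * (20_000 / cfg.mu.sum())
    cfg.check()
    prec = {(g, tp): base for g in cfg.groups for tp in cfg.timepoints}
    prec[("Bact2-Other", "w24")] = rewired  # taxon 0 re-partnered after therapy
    cm, gt = paired_timepoints(cfg, prec)
    write_cohort(cm, gt, OUT / "paired")
    return cm


def main():
    cm1 = cross_sectional()
    cm2 = paired_trajectories()
    print(f"cross-sectional cohort: {cm1.counts.shape[0]} samples x "
          f"{cm1.counts.shape[1]} taxa -> {OUT / 'cross'}")
    print(f"paired cohort: {cm2.counts.shape[0]} samples x "
          f"{cm2.counts.shape[1]} taxa, trajectories "
          f"{sorted(cm2.metadata['trajectory'].unique())} -> {OUT / 'paired'}")


if __name__ == "__main__":
    main()
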