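"""Profile preparation: filtering, RMP rarefaction, QMP, descriptive statistics.

RMP (relative microbiome profiling) rarefies every sample to a fixed read
target by uniform subsampling without replacement. QMP (quantitative
microbiome profiling) corrects counts for 16S rRNA gene copy number, rarefies
every sample to the cohort's minimum observed sampling depth (copy-number
corrected depth divided by flow-cytometry microbial load), and rescales the
result to cells per gram of faecal material.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from isnkit.containers import CountMatrix


def filter_profiles(
    cm: CountMatrix,
    prevalence_min: float = 0.25,
    depth_min: int = 500,
) -> CountMatrix:
    """Drop low-depth samples, then low-prevalence taxa.

    Samples with total reads < ``depth_min`` are removed first; prevalence
    (fraction of retained samples where the taxon is non-zero) is then
    computed on the surviving samples, and taxa below ``prevalence_min``
    are removed.
    """
    depths = cm.depths
    keep_samples = depths[depths >= depth_min].index
    if len(keep_samples) == 0:
        raise ValueError(
            f"all {len(cm.samples)} samples fall below the {depth_min}-read depth filter"
        )
    sub = cm.subset_samples(keep_samples)
    prevalence = (sub.counts > 0).mean(axis=0)
    keep_taxa = prevalence[prevalence >= prevalence_min].index
    if len(keep_taxa) == 0:
        raise ValueError(
            f"all {len(cm.taxa)} taxa fall below the {prevalence_min:.0%} prevalence filter "
            f"({len(cm.samples) - len(keep_samples)} samples were removed by the depth filter)"
        )
    return sub.subset_taxa(keep_taxa)


def _rarefy_rows(counts: np.ndarray, targets: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multivariate-hypergeometric subsample of each row to its target total."""
    out = np.zeros_like(counts, dtype=np.int64)
    for r in range(counts.shape[0]):
        out[r] = rng.multivariate_hypergeometric(counts[r].astype(np.int64), int(targets[r]))
    return out


def rarefy_rmp(cm: CountMatrix, target: int = 10_000, seed: int = 0) -> CountMatrix:
    """Rarefy each sample to exactly ``target`` reads; drop shallower samples."""
    if target <= 0:
        raise ValueError("rarefaction target must be positive")
    depths = cm.depths
    keep = depths[depths >= target].index
    if len(keep) == 0:
        raise ValueError(f"no sample reaches the rarefaction target of {target} reads")
    sub = cm.subset_samples(keep)
    rng = np.random.default_rng(seed)
    vals = _rarefy_rows(sub.counts.values, np.full(len(keep), target), rng)
    counts = pd.DataFrame(vals, index=sub.counts.index, columns=sub.counts.columns)
    return CountMatrix(counts, sub.taxonomy, sub.metadata)


def qmp_transform(cm: CountMatrix, min_rarefied: int = 150, seed: int = 0) -> CountMatrix:
    """Quantitative profiling: copy-number correction, even sampling depth, cells/g.

    Sampling depth of a sample = (sum of counts/copy_number) / microbial load.
    Every sample is rarefied (on floored copy-number-corrected counts) to the
    read total implied by the cohort-minimum sampling depth; samples whose
    rarefied total falls below ``min_rarefied`` are excluded; retained counts
    are rescaled to cells per gram via the sample's load.
    """
    if "microbial_load" not in cm.metadata.columns or cm.metadata["microbial_load"].isna().any():
        missing = (
            list(cm.samples) if "microbial_load" not in cm.metadata.columns
            else list(cm.metadata.index[cm.metadata["microbial_load"].isna()])
        )
        raise ValueError(f"microbial_load missing for samples: {missing[:5]}")
    if "copy_number" not in cm.taxonomy.columns or cm.taxonomy["copy_number"].isna().any():
        missing = (
            list(cm.taxa) if "copy_number" not in cm.taxonomy.columns
            else list(cm.taxonomy.index[cm.taxonomy["copy_number"].isna()])
        )
        raise ValueError(f"copy_number missing for taxa: {missing[:5]}")

    cn = cm.taxonomy.loc[cm.taxa, "copy_number"].values.astype(float)
    corrected = np.floor(cm.counts.values / cn).astype(np.int64)
    corrected_depth = corrected.sum(axis=1).astype(float)
    load = cm.metadata.loc[cm.samples, "microbial_load"].values.astype(float)
    sampling_depth = corrected_depth / load
    min_depth = sampling_depth.min()
    targets = np.floor(min_depth * load).astype(np.int64)
    targets = np.minimum(targets, corrected.sum(axis=1))

    keep = targets >= min_rarefied
    if not keep.any():
        raise ValueError(
            f"every sample's rarefied QMP total falls below {min_rarefied}"
        )
    rng = np.random.default_rng(seed)
    rarefied = _rarefy_rows(corrected[keep], targets[keep], rng)
    # cells per gram: rarefied fraction of the sample times its microbial load
    cells = rarefied * (load[keep] / targets[keep])[:, None]
    samples = cm.samples[keep]
    counts = pd.DataFrame(cells, index=samples, columns=cm.taxa)
    return CountMatrix(counts, cm.taxonomy, cm.metadata.loc[samples], is_integer=False)


@dataclass
class AbundanceSummary:
    """Fractional family abundance per group with >10% dominance flags."""

    fractions: pd.DataFrame  # rows (group keys) x families, each row sums to 1
    dominant: pd.DataFrame   # same shape, boolean
    group_keys: list

    def dominant_families(self) -> list:
        return sorted(self.dominant.columns[self.dominant.any(axis=0)])


def family_abundance_summary(
    cm: CountMatrix,
    group_cols: tuple = ("cohort", "timepoint"),
    dominance_threshold: float = 0.10,
) -> AbundanceSummary:
    """Family read fractions per group (cohort x timepoint by default)."""
    fam = cm.taxonomy.loc[cm.taxa, "family"]
    fam_counts = cm.counts.T.groupby(fam.values).sum().T  # samples x families
    keys = cm.metadata.loc[cm.samples, list(group_cols)]
    grouped = fam_counts.groupby([keys[c] for c in group_cols]).sum()
    if (grouped.sum(axis=1) == 0).any():
        empty = grouped.index[grouped.sum(axis=1) == 0]
        raise ValueError(f"groups with zero total reads: {list(empty)}")
    fractions = grouped.div(grouped.sum(axis=1), axis=0)
    return AbundanceSummary(
        fractions=fractions,
        dominant=fractions > dominance_threshold,
        group_keys=list(group_cols),
    )


def paired_family_test(
    cm: CountMatrix,
    timepoint_a: str,
    timepoint_b: str,
    dominant_only: bool = True,
    dominance_threshold: float = 0.10,
) -> pd.DataFrame:
    """Paired t-tests on per-individual family fractions between two timepoints.

    Bonferroni multiplies each p by the number of families tested (capped at
    1); with ``dominant_only`` both the family set and that multiplier are
    restricted to families dominant (>10% fraction) in either timepoint.
    """
    meta = cm.metadata
    if "individual_id" not in meta.columns:
        raise ValueError("paired_family_test requires individual_id metadata")
    fam = cm.taxonomy.loc[cm.taxa, "family"]
    fam_counts = cm.counts.T.groupby(fam.values).sum().T
    fractions = fam_counts.div(fam_counts.sum(axis=1), axis=0)

    sub = {}
    for tp in (timepoint_a, timepoint_b):
        sel = meta["timepoint"] == tp
        sub[tp] = fractions[sel.values].set_index(meta.loc[sel.values, "individual_id"])
    common = sub[timepoint_a].index.intersection(sub[timepoint_b].index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} matched individuals; need >= 3 pairs")
    a = sub[timepoint_a].loc[common]
    b = sub[timepoint_b].loc[common]

    families = list(fractions.columns)
    if dominant_only:
        # dominant in either timepoint's group mean
        grp_frac = pd.DataFrame({"a": a.mean(axis=0), "b": b.mean(axis=0)})
        dominant = grp_frac.max(axis=1) > dominance_threshold
        families = [f for f in families if dominant[f]]
    m = len(families)
    rows = []
    for f in families:
        diff = b[f].values - a[f].values
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(b[f].values, a[f].values)
        rows.append({"family": f, "t": float(t), "p": float(p),
                     "p_bonferroni": float(min(p * m, 1.0)), "n_pairs": len(common)})
    return pd.DataFrame(rows).set_index("family")


def shannon_index(row: np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i on a single sample's counts."""
    total = row.sum()
    if total <= 0:
        raise ValueError("sample with zero total reads")
    p = row[row > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity_test(
    cm: CountMatrix,
    outcome_col: str = "outcome",
) -> tuple[pd.Series, dict]:
    """Per-sample Shannon diversity + Mann-Whitney test between outcome groups.

    The index (Shannon, natural log) and the test (two-sided rank-sum) are
    recorded in the returned summary for transparency; the choice is a
    documented default, not forced by the data.
    """
    vals = cm.counts.values
    if (vals.sum(axis=1) <= 0).any():
        empty = cm.samples[vals.sum(axis=1) <= 0]
        raise ValueError(f"samples with zero total reads: {list(empty)[:5]}")
    div = pd.Series([shannon_index(v) for v in vals], index=cm.samples, name="shannon")
    outcome = cm.metadata.loc[cm.samples, outcome_col]
    groups = [g for g in outcome.dropna().unique() if g != "missing"]
    if len(groups) != 2:
        raise ValueError(f"need exactly two outcome groups, found {list(groups)}")
    x = div[ (outcome == groups[0]).values ]
    y = div[ (outcome == groups[1]).values ]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("an outcome group is empty")
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    summary = {
        "index": "shannon (natural log)",
        "test": "mann-whitney two-sided",
        "groups": {groups[0]: len(x), groups[1]: len(y)},
        "statistic": float(stat),
        "p": float(p),
    }
    return div, summary
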