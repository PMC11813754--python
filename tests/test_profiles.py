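"""Filtering, rarefaction, QMP, and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest

from isnkit.containers import CountMatrix
from isnkit.profiles import (alpha_diversity_test, family_abundance_summary,
                             filter_profiles, paired_family_test, qmp_transform,
                             rarefy_rmp, shannon_index)


def _cm(counts, families=None, loads=None, extra_meta=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"s{i}" for i in range(counts.shape[0])]
    counts.columns = [f"t{j}" for j in range(counts.shape[1])]
    taxonomy = pd.DataFrame({
        "family": families or [f"F{j}" for j in range(counts.shape[1])],
        "genus": [f"g{j}" for j in range(counts.shape[1])],
        "copy_number": 1.0,
    }, index=counts.columns)
    meta = pd.DataFrame(index=counts.index)
    meta["cohort"] = "CD"
    meta["timepoint"] = "w0"
    meta["outcome"] = ["remission", "no-remission"] * (len(counts) // 2) + \
        ["remission"] * (len(counts) % 2)
    if loads is not None:
        meta["microbial_load"] = loads
    if extra_meta:
        for k, v in extra_meta.items():
            meta[k] = v
    return CountMatrix(counts, taxonomy, meta)


class TestFilterProfiles:
    def test_boundary_rules_and_toy_enumeration(self):
        # 10 taxa x 8 samples; 2 taxa at 12.5% prevalence; 1 sample at 300 reads
        rng = np.random.default_rng(0)
        counts = rng.integers(100, 200, size=(8, 10))
        counts[:, 8] = 0
        counts[0, 8] = 5          # prevalence 1/8 = 12.5% -> dropped
        counts[:, 9] = 0
        counts[1, 9] = 7          # 12.5% -> dropped
        counts[2, :] = 0
        counts[2, 0] = 300        # depth 300 < 500 -> dropped
        cm = _cm(counts)
        out = filter_profiles(cm)
        assert out.counts.shape == (7, 8)

    def test_depth_boundary_is_strictly_less_than(self):
        counts = np.full((5, 3), 200)
        counts[0] = [499, 0, 0]
        counts[1] = [500, 0, 0]
        cm = _cm(counts)
        out = filter_profiles(cm, prevalence_min=0.0)
        assert "s0" not in out.samples and "s1" in out.samples

    def test_prevalence_20pct_taxon_removed(self):
        counts = np.full((5, 2), 600)
        counts[:, 1] = 0
        counts[0, 1] = 10  # 1/5 = 20% < 25%
        out = filter_profiles(_cm(counts))
        assert list(out.taxa) == ["t0"]

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 400, size=(12, 9))
        once = filter_profiles(_cm(counts))
        twice = filter_profiles(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_all_removed_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            filter_profiles(_cm(np.ones((3, 3), dtype=int)))


class TestRarefyRmp:
    def test_retained_samples_sum_exactly_to_target(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 4000, size=(6, 8))
        counts[0] *= 10
        cm = _cm(counts)
        out = rarefy_rmp(cm, target=5000, seed=3)
        assert (out.counts.sum(axis=1) == 5000).all()
        # shallower samples are excluded, not padded
        assert set(out.samples) == set(cm.samples[cm.depths >= 5000])

    def test_below_target_sample_excluded(self):
        counts = np.array([[9_999, 0], [6_000, 6_000]])
        out = rarefy_rmp(_cm(counts), target=10_000, seed=0)
        assert list(out.samples) == ["s1"]

    def test_single_taxon_sample_is_deterministic(self):
        counts = np.array([[15_000, 0], [12_000, 0]])
        out = rarefy_rmp(_cm(counts), target=10_000, seed=1)
        assert (out.counts["t0"] == 10_000).all()

    def test_subsample_never_exceeds_original(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 2000, size=(4, 6)) + 200
        cm = _cm(counts)
        out = rarefy_rmp(cm, target=1000, seed=5)
        assert (out.counts.values <= cm.counts.loc[out.samples].values).all()

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            rarefy_rmp(_cm(np.ones((3, 2), dtype=int)), target=0)


class TestQmp:
    def test_copy_number_division_and_depth_arithmetic(self):
        # loads (1e11, 2e11), equal corrected depths -> sample 0 has twice the
        # sampling depth; both rarefied to the minimum (sample 1's) depth.
        counts = np.array([[500, 500], [500, 500]])
        cm = _cm(counts, loads=[1e11, 2e11])
        out = qmp_transform(cm, min_rarefied=100, seed=0)
        # sample 0 target = 5e-9 * 1e11 = 500... corrected depth is 1000 each
        # sampling depths: 1000/1e11 = 1e-8 vs 1000/2e11 = 5e-9; min 5e-9
        # targets: 5e-9*1e11 = 500 (half of s0's reads), 5e-9*2e11 = 1000
        rarefied_totals = (out.counts / (out.metadata["microbial_load"] /
                                         [500, 1000]).values[:, None]).sum(axis=1)
        assert rarefied_totals.loc["s0"] == pytest.approx(500)
        assert rarefied_totals.loc["s1"] == pytest.approx(1000)

    def test_load_scale_equivariance(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(50, 500, size=(4, 5))
        loads = [1e11, 2e11, 1.5e11, 3e11]
        a = qmp_transform(_cm(counts, loads=loads), min_rarefied=10, seed=7)
        b = qmp_transform(_cm(counts, loads=[3 * x for x in loads]), min_rarefied=10, seed=7)
        np.testing.assert_allclose(b.counts.values, 3 * a.counts.values)

    def test_missing_load_rejected(self):
        cm = _cm(np.ones((3, 2), dtype=int) * 100)
        with pytest.raises(ValueError, match="microbial_load"):
            qmp_transform(cm)


class TestAbundanceStats:
    def test_family_fractions_sum_to_one_and_dominance(self):
        counts = np.array([[60, 0, 40], [60, 0, 40]])
        cm = _cm(counts, families=["FA", "FA", "FB"])
        summ = family_abundance_summary(cm)
        row = summ.fractions.iloc[0]
        assert row.sum() == pytest.approx(1.0, abs=1e-9)
        assert row["FA"] == pytest.approx(0.6)
        assert summ.dominant.iloc[0].all()

    def test_single_family_dominant(self):
        cm = _cm(np.array([[5, 5]]), families=["FA", "FA"])
        summ = family_abundance_summary(cm)
        assert summ.fractions.iloc[0]["FA"] == pytest.approx(1.0)

    def test_paired_t_closed_form(self):
        """10 pairs with mean paired difference 0.05, sd 0.05 -> t = sqrt(10)."""
        rng = np.random.default_rng(8)
        n = 10
        d = rng.normal(0, 1, n)
        d = (d - d.mean()) / d.std(ddof=1) * 0.05 + 0.05  # exact mean/sd
        base = rng.uniform(0.3, 0.5, n)
        fa_w0, fa_w24 = base, base + d
        counts = np.zeros((2 * n, 2))
        total = 10_000
        counts[:n, 0] = np.round(fa_w0 * total)
        counts[n:, 0] = np.round(fa_w24 * total)
        counts[:, 1] = total - counts[:, 0]
        cm = _cm(counts.astype(int), families=["FA", "FB"],
                 extra_meta={"individual_id": [f"i{k}" for k in range(n)] * 2,
                             "timepoint": ["w0"] * n + ["w24"] * n})
        out = paired_family_test(cm, "w0", "w24", dominant_only=True)
        assert out.loc["FA", "t"] == pytest.approx(np.sqrt(10) * 0.05 / 0.05, rel=0.02)

    def test_paired_t_identical_fractions(self):
        n = 5
        counts = np.tile([300, 700], (2 * n, 1))
        cm = _cm(counts, families=["FA", "FB"],
                 extra_meta={"individual_id": [f"i{k}" for k in range(n)] * 2,
                             "timepoint": ["w0"] * n + ["w24"] * n})
        out = paired_family_test(cm, "w0", "w24")
        assert (out["t"] == 0).all() and (out["p"] == 1).all()

    def test_bonferroni_multiplies_and_caps(self):
        n = 6
        rng = np.random.default_rng(11)
        counts = rng.integers(100, 1000, size=(2 * n, 3))
        cm = _cm(counts, families=["FA", "FB", "FC"],
                 extra_meta={"individual_id": [f"i{k}" for k in range(n)] * 2,
                             "timepoint": ["w0"] * n + ["w24"] * n})
        out = paired_family_test(cm, "w0", "w24", dominant_only=False)
        m = len(out)
        expected = np.minimum(out["p"] * m, 1.0)
        np.testing.assert_allclose(out["p_bonferroni"], expected)

    def test_too_few_pairs_rejected(self):
        counts = np.array([[10, 10]] * 4)
        cm = _cm(counts, extra_meta={"individual_id": ["i1", "i2", "i1", "i2"],
                                     "timepoint": ["w0", "w0", "w24", "w24"]})
        with pytest.raises(ValueError, match="pairs"):
            paired_family_test(cm, "w0", "w24")


class TestAlphaDiversity:
    def test_shannon_closed_forms(self):
        assert shannon_index(np.array([25, 25, 25, 25])) == pytest.approx(np.log(4))
        assert shannon_index(np.array([100, 0, 0])) == 0.0

    def test_group_test_reports_its_choices(self):
        rng = np.random.default_rng(12)
        cm = _cm(rng.integers(1, 500, size=(10, 6)))
        div, summary = alpha_diversity_test(cm)
        assert len(div) == 10
        assert "shannon" in summary["index"] and "mann-whitney" in summary["test"]

    def test_null_rarely_significant(self):
        """Identical group compositions: p < 0.05 in at most a few null runs."""
        sig = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            cm = _cm(rng.integers(1, 500, size=(20, 8)))
            _, summary = alpha_diversity_test(cm)
            sig += summary["p"] < 0.05
        assert sig <= 4  # ~95% of null simulations stay non-significant

    def test_zero_total_sample_rejected(self):
        counts = np.array([[0, 0], [5, 5]])
        with pytest.raises(ValueError, match="zero total"):
            alpha_diversity_test(_cm(counts))
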