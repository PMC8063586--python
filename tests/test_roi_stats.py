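"""ROI summaries, group ANOVA, and ratio computations."""

import numpy as np
import pandas as pd
import pytest

from tdmri.datasets import ROILabelMap
from tdmri.roi_stats import (DesignError, anova_twoway, group_compare,
                             roi_summaries, thickness_ratio, volume_reduction)


@pytest.fixture
def simple_map():
    labels = np.zeros((10, 10, 10), dtype=int)
    labels[:5] = 1
    labels[5:] = 2
    return ROILabelMap(labels=labels, names={1: "A", 2: "B"},
                       voxel_size=(0.1, 0.1, 0.1))


class TestROISummaries:
    def test_uniform_roi(self, simple_map):
        vol = np.where(simple_map.labels == 1, 3.5, 1.0)
        df = roi_summaries(simple_map, {"adc": vol})
        row = df[df["roi"] == "A"].iloc[0]
        assert row["mean"] == 3.5
        assert row["sd"] == 0.0
        assert row["n_voxels"] == 500

    def test_volume_bookkeeping(self, simple_map):
        df = roi_summaries(simple_map, {"x": np.ones((10, 10, 10))})
        assert df["volume_mm3"].sum() == pytest.approx(1.0, rel=1e-12)
        # 500 voxels at (0.1 mm)^3 → 0.5 mm³
        assert df.iloc[0]["volume_mm3"] == pytest.approx(0.5)

    def test_empty_roi_flagged(self):
        labels = np.ones((4, 4, 4), dtype=int)
        m = ROILabelMap(labels=labels, names={1: "A", 2: "missing"},
                        voxel_size=(0.1, 0.1, 0.1))
        df = roi_summaries(m, {"x": np.ones((4, 4, 4))})
        row = df[df["roi"] == "missing"].iloc[0]
        assert row["empty"] and row["n_voxels"] == 0 and np.isnan(row["mean"])


class TestVolumeReduction:
    @pytest.mark.parametrize("eu,ts,pct", [(24.95, 16.48, 34),
                                           (408.09, 355.52, 13)])
    def test_reported_reductions(self, eu, ts, pct):
        assert round(volume_reduction(eu, ts)) == pct

    def test_identity(self):
        assert volume_reduction(5.0, 5.0) == 0.0

    def test_complement_identity(self):
        a, b = 7.3, 4.1
        assert volume_reduction(a, b) + 100 * b / a == pytest.approx(100.0,
                                                                     rel=1e-12)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            volume_reduction(0.0, 1.0)


def _toy_table(offset=0.0, noise=0.0, n=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, base in (("Eu", 0.0), ("Ts", offset)):
        for s in range(n):
            for f in (0, 50, 100, 200):
                rows.append({"subject": f"{g}{s}", "group": g,
                             "frequency": f,
                             "value": 1.0 + base + f * 1e-3
                             + noise * rng.standard_normal()})
    return pd.DataFrame(rows)


class TestGroupCompare:
    def test_identical_groups_null(self):
        # same subject values replicated into both groups: within-group
        # variance is nonzero but the group effect is exactly absent
        eu = _toy_table(offset=0.0, noise=0.05, seed=1)
        eu = eu[eu["group"] == "Eu"]
        ts = eu.copy()
        ts["group"] = "Ts"
        ts["subject"] = ts["subject"].str.replace("Eu", "Ts")
        res = group_compare(pd.concat([eu, ts]), value="value")
        assert res["anova"].loc["group", "F"] == pytest.approx(0.0, abs=1e-9)
        assert not res["posthoc"]["significant"].any()

    def test_large_offset_detected(self):
        res = group_compare(_toy_table(offset=0.5, noise=0.01), value="value")
        assert res["anova"].loc["group", "PR(>F)"] < 1e-6
        assert res["posthoc"]["significant"].all()

    def test_balanced_2x2_matches_closed_form(self):
        # textbook two-way ANOVA with 2 replicates per cell, computed by
        # hand from sums of squares
        rows = []
        data = {("Eu", 0): [1.0, 1.2], ("Eu", 50): [2.0, 2.2],
                ("Ts", 0): [0.8, 1.0], ("Ts", 50): [2.4, 2.6]}
        for (g, f), vals in data.items():
            for i, v in enumerate(vals):
                rows.append({"group": g, "frequency": f, "value": v,
                             "subject": f"{g}{i}"})
        df = pd.DataFrame(rows)
        aov = anova_twoway(df, "value", "group", "frequency")
        y = np.array([v for vals in data.values() for v in vals])
        gm = y.mean()
        mean_g = {g: np.mean(data[(g, 0)] + data[(g, 50)]) for g in ("Eu", "Ts")}
        mean_f = {f: np.mean(data[("Eu", f)] + data[("Ts", f)]) for f in (0, 50)}
        ss_g = 4 * sum((m - gm) ** 2 for m in mean_g.values())
        ss_f = 4 * sum((m - gm) ** 2 for m in mean_f.values())
        cell_means = {k: np.mean(v) for k, v in data.items()}
        ss_int = 2 * sum((cell_means[(g, f)] - mean_g[g] - mean_f[f] + gm) ** 2
                         for g in ("Eu", "Ts") for f in (0, 50))
        ss_err = sum((v - cell_means[k]) ** 2
                     for k, vals in data.items() for v in vals)
        ms_err = ss_err / 4
        assert aov.loc["group", "F"] == pytest.approx(ss_g / ms_err, rel=1e-9)
        assert aov.loc["frequency", "F"] == pytest.approx(ss_f / ms_err,
                                                          rel=1e-9)
        assert aov.loc["group:frequency", "F"] == pytest.approx(
            ss_int / ms_err, rel=1e-9)

    def test_power_on_synthetic_offset(self):
        # known offset ≫ noise detected in nearly all seeds
        hits = 0
        for seed in range(100):
            res = group_compare(_toy_table(offset=0.2, noise=0.05, seed=seed),
                                value="value")
            hits += bool(res["anova"].loc["group", "PR(>F)"] < 0.05)
        assert hits > 95

    def test_single_group_rejected(self):
        df = _toy_table()
        with pytest.raises(DesignError):
            group_compare(df[df["group"] == "Eu"], value="value")

    def test_holm_correction_monotone(self):
        res = group_compare(_toy_table(offset=0.1, noise=0.05), value="value",
                            holm=True)
        assert (res["posthoc"]["p_holm"] >= res["posthoc"]["p"] - 1e-15).all()


class TestThicknessRatio:
    def test_identical_lists(self):
        mean, sem = thickness_ratio([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert mean == 100.0 and sem == 0.0

    def test_uniform_scaling(self):
        eu = np.array([1.0, 2.0, 3.0])
        mean, sem = thickness_ratio(0.8 * eu, eu)
        assert mean == pytest.approx(80.0, rel=1e-12)
        assert sem == pytest.approx(0.0, abs=1e-9)

    def test_jittered_multiplier_recovered(self):
        # phantom-like scenario: thickness multiplier 0.85 with 5% jitter,
        # n = 5 pairs; mean ratio lands in [80, 90] in ≥95 % of seeds
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            eu = rng.uniform(0.8, 1.2, 5)
            ts = 0.85 * eu * (1 + 0.05 * rng.standard_normal(5))
            mean, _ = thickness_ratio(ts, eu)
            hits += bool(80.0 <= mean <= 90.0)
        assert hits >= 95

    def test_zero_denominator_excluded(self):
        mean, _ = thickness_ratio([0.8, 0.9], [1.0, 0.0])
        assert mean == pytest.approx(80.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            thickness_ratio([], [])
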