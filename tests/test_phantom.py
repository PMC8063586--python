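"""Layered phantom generator: ground-truth recovery and group structure."""

import numpy as np
import pytest

from tdmri.adc_dti import fit_adc
from tdmri.phantom import (GroupModifiers, LayerSpec, eu_layers,
                           generate_group, generate_phantom, ts_modifiers)
from tdmri.td_models import delta_adc_map

FREQS = (0.0, 50.0, 100.0, 200.0)


def _adc_maps(dwi):
    maps = {}
    for cond in dwi.conditions:
        m = fit_adc(dwi, cond)
        maps[m.frequency] = m.adc
    return maps


class TestGeneratePhantom:
    def test_noiseless_single_layer_round_trip(self):
        table = {f: 0.3 + 1e-3 * f for f in FREQS}
        layers = [LayerSpec(1, "uniform", table)]
        r = generate_phantom(layers, shape=(12, 12, 2), snr=None, seed=0)
        slope, intercept = delta_adc_map(_adc_maps(r.dwi), mask=r.dwi.mask)
        sel = r.roi_map.labels == 1
        np.testing.assert_allclose(slope[sel], 1e-3, atol=1e-12)
        np.testing.assert_allclose(intercept[sel], 0.3, atol=1e-9)

    def test_noiseless_default_layers_recover_ground_truth(self):
        r = generate_phantom(shape=(24, 24, 2), snr=None, seed=0)
        slope, _ = delta_adc_map(_adc_maps(r.dwi), mask=r.dwi.mask)
        for name, gt in r.ground_truth["layers"].items():
            sel = r.roi_map.labels == gt["label"]
            np.testing.assert_allclose(slope[sel], gt["delta_adc"],
                                       atol=1e-10, err_msg=name)

    def test_rician_bias_bounded_by_analytic_oracle(self):
        # two-point log estimator bias under Rician noise, vs a direct
        # numeric evaluation of E[ln(S0_hat/S_hat)] at the same SNR and
        # the layer's true PG ADC
        r = generate_phantom(shape=(40, 40, 4), snr=20.0, seed=1)
        gt = r.ground_truth["layers"]["IGL_PCL"]
        adc_true = gt["adc_table"]["0.0"]

        rng = np.random.default_rng(42)
        snr, b = 20.0, 1.0
        sigma = 1.0 / snr
        n = 200_000
        s0 = np.hypot(1 + rng.normal(0, sigma, (n, 2)),
                      rng.normal(0, sigma, (n, 2))).mean(axis=1)
        strue = np.exp(-b * adc_true)
        s = np.hypot(strue + rng.normal(0, sigma, n),
                     rng.normal(0, sigma, n))
        oracle_bias = np.mean(np.log(s0 / s) / b) - adc_true

        m = fit_adc(r.dwi, "PG")
        sel = r.roi_map.labels == gt["label"]
        bias = np.nanmean(m.adc[sel]) - adc_true
        assert abs(bias - oracle_bias) < 0.02

    def test_group_direction_ts_lower_dispersion(self):
        eu = generate_phantom(eu_layers(), shape=(24, 24, 2), snr=None, seed=0)
        ts_layers = ts_modifiers().apply(eu_layers())
        ts = generate_phantom(ts_layers, shape=(24, 24, 2), snr=None, seed=0)
        s_eu, _ = delta_adc_map(_adc_maps(eu.dwi), mask=eu.dwi.mask)
        s_ts, _ = delta_adc_map(_adc_maps(ts.dwi), mask=ts.dwi.mask)
        sel_eu = eu.roi_map.labels == 2
        sel_ts = ts.roi_map.labels == 2
        assert np.nanmean(s_ts[sel_ts]) < np.nanmean(s_eu[sel_eu])

    def test_unknown_label_config_rejected(self):
        layers = [LayerSpec(1, "a", {f: 0.3 for f in FREQS}),
                  LayerSpec(1, "b", {f: 0.4 for f in FREQS})]
        with pytest.raises(ValueError):
            generate_phantom(layers, snr=None)

    def test_deterministic_per_seed(self):
        a = generate_phantom(shape=(10, 10, 2), snr=20, seed=5)
        b = generate_phantom(shape=(10, 10, 2), snr=20, seed=5)
        np.testing.assert_array_equal(a.dwi.data, b.dwi.data)

    def test_label_volumes_partition_mask(self):
        r = generate_phantom(shape=(24, 24, 2), snr=None, seed=0)
        total = sum(r.roi_map.volume_of(l) for l in r.roi_map.names)
        mask_vol = np.count_nonzero(r.dwi.mask) * r.roi_map.voxel_volume
        assert total == pytest.approx(mask_vol, rel=1e-12)


class TestSNRRecovery:
    def test_snr20_median_error_within_5_percent(self):
        # voxelwise ΔADC recovery in the strongly dispersing layer over
        # 20 noisy phantoms
        errs = []
        for seed in range(20):
            r = generate_phantom(shape=(24, 24, 2), snr=20.0, seed=seed)
            slope, _ = delta_adc_map(_adc_maps(r.dwi), mask=r.dwi.mask)
            gt = r.ground_truth["layers"]["IGL_PCL"]
            sel = r.roi_map.labels == gt["label"]
            est = np.nanmean(slope[sel])
            errs.append(abs(est - gt["delta_adc"]) / gt["delta_adc"])
        assert np.median(errs) < 0.05


class TestGenerateGroup:
    def test_manifest_and_determinism(self):
        reals, manifest = generate_group(3, subject_cv=0.05, snr=20,
                                         shape=(12, 12, 2), seed=3)
        assert len(reals) == 6
        assert len(manifest) == 6
        assert set(manifest["group"]) == {"Eu", "Ts"}
        reals2, manifest2 = generate_group(3, subject_cv=0.05, snr=20,
                                           shape=(12, 12, 2), seed=3)
        np.testing.assert_array_equal(reals[0].dwi.data, reals2[0].dwi.data)

    def test_zero_variation_identical_within_group(self):
        reals, _ = generate_group(2, subject_cv=0.0, snr=None,
                                  shape=(12, 12, 2), seed=0)
        eu = [r for r in reals if r.ground_truth["group"] == "Eu"]
        np.testing.assert_array_equal(eu[0].dwi.data, eu[1].dwi.data)

    def test_modifier_validation(self):
        with pytest.raises(ValueError):
            GroupModifiers(dispersion_scale={"IGL_PCL": 1.5}).apply(eu_layers())
        with pytest.raises(ValueError):
            GroupModifiers(thickness_scale={"IGL_PCL": 0.0}).apply(eu_layers())

    def test_thickness_modifier_thins_layer(self):
        eu = generate_phantom(eu_layers(), shape=(48, 48, 2), snr=None, seed=0)
        ts_layers = GroupModifiers(
            thickness_scale={"IGL_PCL": 0.5}).apply(eu_layers())
        ts = generate_phantom(ts_layers, shape=(48, 48, 2), snr=None, seed=0)
        assert ts.roi_map.volume_of(2) < eu.roi_map.volume_of(2)
        # untouched core unchanged
        assert ts.roi_map.volume_of(1) == eu.roi_map.volume_of(1)
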