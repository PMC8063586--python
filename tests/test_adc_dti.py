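"""ADC mapping and tensor fitting against forward-model oracles."""

import numpy as np
import pytest

from tdmri.adc_dti import (ProtocolError, dec_map, fit_adc, fit_dti,
                           fractional_anisotropy)
from tdmri.datasets import DWIDataset, gradient_table_rows
from tdmri.directions import DIRECTIONS_10, DIRECTIONS_30


def _dataset_from_signals(data, directions=DIRECTIONS_10, b=1.0, n_b0=2,
                          conditions=None):
    conditions = conditions or [{"kind": "PG", "delta": 5.0, "Delta": 20.0}]
    gtab = gradient_table_rows(n_b0=n_b0, directions=directions, b=b,
                               conditions=conditions)
    return DWIDataset(data=data, gtab=gtab, voxel_size=(0.1, 0.1, 0.1))


def _tensor_signals(D, directions, b, shape=(2, 2, 1), n_b0=2):
    n_vol = n_b0 + len(directions)
    data = np.ones(shape + (n_vol,))
    for i, g in enumerate(directions):
        adc = g @ D @ g
        data[..., n_b0 + i] = np.exp(-b * adc)
    return data


class TestFitADC:
    def test_closed_form_single_voxel(self):
        data = np.ones((1, 1, 1, 12))
        data[..., 2:] = np.exp(-0.5)
        ds = _dataset_from_signals(data)
        m = fit_adc(ds, "PG")
        assert m.adc[0, 0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_isotropic_phantom_recovers_diffusivity(self):
        data = np.ones((3, 3, 2, 12))
        data[..., 2:] = np.exp(-1.0 * 2.0)
        ds = _dataset_from_signals(data)
        m = fit_adc(ds, "PG")
        np.testing.assert_allclose(m.adc, 2.0, atol=1e-12)
        assert m.n_invalid == 0

    def test_anisotropic_voxel_matches_scheme_average(self):
        # the mean over directions equals the scheme average of gᵀDg
        D = np.diag([1.7, 0.3, 0.3])
        data = _tensor_signals(D, DIRECTIONS_10, b=1.0)
        ds = _dataset_from_signals(data)
        m = fit_adc(ds, "PG")
        expected = np.mean([g @ D @ g for g in DIRECTIONS_10])
        np.testing.assert_allclose(m.adc, expected, atol=1e-12)

    def test_nonpositive_signal_masked_and_counted(self):
        data = np.ones((2, 1, 1, 12))
        data[..., 2:] = np.exp(-0.5)
        data[1, 0, 0, 5] = 0.0
        ds = _dataset_from_signals(data)
        m = fit_adc(ds, "PG")
        assert np.isnan(m.adc[1, 0, 0]) and not np.isnan(m.adc[0, 0, 0])
        assert m.n_invalid == 1

    def test_geometric_mean_option_equals_arithmetic_noiseless(self):
        D = np.diag([1.7, 0.3, 0.3])
        data = _tensor_signals(D, DIRECTIONS_10, b=1.0)
        ds = _dataset_from_signals(data)
        a = fit_adc(ds, "PG", average="arithmetic")
        g = fit_adc(ds, "PG", average="geometric")
        np.testing.assert_allclose(g.adc, a.adc, atol=1e-12)
        with pytest.raises(ValueError):
            fit_adc(ds, "PG", average="harmonic")

    def test_missing_condition_rejected(self):
        data = np.ones((1, 1, 1, 12))
        ds = _dataset_from_signals(data)
        with pytest.raises(ProtocolError):
            fit_adc(ds, "OG999")


class TestFitDTI:
    def test_isotropic_fa_zero(self):
        D = np.eye(3) * 0.8
        data = _tensor_signals(D, DIRECTIONS_30, b=2.0, n_b0=3)
        ds = _dataset_from_signals(data, DIRECTIONS_30, b=2.0, n_b0=3)
        t = fit_dti(ds)
        assert np.all(np.abs(t.fa[t.valid]) < 1e-9)
        np.testing.assert_allclose(t.md[t.valid], 0.8, atol=1e-9)

    def test_prolate_tensor_round_trip(self):
        evals = np.array([1.7, 0.3, 0.3])
        # rotate the tensor to a non-axis-aligned frame
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        D = R @ np.diag(evals) @ R.T
        data = _tensor_signals(D, DIRECTIONS_30, b=2.0, n_b0=3)
        ds = _dataset_from_signals(data, DIRECTIONS_30, b=2.0, n_b0=3)
        t = fit_dti(ds)
        np.testing.assert_allclose(t.evals[0, 0, 0], evals, atol=1e-9)
        fa_closed = np.sqrt(1.5 * np.sum((evals - evals.mean()) ** 2)
                            / np.sum(evals**2))
        assert t.fa[0, 0, 0] == pytest.approx(fa_closed, abs=1e-9)
        # principal eigenvector along the rotated x axis (up to sign)
        e1 = t.evecs[0, 0, 0][:, 0]
        assert abs(e1 @ (R @ np.array([1.0, 0, 0]))) == pytest.approx(1, abs=1e-9)

    def test_fa_rotation_invariance(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        evals = np.array([1.2, 0.5, 0.2])
        D = Q @ np.diag(evals) @ Q.T
        data = _tensor_signals(D, DIRECTIONS_30 @ Q.T, b=2.0, n_b0=3)
        ds = _dataset_from_signals(data, DIRECTIONS_30 @ Q.T, b=2.0, n_b0=3)
        t1 = fit_dti(ds)
        data2 = _tensor_signals(np.diag(evals), DIRECTIONS_30, b=2.0, n_b0=3)
        ds2 = _dataset_from_signals(data2, DIRECTIONS_30, b=2.0, n_b0=3)
        t2 = fit_dti(ds2)
        assert t1.fa[0, 0, 0] == pytest.approx(t2.fa[0, 0, 0], abs=1e-9)

    def test_insufficient_directions_rejected(self):
        dirs = DIRECTIONS_10[:5]
        data = _tensor_signals(np.eye(3), dirs, b=1.0)
        ds = _dataset_from_signals(data, dirs)
        with pytest.raises(ProtocolError):
            fit_dti(ds)


class TestDECMap:
    def _tensor_map_for(self, e1):
        evals = np.array([1.5, 0.3, 0.3])
        v = np.asarray(e1, dtype=float)
        v /= np.linalg.norm(v)
        # build an orthonormal frame with v as principal axis
        other = np.eye(3)[np.argmin(np.abs(v))]
        u2 = np.cross(v, other)
        u2 /= np.linalg.norm(u2)
        u3 = np.cross(v, u2)
        D = (evals[0] * np.outer(v, v) + evals[1] * np.outer(u2, u2)
             + evals[2] * np.outer(u3, u3))
        data = _tensor_signals(D, DIRECTIONS_30, b=2.0, n_b0=3,
                               shape=(1, 1, 1))
        ds = _dataset_from_signals(data, DIRECTIONS_30, b=2.0, n_b0=3)
        return fit_dti(ds)

    def test_fa_zero_voxel_is_black(self):
        data = _tensor_signals(np.eye(3) * 0.5, DIRECTIONS_30, b=2.0, n_b0=3)
        ds = _dataset_from_signals(data, DIRECTIONS_30, b=2.0, n_b0=3)
        rgb = dec_map(fit_dti(ds))
        np.testing.assert_allclose(rgb, 0.0, atol=1e-9)

    def test_superior_inferior_is_green(self):
        t = self._tensor_map_for([0, 1, 0])
        rgb = dec_map(t)[0, 0, 0]
        assert rgb[1] > 0.5 and rgb[0] < 1e-6 and rgb[2] < 1e-6

    def test_through_plane_is_blue(self):
        t = self._tensor_map_for([0, 0, 1])
        rgb = dec_map(t)[0, 0, 0]
        assert rgb[2] > 0.5 and rgb[0] < 1e-6 and rgb[1] < 1e-6


def test_fractional_anisotropy_limits():
    assert fractional_anisotropy(np.array([1.0, 1.0, 1.0])) == 0.0
    # stick limit → FA → 1
    assert fractional_anisotropy(np.array([1.0, 0.0, 0.0])) == pytest.approx(1.0)
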