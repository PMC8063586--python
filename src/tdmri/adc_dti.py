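"""Per-voxel ADC mapping and diffusion-tensor fitting.

ADC follows the mono-exponential model S = S0·exp(−b·ADC): per direction
ADC_i = ln(S̄0/S_i)/b (b0 volumes averaged before the log), and the mean
ADC map is the arithmetic mean over directions. The tensor fit is the
standard log-linear least-squares fit of ln(S/S̄0) = −b·gᵀDg, with
eigenvalues sorted descending, FA from the normalised eigenvalue
dispersion, and a direction-encoded colour (DEC) map built from the
principal eigenvector weighted by FA.

Colour convention (sagittal reading): red = anterior–posterior (x),
green = superior–inferior (y), blue = left–right / through-plane (z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import DWIDataset

__all__ = ["ADCMap", "TensorMap", "fit_adc", "fit_dti", "dec_map",
           "ProtocolError"]


class ProtocolError(ValueError):
    """Raised when the acquisition scheme cannot support the requested fit."""


@dataclass
class ADCMap:
    """Mean ADC per voxel for one diffusion condition."""

    condition: str
    adc: np.ndarray  # (x, y, z) µm²/ms; NaN outside valid voxels
    per_direction: np.ndarray  # (x, y, z, n_dir)
    valid: np.ndarray  # (x, y, z) bool
    n_invalid: int
    frequency: float  # Hz; 0 for PG
    b: float


@dataclass
class TensorMap:
    """Voxelwise diffusion tensor decomposition."""

    evals: np.ndarray  # (x, y, z, 3) descending, µm²/ms
    evecs: np.ndarray  # (x, y, z, 3, 3); evecs[..., :, i] ↔ evals[..., i]
    fa: np.ndarray  # (x, y, z) in [0, 1]
    md: np.ndarray  # (x, y, z) µm²/ms
    valid: np.ndarray  # (x, y, z) bool
    n_clamped: int  # voxels with negative eigenvalues clamped to 0


def _condition_frequency(ds: DWIDataset, condition: str) -> float:
    sub = ds.gtab[(ds.gtab["b"] > 0)]
    from .datasets import condition_labels
    labels = condition_labels(ds.gtab)
    rows = ds.gtab[(labels == condition) & (ds.gtab["b"] > 0)]
    if len(rows) == 0:
        raise ProtocolError(f"no diffusion-weighted volumes for {condition!r}")
    row = rows.iloc[0]
    return 0.0 if row["kind"] == "PG" else float(row["f_or_delta"])


def fit_adc(ds: DWIDataset, condition: str,
            average: str = "arithmetic") -> ADCMap:
    """Mean ADC map for one condition from its (b0, b) volume pair(s).

    ``average`` is "arithmetic" (mean of per-direction ADCs, default) or
    "geometric" (ADC of the geometric-mean signal — identical for the
    mono-exponential model, differing under noise). Voxels with
    non-positive signal in any used volume are masked out and counted in
    ``n_invalid``.
    """
    i_b0, i_dwi = ds.volumes_for(condition)
    if len(i_b0) == 0 or len(i_dwi) == 0:
        raise ProtocolError(
            f"condition {condition!r} needs ≥1 b0 and ≥1 DWI volume")
    b = float(ds.gtab["b"].iloc[i_dwi[0]])
    s0 = ds.data[..., i_b0].mean(axis=-1)
    s = ds.data[..., i_dwi]
    valid = (s0 > 0) & np.all(s > 0, axis=-1)
    if ds.mask is not None:
        n_invalid = int(np.count_nonzero(ds.mask & ~valid))
        valid &= ds.mask
    else:
        n_invalid = int(np.count_nonzero(~valid))
    if average not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown averaging mode {average!r}")
    per_dir = np.full(s.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_dir[valid] = np.log(s0[valid, None] / s[valid]) / b
    adc = np.full(s0.shape, np.nan)
    if average == "arithmetic":
        adc[valid] = per_dir[valid].mean(axis=-1)
    else:
        gm = np.exp(np.log(s[valid]).mean(axis=-1))
        adc[valid] = np.log(s0[valid] / gm) / b
    return ADCMap(condition=condition, adc=adc, per_direction=per_dir,
                  valid=valid, n_invalid=n_invalid,
                  frequency=_condition_frequency(ds, condition), b=b)


def _design_matrix(bvals: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    g = dirs
    return bvals[:, None] * np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])


def fit_dti(ds: DWIDataset) -> TensorMap:
    """Log-linear least-squares tensor fit over all diffusion-weighted
    volumes (all b0 volumes averaged as the reference)."""
    i_b0 = np.flatnonzero(ds.gtab["b"] == 0)
    i_dwi = np.flatnonzero(ds.gtab["b"] > 0)
    if len(i_b0) == 0:
        raise ProtocolError("tensor fit needs at least one b0 volume")
    dirs = ds.gtab[["gx", "gy", "gz"]].to_numpy(dtype=float)[i_dwi]
    bvals = ds.gtab["b"].to_numpy(dtype=float)[i_dwi]
    A = _design_matrix(bvals, dirs)
    if len(i_dwi) < 6 or np.linalg.matrix_rank(A) < 6:
        raise ProtocolError(
            "tensor fit needs ≥6 non-collinear diffusion directions")

    s0 = ds.data[..., i_b0].mean(axis=-1)
    s = ds.data[..., i_dwi]
    valid = (s0 > 0) & np.all(s > 0, axis=-1)
    if ds.mask is not None:
        valid &= ds.mask

    shape = s0.shape
    y = np.zeros(shape + (len(i_dwi),))
    with np.errstate(divide="ignore", invalid="ignore"):
        y[valid] = -np.log(s[valid] / s0[valid, None])
    coef, *_ = np.linalg.lstsq(A, y[valid].T, rcond=None)  # (6, n_valid)

    n_valid = coef.shape[1]
    D = np.zeros((n_valid, 3, 3))
    D[:, 0, 0] = coef[0]
    D[:, 1, 1] = coef[1]
    D[:, 2, 2] = coef[2]
    D[:, 0, 1] = D[:, 1, 0] = coef[3]
    D[:, 0, 2] = D[:, 2, 0] = coef[4]
    D[:, 1, 2] = D[:, 2, 1] = coef[5]
    w, v = np.linalg.eigh(D)  # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    n_clamped = int(np.count_nonzero(np.any(w < 0, axis=1)))
    w = np.clip(w, 0.0, None)

    evals = np.zeros(shape + (3,))
    evecs = np.zeros(shape + (3, 3))
    evals[valid] = w
    evecs[valid] = v
    md = evals.mean(axis=-1)
    fa = fractional_anisotropy(evals)
    fa[~valid] = 0.0
    return TensorMap(evals=evals, evecs=evecs, fa=fa, md=md, valid=valid,
                     n_clamped=n_clamped)


def fractional_anisotropy(evals: np.ndarray) -> np.ndarray:
    """FA from eigenvalues (last axis of length 3)."""
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sum((evals - mean) ** 2, axis=-1)
    den = np.sum(evals**2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.nan_to_num(fa, nan=0.0)


def dec_map(t: TensorMap) -> np.ndarray:
    """Direction-encoded colour volume (x, y, z, 3) in [0, 1]:
    |principal-eigenvector components| × FA."""
    e1 = t.evecs[..., :, 0]
    rgb = np.abs(e1) * t.fa[..., None]
    return np.clip(rgb, 0.0, 1.0)
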