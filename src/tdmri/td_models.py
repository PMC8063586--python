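"""Diffusion-time (frequency) dispersion models of the ADC.

Two descriptions of ADC versus oscillating-gradient frequency f (with the
pulsed-gradient condition entering at f = 0):

* linear:     ADC(f) = ΔADC·f + ADC0 — the slope ΔADC (µm²·ms⁻¹·Hz⁻¹)
  quantifies the degree of diffusion-time dependence;
* power law:  ADC(f) = α·f^θ + ADC0 — θ (the dispersion rate, bounded to
  [0, 2]) reflects structural disorder, α ≥ 0 scales the dispersion.

The linear model is fit per ROI or per voxel by ordinary least squares.
The power law is fit at group level on pooled subject samples (per-subject
fitting of three parameters on four frequencies is unstable and only
exposed behind an explicit flag downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["TdFitResult", "FitError", "fit_linear_td", "delta_adc_map",
           "fit_powerlaw_group"]

THETA_BOUNDS = (0.0, 2.0)


class FitError(ValueError):
    pass


@dataclass
class TdFitResult:
    """Result of a dispersion fit (linear or power-law)."""

    model: str  # "linear" | "power"
    adc0: float
    delta_adc: float | None = None  # linear slope
    alpha: float | None = None
    theta: float | None = None
    adc0_se: float | None = None
    delta_adc_se: float | None = None
    residual: float = 0.0  # RMS residual
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    frequencies: np.ndarray | None = None

    def predict(self, f) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        if self.model == "linear":
            return self.delta_adc * f + self.adc0
        return self.alpha * np.power(f, self.theta, where=f > 0,
                                     out=np.ones_like(f)) * (f > 0) + self.adc0


def _as_xy(adc_by_frequency) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(adc_by_frequency, dict):
        f = np.array(sorted(adc_by_frequency), dtype=float)
        y = np.array([adc_by_frequency[k] for k in sorted(adc_by_frequency)],
                     dtype=float)
    else:
        f, y = (np.asarray(a, dtype=float) for a in adc_by_frequency)
    return f, y


def fit_linear_td(adc_by_frequency, include_pg_as_zero: bool = True
                  ) -> TdFitResult:
    """Ordinary least-squares fit of ADC(f) = ΔADC·f + ADC0.

    ``adc_by_frequency`` is a {frequency_Hz: ADC} mapping (PG at f = 0) or
    an (f, adc) pair of arrays. With ``include_pg_as_zero`` False, f = 0
    entries are dropped before fitting.
    """
    f, y = _as_xy(adc_by_frequency)
    if not include_pg_as_zero:
        keep = f > 0
        f, y = f[keep], y[keep]
    if len(np.unique(f)) < 2:
        raise FitError("linear dispersion fit needs ≥2 distinct frequencies")
    res = stats.linregress(f, y)
    pred = res.slope * f + res.intercept
    return TdFitResult(
        model="linear", adc0=float(res.intercept),
        delta_adc=float(res.slope), adc0_se=float(res.intercept_stderr),
        delta_adc_se=float(res.stderr),
        residual=float(np.sqrt(np.mean((y - pred) ** 2))),
        frequencies=f)


def delta_adc_map(adc_maps: dict[float, np.ndarray],
                  mask: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise linear dispersion fit over co-registered ADC maps.

    ``adc_maps`` maps frequency (Hz, PG at 0) → 3-D ADC volume. Returns
    (ΔADC map, ADC0 map); voxels invalid (NaN) in any input propagate NaN.
    """
    freqs = np.array(sorted(adc_maps), dtype=float)
    if len(freqs) < 2:
        raise FitError("need ≥2 frequencies")
    shapes = {adc_maps[f].shape for f in freqs}
    if len(shapes) != 1:
        raise ValueError("ADC maps are not on a common grid")
    stack = np.stack([adc_maps[f] for f in freqs], axis=-1)
    valid = np.all(np.isfinite(stack), axis=-1)
    if mask is not None:
        valid &= mask
    fc = freqs - freqs.mean()
    denom = np.sum(fc**2)
    slope = np.full(stack.shape[:3], np.nan)
    intercept = np.full(stack.shape[:3], np.nan)
    ymean = stack.mean(axis=-1)
    slope_v = np.tensordot(stack, fc, axes=([-1], [0])) / denom
    slope[valid] = slope_v[valid]
    intercept[valid] = ymean[valid] - slope_v[valid] * freqs.mean()
    return slope, intercept


def fit_powerlaw_group(samples, *, fix_theta: float | None = None,
                       theta_bounds: tuple[float, float] = THETA_BOUNDS
                       ) -> TdFitResult:
    """Bounded nonlinear least-squares fit of ADC(f) = α·f^θ + ADC0 on
    pooled samples.

    ``samples`` is a list of {frequency: ADC} mappings (one per subject) or
    a single mapping; all points are pooled into one fit, as per-subject
    fitting of (α, θ, ADC0) on four frequencies is unstable. f = 0 points
    anchor ADC0. Non-convergence or degeneracy is flagged, not raised.
    """
    if isinstance(samples, dict):
        samples = [samples]
    f_all, y_all = [], []
    for s in samples:
        f, y = _as_xy(s)
        f_all.append(f)
        y_all.append(y)
    f = np.concatenate(f_all)
    y = np.concatenate(y_all)
    if len(f) < 4:
        raise FitError("pooled power-law fit needs ≥4 points")

    lin = fit_linear_td((f, y))
    flags: list[str] = []

    if fix_theta is not None:
        # with θ fixed the model is linear in (α, ADC0)
        p = np.where(f > 0, np.power(f, fix_theta, where=f > 0,
                                     out=np.zeros_like(f)), 0.0)
        X = np.column_stack([p, np.ones_like(f)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ coef
        return TdFitResult(model="power", adc0=float(coef[1]),
                           alpha=float(coef[0]), theta=float(fix_theta),
                           residual=float(np.sqrt(np.mean((y - pred) ** 2))),
                           frequencies=f, flags=flags)

    alpha0 = max(lin.delta_adc, 1e-12)
    adc0_0 = max(lin.adc0, 1e-6)

    def resid(p):
        alpha, theta, adc0 = p
        pred = np.where(f > 0, alpha * np.power(f, theta, where=f > 0,
                                                out=np.ones_like(f)), 0.0) + adc0
        return pred - y

    lo = np.array([0.0, theta_bounds[0], 1e-9])
    hi = np.array([np.inf, theta_bounds[1], np.inf])
    sol = optimize.least_squares(resid, x0=[alpha0, 1.0, adc0_0],
                                 bounds=(lo, hi))
    alpha, theta, adc0 = sol.x
    if not sol.success:
        flags.append("non-convergence")
    # θ is unidentifiable when the dispersion amplitude vanishes
    scale = max(np.ptp(y), abs(adc0), 1e-12)
    if alpha * (np.max(f) ** min(theta, theta_bounds[1])) < 1e-6 * scale:
        flags.append("theta-unidentifiable")
    return TdFitResult(model="power", adc0=float(adc0), alpha=float(alpha),
                       theta=float(theta),
                       residual=float(np.sqrt(np.mean(sol.fun**2))),
                       converged=bool(sol.success), flags=flags,
                       frequencies=f)
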