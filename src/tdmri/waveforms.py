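"""Diffusion-encoding gradient waveforms and derived protocol quantities.

Pulsed-gradient (PG) and cosine oscillating-gradient (OG) spin-echo
encodings are represented by their *effective* gradient: the 180° refocusing
pulse is folded in as a sign inversion of the second lobe, so a refocused
waveform integrates to zero.

Internal unit system (used consistently across the package):

* time in ms, length in µm, gradient amplitude in T/m,
* gyromagnetic ratio ``GAMMA`` in rad·s⁻¹·T⁻¹ (proton),
* b-values in ms/µm² (numerically equal to 10³ s/mm²).

The effective diffusion time is Δ−δ/3 for PG and 1/(4f) for cosine OG; the
corresponding diffusion length is l = sqrt(2·D·t_d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAMMA",
    "GradientWaveform",
    "InvalidProtocolError",
    "make_pg",
    "make_og_cosine",
    "bvalue",
    "amplitude_for_b",
    "effective_diffusion_time",
    "diffusion_length",
]

#: Proton gyromagnetic ratio, rad·s⁻¹·T⁻¹.
GAMMA = 2.6752218744e8

#: Phase accrued per (T/m)·µm·ms, i.e. GAMMA converted to package units.
GAMMA_PHASE = GAMMA * 1e-9

#: Default maximum gradient amplitude of the emulated preclinical system, T/m.
DEFAULT_G_MAX = 1.5

_REFOCUS_RTOL = 1e-9


class InvalidProtocolError(ValueError):
    """Raised for physically inconsistent encoding parameters."""


@dataclass(frozen=True)
class GradientWaveform:
    """One diffusion-encoding axis as a time-sampled effective gradient.

    ``samples[i]`` is the (signed) effective gradient amplitude over the
    interval ``[i*time_step, (i+1)*time_step)``; sampling is at interval
    midpoints so integer-cycle cosine lobes refocus exactly.
    """

    kind: str  # "PG" | "OG"
    G: float  # T/m
    time_step: float  # ms
    samples: np.ndarray = field(repr=False)  # T/m, signed
    delta: float | None = None  # ms (PG)
    Delta: float | None = None  # ms (PG)
    freq: float | None = None  # Hz (OG)
    n_cycles: int | None = None  # per lobe (OG)
    gamma: float = GAMMA

    @property
    def duration(self) -> float:
        """Total encoding duration in ms."""
        return len(self.samples) * self.time_step

    @property
    def times(self) -> np.ndarray:
        """Midpoint time of every sample, ms."""
        return (np.arange(len(self.samples)) + 0.5) * self.time_step

    def net_moment(self) -> float:
        """Zeroth gradient moment ∫g(t)dt in (T/m)·ms; ~0 when refocused."""
        return float(np.sum(self.samples) * self.time_step)

    def is_refocused(self, rtol: float = 1e-6) -> bool:
        scale = float(np.sum(np.abs(self.samples)) * self.time_step)
        if scale == 0.0:
            return True
        return abs(self.net_moment()) <= rtol * scale

    def with_amplitude(self, G: float) -> "GradientWaveform":
        """Same timing, rescaled amplitude."""
        if self.G == 0:
            raise ValueError("cannot rescale a zero-amplitude waveform")
        return GradientWaveform(
            kind=self.kind,
            G=G,
            time_step=self.time_step,
            samples=self.samples * (G / self.G),
            delta=self.delta,
            Delta=self.Delta,
            freq=self.freq,
            n_cycles=self.n_cycles,
            gamma=self.gamma,
        )

    def to_csv(self, path) -> None:
        """Write the waveform as two-column CSV (time ms, amplitude T/m)."""
        arr = np.column_stack([self.times, self.samples])
        np.savetxt(path, arr, delimiter=",", header="time_ms,amplitude_T_per_m",
                   comments="")


def _n_samples(duration: float, dt: float, what: str) -> int:
    n = duration / dt
    n_round = round(n)
    if n_round < 1 or abs(n - n_round) > 1e-6 * max(1.0, n):
        raise ValueError(
            f"time_step {dt} ms does not evenly divide {what} ({duration} ms)"
        )
    return n_round


def make_pg(G: float, delta: float, Delta: float, time_step: float = 0.01,
            gamma: float = GAMMA) -> GradientWaveform:
    """Pulsed-gradient encoding: two rectangular lobes of width ``delta``
    (ms) whose leading edges are ``Delta`` (ms) apart; the second lobe is
    sign-inverted by the refocusing pulse."""
    if time_step <= 0:
        raise ValueError("time_step must be positive")
    if delta <= 0:
        raise InvalidProtocolError("delta must be positive")
    if delta > Delta:
        raise InvalidProtocolError(
            f"diffusion duration delta={delta} ms exceeds separation Delta={Delta} ms"
        )
    n_lobe = _n_samples(delta, time_step, "delta")
    n_gap = _n_samples(Delta - delta, time_step, "Delta-delta") if Delta > delta else 0
    samples = np.concatenate([
        np.full(n_lobe, G, dtype=float),
        np.zeros(n_gap),
        np.full(n_lobe, -G, dtype=float),
    ])
    return GradientWaveform(kind="PG", G=G, time_step=time_step, samples=samples,
                            delta=delta, Delta=Delta, gamma=gamma)


def make_og_cosine(G: float, freq: float, n_cycles: int, time_step: float = 0.01,
                   gamma: float = GAMMA) -> GradientWaveform:
    """Cosine oscillating-gradient encoding: two cosine-modulated lobes of
    duration ``n_cycles/freq`` each (opposite effective sign), so each lobe
    self-refocuses. ``freq`` in Hz."""
    if time_step <= 0:
        raise ValueError("time_step must be positive")
    if freq <= 0:
        raise InvalidProtocolError("oscillating frequency must be positive")
    if n_cycles != int(n_cycles) or n_cycles < 1:
        raise ValueError("n_cycles must be a positive integer")
    n_cycles = int(n_cycles)
    lobe_ms = 1e3 * n_cycles / freq
    n_lobe = _n_samples(lobe_ms, time_step, "lobe duration n_cycles/f")
    t_mid = (np.arange(n_lobe) + 0.5) * time_step  # ms within lobe
    lobe = G * np.cos(2.0 * np.pi * freq * t_mid * 1e-3)
    samples = np.concatenate([lobe, -lobe])
    return GradientWaveform(kind="OG", G=G, time_step=time_step, samples=samples,
                            freq=freq, n_cycles=n_cycles, gamma=gamma)


def bvalue(w: GradientWaveform) -> float:
    """Diffusion weighting b = γ²∫q(t)²dt with q(t)=∫g(t')dt', in ms/µm².

    The integral is evaluated exactly for the piecewise-constant sampled
    waveform, so ideal-PG closed forms are matched to sampling accuracy.
    """
    if not w.is_refocused():
        raise InvalidProtocolError("waveform is not refocused (nonzero net moment)")
    dt = w.time_step
    g = w.samples
    q0 = np.concatenate([[0.0], np.cumsum(g)[:-1]]) * dt  # q at step start
    integral = np.sum(q0 * q0 * dt + q0 * g * dt**2 + g * g * dt**3 / 3.0)
    return float(w.gamma**2 * 1e-18 * integral)


def amplitude_for_b(kind: str, target_b: float, *, delta: float | None = None,
                    Delta: float | None = None, freq: float | None = None,
                    n_cycles: int | None = None, time_step: float = 0.01,
                    g_max: float = DEFAULT_G_MAX) -> float:
    """Gradient amplitude (T/m) giving ``target_b`` (ms/µm²) for the given
    timing. Warns (does not fail) if the amplitude exceeds ``g_max``."""
    if target_b < 0:
        raise ValueError("target_b must be non-negative")
    if target_b == 0:
        return 0.0
    if kind.upper() == "PG":
        ref = make_pg(1.0, delta, Delta, time_step)
    elif kind.upper() == "OG":
        ref = make_og_cosine(1.0, freq, n_cycles, time_step)
    else:
        raise ValueError(f"unknown waveform kind {kind!r}")
    G = float(np.sqrt(target_b / bvalue(ref)))
    if G > g_max:
        warnings.warn(
            f"required gradient amplitude {G:.3f} T/m exceeds the hardware "
            f"bound {g_max} T/m", stacklevel=2)
    return G


def effective_diffusion_time(w: GradientWaveform) -> float:
    """Effective diffusion time t_d in ms: Δ−δ/3 for PG, 1/(4f) for OG."""
    if w.kind == "PG":
        return w.Delta - w.delta / 3.0
    return 1e3 / (4.0 * w.freq)


def diffusion_length(D: float, t_d: float) -> float:
    """One-dimensional diffusion length l = sqrt(2·D·t_d), µm
    (D in µm²/ms, t_d in ms)."""
    if D < 0 or t_d < 0:
        raise ValueError("D and t_d must be non-negative")
    return float(np.sqrt(2.0 * D * t_d))
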