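"""Synthetic layered "cerebellum" phantom generator.

The phantom emulates the three-ROI laminar topology of a mid-sagittal
cerebellar folium as concentric 2-D bands extruded to a thin slab:

* label 1, WM_IGL  — core (white matter + inner internal granular layer)
* label 2, IGL_PCL — middle rim (outer IGL + Purkinje cell layer)
* label 3, ML_EGL  — outer rim (molecular / external granular layer)
* label 0 — background (free-water-like, excluded from the brain mask)

Each layer carries a ground-truth ADC(f) table over the four-condition
protocol (PG at f = 0 plus three oscillating frequencies). Signals follow
S = S0·exp(−b·ADC_layer(f)) per condition and direction, with optional
Rician noise at a stated b0 SNR. A trisomic-like (Ts) group is derived
from the euploid-like (Eu) specification by scaling the frequency-
dependent part of the ADC table (emulating reduced cell/neurite packing,
which lowers dispersion) and optionally thinning layers.

Default tables are mechanistic: they were computed with the bundled Monte
Carlo simulator (granule-cell-like sphere packing for the cellular layers,
neurite-like cylinder packing for WM and molecular layers) and are frozen
as constants; ``layer_tables_from_simulation`` regenerates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import DWIDataset, ROILabelMap, gradient_table_rows
from .directions import DIRECTIONS_10, DIRECTIONS_30

__all__ = ["LayerSpec", "GroupModifiers", "PhantomRealization",
           "generate_phantom", "generate_group", "eu_layers", "ts_modifiers",
           "PROTOCOL_FREQUENCIES"]

#: Protocol frequencies (Hz); PG enters at 0.
PROTOCOL_FREQUENCIES = (0.0, 50.0, 100.0, 200.0)

#: Conditions of the four-frequency protocol (PG δ/Δ = 5/20 ms).
PROTOCOL_CONDITIONS = (
    {"kind": "PG", "delta": 5.0, "Delta": 20.0},
    {"kind": "OG", "freq": 50.0, "n_cycles": 1},
    {"kind": "OG", "freq": 100.0, "n_cycles": 2},
    {"kind": "OG", "freq": 200.0, "n_cycles": 4},
)

# Frozen mechanistic ADC(f) tables (µm²/ms at f in Hz), from the bundled
# Monte Carlo simulator at D0 = 2 µm²/ms, b = 1 ms/µm², 25k walkers:
#   WM_IGL  — 50/50 signal mixture of a neurite-like cylinder pack
#             (d = 1.0 µm, fraction 0.65) and the IGL sphere pack: the
#             ROI spans white matter AND the inner granular layer
#   IGL_PCL — granule-cell-like sphere pack, d = 6 µm, fraction 0.39
#   ML_EGL  — neurite-like cylinder pack, d = 1.0 µm, fraction 0.5
#             (essentially dispersion-free at these frequencies)
# (regenerate with layer_tables_from_simulation).
_DEFAULT_TABLES = {
    "WM_IGL": {0.0: 0.450, 50.0: 0.484, 100.0: 0.564, 200.0: 0.669},
    "IGL_PCL": {0.0: 0.690, 50.0: 0.779, 100.0: 1.013, 200.0: 1.376},
    "ML_EGL": {0.0: 0.445, 50.0: 0.443, 100.0: 0.456, 200.0: 0.450},
}


@dataclass(frozen=True)
class LayerSpec:
    """One phantom layer: label, name, and ground-truth ADC(f) table."""

    label: int
    name: str
    adc_table: dict[float, float]  # Hz -> µm²/ms
    thickness: float = 1.0  # relative band width
    orientation: str = "isotropic"  # isotropic|superior_inferior|radial|through_plane
    fa: float = 0.0  # target FA of the layer tensor (DTI volumes only)

    def slope_intercept(self) -> tuple[float, float]:
        f = np.array(sorted(self.adc_table), dtype=float)
        y = np.array([self.adc_table[k] for k in sorted(self.adc_table)])
        slope, intercept = np.polyfit(f, y, 1)
        return float(slope), float(intercept)


@dataclass(frozen=True)
class GroupModifiers:
    """Multiplicative deviations of the trisomic-like group.

    ``dispersion_scale`` scales the frequency-dependent part of each
    layer's ADC table about its f = 0 value — the microstructural reading
    is reduced cell/neurite density, which lowers ΔADC while leaving the
    long-diffusion-time ADC almost unchanged. ``thickness_scale`` thins
    layers (hypoplasia).
    """

    dispersion_scale: dict[str, float] = field(default_factory=dict)
    thickness_scale: dict[str, float] = field(default_factory=dict)

    def apply(self, layers: list[LayerSpec]) -> list[LayerSpec]:
        out = []
        for ly in layers:
            m = self.dispersion_scale.get(ly.name, 1.0)
            if not 0 < m <= 1:
                raise ValueError("dispersion scale must be in (0, 1]")
            adc0 = ly.adc_table[min(ly.adc_table)]
            table = {f: adc0 + m * (v - adc0) for f, v in ly.adc_table.items()}
            th = self.thickness_scale.get(ly.name, 1.0)
            if th <= 0:
                raise ValueError("thickness scale must be positive")
            out.append(replace(ly, adc_table=table, thickness=ly.thickness * th))
        return out


def eu_layers() -> list[LayerSpec]:
    """Euploid-like default layer specification."""
    return [
        LayerSpec(1, "WM_IGL", dict(_DEFAULT_TABLES["WM_IGL"]),
                  orientation="superior_inferior", fa=0.6),
        LayerSpec(2, "IGL_PCL", dict(_DEFAULT_TABLES["IGL_PCL"]),
                  orientation="radial", fa=0.4),
        LayerSpec(3, "ML_EGL", dict(_DEFAULT_TABLES["ML_EGL"]),
                  orientation="through_plane", fa=0.4),
    ]


def ts_modifiers() -> GroupModifiers:
    """Trisomic-like default: reduced dispersion in the cellular layers
    (reduced granule-cell and neurite density) and mild layer thinning."""
    return GroupModifiers(
        dispersion_scale={"WM_IGL": 0.8, "IGL_PCL": 0.8, "ML_EGL": 1.0},
        thickness_scale={"IGL_PCL": 0.85, "ML_EGL": 0.96},
    )


@dataclass
class PhantomRealization:
    """One synthetic subject: DWI data, labels, and lossless ground truth."""

    dwi: DWIDataset
    roi_map: ROILabelMap
    ground_truth: dict
    seed: int
    dti: DWIDataset | None = None


def _band_label_map(shape, layers: list[LayerSpec], voxel_size) -> np.ndarray:
    """Concentric-band label geometry in-plane, extruded along z."""
    nx, ny, nz = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
    r = np.hypot(xx - cx, yy - cy)
    r_out = 0.46 * min(nx, ny)
    widths = np.array([ly.thickness for ly in layers], dtype=float)
    # base partition of the folium radius: core half, two rims a quarter
    # each (three-layer default), else equal shares; thinning a layer
    # shrinks the folium (no renormalisation)
    n = len(layers)
    fr = np.array([0.5, 0.25, 0.25]) if n == 3 else np.full(n, 1.0 / n)
    bounds = np.cumsum(fr * widths) * r_out
    plane = np.zeros((nx, ny), dtype=np.int16)
    for ly, b_out in zip(reversed(layers), bounds[::-1]):
        plane[r <= b_out] = ly.label
    return np.repeat(plane[:, :, None], nz, axis=2)


def _rician(rng: np.random.Generator, s: np.ndarray, sigma: float) -> np.ndarray:
    return np.hypot(s + rng.normal(0, sigma, s.shape),
                    rng.normal(0, sigma, s.shape))


_ORIENTATIONS = {
    "superior_inferior": np.array([0.0, 1.0, 0.0]),
    "through_plane": np.array([0.0, 0.0, 1.0]),
}


def _prolate_evals(md: float, fa: float) -> np.ndarray:
    """Eigenvalues (λ1, λ2, λ2) of a prolate tensor with given MD and FA."""
    if fa == 0:
        return np.array([md, md, md])
    # solve FA for prolate tensor: λ1 = md(1+2x), λ2 = md(1−x)
    # FA = 3x/sqrt(3+6x²) → x = FA·sqrt(3/(9−6FA²))... derived algebraically
    x = fa * np.sqrt(3.0 / (9.0 - 6.0 * fa**2))
    lam1 = md * (1 + 2 * x)
    lam2 = md * (1 - x)
    return np.array([lam1, lam2, lam2])


def generate_phantom(layers: list[LayerSpec] | None = None, *,
                     shape=(32, 32, 4), voxel_size=(0.1, 0.1, 0.1),
                     snr: float | None = 20.0, seed: int = 0,
                     b: float = 1.0, n_b0: int = 2,
                     directions: np.ndarray = DIRECTIONS_10,
                     noise: str = "rician",
                     include_dti: bool = False,
                     dti_b: float = 2.0) -> PhantomRealization:
    """Build one synthetic subject.

    Per voxel and condition, S = S0·exp(−b·ADC_layer(f)) with S0 = 1
    (background uses free-water ADC at all f), then Rician (or Gaussian)
    noise at the given b0 SNR; ``snr=None`` disables noise. Deterministic
    per seed.
    """
    layers = layers if layers is not None else eu_layers()
    labels_present = [ly.label for ly in layers]
    if len(set(labels_present)) != len(labels_present):
        raise ValueError("layer labels must be unique")
    rng = np.random.default_rng(seed)
    label_vol = _band_label_map(shape, layers, voxel_size)
    gtab = gradient_table_rows(n_b0=n_b0, directions=np.asarray(directions),
                               b=b, conditions=list(PROTOCOL_CONDITIONS))

    free_adc = 2.0  # background water
    adc_of = {ly.label: ly.adc_table for ly in layers}
    freqs = sorted(layers[0].adc_table)

    nvol = len(gtab)
    data = np.ones(shape + (nvol,), dtype=float)
    for ivol, row in gtab.iterrows():
        if row["b"] == 0:
            continue
        f = 0.0 if row["kind"] == "PG" else float(row["f_or_delta"])
        adc_vol = np.full(shape, free_adc)
        for ly in layers:
            adc_vol[label_vol == ly.label] = ly.adc_table[f]
        data[..., ivol] = np.exp(-row["b"] * adc_vol)

    if snr is not None:
        sigma = 1.0 / snr
        if noise == "rician":
            data = _rician(rng, data, sigma)
        elif noise == "gaussian":
            data = data + rng.normal(0, sigma, data.shape)
        else:
            raise ValueError(f"unknown noise model {noise!r}")

    mask = label_vol > 0
    dwi = DWIDataset(data=data, gtab=gtab, voxel_size=tuple(voxel_size),
                     mask=mask)
    roi_map = ROILabelMap(labels=label_vol,
                          names={ly.label: ly.name for ly in layers},
                          voxel_size=tuple(voxel_size))

    gt = {
        "seed": seed,
        "snr": snr,
        "layers": {
            ly.name: {
                "label": ly.label,
                "adc_table": {str(f): v for f, v in ly.adc_table.items()},
                "delta_adc": ly.slope_intercept()[0],
                "adc0": ly.slope_intercept()[1],
                "thickness": ly.thickness,
            } for ly in layers
        },
    }

    dti_ds = None
    if include_dti:
        dti_ds = _generate_dti(layers, label_vol, shape, voxel_size, rng,
                               snr, noise, dti_b)
    return PhantomRealization(dwi=dwi, roi_map=roi_map, ground_truth=gt,
                              seed=seed, dti=dti_ds)


def _generate_dti(layers, label_vol, shape, voxel_size, rng, snr, noise,
                  dti_b) -> DWIDataset:
    """Separate tensor acquisition (30 directions, 3 b0) with per-layer
    prolate tensors oriented by the layer's anatomical reading."""
    dirs = DIRECTIONS_30
    gtab = gradient_table_rows(
        n_b0=3, directions=dirs, b=dti_b,
        conditions=[{"kind": "PG", "delta": 3.4, "Delta": 8.5}])
    nx, ny, nz = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
    radial = np.stack([xx - cx, yy - cy, np.zeros_like(xx, dtype=float)], -1)
    nrm = np.linalg.norm(radial, axis=-1, keepdims=True)
    radial = np.divide(radial, nrm, out=np.zeros_like(radial), where=nrm > 0)

    data = np.ones(shape + (len(gtab),), dtype=float)
    bmat = gtab[["b", "gx", "gy", "gz"]].to_numpy(dtype=float)
    for ly in layers:
        sel2d = label_vol[:, :, 0] == ly.label
        md = ly.adc_table[min(ly.adc_table)]
        lam = _prolate_evals(md, ly.fa)
        if ly.orientation == "radial":
            e1_map = radial
        elif ly.orientation in _ORIENTATIONS:
            e1_map = np.broadcast_to(_ORIENTATIONS[ly.orientation],
                                     (nx, ny, 3)).copy()
        else:  # isotropic
            e1_map = np.broadcast_to(np.array([1.0, 0.0, 0.0]), (nx, ny, 3)).copy()
        for ivol, (bv, gx, gy, gz) in enumerate(bmat):
            if bv == 0:
                continue
            g = np.array([gx, gy, gz])
            proj = e1_map @ g  # cos angle to principal axis
            adc_dir = lam[1] + (lam[0] - lam[1]) * proj**2
            vol = np.where(sel2d, np.exp(-bv * adc_dir), data[:, :, 0, ivol])
            for z in range(nz):
                data[:, :, z, ivol] = np.where(sel2d, vol, data[:, :, z, ivol])
    if snr is not None:
        sigma = 1.0 / snr
        if noise == "rician":
            data = _rician(rng, data, sigma)
        else:
            data = data + rng.normal(0, sigma, data.shape)
    return DWIDataset(data=data, gtab=gtab, voxel_size=tuple(voxel_size),
                      mask=label_vol > 0)


def generate_group(n_per_group: int, *, eu: list[LayerSpec] | None = None,
                   ts: GroupModifiers | None = None,
                   subject_cv: float = 0.05, snr: float | None = 20.0,
                   shape=(32, 32, 4), voxel_size=(0.1, 0.1, 0.1),
                   seed: int = 0,
                   ) -> tuple[list[PhantomRealization], pd.DataFrame]:
    """Generate an Eu-like and a Ts-like cohort.

    Between-subject variation is a multiplicative lognormal factor (CV
    ``subject_cv``) applied per subject and layer to the whole ADC(f)
    table. Returns (realizations, manifest); manifest columns: subject,
    group, seed.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    eu = eu if eu is not None else eu_layers()
    ts_layers = (ts if ts is not None else ts_modifiers()).apply(eu)
    rng = np.random.default_rng(seed)
    sigma_ln = np.sqrt(np.log(1.0 + subject_cv**2))
    realizations, rows = [], []
    for group, base in (("Eu", eu), ("Ts", ts_layers)):
        for i in range(n_per_group):
            subj_layers = []
            for ly in base:
                m = float(rng.lognormal(-0.5 * sigma_ln**2, sigma_ln)) \
                    if subject_cv > 0 else 1.0
                subj_layers.append(replace(
                    ly, adc_table={f: v * m for f, v in ly.adc_table.items()}))
            subj_seed = int(rng.integers(0, 2**31 - 1))
            r = generate_phantom(subj_layers, shape=shape,
                                 voxel_size=voxel_size, snr=snr,
                                 seed=subj_seed)
            r.ground_truth["group"] = group
            realizations.append(r)
            rows.append({"subject": f"{group}{i + 1:02d}", "group": group,
                         "seed": subj_seed})
    return realizations, pd.DataFrame(rows)


def layer_tables_from_simulation(*, n_walkers: int = 20_000, seed: int = 0,
                                 ) -> dict[str, dict[float, float]]:
    """Recompute the default mechanistic layer ADC(f) tables with the
    Monte Carlo simulator (slow; the frozen module constants were produced
    this way at larger walker counts)."""
    from . import mc_sim, substrates
    from .grid import time_step_for

    specs = {
        "WM": substrates.cylinder_pack(
            1.0, substrates.separation_for_fraction("cylinder_pack", 0.65)),
        "IGL_PCL": substrates.sphere_pack(
            6.0, substrates.separation_for_fraction("sphere_pack", 0.39)),
        "ML_EGL": substrates.cylinder_pack(
            1.0, substrates.separation_for_fraction("cylinder_pack", 0.5)),
    }
    raw = {}
    for name, sub in specs.items():
        df = mc_sim.adc_spectrum(sub, n_walkers=n_walkers,
                                 time_step=time_step_for(sub), seed=seed)
        raw[name] = dict(zip(df["f_Hz"], df["ADC"]))
    # the WM/IGL ROI spans white matter and inner IGL: 50/50 signal mixture
    wm_igl = {f: float(-np.log(0.5 * np.exp(-raw["WM"][f])
                               + 0.5 * np.exp(-raw["IGL_PCL"][f])))
              for f in raw["WM"]}
    out = {"WM_IGL": wm_igl, "IGL_PCL": raw["IGL_PCL"],
           "ML_EGL": raw["ML_EGL"]}
    return {name: {f: float(np.round(v, 3)) for f, v in tab.items()}
            for name, tab in out.items()}
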