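# tdmri — time-dependent diffusion MRI of layered microstructure

Water diffusion measured at short diffusion times (t_d) is sensitive to
micron-scale structure: restricted water explores few barriers when t_d
is short and many when it is long, so the apparent diffusion coefficient
(ADC) falls as t_d grows. Oscillating-gradient (OG) encoding at frequency
f reaches t_d = 1/(4f) — milliseconds and below — while pulsed-gradient
(PG) encoding probes the long-t_d regime (t_d = Δ−δ/3). The frequency
dispersion of the ADC,

    ADC(f) = ΔADC·f + ADC0            (linear, slope ΔADC)
    ADC(f) = α·f^θ + ADC0             (power law, dispersion rate θ)

is a compact marker of cell and neurite density, well suited to the
cerebellar cortex, whose granule cells (~5–6 µm) match the diffusion
lengths l = √(2·D·t_d) ≈ 2–9 µm spanned by a 0–200 Hz protocol. Reduced
granule-cell packing — as in trisomic cerebellar hypoplasia — lowers
ΔADC.

This package is for researchers who want to simulate, fit, and
statistically compare such protocols without scanner data. It provides:

* `tdmri.waveforms` — PG/cosine-OG effective gradients, b-values
  (γ²∫q² dt), effective diffusion times, diffusion lengths;
* `tdmri.substrates` / `tdmri.mc_sim` — Monte Carlo random walks with
  specular reflection in periodic sphere/cylinder packings (numba
  kernels), yielding per-condition signals and ADCs;
* `tdmri.grid` — ΔADC over diameter × intracellular-fraction grids;
* `tdmri.phantom` — a synthetic layered "cerebellum" (WM/IGL, IGL/PCL,
  ML/EGL bands) with mechanistic ADC(f) tables, Rician noise, an
  optional DTI acquisition for direction-encoded-colour delineation, and
  euploid-like vs trisomic-like cohorts;
* `tdmri.adc_dti` / `tdmri.td_models` — ADC maps, tensor/FA/DEC maps,
  voxelwise ΔADC, pooled power-law fits;
* `tdmri.roi_stats` / `tdmri.study` — two-way ANOVA with Welch post hoc
  tests, volume/thickness ratios, and the end-to-end group study.

Numbered drivers under `analysis/` run the full story:
`01_protocol_quantities.py`, `02_microstructure_grid.py`,
`03_phantom_study.py`, `04_group_detection.py`, writing tables to
`results/`. A `tdmri` CLI exposes the same steps
(`phantom`, `simulate`, `adc`, `dti`, `tdfit`, `roistats`, `pipeline`,
`grid`).

## Worked example

```python
>>> from tdmri import make_og_cosine, effective_diffusion_time, diffusion_length
>>> w = make_og_cosine(G=1.05, freq=200, n_cycles=4)
>>> effective_diffusion_time(w)
1.25
>>> round(diffusion_length(2.0, 1.25), 1)
2.2
```

At 200 Hz the encoding probes 1.25 ms diffusion times — a 2.2 µm length
scale, inside a granule cell. Simulating a granule-cell-like substrate
(spheres, d = 8 µm, intracellular fraction 0.39) across the protocol:

```python
>>> from tdmri import substrates, mc_sim
>>> sub = substrates.sphere_pack(8.0, 1.1)
>>> df = mc_sim.adc_spectrum(sub, n_walkers=20000, seed=4)
>>> df[["condition", "f_Hz", "t_d_ms", "ADC", "SE"]]
  condition   f_Hz     t_d_ms       ADC        SE
0        PG    0.0  18.333333  0.711398  0.006697
1      OG50   50.0   5.000000  0.906106  0.007128
2     OG100  100.0   2.500000  1.274713  0.009776
3     OG200  200.0   1.250000  1.552938  0.013153
```

ADC rises from 0.71 µm²/ms at long t_d to 1.55 µm²/ms at 200 Hz — the
restricted pool looks progressively freer as the diffusion length drops
below the cell size. The linear dispersion slope of this spectrum,

```python
>>> from tdmri import fit_linear_td
>>> fit = fit_linear_td(dict(zip(df["f_Hz"], df["ADC"])))
>>> round(fit.delta_adc, 5), round(fit.adc0, 3)
(0.00432, 0.734)
```

gives ΔADC ≈ 4.3×10⁻³ µm²·ms⁻¹·Hz⁻¹. Across a diameter × fraction grid
(`analysis/02_microstructure_grid.py`) ΔADC grows with intracellular
fraction and peaks near 9 µm diameters — the scale the protocol's
diffusion lengths straddle — while neurite-calibre cylinders disperse
weakly and only trend upward with diameter and packing.

The synthetic group study (`analysis/03_phantom_study.py`,
`04_group_detection.py`) generates five euploid-like and five
trisomic-like subjects (SNR 20), where the trisomic spec scales layer
dispersion by 0.8 in the granule-cell-containing layers and thins them.
The analysis recovers the encoded phenotype: no PG-ADC group difference,
an OG-ADC deficit growing with f, reduced ΔADC in the modified layers,
and a smaller cerebellum — in every one of 20 replicate studies.

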