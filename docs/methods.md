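# Methods

This package implements a diffusion-time (t_d)–dependent diffusion-MRI
analysis chain for layered cerebellar microstructure, together with the
Monte Carlo machinery and synthetic data needed to exercise it without
scan data. This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic experiments do
and do not demonstrate.

## Diffusion encodings and protocol quantities

Two encodings are modelled through their *effective* gradient (the 180°
refocusing pulse enters as a sign flip of the second lobe; no RF is
simulated):

* **Pulsed gradient (PG):** two ideal rectangles of duration δ whose
  leading edges are Δ apart. Default timing δ/Δ = 5/20 ms. No ramps are
  modelled — the protocol quantities are reported at a precision far
  above any slew-rate correction.
* **Cosine oscillating gradient (OG):** two cosine-modulated lobes of
  duration n/f each (integer cycles, so each lobe self-refocuses), pure
  cosine with rectangular envelope. The protocol uses 50/100/200 Hz with
  1/2/4 cycles, so every lobe lasts 20 ms.

Unit system: time in ms, length in µm, gradient in T/m, γ =
2.6752×10⁸ rad·s⁻¹·T⁻¹; b-values in ms/µm² (≡10³ s/mm²). b is computed by
exact integration of the piecewise-constant sampled waveform,
b = γ²∫q², and matches the rectangular-PG and cosine-OG closed forms to
sampling accuracy. Amplitudes for b = 1 ms/µm² stay below the 1.5 T/m
hardware bound assumed for the emulated preclinical system; exceeding the
bound warns rather than fails.

Effective diffusion times are Δ−δ/3 for PG (18.3 ms) and 1/(4f) for
cosine OG (5, 2.5, 1.25 ms), and the probed length scale is the 1-D
diffusion length l = √(2·D·t_d) — 8.9 µm down to 2.2 µm at
D = 2 µm²/ms. These follow the printed protocol values; the square-root
form is the only dimensionally consistent reading and reproduces every
printed length.

## Substrates and the random walk

Restricting geometries are periodic square packings with one impermeable
obstacle per cell (edge k·d): spheres (cell bodies) with fraction
π/(6k³), infinite parallel cylinders (neurites) with fraction π/(4k²).
The cylinder upper fraction at k = 1.1 is π/4.84 ≈ 0.65 by this closed
form, which we treat as authoritative.

Walkers take Gaussian steps (per-axis scale √(2·D0·dt)) and reflect
specularly off membranes, with multiple reflections per step resolved
exactly; a step needing more than 10 bounces is rejected (the walker
stays; occurrences are counted and are vanishingly rare at the step-size
limits used). After each bounce the walker is nudged 10⁻⁶·d off the
surface to avoid re-detection. Collision search exploits the cubic
Voronoi property: the nearest obstacle centre is the own-cell centre, so
a step shorter than its distance to the nearest membrane advances freely;
only near-surface steps scan the 27 (9 in 2-D) neighbouring cells.
Impermeability is exact: compartment membership is conserved bit-for-bit
over millions of steps (tested).

The spin phase along direction u is φ = γ·Σ g(t_i)·(x_i·u)·dt with
post-step positions; the per-walker q-vector Σ g·x·dt is accumulated so
*any* direction can be evaluated after the walk. The signal is the
ensemble mean of cos φ (real channel), which is free of the Rician floor
that magnitude averaging adds at finite walker counts. ADC is taken from
the single (b0, b) pair, −ln(E)/b, matching a two-point acquisition. The
exact discrete-walk expectation of the free-diffusion ADC equals D0 for
these waveforms (verified analytically against the step covariance), so
the estimator is unbiased, with Monte Carlo SE reported from the
per-walker spread.

Key defaults: D0 = 2 µm²/ms; b = 1 ms/µm²; time step capped at 0.005 ms
and reduced as d²/(600·D0) so the RMS step stays below d/10; walkers
initialised uniformly over one unit cell ("everywhere"), with intra-/
extra-only options for calibration experiments. All conditions share the
walker trajectories (common random numbers), which substantially
stabilises condition *differences* such as the dispersion slope; the
slope's uncertainty is estimated by a walker bootstrap.

Validation anchors:

* free diffusion reproduces D0 within 3 SE at every condition;
* rescaling lengths ×2 and times ×4 (gradient ÷8) leaves the signal
  bit-identical (exact scaling invariance);
* the early time-dependence of intra-sphere walkers follows the 3-D
  short-time surface-to-volume expansion
  D(t)/D0 = 1 − (4/(9√π))·(S/V)·√(D0·t). Note the 1/d dimension factor
  in the coefficient: Monte Carlo convergence tests (deficit ratio → 1.00
  as t → 0) confirm the 3-D form. D(t) is measured as ⟨|x−x0|²⟩/(6t),
  the narrow-pulse-limit diffusivity, which is the quantity the expansion
  describes. Because the short-time deficit is only ~1% of D0, it is
  estimated with a paired common-random-numbers design (the same steps
  propagated freely and through the substrate): walkers that never meet a
  membrane cancel exactly, cutting the deficit's Monte Carlo error to a
  few percent at 10⁵ walkers.

## Dispersion models

ADC versus oscillating frequency (PG mapped to f = 0) is summarised two
ways:

* **Linear:** ADC(f) = ΔADC·f + ADC0 by OLS; ΔADC (µm²·ms⁻¹·Hz⁻¹) is the
  scalar degree of t_d-dependence. Frequencies are carried in Hz, so
  tissue-like slopes are ~10⁻³; display layers may scale by 10³.
* **Power law:** ADC(f) = α·f^θ + ADC0 by bounded nonlinear least
  squares (α ≥ 0, θ ∈ [0,2], ADC0 > 0), initialised from the linear fit
  (θ₀ = 1, α₀ = ΔADC). θ fixed at 1 reproduces the linear estimates
  exactly (nesting). Power-law fitting is done on pooled group samples:
  with four frequencies and three parameters, per-subject fits are
  unstable (bootstrapped θ spread exceeds the pooled one — tested), so
  per-subject fitting sits behind an explicit flag. f = 0 points anchor
  ADC0 in both models; flat data flags θ as unidentifiable instead of
  raising.

The θ bounds cover the structural-disorder range discussed in the
dispersion literature and are exposed as a configuration knob.

## Synthetic layered phantom

The phantom reduces a mid-sagittal cerebellar folium to concentric 2-D
bands extruded to a thin slab: WM/IGL core (label 1), IGL/PCL rim (2),
ML/EGL outer rim (3), free-water background. The folium radius partitions
1/2 : 1/4 : 1/4; layer-thickness multipliers shrink bands (and the whole
folium — hypoplasia) without renormalisation.

Each layer carries a ground-truth ADC(f) table stored losslessly next to
the images. The default tables are **mechanistic** — computed by the
bundled simulator at 25k walkers and frozen as constants:

| layer  | substrate                                   | ADC(f) µm²/ms at 0/50/100/200 Hz |
|--------|---------------------------------------------|----------------------------------|
| WM_IGL | 50/50 signal mix: cylinder d=1 µm frac 0.65 + the IGL sphere pack | 0.450/0.484/0.564/0.669 |
| IGL_PCL| sphere d=6 µm, fraction 0.39                | 0.690/0.779/1.013/1.376 |
| ML_EGL | cylinder d=1 µm, fraction 0.5               | 0.445/0.443/0.456/0.450 |

The WM/IGL ROI is modelled as a mixture because it spans white matter
*and* the inner granular layer; granule-cell restriction is what gives it
measurable dispersion. The molecular-layer table is essentially flat at
these frequencies — sub-micron neurites are fully coarse-grained — which
reproduces the strong ΔADC contrast between granular and molecular
layers.

Signals follow S = S0·exp(−b·ADC_layer(f)) per condition and direction
(S0 = 1), with Rician noise at a stated b0 SNR (Gaussian available for
debugging); SNR 20 is the working default. An optional tensor acquisition
(30 directions, b = 2 ms/µm², 3 b0) gives each layer a prolate tensor
oriented superior–inferior (WM core), radially in-plane (IGL/PCL), or
through-plane (ML/EGL), so the direction-encoded colour map shows the
green/red/blue three-band topology used to delineate the ROIs.

**Trisomic-like (Ts) group.** The Ts specification scales the
frequency-dependent part of the layer tables by 0.8 in WM/IGL and
IGL/PCL (reduced granule-cell/neurite packing lowers dispersion while
leaving the long-t_d ADC almost unchanged), thins IGL/PCL to 0.85 and
ML/EGL to 0.96, and leaves the molecular-layer dispersion untouched. The
0.8 factor is motivated by the ~80–85% layer ratios of the modelled
phenotype, not fitted to any measured outcome. Between-subject variation
is a lognormal multiplier (CV 5%) per subject and layer applied to the
whole table. Cohort sizes default to 5 per group (neonatal design).

This construction is deliberately idealised: no anatomical foliation, no
partial-volume mixing beyond voxel-wise layer assignment, no EPI/GRASE
artefacts, no registration errors, no fixation effects. Passing tests
therefore demonstrate the *analysis chain* (mapping, dispersion fitting,
group statistics) and the *simulated physics*, not robustness to real
acquisition confounds.

## ADC/DTI mapping

Per-direction ADC_i = ln(S̄0/S_i)/b with all b0 volumes averaged before
the log; the mean map is the arithmetic mean over directions (equivalent
at this b to trace/3 for a uniform scheme; a geometric-mean option
exists). Non-positive signals mask the voxel and are counted. The tensor
fit is standard log-linear least squares of ln(S/S̄0) = −b·gᵀDg (≥6
non-collinear directions enforced by rank check), eigenvalues sorted
descending, negatives clamped to zero with a counter, FA from the
normalised eigenvalue dispersion. DEC colours: red = anterior–posterior
(x), green = superior–inferior (y), blue = through-plane (z), channels
|e1|·FA. The 10- and 30-direction schemes are fixed electrostatic-
repulsion sets shipped as constants; at b = 1 the direction-averaged ADC
is scheme-insensitive to within noise.

## Group statistics

ADC is compared by two-way fixed-effects ANOVA (group × frequency; for
ΔADC, group × ROI) with type-II sums of squares, followed by post hoc
Welch (unequal-variance) t-tests at each level — Welch uniformly, since
that is the stated convention for the volumetric table and nothing argues
for pooled variance elsewhere. No multiple-testing correction by default
(mirroring the reporting convention); Holm is available. Volume
reductions are 100·(1 − Ts/Eu), reported rounded to integer percent with
floats retained. Thickness ratios are pairwise Ts/Eu percentages with
SEM.

## Microstructure-grid experiment

The grid driver sweeps diameter × intracellular fraction and fits ΔADC
per cell. Sizes were scaled to what one CPU resolves in minutes while
keeping the orderings decisive:

* spheres: d ∈ {4, 9, 16} µm × fractions {0.15, 0.25, 0.39}, 12k
  walkers. Found: ΔADC increases with fraction at every diameter and
  peaks at the interior diameter (9 µm) for every fraction — the peak
  sits where the probed diffusion lengths (2.2–8.9 µm) straddle the cell
  size.
* cylinders: d ∈ {1.2, 1.8, 2.4} µm × fractions {0.35, 0.5, 0.65}, 16k
  walkers. Sub-micron cylinders are almost fully coarse-grained at
  50–200 Hz, so their dispersion is tiny (ΔADC ~10⁻⁵, occasionally
  slightly negative in the periodic lattice at low fraction) and
  fraction contrasts drown in Monte Carlo noise at feasible walker
  counts. The grid therefore extends to 2.4 µm, where the four-frequency
  window resolves the orderings; the diameter trend is tested on
  fraction-averaged ΔADC and the fraction trend on the diameter-averaged
  0.35 → 0.65 contrast, both pooled across the grid. Within this grid
  ΔADC increases with both diameter and fraction.

ΔADC uncertainties per grid cell come from a walker bootstrap on the
shared trajectories.

## Known limitations

* Periodic (crystalline) packings carry coherent structure absent in
  disordered tissue; near-coarse-grained cylinder lattices can show
  marginally negative dispersion slopes.
* The phantom's layers are homogeneous; no partial-volume or exchange.
* Walker counts and time steps trade precision for single-CPU runtime;
  all stochastic acceptance checks state the sizes used and test
  orderings or tolerance bands, not figure-level magnitudes.
* The two-point ADC estimator inherits Rician bias at low SNR; the
  phantom tests bound it against a numeric oracle rather than correcting
  it, as the analysis chain under study does not correct it either.
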