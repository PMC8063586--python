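"""Monte Carlo ΔADC over cell- and neurite-like substrate grids.

Drives the random-walk simulator over square-packed impermeable sphere
(granule-cell-like) and cylinder (neurite-like) substrates across a
diameter × intracellular-fraction grid, fits the linear dispersion slope
ΔADC per cell, and writes tidy CSVs. The headline behaviour: for sphere
packs ΔADC grows with intracellular fraction and peaks at diameters
comparable to the probed diffusion lengths; for cylinder packs ΔADC grows
with both diameter and intra-neurite fraction.

Writes results/grid_spheres.csv and results/grid_cylinders.csv.
Run with --fast for a coarse quick look.
"""

import argparse
from pathlib import Path

from tdmri.grid import simulate_grid

OUT = Path(__file__).resolve().parents[1] / "results"

SPHERE_DIAMETERS = [4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0]
SPHERE_FRACTIONS = [0.15, 0.25, 0.39]
CYL_DIAMETERS = [1.2, 1.8, 2.4]
CYL_FRACTIONS = [0.35, 0.5, 0.65]


def main(fast: bool = False, seed: int = 0):
    OUT.mkdir(exist_ok=True)
    nw_s, nw_c = (4000, 4000) if fast else (12000, 12000)
    sph_d = [4.0, 9.0, 16.0] if fast else SPHERE_DIAMETERS

    spheres = simulate_grid("sphere_pack", sph_d, SPHERE_FRACTIONS,
                            n_walkers=nw_s, seed=seed)
    spheres.to_csv(OUT / "grid_spheres.csv", index=False)
    print("spheres:")
    print(spheres[["diameter_um", "fraction", "delta_adc",
                   "delta_adc_se"]].to_string(index=False))
    peak = spheres.loc[spheres.groupby("fraction")["delta_adc"].idxmax()]
    print("\nΔADC peaks at diameters:",
          dict(zip(peak["fraction"], peak["diameter_um"])))

    cylinders = simulate_grid("cylinder_pack", CYL_DIAMETERS, CYL_FRACTIONS,
                              n_walkers=nw_c, seed=seed)
    cylinders.to_csv(OUT / "grid_cylinders.csv", index=False)
    print("\ncylinders:")
    print(cylinders[["diameter_um", "fraction", "delta_adc",
                     "delta_adc_se"]].to_string(index=False))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--fast", action="store_true")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    main(fast=args.fast, seed=args.seed)
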