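"""Generate the synthetic study data: landscape, observations, temperatures.

Builds a 20 x 20 cell equal-area landscape (50 km cells over central
Europe), lays a ground-truth flowering surface over it (20 d per 1000 m
elevation, 4 d per degree latitude, 0.5 d per degree longitude, a 7-day
delay in the second year), samples spatially clustered presence-only
observations for two years, and synthesises daily temperature fields with
the first year uniformly 2 degC warmer. Raw tables go to scratch/ (they are
large and fully regenerable from the seed); a compact truth summary goes to
results/.
"""

import argparse
import json
from pathlib import Path

from phenoshift import synthetic as synth
from phenoshift.io import write_temperature_netcdf

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    scratch = ROOT / "scratch" / "analysis"
    results = ROOT / "results"
    scratch.mkdir(parents=True, exist_ok=True)
    results.mkdir(parents=True, exist_ok=True)

    grid, cov = synth.make_landscape(seed=seed)
    surface = synth.TrueSurface()  # Hopkins-style gradients, 7-day year shift
    effort = synth.EffortModel()  # clustered effort, ~60 obs/cell on average
    climate = synth.SyntheticClimate()

    medians = synth.make_true_surface(cov, surface)
    obs = synth.sample_observations(
        medians, effort, surface, [2020, 2021], seed=seed + 1, grid=grid
    )
    obs.to_csv(scratch / "observations.csv")
    cov.to_csv(scratch / "covariates.csv", index=False)

    for i, year in enumerate((2020, 2021)):
        cube = synth.synth_temperature(
            cov, climate, year, seed=seed + 100 + i,
            warming_offset=2.0 if year == 2020 else 0.0,
        )
        write_temperature_netcdf(cube, scratch / f"temperature_{year}.nc")

    summary = {
        "seed": seed,
        "n_cells": int(grid.n_cells),
        "n_observations": int(len(obs.frame)),
        "per_year": obs.frame.groupby("year").size().to_dict(),
        "true_surface": obs.truth["surface"],
        "warming_offset_2020_degC": 2.0,
    }
    with open(results / "simulation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    print(f"landscape: {grid.n_cols} x {grid.n_rows} cells of "
          f"{grid.cell_size/1000:.0f} km ({grid.n_cells} cells)")
    print(f"observations: {len(obs.frame)} over 2 years "
          f"({summary['per_year']})")
    print(f"raw tables in {scratch}, summary in {results/'simulation_summary.json'}")


if __name__ == "__main__":
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=1)
    main(**vars(p.parse_args()))
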