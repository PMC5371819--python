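#!/usr/bin/env python
"""Reconstruct the 2D free-energy surface of the coupled landscape.

The landscape emulates the stepped swiveling picture: along the first
coordinate a tilted sawtooth, along the second a harmonic channel whose
center stays constant over the first part of the range and then moves
linearly — so minima first line up at constant y, then continue diagonally.
Reports the basin list and whether the channel center is tracked.
"""

from pathlib import Path

import numpy as np

from swiveldyn.pipeline import RunConfig, run_pmf_analysis

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    config = RunConfig(out_dir=str(RESULTS / "pmf_2d"),
                       wham_manifest=str(RESULTS / "windows_2d" / "manifest.json"),
                       grid_range=[[25.0, 43.0], [28.0, 46.0]],
                       bin_width=0.5, bootstrap_resamples=20, seed=7)
    report = run_pmf_analysis(config)
    print(f"WHAM converged in {report.stages['wham']['iterations']} "
          f"iterations over a "
          f"{report.stages['load_windows']['n_windows']}-window 2D set")
    basins = sorted((m for m in report.stages["features"]["minima"]
                     if m["free_energy"] <= 3.0),
                    key=lambda m: m["position"][0])
    print(f"\nbasins with PMF <= 3 kcal/mol:")
    print(f"{'x (A)':>8} {'y (A)':>8} {'PMF (kcal/mol)':>15}")
    for m in basins:
        x, y = m["position"]
        print(f"{x:8.2f} {y:8.2f} {m['free_energy']:15.3f}")
    xs = np.array([m["position"][0] for m in basins])
    ys = np.array([m["position"][1] for m in basins])
    flat = ys[xs <= 32.0]
    diag = ys[xs > 32.0]
    if len(flat) >= 2 and len(diag) >= 2:
        print(f"\nchannel center: y spread {np.ptp(flat):.2f} A below the "
              f"coupling threshold, then drifts {ys.max() - diag.min():.1f} A"
              " diagonally beyond it")
    print(f"tables under {RESULTS / 'pmf_2d'}")


if __name__ == "__main__":
    main()
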