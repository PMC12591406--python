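#!/usr/bin/env python
"""Extract per-identification habitat covariates and the effort grid.

Samples water depth, distance to shore, and barrier-aware water distance to
the 200 m shelf-break isobath at every daily-encounter location, expands to
one row per identification, and bins survey tracks plus sightings into a
5 km relative-effort fishnet; also profiles shelf width every 3 km along
the isobath.
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from orcasoc import encounters, seascape


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--network", type=Path, default=Path("results/network"))
    ap.add_argument("--out", type=Path, default=Path("results/geospatial"))
    ap.add_argument("--lon0", type=float, default=-125.0)
    ap.add_argument("--lat0", type=float, default=40.0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    warnings.simplefilter("ignore")

    grid = seascape.read_ascii_grid(args.data / "seascape.asc")
    daily, _ = encounters.read_encounters(args.network / "daily_encounters.csv")
    retained = set(pd.read_csv(args.network / "sri_matrix.csv", index_col=0).index)

    cov = seascape.covariate_table(daily, grid, args.lon0, args.lat0, retained)
    cov.to_csv(args.out / "covariates.csv", index=False)

    tracks_df = pd.read_csv(args.data / "tracks.csv")
    tracks = [g[["x", "y"]].to_numpy() for _, g in tracks_df.groupby("track_id")]
    x, y = seascape.lonlat_to_xy(np.array([r.lon for r in daily]),
                                 np.array([r.lat for r in daily]),
                                 args.lon0, args.lat0)
    effort, xe, ye = seascape.effort_grid(tracks, np.column_stack([x, y]))
    np.savetxt(args.out / "effort_grid.csv", effort, delimiter=",", fmt="%d")

    profile = seascape.shelf_width_profile(grid)
    pd.DataFrame([{"x": p[0], "y": p[1], "width_km": w} for p, w in profile]).to_csv(
        args.out / "shelf_width_profile.csv", index=False)

    with open(args.out / "summary.json", "w") as fh:
        json.dump({"n_identifications": len(cov),
                   "n_effort_points": int(effort.sum()),
                   "n_shelf_samples": len(profile)}, fh, indent=1)
    widths = [w for _, w in profile]
    print(f"{len(cov)} identifications with covariates; shelf width spans "
          f"{min(widths):.1f}-{max(widths):.1f} km over {len(profile)} samples; "
          f"{int(effort.sum())} effort points binned")


if __name__ == "__main__":
    main()
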