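#!/usr/bin/env python
"""Regress association strength on habitat and geography similarity (MRQAP).

Builds dyadic similarity matrices from per-individual covariate means
(depth, distance to shore, distance to the shelf break, and combined
geographic proximity), fits the multiple matrix regression with QAP
permutation inference, and — because the habitat predictors are strongly
collinear in this system — also fits each habitat predictor alone.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from orcasoc import association, mrqap


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--network", type=Path, default=Path("results/network"))
    ap.add_argument("--covariates", type=Path,
                    default=Path("results/geospatial/covariates.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/mrqap"))
    ap.add_argument("--n-perm", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    frame = pd.read_csv(args.network / "sri_matrix.csv", index_col=0)
    ids = list(frame.index)
    assoc = association.AssociationMatrix(
        ids=ids, sri=frame.to_numpy(),
        counts=association.PairCounts(ids=ids, X=np.eye(len(ids), dtype=int),
                                      n=np.ones(len(ids), dtype=int)))
    cov = pd.read_csv(args.covariates)
    means = cov.replace([np.inf, -np.inf], np.nan).groupby("individual")[
        ["depth_m", "dist_shore_km", "dist_shelf_km", "lat", "lon"]].mean().reindex(ids)

    preds = [
        mrqap.build_predictor(means["depth_m"].to_numpy(), "depth_similarity"),
        mrqap.build_predictor(means["dist_shore_km"].to_numpy(), "shore_distance_similarity"),
        mrqap.build_predictor(means["dist_shelf_km"].to_numpy(), "shelf_distance_similarity"),
        mrqap.geographic_predictor(means["lat"].to_numpy(), means["lon"].to_numpy()),
    ]
    multi = mrqap.fit_mrqap(assoc, preds, n_perm=args.n_perm, seed=args.seed)
    multi.to_json(args.out / "mrqap_multiple.json")

    singles = {}
    for p in preds[:3]:
        res = mrqap.fit_mrqap(assoc, [p], n_perm=args.n_perm, seed=args.seed)
        singles[p.name] = {"beta": float(res.beta[0]), "p": float(res.p_perm[0])}
    (args.out / "mrqap_single_predictor.json").write_text(json.dumps(singles, indent=1))

    print(f"multiple MRQAP: adj R^2 = {multi.adj_r2:.3f}, F = {multi.f_stat:.0f}, "
          f"{args.n_perm} QAP permutations")
    for name, beta, p in zip(multi.predictor_names, multi.beta, multi.p_perm):
        print(f"  {name:28s} beta = {beta:+.3f}  p = {p:.3g}")
    print("single-predictor habitat similarity fits:")
    for name, d in singles.items():
        print(f"  {name:28s} beta = {d['beta']:+.3f}  p = {d['p']:.3g}")


if __name__ == "__main__":
    main()
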