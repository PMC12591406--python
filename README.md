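# orcasoc

Social-network and habitat analysis of photo-identified killer whale
encounters.

Mammal-eating (transient) killer whales range along the northeast Pacific
coast in small matrilineal groups that meet and part fluidly. Whether such
a population is one social unit or several is not visible from any single
sighting: it emerges from thousands of photo-identification records — who
was seen with whom, where, and over what habitat. `orcasoc` implements the
full analysis chain that turns raw encounter tables and a bathymetry raster
into that answer, for ecologists working with gambit-of-the-group
photo-identification data:

1. **Standardization** — merge multi-source reports into daily encounters
   (first-sighting location, subset absorption), require complete group
   identification, and drop individuals seen fewer than 3 times.
2. **Association network** — the simple ratio index per pair,
   `SRI_ij = X_ij / (X_ij + Y_i + Y_j)`, where `X_ij` counts groups holding
   both whales and `Y_i`, `Y_j` groups holding one without the other; the
   gambit of the group treats all members of a photographed group as
   associating.
3. **Community delineation** — UPGMA clustering on `1 − SRI`, the
   cophenetic correlation coefficient (CCC) as a tree-fidelity check, and
   the dendrogram cut maximizing the weighted Newman modularity
   `Q = Σ_c [w_c/W − (s_c/2W)²]`.
4. **Geospatial covariates** — water depth, Euclidean distance to shore,
   and *water* distance to the 200 m shelf-break isobath computed as a
   multi-source shortest path over water cells only, so land acts as a
   barrier; shelf-width profiles along the isobath and 5 km effort grids.
5. **MRQAP** — matrix regression of association on dyadic habitat- and
   geography-similarity matrices, with significance from quadratic
   assignment (row/column) permutations of the response.
6. **Habitat envelopes** — empirical 90% quantile thresholds (inner
   community: distance to shore; outer community: |distance to shelf
   break|) and the overlap zones they imply on the seascape.

Because real sighting archives are hard to share, the package ships a
ground-truthed simulator (`orcasoc.synth`) of the whole study system — a
north-to-south narrowing continental shelf, two latent subpopulations with
nearshore vs. shelf-break spatial kernels, matrilines of 2–10 whales
(mode 4), daily fission–fusion grouping with rare cross-subpopulation
mixing, and spatially heterogeneous detection — so that every stage of the
chain is testable against known truth.

## Worked example

The `analysis/` scripts run the study on the default synthetic system
(≈160 whales, 365 days):

```sh
python analysis/01_simulate_system.py --seed 1
python analysis/02_build_network.py
python analysis/03_delineate_communities.py
python analysis/04_habitat_covariates.py
python analysis/05_mrqap_regression.py
python analysis/06_habitat_envelopes.py
```

which prints, stage by stage:

```
simulated 163 whales (79 inner / 84 outer), 454 raw encounter records over 365 days -> results/synthetic
454 raw records -> 422 daily encounters (32 duplicate reports absorbed); network kept 163 whales, excluded 0 seen <3 times
CCC = 0.988, Q_max = 0.494 at 2 communities (sizes [84, 79]); ARI vs planted subpopulations = 1.000
6172 identifications with covariates; shelf width spans 13.0-50.0 km over 27 samples; 847 effort points binned
multiple MRQAP: adj R^2 = 0.289, F = 2678, 1000 QAP permutations
...
inner community averages 2.5 km from shore; rank-sum shore-distance test U = 162510, p = 0
90% envelopes: inner within 4.4 km of shore, outer within 9.0 km of the shelf break; 8 overlap cells where the shelf narrows
mixed associations: 4 encounters (0.9% of 422); 66 predation events tabulated
```

Reading the output: the dendrogram represents the association matrix almost
perfectly (CCC = 0.988), the modularity-best cut splits the network into
exactly the two planted subpopulations (adjusted Rand index 1.0,
Q_max ≈ 0.49 — near the 0.5 ceiling for two balanced communities), fewer
than 1% of encounters mix the two communities, and the fitted envelopes
recover the nearshore vs. shelf-break habitat split, overlapping only where
the shelf narrows toward shore.

The same pipeline runs from a single config through the CLI
(`orcasoc run-all --config cfg.yaml --out-dir out`) or
`orcasoc.pipeline.run_all`; real data enter as a CSV/XLSX encounter table
plus an ESRI ASCII elevation grid.

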