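"""Cluster-wise habitat use: summaries, tests, envelopes, mixed associations.

The unit of analysis is the *identification* — one individual detected in
one daily encounter — matching how photo-identification studies count
habitat use.  Habitat envelopes are empirical quantile thresholds: the
inner-coast envelope is the q-quantile (default 0.90) of identifications'
distance to shore, the outer-coast envelope the q-quantile of |signed
distance to the shelf break|.  By construction at least a fraction q of the
fitting identifications fall inside their own envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .encounters import EncounterRecord
from .seascape import SeascapeGrid, classify_cells, isobath_distance_field, shore_distance_field

__all__ = [
    "HabitatSummary",
    "EnvelopeModel",
    "summarize",
    "rank_sum_test",
    "fit_envelope",
    "envelope_zones",
    "mixed_associations",
    "prey_composition",
]


@dataclass
class HabitatSummary:
    """Per-cluster summary of one habitat variable over identifications."""

    cluster: int
    variable: str
    mean: float
    se: float
    min: float
    max: float
    n: int
    se_defined: bool = True


@dataclass
class EnvelopeModel:
    """Quantile habitat envelope for the inner/outer subpopulations."""

    inner_shore_threshold_km: float
    outer_shelf_threshold_km: float
    q: float = 0.90


def summarize(
    covariates: pd.DataFrame,
    partition: dict[str, int],
    variable: str,
    cluster_col: str = "individual",
) -> list[HabitatSummary]:
    """Mean, SE (= sd/sqrt(n)), min, max, n of ``variable`` per cluster.

    ``covariates`` has one row per identification; cluster membership comes
    from ``partition`` via the ``cluster_col`` id column.  Empty clusters
    are omitted with a warning; a single-value cluster reports SE 0 with
    ``se_defined=False``.
    """
    df = covariates.copy()
    df["_cluster"] = df[cluster_col].map(partition)
    missing = df["_cluster"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} identifications without cluster label dropped", stacklevel=2)
        df = df[~missing]
    out: list[HabitatSummary] = []
    for cluster in sorted(set(partition.values())):
        vals = df.loc[df["_cluster"] == cluster, variable].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            warnings.warn(f"cluster {cluster}: no identifications for {variable}", stacklevel=2)
            continue
        n = len(vals)
        if n > 1:
            se = float(np.std(vals, ddof=1) / np.sqrt(n))
            se_defined = True
        else:
            se = 0.0
            se_defined = False
        out.append(
            HabitatSummary(
                cluster=cluster,
                variable=variable,
                mean=float(np.mean(vals)),
                se=se,
                min=float(np.min(vals)),
                max=float(np.max(vals)),
                n=n,
                se_defined=se_defined,
            )
        )
    return out


def rank_sum_test(x, y) -> tuple[float, float, float]:
    """Wilcoxon/Mann-Whitney rank-sum test with midranks for ties.

    Returns ``(U, W, p)`` where U is the Mann-Whitney statistic for the
    first sample, W its rank sum, and p a two-sided p-value: exact by full
    enumeration of rank assignments when n+m <= 12, otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    Two identical samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _stats.rankdata(pooled)
    w = float(ranks[:n].sum())
    u = w - n * (n + 1) / 2.0

    if np.ptp(pooled) == 0:
        return u, w, 1.0

    if n + m <= 12:
        # exact two-sided p by enumerating all C(n+m, n) assignments of the
        # pooled (midranked) values to the first sample
        mid = n * m / 2.0
        obs_dev = abs(u - mid)
        count = 0
        total = 0
        for idx in combinations(range(n + m), n):
            w_star = ranks[list(idx)].sum()
            u_star = w_star - n * (n + 1) / 2.0
            if abs(u_star - mid) >= obs_dev - 1e-9:
                count += 1
            total += 1
        return u, w, count / total

    res = _stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, w, float(res.pvalue)


def fit_envelope(
    covariates: pd.DataFrame,
    partition: dict[str, int],
    inner_label: int,
    outer_label: int,
    q: float = 0.90,
    cluster_col: str = "individual",
) -> EnvelopeModel:
    """Fit the quantile habitat envelope.

    Thresholds are the empirical q-quantiles (linear interpolation between
    order statistics) of the inner cluster's ``dist_shore_km`` and the outer
    cluster's ``abs(signed_shelf_km)`` over identifications.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    df = covariates.copy()
    df["_cluster"] = df[cluster_col].map(partition)
    inner = df.loc[df["_cluster"] == inner_label, "dist_shore_km"].dropna().to_numpy()
    outer = np.abs(df.loc[df["_cluster"] == outer_label, "signed_shelf_km"].dropna().to_numpy())
    outer = outer[np.isfinite(outer)]
    if len(inner) == 0 or len(outer) == 0:
        raise ValueError("both clusters must have identifications to fit the envelope")
    return EnvelopeModel(
        inner_shore_threshold_km=float(np.quantile(inner, q)),
        outer_shelf_threshold_km=float(np.quantile(outer, q)),
        q=q,
    )


def envelope_zones(grid: SeascapeGrid, envelope: EnvelopeModel, level_m: float = 200.0) -> np.ndarray:
    """Label water cells by envelope membership.

    Returns an integer raster: 0 = neither, 1 = inner only, 2 = outer only,
    3 = overlap; land cells are -1.  A cell is inner when its shore distance
    is within the inner threshold, outer when |signed shelf distance| is
    within the outer threshold.
    """
    land = classify_cells(grid)
    shore_km = shore_distance_field(grid)
    _, signed_km = isobath_distance_field(grid, level_m)
    inner = (~land) & (shore_km <= envelope.inner_shore_threshold_km)
    outer = (~land) & np.isfinite(signed_km) & (np.abs(signed_km) <= envelope.outer_shelf_threshold_km)
    zones = np.zeros(grid.shape, dtype=np.int8)
    zones[inner] = 1
    zones[outer] = 2
    zones[inner & outer] = 3
    zones[land] = -1
    return zones


def mixed_associations(
    records: list[EncounterRecord],
    partition: dict[str, int],
) -> tuple[int, float, list[EncounterRecord]]:
    """Count encounters whose identified members span more than one cluster.

    Returns ``(count, proportion, roster)`` over all retained encounters;
    individuals absent from the partition (filtered out) are ignored.
    """
    mixed: list[EncounterRecord] = []
    total = 0
    for rec in records:
        labels = {partition[i] for i in rec.individuals if i in partition}
        if not labels:
            continue
        total += 1
        if len(labels) > 1:
            mixed.append(rec)
    proportion = len(mixed) / total if total else 0.0
    return len(mixed), proportion, mixed


def prey_composition(
    records: list[EncounterRecord],
    partition: dict[str, int],
) -> pd.DataFrame:
    """Predation-event composition per cluster.

    An encounter's predation events are attributed to the cluster of its
    identified members (mixed encounters count toward each cluster present).
    Returns a tidy table (cluster, prey_species, count, percent); percents
    sum to 100 within each cluster up to rounding.  Clusters without
    predations are omitted with a warning.
    """
    counts: dict[int, dict[str, int]] = {}
    for rec in records:
        if not rec.predations:
            continue
        labels = {partition[i] for i in rec.individuals if i in partition}
        for label in labels:
            bucket = counts.setdefault(label, {})
            for species, k in rec.predations:
                bucket[species] = bucket.get(species, 0) + k
    rows = []
    for cluster in sorted(set(partition.values())):
        bucket = counts.get(cluster)
        if not bucket:
            warnings.warn(f"cluster {cluster}: no predation events recorded", stacklevel=2)
            continue
        total = sum(bucket.values())
        for species in sorted(bucket):
            rows.append(
                {
                    "cluster": cluster,
                    "prey_species": species,
                    "count": bucket[species],
                    "percent": 100.0 * bucket[species] / total,
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "prey_species", "count", "percent"])
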