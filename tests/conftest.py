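"""Shared fixtures and independent oracles for the test suite.

Oracles here deliberately avoid the package's own computation paths:
brute-force per-pair recounts for the association index, a heapq Dijkstra
for grid water distances, and a double-loop modularity sum.
"""

from __future__ import annotations

import datetime as dt
import heapq
import itertools

import numpy as np
import pytest

from orcasoc.encounters import EncounterRecord


# --------------------------------------------------------------------------
# record builders
# --------------------------------------------------------------------------

def make_record(
    eid: str,
    date: str,
    ids,
    time: str = "09:00",
    lon: float = -125.0,
    lat: float = 48.0,
    predations=(),
    all_identified: bool = True,
) -> EncounterRecord:
    ids = frozenset(ids)
    return EncounterRecord(
        encounter_id=eid,
        date=dt.date.fromisoformat(date),
        time=dt.time.fromisoformat(time),
        lon=lon,
        lat=lat,
        individuals=ids,
        reported_group_size=len(ids) if all_identified else len(ids) + 1,
        all_identified=all_identified,
        predations=tuple(predations),
    )


def random_daily_records(rng: np.random.Generator, n_ids: int, n_days: int):
    """Random fully-identified daily encounters: each individual in at most
    one group per day (so the simple-ratio denominator assumption holds)."""
    ids = [f"W{k:02d}" for k in range(n_ids)]
    records = []
    eid = 0
    for day in range(n_days):
        date = (dt.date(2020, 1, 1) + dt.timedelta(days=day)).isoformat()
        pool = [i for i in ids if rng.random() < 0.6]
        rng.shuffle(pool)
        while pool:
            size = min(len(pool), 1 + int(rng.integers(1, 4)))
            group, pool = pool[:size], pool[size:]
            eid += 1
            records.append(make_record(f"R{eid}", date, group, time="08:00"))
    return ids, records


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def sri_bruteforce(records, i: str, j: str) -> float:
    """Direct per-pair recount of the simple ratio index from raw records."""
    x = sum(1 for r in records if i in r.individuals and j in r.individuals)
    yi = sum(1 for r in records if i in r.individuals and j not in r.individuals)
    yj = sum(1 for r in records if j in r.individuals and i not in r.individuals)
    denom = x + yi + yj
    return x / denom if denom else 0.0


def modularity_bruteforce(labels: dict, ids, a: np.ndarray) -> float:
    """O(n^2) double-sum modularity: Q = (1/2W) sum_ij [a_ij - s_i s_j / 2W] d(c_i, c_j)."""
    n = len(ids)
    two_w = sum(a[i, j] for i in range(n) for j in range(n) if i != j)
    s = [sum(a[i, j] for j in range(n) if j != i) for i in range(n)]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[ids[i]] == labels[ids[j]]:
                q += a[i, j] - s[i] * s[j] / two_w
    return q / two_w


def dijkstra_oracle(water: np.ndarray, sources, cell: float) -> np.ndarray:
    """Plain heapq multi-source Dijkstra on the 8-connected water grid."""
    nrows, ncols = water.shape
    dist = np.full((nrows, ncols), np.inf)
    heap = []
    for r, c in sources:
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))
    diag = cell * np.sqrt(2.0)
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc in itertools.product((-1, 0, 1), repeat=2):
            if dr == 0 and dc == 0:
                continue
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < nrows and 0 <= c2 < ncols) or not water[r2, c2]:
                continue
            nd = d + (diag if dr and dc else cell)
            if nd < dist[r2, c2]:
                dist[r2, c2] = nd
                heapq.heappush(heap, (nd, r2, c2))
    return dist


def cophenetic_bruteforce(linkage: np.ndarray, n: int) -> np.ndarray:
    """Pairwise merge heights by explicit cluster tracking (condensed order)."""
    members = {k: {k} for k in range(n)}
    heights = np.zeros((n, n))
    for m, (a, b, h, _) in enumerate(linkage):
        sa, sb = members.pop(int(a)), members.pop(int(b))
        for i in sa:
            for j in sb:
                heights[i, j] = heights[j, i] = h
        members[n + m] = sa | sb
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            out.append(heights[i, j])
    return np.array(out)


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_synthetic():
    """One full default-condition synthetic dataset, shared across tests."""
    from orcasoc import synth

    cfg = synth.SimConfig(seed=7)
    grid = synth.make_seascape(cfg)
    registry, truth = synth.simulate_population(cfg)
    records, tracks = synth.simulate_encounters(registry, truth, grid, cfg)
    return cfg, grid, registry, truth, records, tracks


@pytest.fixture(scope="session")
def small_seascape():
    """A small, fast seascape with the default narrowing-shelf geometry."""
    from orcasoc import synth

    cfg = synth.SimConfig(seed=3, nrows=60, ncols=90, cell_size=1000.0,
                          shelf_north_km=50.0, shelf_south_km=12.0)
    return cfg, synth.make_seascape(cfg)
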