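"""Synthetic seascape and two-subpopulation encounter simulator.

Generates ground-truthed data mimicking a coastal transient killer whale
study system: a continental shelf that narrows from north to south, two
latent subpopulations with distinct spatial kernels — an *inner* one
concentrated near shore (lognormal shore distance, median ~2 km) and an
*outer* one centered on the 200 m shelf-break isobath (normal, sd ~5 km) —
matrilineal social units of 2-10 whales (mode 4), daily fission-fusion
grouping with a high within-subpopulation merge rate and a rare
cross-subpopulation merge rate, and spatially heterogeneous detection
(nearshore effort higher than offshore).  Every pipeline stage can be
validated against the returned ground truth.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .encounters import EncounterRecord, Individual
from .seascape import (
    SeascapeGrid,
    classify_cells,
    isobath_distance_field,
    shore_distance_field,
    xy_to_lonlat,
)

__all__ = ["SimConfig", "GroundTruth", "make_seascape", "simulate_population", "simulate_encounters"]

INNER, OUTER = "inner", "outer"

PREY_PMF = {
    # emulating observed predation compositions per subpopulation
    INNER: {
        "harbor_seal": 0.64,
        "harbor_porpoise": 0.21,
        "steller_sea_lion": 0.09,
        "california_sea_lion": 0.03,
        "other": 0.03,
    },
    OUTER: {
        "california_sea_lion": 0.49,
        "gray_whale_calf": 0.20,
        "dolphin": 0.08,
        "elephant_seal": 0.07,
        "other": 0.16,
    },
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic system.

    Spatial units are meters unless suffixed ``_km``.  Probabilities are
    per-day.  ``p_w`` (within-subpopulation merge acceptance) is high and
    ``p_b`` (cross-subpopulation) low, so that mixing is rare (~1% of
    encounters) while subpopulation-level association is dense enough that
    the two communities dominate the modularity landscape.
    """

    seed: int = 0
    # seascape
    nrows: int = 140
    ncols: int = 150
    cell_size: float = 500.0
    coast_cols: int = 6  # land columns along the east edge
    shelf_north_km: float = 50.0  # shelf-break offshore distance at row 0
    shelf_south_km: float = 12.0  # ... at the last row
    offshore_slope_m_per_km: float = 25.0
    canyons: tuple[tuple[int, float, float], ...] = ()  # (row, amplitude_km, width_rows)
    lon0: float = -125.0
    lat0: float = 40.0
    # population
    n_matrilines_per_subpop: int = 20
    matriline_size_n: int = 8  # size = 2 + Binomial(n, p): range 2-10, mode 4
    matriline_size_p: float = 0.25
    roving_male_fraction: float = 0.10
    # optional rarely-present "visitor" matrilines (off by default: whales
    # retained with a bare handful of sightings carry so little association
    # weight that they form spurious satellite communities)
    visitor_fraction: float = 0.0
    visitor_presence: float = 0.02
    # fission-fusion & detection
    n_days: int = 365
    start_date: _dt.date = _dt.date(2020, 1, 1)
    p_w: float = 0.35
    p_b: float = 0.001
    detect_nearshore: float = 0.12
    detect_offshore: float = 0.08
    nearshore_cutoff_km: float = 10.0
    # spatial kernels
    inner_median_shore_km: float = 2.0
    inner_sigma_log: float = 0.6
    outer_sd_shelf_km: float = 5.0
    # reporting artifacts
    duplicate_report_rate: float = 0.08
    predation_rate: float = 0.12

    def __post_init__(self) -> None:
        for p in (self.p_w, self.p_b, self.detect_nearshore, self.detect_offshore,
                  self.visitor_presence, self.duplicate_report_rate, self.predation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.p_b > self.p_w:
            raise ValueError("cross-subpopulation merge rate must not exceed within rate")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["start_date"] = self.start_date.isoformat()
        return hashlib.sha1(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class GroundTruth:
    """Latent state behind the simulated records."""

    subpopulation: dict[str, str]  # individual id -> {inner, outer}
    matriline: dict[str, str]  # individual id -> matriline id
    encounters: list[dict] = field(default_factory=list)  # true group composition & location
    config_hash: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "subpopulation": self.subpopulation,
                    "matriline": self.matriline,
                    "encounters": self.encounters,
                },
                fh,
            )


def make_seascape(config: SimConfig) -> SeascapeGrid:
    """Build the deterministic synthetic elevation grid.

    Land occupies ``coast_cols`` columns along the east edge (+10 m); water
    depth increases linearly from the shoreline, crossing 200 m exactly at
    the per-row shelf-break distance (linear north-to-south narrowing),
    then steepens down the slope.  Optional canyon incisions pull the
    isobath locally shoreward.
    """
    nrows, ncols, cell = config.nrows, config.ncols, config.cell_size
    water_cols = ncols - config.coast_cols
    max_water_km = water_cols * cell / 1000.0
    shelf_km = np.linspace(config.shelf_north_km, config.shelf_south_km, nrows)
    for row, amp_km, width in config.canyons:
        r = np.arange(nrows)
        shelf_km = shelf_km - amp_km * np.exp(-0.5 * ((r - row) / width) ** 2)
    if (shelf_km >= max_water_km).any():
        raise ValueError("shelf-break distance exceeds the water extent of the grid")
    if (shelf_km <= 0).any():
        raise ValueError("canyon incision pushed the shelf break onto land")

    elev = np.full((nrows, ncols), 10.0)
    cols = np.arange(ncols)
    # shore distance (km) of each column measured from the first land column
    s_km = (water_cols - cols) * cell / 1000.0
    for r in range(nrows):
        d = shelf_km[r]
        depth = np.where(
            s_km <= d,
            200.0 * s_km / d,
            200.0 + config.offshore_slope_m_per_km * (s_km - d),
        )
        water = cols < water_cols
        elev[r, water] = -np.minimum(depth[water], 3000.0)
    return SeascapeGrid(origin=(0.0, (nrows - 1) * cell), cell_size=cell, elevation=elev)


def _matriline_size(rng: np.random.Generator, config: SimConfig) -> int:
    # 2 + Binomial(8, 0.25): support 2-10, mode 4, mean 4
    return 2 + int(rng.binomial(config.matriline_size_n, config.matriline_size_p))


def simulate_population(config: SimConfig) -> tuple[list[Individual], GroundTruth]:
    """Sample the registry of matrilines, roving males, and subpopulation labels."""
    rng = np.random.default_rng(config.seed)
    registry: list[Individual] = []
    subpop: dict[str, str] = {}
    matriline: dict[str, str] = {}
    letters = "ABCDEFGHIJ"
    for pop, prefix in ((INNER, "T"), (OUTER, "OCT")):
        for k in range(config.n_matrilines_per_subpop):
            mid = f"{prefix}{k:03d}"
            size = _matriline_size(rng, config)
            for j in range(size):
                wid = f"{mid}{letters[j]}"
                sex = "female" if j == 0 else ("male" if rng.random() < 0.5 else "female")
                registry.append(Individual(id=wid, matriline_id=mid, sex_class=sex))
                subpop[wid] = pop
                matriline[wid] = mid
        n_roving = int(round(config.roving_male_fraction * config.n_matrilines_per_subpop))
        for k in range(n_roving):
            wid = f"{prefix}M{k:02d}"
            registry.append(Individual(id=wid, matriline_id=wid, sex_class="male"))
            subpop[wid] = pop
            matriline[wid] = wid
    truth = GroundTruth(subpopulation=subpop, matriline=matriline, config_hash=config.config_hash())
    return registry, truth


class _Unit:
    """A social unit (matriline or lone male) for daily grouping."""

    __slots__ = ("mid", "members", "pop", "presence")

    def __init__(self, mid: str, members: list[str], pop: str, presence: float):
        self.mid = mid
        self.members = members
        self.pop = pop
        self.presence = presence


def _build_units(registry: list[Individual], truth: GroundTruth, config: SimConfig,
                 rng: np.random.Generator) -> list[_Unit]:
    by_mid: dict[str, list[str]] = {}
    for ind in registry:
        by_mid.setdefault(ind.matriline_id, []).append(ind.id)
    units = []
    for mid, members in by_mid.items():
        pop = truth.subpopulation[members[0]]
        presence = config.visitor_presence if rng.random() < config.visitor_fraction else 1.0
        units.append(_Unit(mid, sorted(members), pop, presence))
    return units


def _row_samplers(grid: SeascapeGrid):
    """Per-row arrays of (cols, shore_km, signed_shelf_km) over water cells."""
    land = classify_cells(grid)
    shore_km = shore_distance_field(grid)
    _, signed_km = isobath_distance_field(grid)
    rows = []
    for r in range(grid.shape[0]):
        cols = np.nonzero(~land[r])[0]
        rows.append((cols, shore_km[r, cols], signed_km[r, cols]))
    return rows


def simulate_encounters(
    registry: list[Individual],
    truth: GroundTruth,
    seascape: SeascapeGrid,
    config: SimConfig,
) -> tuple[list[EncounterRecord], list[np.ndarray]]:
    """Run the daily fission-fusion, placement and detection process.

    Each day the present units are visited in random order; a unit joins the
    first existing group that accepts it (acceptance ``p_w`` within its
    subpopulation, ``p_b`` across), otherwise founds a new group — each
    individual therefore belongs to exactly one group per day.  Each group
    draws a location from its founder subpopulation's spatial kernel (inner:
    lognormal distance to shore; outer: normal signed shelf-break distance),
    and is detected with a nearshore- or offshore-specific probability.
    Detected groups become fully identified :class:`EncounterRecord`s; a
    small fraction is reported twice the same day (later time, same group)
    to exercise daily consolidation.  Survey tracklines are emitted weekly
    for effort grids.  Appends the true composition of every detected group
    to ``truth.encounters``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1717]))
    units = _build_units(registry, truth, config, rng)
    samplers = _row_samplers(seascape)
    nrows = seascape.shape[0]
    records: list[EncounterRecord] = []
    counter = 0

    def draw_location(pop: str) -> tuple[float, float, float]:
        for _ in range(50):
            r = int(rng.integers(0, nrows))
            cols, shore, signed = samplers[r]
            if pop == INNER:
                target = config.inner_median_shore_km * np.exp(rng.normal(0.0, config.inner_sigma_log))
                k = int(np.argmin(np.abs(shore - target)))
                err = abs(shore[k] - target)
            else:
                target = rng.normal(0.0, config.outer_sd_shelf_km)
                finite = np.isfinite(signed)
                if not finite.any():
                    continue
                k = int(np.argmin(np.abs(np.where(finite, signed, np.inf) - target)))
                err = abs(signed[k] - target)
            if err <= 3.0:  # km: accept if the row can realize the target
                x, y = seascape.xy_of(r, cols[k])
                jit = (rng.random(2) - 0.5) * 0.8 * seascape.cell_size
                return float(x + jit[0]), float(y + jit[1]), float(shore[k])
        raise RuntimeError("spatial kernel incompatible with seascape: no water at target distance")

    for day in range(config.n_days):
        date = config.start_date + _dt.timedelta(days=day)
        present = [u for u in units if rng.random() < u.presence]
        rng.shuffle(present)
        groups: list[list[_Unit]] = []
        for unit in present:
            order = rng.permutation(len(groups))
            joined = False
            for gi in order:
                accept = config.p_w if groups[gi][0].pop == unit.pop else config.p_b
                if rng.random() < accept:
                    groups[gi].append(unit)
                    joined = True
                    break
            if not joined:
                groups.append([unit])

        minute_base = 7 * 60
        for group in groups:
            pop = group[0].pop
            x, y, shore_d = draw_location(pop)
            p_det = config.detect_nearshore if shore_d <= config.nearshore_cutoff_km else config.detect_offshore
            if rng.random() >= p_det:
                continue
            members = sorted(m for u in group for m in u.members)
            lon, lat = xy_to_lonlat(x, y, config.lon0, config.lat0)
            minute = minute_base + int(rng.integers(0, 8 * 60))
            predations: tuple[tuple[str, int], ...] = ()
            if rng.random() < config.predation_rate:
                pmf = PREY_PMF[pop]
                species = rng.choice(list(pmf), p=list(pmf.values()))
                predations = ((str(species), 1),)
            counter += 1
            rec = EncounterRecord(
                encounter_id=f"E{counter:06d}",
                date=date,
                time=_dt.time(minute // 60, minute % 60),
                lon=float(lon),
                lat=float(lat),
                individuals=frozenset(members),
                reported_group_size=len(members),
                all_identified=True,
                source=str(rng.choice(["small_vessel", "opportunistic", "ship_survey"], p=[0.3, 0.65, 0.05])),
                predations=predations,
            )
            records.append(rec)
            truth.encounters.append(
                {
                    "encounter_id": rec.encounter_id,
                    "date": date.isoformat(),
                    "members": members,
                    "x": x,
                    "y": y,
                    "subpopulations": sorted({u.pop for u in group}),
                }
            )
            if rng.random() < config.duplicate_report_rate:
                counter += 1
                minute2 = min(minute + int(rng.integers(30, 180)), 23 * 60)
                records.append(
                    EncounterRecord(
                        encounter_id=f"E{counter:06d}",
                        date=date,
                        time=_dt.time(minute2 // 60, minute2 % 60),
                        lon=float(lon) + float(rng.normal(0, 0.002)),
                        lat=float(lat) + float(rng.normal(0, 0.002)),
                        individuals=frozenset(members),
                        reported_group_size=len(members),
                        all_identified=True,
                        source="opportunistic",
                        predations=(),
                    )
                )

    tracks = _survey_tracks(seascape, config, rng)
    return records, tracks


def _survey_tracks(seascape: SeascapeGrid, config: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Weekly alongshore tracklines, biased nearshore like the real effort."""
    nrows, ncols = seascape.shape
    cell = seascape.cell_size
    x_shore = (ncols - config.coast_cols) * cell
    y_max = (nrows - 1) * cell
    tracks = []
    for _ in range(max(1, config.n_days // 7)):
        offset_km = 2.0 * np.exp(rng.normal(0.0, 0.8))  # mostly nearshore
        x = max(cell, x_shore - offset_km * 1000.0)
        y0 = rng.uniform(0.2, 0.8) * y_max
        length = rng.uniform(10_000.0, 40_000.0)
        y1 = np.clip(y0 + rng.choice([-1.0, 1.0]) * length, 0.0, y_max)
        tracks.append(np.array([[x, y0], [x, y1]]))
    return tracks
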