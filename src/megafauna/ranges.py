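"""Species acceptance filters, occurrence cleaning, gap filling and counts.

The curated inventory of extinct or continentally extirpated large mammals is
reduced to the analysis set by mass threshold, direct-dating requirement and
study-window overlap; raw occurrence points are cleaned and snapped to
regions; fossil-record gaps in each species range are filled along
environmentally plausible paths; and the filled presence matrix yields
per-region extinct counts and per-continent tallies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidConfigError

STUDY_WINDOW_BP = (132_000.0, 1_000.0)  # (oldest, youngest) years BP


def filter_species(
    records: pd.DataFrame,
    min_mass_kg: float = 10.0,
    window: tuple[float, float] = STUDY_WINDOW_BP,
    include_uncertain: bool = False,
) -> pd.DataFrame:
    """Subset of species passing the acceptance rules.

    A species is retained iff its status is "accepted" (or "uncertain" when
    ``include_uncertain``), its mass is >= ``min_mass_kg`` (inclusive), it has
    a directly dated record, and its dated interval [latest, earliest]
    intersects the study window.  Species dated entirely younger than the
    window's late bound (losses in the last millennium) are excluded.
    """
    req = {"name", "mass_kg", "status", "direct_date", "earliest_bp", "latest_bp"}
    missing = req - set(records.columns)
    if missing:
        raise InvalidConfigError(f"species table missing columns {sorted(missing)}")
    oldest, youngest = window
    status_ok = records["status"] == "accepted"
    if include_uncertain:
        status_ok |= records["status"] == "uncertain"
    mass_ok = records["mass_kg"] >= min_mass_kg
    dated_ok = records["direct_date"].astype(bool)
    # interval [latest, earliest] (years BP, latest <= earliest) must
    # intersect [youngest, oldest]; bounds inclusive
    window_ok = (records["earliest_bp"] >= youngest) & (records["latest_bp"] <= oldest)
    out = records[status_ok & mass_ok & dated_ok & window_ok]
    if out.empty:
        warnings.warn("no species pass the acceptance filters")
    return out.reset_index(drop=True)


def clean_occurrences(
    points: pd.DataFrame,
    dated_continents: dict[str, set] | None = None,
    continental_species: set | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop erroneous occurrence records; log every drop with a reason code.

    Removes records at exactly (0, 0), captive-flagged records, records on a
    continent where the species has no dated site, and extant-range records
    of continentally extinct species.  Returns (cleaned, drop_log).
    """
    req = {"species", "lon", "lat"}
    missing = req - set(points.columns)
    if missing:
        raise InvalidConfigError(f"occurrence table missing columns {sorted(missing)}")
    dated_continents = dated_continents or {}
    continental_species = continental_species or set()

    reasons = pd.Series("", index=points.index, dtype=object)
    zero = (points["lon"] == 0.0) & (points["lat"] == 0.0)
    reasons[zero] = "zero-coordinate"
    if "captive" in points.columns:
        cap = points["captive"].astype(bool) & (reasons == "")
        reasons[cap] = "captive"
    if "continent" in points.columns and dated_continents:
        off = points.apply(
            lambda r: r["species"] in dated_continents
            and r["continent"] not in dated_continents[r["species"]],
            axis=1,
        ) & (reasons == "")
        reasons[off] = "off-continent"
    if "in_extant_range" in points.columns:
        ext = (
            points["in_extant_range"].astype(bool)
            & points["species"].isin(continental_species)
            & (reasons == "")
        )
        reasons[ext] = "extant-range"

    dropped = reasons != ""
    log = points[dropped].copy()
    log["reason"] = reasons[dropped]
    return points[~dropped].reset_index(drop=True), log.reset_index(drop=True)


def snap_to_nearest_region(
    point: tuple[float, float],
    regions,
    snap_radius_km: float = 50.0,
    geometries: dict | None = None,
) -> int | None:
    """Region containing the point, else the nearest region within the snap
    radius (coastal records displaced by lower glacial sea levels), else None.

    ``point`` is (x_km, y_km) in world coordinates.  With ``geometries``
    (region_id -> shapely geometry) containment and boundary distance are
    exact; otherwise centroids stand in.  Distance ties break toward the
    smallest region id.
    """
    from shapely.geometry import Point

    p = Point(point)
    if geometries:
        best = None
        for rid in sorted(geometries):
            geom = geometries[rid]
            if geom.covers(p):
                return rid
            d = geom.distance(p)
            if best is None or d < best[0] - 1e-12:
                best = (d, rid)
        if best is not None and best[0] <= snap_radius_km:
            return best[1]
        return None
    cents = regions.centroids
    ids = regions.table["region_id"].to_numpy()
    d = np.hypot(cents[:, 0] - point[0], cents[:, 1] - point[1])
    order = np.lexsort((ids, d))
    if d[order[0]] <= snap_radius_km:
        return int(ids[order[0]])
    return None


def region_geometries(regions) -> dict:
    """Shapely polygons of each region's lattice cells (km coordinates)."""
    from shapely.geometry import box
    from shapely.ops import unary_union

    cs = regions.cell_size_km
    out = {}
    rows, cols = regions.membership.shape
    for rid in regions.table["region_id"]:
        cells = np.argwhere(regions.membership == rid)
        out[int(rid)] = unary_union(
            [box(c * cs, r * cs, (c + 1) * cs, (r + 1) * cs) for r, c in cells]
        )
    return out


@dataclass
class FillResult:
    present: set
    provenance: dict  # region_id -> "direct" | "interpolated"
    unfilled_gaps: list  # pairs of components left disconnected


def fill_gaps(
    present: set,
    adjacency: nx.Graph,
    region_env: dict,
    peripheral: set | None = None,
) -> FillResult:
    """Fill fossil-record gaps in one species range.

    (i) Disjoint occupied components are connected along the least-cost path,
    where stepping onto region t costs |env(t) - mean env of the directly
    occupied regions| — the path that best reflects the environmental
    conditions where specimens were recovered.  (ii) Unoccupied regions all
    of whose neighbours are occupied ("holes") are filled, to a fixpoint.
    (iii) Peripheral regions are filled only when explicitly listed.
    Direct presences are never modified.
    """
    present = set(present)
    if not present <= set(adjacency.nodes):
        raise InvalidConfigError("present regions missing from adjacency graph")
    prov = {r: "direct" for r in present}
    filled = set(present)
    unfilled = []

    env_mean = float(np.mean([region_env[r] for r in present])) if present else 0.0

    def step_cost(_u, v, _d) -> float:
        return abs(region_env[v] - env_mean)

    # rule (i): connect disjoint components by least-cost paths
    comps = [set(c) & filled for c in nx.connected_components(adjacency.subgraph(filled))]
    while len(comps) > 1:
        best = None
        for a in range(len(comps)):
            for b in range(a + 1, len(comps)):
                for s in sorted(comps[a]):
                    try:
                        length, path = nx.multi_source_dijkstra(
                            adjacency, {s}, weight=step_cost
                        )
                    except nx.NetworkXNoPath:  # pragma: no cover
                        continue
                    for t in sorted(comps[b]):
                        if t in length and (best is None or length[t] < best[0] - 1e-12):
                            best = (length[t], path[t], a, b)
        if best is None:
            unfilled.append((comps[0], comps[1]))
            break
        _, path, a, b = best
        for r in path:
            if r not in filled:
                filled.add(r)
                prov[r] = "interpolated"
        merged = comps[a] | comps[b] | set(path)
        comps = [c for i, c in enumerate(comps) if i not in (a, b)] + [merged]
        comps = [set(c) & filled for c in nx.connected_components(adjacency.subgraph(filled))]

    # rule (ii): fill holes (all neighbours occupied) to a fixpoint.  A
    # single-neighbour leaf is an edge-of-range case, not a hole, and is
    # only filled through the explicit peripheral list of rule (iii).
    changed = True
    while changed:
        changed = False
        for r in sorted(set(adjacency.nodes) - filled):
            nbrs = list(adjacency.neighbors(r))
            if len(nbrs) >= 2 and all(nb in filled for nb in nbrs):
                filled.add(r)
                prov[r] = "interpolated"
                changed = True

    # rule (iii): explicit peripheral additions only
    for r in sorted(peripheral or set()):
        if r not in filled:
            filled.add(r)
            prov[r] = "interpolated"

    return FillResult(filled, prov, unfilled)


def fill_presence_matrix(
    presence: pd.DataFrame,
    regions,
    region_env: dict,
    peripheral: dict | None = None,
) -> pd.DataFrame:
    """Apply :func:`fill_gaps` to every species of a long-form presence table."""
    peripheral = peripheral or {}
    rows = []
    for sp_name, grp in presence.groupby("species", sort=True):
        res = fill_gaps(
            set(grp["region_id"]),
            regions.adjacency,
            region_env,
            peripheral.get(sp_name),
        )
        rows.extend(
            {"species": sp_name, "region_id": r, "provenance": res.provenance[r]}
            for r in sorted(res.present)
        )
    return pd.DataFrame(rows, columns=["species", "region_id", "provenance"])


def extinction_counts(
    presence: pd.DataFrame, regions
) -> tuple[pd.Series, pd.Series]:
    """Per-region extinct-species counts and per-continent species tallies.

    The continent tally counts species present in at least one region of the
    continent; a species spanning several continents counts on each, so the
    tallies may sum to more than the number of species.
    """
    ids = regions.table["region_id"]
    per_region = (
        presence.groupby("region_id")["species"].nunique().reindex(ids, fill_value=0)
    )
    per_region.name = "extinct_count"
    cont = regions.table.set_index("region_id")["continent"]
    joined = presence.assign(continent=presence["region_id"].map(cont))
    per_continent = joined.groupby("continent")["species"].nunique()
    per_continent.name = "species_count"
    return per_region, per_continent
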