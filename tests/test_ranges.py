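from itertools import chain

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from megafauna.ranges import (
    clean_occurrences,
    extinction_counts,
    fill_gaps,
    fill_presence_matrix,
    filter_species,
    region_geometries,
    snap_to_nearest_region,
)
from megafauna.synthetic import WorldConfig, generate_regions, generate_species_table


def species_frame(masses, **overrides):
    n = len(masses)
    base = {
        "name": [f"s{i}" for i in range(n)],
        "mass_kg": masses,
        "status": ["accepted"] * n,
        "direct_date": [True] * n,
        "earliest_bp": [50_000.0] * n,
        "latest_bp": [12_000.0] * n,
        "scope": ["global"] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestFilterSpecies:
    def test_mass_threshold_inclusive_at_10(self):
        df = species_frame([9.9, 10.0, 44.0, 200.0, 8.0])
        out = filter_species(df, min_mass_kg=10.0)
        assert len(out) == 3
        assert set(out["mass_kg"]) == {10.0, 44.0, 200.0}

    def test_mass_threshold_44(self):
        df = species_frame([9.9, 10.0, 44.0, 200.0, 8.0])
        assert len(filter_species(df, min_mass_kg=44.0)) == 2

    def test_recent_loss_excluded(self):
        # dated only 900 years BP: lost within the last millennium
        df = species_frame([100.0], earliest_bp=[900.0], latest_bp=[600.0])
        with pytest.warns(UserWarning):
            out = filter_species(df)
        assert out.empty

    def test_window_bounds_inclusive(self):
        df = species_frame([100.0, 100.0], earliest_bp=[132_000.0, 1_000.0],
                           latest_bp=[131_000.0, 1_000.0])
        assert len(filter_species(df)) == 2

    def test_undated_excluded(self):
        df = species_frame([100.0], direct_date=[False])
        with pytest.warns(UserWarning):
            assert filter_species(df).empty

    def test_uncertain_flag(self):
        df = species_frame([100.0, 100.0], status=["accepted", "uncertain"])
        assert len(filter_species(df)) == 1
        assert len(filter_species(df, include_uncertain=True)) == 2

    def test_monotone_in_mass(self, small_world):
        sp, _ = generate_species_table(200, small_world, seed=0)
        n10 = len(filter_species(sp, 10.0))
        n44 = len(filter_species(sp, 44.0))
        assert n44 <= n10 <= 200


class TestCleanOccurrences:
    def test_zero_coordinate(self):
        pts = pd.DataFrame({"species": ["a"], "lon": [0.0], "lat": [0.0]})
        kept, log = clean_occurrences(pts)
        assert kept.empty
        assert log["reason"].tolist() == ["zero-coordinate"]

    def test_captive_dropped(self):
        pts = pd.DataFrame(
            {"species": ["a"], "lon": [5.0], "lat": [5.0], "captive": [True]}
        )
        kept, log = clean_occurrences(pts)
        assert kept.empty and log["reason"].tolist() == ["captive"]

    def test_count_conservation(self):
        pts = pd.DataFrame(
            {
                "species": ["a"] * 5,
                "lon": [0.0, 1, 2, 3, 4],
                "lat": [0.0, 1, 2, 3, 4],
                "captive": [False, True, False, False, False],
            }
        )
        kept, log = clean_occurrences(pts)
        assert len(kept) == 3 and len(log) == 2
        assert len(kept) + len(log) == len(pts)

    def test_off_continent_and_extant_range(self):
        pts = pd.DataFrame(
            {
                "species": ["a", "a", "b"],
                "lon": [1.0, 2.0, 3.0],
                "lat": [1.0, 2.0, 3.0],
                "continent": [0, 1, 0],
                "in_extant_range": [False, False, True],
            }
        )
        kept, log = clean_occurrences(
            pts, dated_continents={"a": {0}}, continental_species={"b"}
        )
        assert kept["continent"].tolist() == [0]
        assert sorted(log["reason"]) == ["extant-range", "off-continent"]


@pytest.fixture(scope="module")
def world():
    return generate_regions(
        WorldConfig(n_regions=9, grid_shape=(3, 3), cell_size_km=100.0,
                    continents=1, hominin_map={0: "Homo-origin"})
    )


class TestSnap:
    def test_point_inside(self, world):
        geoms = region_geometries(world)
        rid = world.membership[1, 1]
        assert snap_to_nearest_region((150.0, 150.0), world, geometries=geoms) == rid

    def test_offshore_within_radius(self, world):
        geoms = region_geometries(world)
        # 10 km off the left edge, adjacent to the cell at row 0 col 0
        rid = world.membership[0, 0]
        assert snap_to_nearest_region((-10.0, 50.0), world, snap_radius_km=50.0,
                                      geometries=geoms) == rid

    def test_beyond_radius_dropped(self, world):
        geoms = region_geometries(world)
        assert snap_to_nearest_region((-200.0, 50.0), world, snap_radius_km=50.0,
                                      geometries=geoms) is None

    def test_tie_break_smallest_id(self):
        world = generate_regions(
            WorldConfig(n_regions=8, grid_shape=(1, 8), cell_size_km=100.0,
                        continents=1, hominin_map={0: "Homo-origin"})
        )
        geoms = {2: world_geom(world, 2), 5: world_geom(world, 5)}
        # equidistant from regions 2 and 5 -> smallest id wins
        mid_x = (geoms[2].centroid.x + geoms[5].centroid.x) / 2
        rid = snap_to_nearest_region((mid_x, 200.0), world, snap_radius_km=1e9,
                                     geometries=geoms)
        assert rid == 2


def world_geom(world, rid):
    return region_geometries(world)[rid]


class TestFillGaps:
    @pytest.fixture()
    def chain3(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        return g

    def test_chain_gap_filled(self, chain3):
        env = {"A": 1.0, "B": 1.0, "C": 1.0}
        res = fill_gaps({"A", "C"}, chain3, env)
        assert res.present == {"A", "B", "C"}
        assert res.provenance["B"] == "interpolated"
        assert res.provenance["A"] == "direct"

    def test_hole_filled(self):
        # centre region with all 4 neighbours present
        g = nx.Graph()
        for nb in "NESW":
            g.add_edge("mid", nb)
        g.add_edges_from([("N", "E"), ("E", "S"), ("S", "W"), ("W", "N")])
        env = dict.fromkeys(g.nodes, 0.0)
        res = fill_gaps(set("NESW"), g, env)
        assert "mid" in res.present
        assert res.provenance["mid"] == "interpolated"

    def test_least_cost_path_vs_enumeration(self):
        # two candidate corridors between the occupied ends of a ring
        g = nx.Graph()
        top = ["A", "t1", "t2", "B"]
        bottom = ["A", "b1", "b2", "B"]
        nx.add_path(g, top)
        nx.add_path(g, bottom)
        env = {"A": 0.0, "B": 0.0, "t1": 5.0, "t2": 5.0, "b1": 0.1, "b2": 0.2}
        res = fill_gaps({"A", "B"}, g, env)
        assert res.present == {"A", "B", "b1", "b2"}
        # oracle: exhaustive enumeration of simple paths by total step cost
        best = min(
            nx.all_simple_paths(g, "A", "B"),
            key=lambda p: sum(abs(env[r]) for r in p[1:]),
        )
        assert res.present == {"A", "B"} | set(best[1:-1])

    def test_peripheral_requires_explicit_list(self, chain3):
        env = dict.fromkeys(chain3.nodes, 0.0)
        res = fill_gaps({"A", "B"}, chain3, env)
        assert "C" not in res.present
        res2 = fill_gaps({"A", "B"}, chain3, env, peripheral={"C"})
        assert res2.provenance["C"] == "interpolated"

    def test_disconnected_components_logged(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_edge("C", "D")
        env = dict.fromkeys(g.nodes, 0.0)
        res = fill_gaps({"A", "C"}, g, env)
        assert res.unfilled_gaps
        assert res.present == {"A", "C"}

    def test_monotone_and_idempotent(self, small_world, rng):
        env = {int(r): float(v) for r, v in
               zip(small_world.table["region_id"], rng.uniform(0, 1, small_world.n))}
        nodes = list(small_world.adjacency.nodes)
        present = set(rng.choice(nodes, size=6, replace=False).tolist())
        res = fill_gaps(present, small_world.adjacency, env)
        assert present <= res.present
        res2 = fill_gaps(res.present, small_world.adjacency, env)
        assert res2.present == res.present

    def test_direct_presences_never_modified(self, chain3):
        env = dict.fromkeys(chain3.nodes, 0.0)
        res = fill_gaps({"A", "C"}, chain3, env)
        assert res.provenance["A"] == res.provenance["C"] == "direct"


class TestExtinctionCounts:
    def test_counts_and_multicontinent_tally(self, small_world):
        t = small_world.table
        r_by_cont = {c: g["region_id"].iloc[0] for c, g in t.groupby("continent")}
        presence = pd.DataFrame(
            {
                "species": ["x", "x", "y", "z"],
                "region_id": [r_by_cont[0], r_by_cont[1], r_by_cont[0], r_by_cont[0]],
                "provenance": ["direct"] * 4,
            }
        )
        per_region, per_cont = extinction_counts(presence, small_world)
        assert per_region[r_by_cont[0]] == 3
        assert per_region[r_by_cont[1]] == 1
        # species x spans two continents and counts in both tallies
        assert per_cont[0] == 3 and per_cont[1] == 1
        assert per_cont.sum() > presence["species"].nunique()

    def test_empty_region_zero(self, small_world):
        presence = pd.DataFrame(
            {"species": ["x"], "region_id": [0], "provenance": ["direct"]}
        )
        per_region, _ = extinction_counts(presence, small_world)
        assert (per_region.drop(index=0) == 0).all()

    def test_provenance_accounting(self, small_world, rng):
        sp, pres = generate_species_table(40, small_world, seed=6)
        env = dict(zip(small_world.table["region_id"],
                       rng.uniform(0, 1, small_world.n)))
        filled = fill_presence_matrix(pres, small_world, env)
        assert set(filled["provenance"]) <= {"direct", "interpolated"}
        n_direct = (filled["provenance"] == "direct").sum()
        n_interp = (filled["provenance"] == "interpolated").sum()
        assert n_direct + n_interp == len(filled)
        assert n_direct == len(pres.drop_duplicates(["species", "region_id"]))
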