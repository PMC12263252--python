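from collections import Counter

import numpy as np
import pandas as pd
import pytest

from pteroevo import (DataError, OccupancyTable, RegimeScheme, TraitTable,
                      assign_categories, paint_internal_nodes,
                      randomize_regimes, simulate_island_communities)
from pteroevo.regimes import scheme_from_files, scheme_to_files


def occ_of(mapping):
    rows = [{"area": a, "area_kind": "island", "taxon": t}
            for a, taxa in mapping.items() for t in taxa]
    return OccupancyTable(pd.DataFrame(rows))


class TestAssignCategories:
    def test_three_species_rank_order(self):
        occ = occ_of({"isl": ["a", "b", "c"]})
        tr = TraitTable.from_means({"a": 49.3, "b": 59.0, "c": 70.6})
        s = assign_categories(occ, tr)
        assert s.tip_categories == {"a": "S", "b": "M", "c": "L"}

    def test_two_species_same_band_split(self):
        # both in the middle band; a 3 mm gap exceeds 5% of the global
        # range, so the pair is split into adjacent bands
        occ = occ_of({"isl1": ["a", "b", "c"], "isl2": ["d", "e"]})
        tr = TraitTable.from_means({"a": 40.0, "b": 55.0, "c": 70.0,
                                    "d": 51.0, "e": 54.0})
        s = assign_categories(occ, tr)
        assert s.tip_categories["d"] != s.tip_categories["e"]
        assert {s.tip_categories["d"], s.tip_categories["e"]} == {"S", "M"}

    def test_two_species_overlapping_share_band(self):
        # gap below the threshold: genuine size overlap, same label
        occ = occ_of({"isl1": ["a", "b", "c"], "isl2": ["d", "e"]})
        tr = TraitTable.from_means({"a": 40.0, "b": 55.0, "c": 70.0,
                                    "d": 50.0, "e": 50.5})
        s = assign_categories(occ, tr)
        assert s.tip_categories["d"] == s.tip_categories["e"]

    def test_widespread_modal_category(self):
        areas = {f"isl{i}": ["w", f"x{i}", f"y{i}"] for i in range(5)}
        sizes = {"w": 60.0}
        for i in range(5):
            # w ranks M in four areas, L in one
            if i < 4:
                sizes[f"x{i}"], sizes[f"y{i}"] = 45.0, 75.0
            else:
                sizes[f"x{i}"], sizes[f"y{i}"] = 40.0, 50.0
        s = assign_categories(occ_of(areas), TraitTable.from_means(sizes))
        assert s.tip_categories["w"] == "M"

    def test_isolated_taxon_by_scheme(self):
        occ = occ_of({"isl1": ["a", "b", "c"], "isl2": ["z"]})
        tr = TraitTable.from_means({"a": 45., "b": 55., "c": 65., "z": 50.})
        assert assign_categories(occ, tr, "three_cat").tip_categories["z"] == "M"
        assert assign_categories(occ, tr, "four_cat").tip_categories["z"] == "I"

    def test_modal_tie_errors_unless_option(self):
        areas = {"isl1": ["w", "x1", "y1"], "isl2": ["w", "x2", "y2"]}
        sizes = {"w": 60.0, "x1": 45.0, "y1": 75.0,   # w -> M
                 "x2": 40.0, "y2": 50.0}              # w -> L
        occ, tr = occ_of(areas), TraitTable.from_means(sizes)
        with pytest.raises(DataError, match="tie"):
            assign_categories(occ, tr)
        s = assign_categories(occ, tr, tie_break="prefer_middle")
        assert s.tip_categories["w"] == "M"

    def test_taxon_without_area_errors(self):
        occ = occ_of({"isl": ["a", "b", "c"]})
        tr = TraitTable.from_means({"a": 45., "b": 55., "c": 65., "q": 50.})
        with pytest.raises(DataError, match="no area"):
            assign_categories(occ, tr)

    def test_row_order_invariance(self):
        rows = [{"area": a, "area_kind": "island", "taxon": t}
                for a, taxa in {"i1": ["a", "b", "c"],
                                "i2": ["d", "e"]}.items() for t in taxa]
        tr = TraitTable.from_means({"a": 40., "b": 55., "c": 70.,
                                    "d": 51., "e": 54.})
        s1 = assign_categories(OccupancyTable(pd.DataFrame(rows)), tr)
        s2 = assign_categories(OccupancyTable(pd.DataFrame(rows[::-1])), tr)
        assert s1.tip_categories == s2.tip_categories

    def test_recovers_planted_tiers_exactly(self):
        sizes = {f"t{i:02d}": 38.0 + 1.55 * i for i in range(30)}
        comm = simulate_island_communities(sizes, n_areas=8,
                                           species_per_area=3,
                                           structure="displaced",
                                           min_gap=8.0, seed=7)
        tr = TraitTable.from_means({t: sizes[t]
                                    for t in comm.occupancy.taxa})
        s = assign_categories(comm.occupancy, tr, "three_cat")
        for taxon, tier in comm.planted_tiers.items():
            assert s.tip_categories[taxon] == tier


class TestPainting:
    def test_default_is_medium(self, yule56, scheme4_56):
        painted = paint_internal_nodes(yule56, scheme4_56)
        cats = painted.node_categories(yule56)
        for v in yule56.internal_indices:
            assert cats[int(v)] == "M"

    def test_explicit_category(self, yule56, scheme4_56):
        painted = paint_internal_nodes(yule56, scheme4_56, "L")
        assert painted.internal_category == "L"

    def test_isolated_invalid_for_three_cat(self, yule56, scheme3_56):
        with pytest.raises(DataError):
            paint_internal_nodes(yule56, scheme3_56, "I")


class TestRandomization:
    def test_permute_preserves_counts(self, scheme3_56):
        r = randomize_regimes(scheme3_56, "permute", seed=3)
        assert (Counter(r.tip_categories.values())
                == Counter(scheme3_56.tip_categories.values()))
        assert r.seed == 3

    def test_uniform_frequencies(self, scheme3_56):
        counts = Counter()
        n_sims = 60
        for s in range(n_sims):
            r = randomize_regimes(scheme3_56, "uniform", seed=s)
            counts.update(r.tip_categories.values())
        total = sum(counts.values())
        se = np.sqrt((1 / 3) * (2 / 3) / total)
        for cat in "SML":
            assert abs(counts[cat] / total - 1 / 3) < 3 * se

    def test_same_seed_same_assignment(self, scheme3_56):
        a = randomize_regimes(scheme3_56, "permute", seed=11)
        b = randomize_regimes(scheme3_56, "permute", seed=11)
        assert a.tip_categories == b.tip_categories

    def test_four_cat_never_randomized(self, scheme4_56):
        with pytest.raises(DataError):
            randomize_regimes(scheme4_56, "permute", seed=0)


class TestSerialization:
    def test_round_trip(self, tmp_path, scheme4_56):
        csv, js = tmp_path / "s.csv", tmp_path / "s.json"
        scheme_to_files(scheme4_56, csv, js)
        back = scheme_from_files(csv, js)
        assert back.tip_categories == scheme4_56.tip_categories
        assert back.scheme_id == scheme4_56.scheme_id
        assert back.internal_category == scheme4_56.internal_category
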